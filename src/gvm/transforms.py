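"""Topological transitions as declarative graph transformations.

Cell rearrangements are executed in two steps:

1. **Pattern matching** binds the elements of a local neighbourhood (a
   short edge in state E, a triangle in state T, a six-fold vertex in state
   V) to conventional *roles* ``v1..v3, e1..e9, p1..p10, c1..c5``
   (:func:`match_E`, :func:`match_T`, :func:`match_V`).
2. **Graph transformation** applies a fixed, declarative list of relation
   deletions and signed relation creations expressed in those roles
   (:class:`TransformationGraph`); signs of created relations are resolved
   at apply time from the two contextual-sign rules:

   * a new vertex->edge relation inherits the sign of the vertex it
     replaces: ``s'_{i,j} = s_{k,j}``;
   * a new edge->polygon (or polygon->cell) relation is fixed by requiring
     cycle closure (surface closure) at the shared vertex (edge):
     ``sigma'_{i,j} = -s'_{k,i} s'_{k,l} sigma_{l,j}``.

Roles whose defining elements do not exist are simply left unbound and the
corresponding deletions/creations are skipped.  This *optional-role*
semantics is what makes the 3D edge-to-triangle (ET) transformation reduce
exactly to the planar T1 transition when applied to a 2D tiling: the
triangle roles cannot bind, and the executed sub-transformation is the T1
transformation graph.

Every transition is validated against the topological rules (edge pairs
share at most one vertex, polygon pairs at most one edge, cell pairs at
most one polygon, all closures) on the affected neighbourhood; a violating
transformation is immediately reversed and reported via
:class:`TransformationRejected`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .graph import GVMGraph, MetagraphError, TopologyError
from .geometry import SimulationBox, minimum_image, polygon_centroid, polygon_normal

__all__ = [
    "MatchError",
    "TransformationRejected",
    "MatchedSubgraph",
    "TransformationGraph",
    "AppliedTransformation",
    "T1_TRANSFORMATION", "ET_TRANSFORMATION", "TE_TRANSFORMATION",
    "EV_TRANSFORMATION", "VT_TRANSFORMATION", "TV_TRANSFORMATION",
    "VE_TRANSFORMATION",
    "T1_TO_ET_ROLES",
    "sign_new_vertex_edge", "sign_new_edge_polygon",
    "match_E", "match_T", "match_V", "match_T1",
    "apply_EV", "apply_VT", "apply_TV", "apply_VE",
    "apply_ET", "apply_TE", "apply_T1",
    "rollback",
]


class MatchError(ValueError):
    """The anchor element does not satisfy the pattern ("pattern not matched")."""


class TransformationRejected(RuntimeError):
    """A transformation broke a topological rule and was immediately reversed."""

    def __init__(self, violations: list[str]):
        super().__init__("; ".join(violations))
        self.violations = violations


_LABEL_OF_PREFIX = {"v": "vertex", "e": "edge", "p": "polygon", "c": "cell"}


def _label(role: str) -> str:
    return _LABEL_OF_PREFIX[role[0]]


@dataclass
class MatchedSubgraph:
    """Role -> node-id binding produced by pattern matching."""

    kind: str
    roles: dict[str, int]
    anchor: tuple[str, int]


@dataclass(frozen=True)
class TransformationGraph:
    """Declarative description of one topological transition.

    ``new_nodes`` entries are ``(role, label, pre_existing_partners,
    new_partners)``; a new node is instantiated only when all of its
    pre-existing partner roles are bound and all of its new partner roles
    were themselves instantiated (this implements the dimensional
    reduction of optional roles).  ``creations`` carry a symbolic sign
    expression resolved at apply time: ``("const", v)``, ``("eq6", k)``
    (inherit the prior sign of vertex role ``k`` on the target edge) or
    ``("eq7", k, l)`` (closure at shared element ``k`` with adjacent
    element ``l``).
    """

    kind: str
    deletions: tuple[tuple[str, str], ...]
    creations: tuple[tuple[str, str, tuple], ...]
    new_nodes: tuple[tuple[str, str, tuple, tuple], ...] = ()
    removed_nodes: tuple[str, ...] = ()


@dataclass
class AppliedTransformation:
    """Executed transformation: everything needed to report or reverse it."""

    kind: str
    roles: dict[str, int]
    anchor: tuple[str, int]
    created_nodes: list[tuple[str, int]] = field(default_factory=list)
    deleted_nodes: list[tuple[str, int, dict]] = field(default_factory=list)
    deleted_relations: list = field(default_factory=list)
    created_relations: list = field(default_factory=list)
    role_deletions: list[tuple[str, str]] = field(default_factory=list)
    role_creations: list[tuple[str, str]] = field(default_factory=list)
    pos_old: dict[int, np.ndarray | None] = field(default_factory=dict)

    def transformation_graph(self) -> tuple[set, set]:
        """(role deletions, role creations) actually executed."""
        return set(self.role_deletions), set(self.role_creations)


# ------------------------------------------------------------------ sign rules

def sign_new_vertex_edge(graph: GVMGraph, k_prior_vertex: int, j_edge: int) -> int:
    """Sign for a vertex that replaces ``k_prior_vertex`` on edge ``j_edge``."""
    try:
        return graph.sign(("vertex", k_prior_vertex), ("edge", j_edge))
    except KeyError:
        raise MatchError(
            f"sign source missing: vertex {k_prior_vertex} not on edge {j_edge}"
        ) from None


def sign_new_edge_polygon(graph: GVMGraph, i_edge: int, j_polygon: int,
                          k_vertex: int, l_edge: int) -> int:
    """Sign of a new edge ``i`` in polygon ``j`` by closure at vertex ``k``.

    ``k`` must be shared by edges ``i`` and ``l`` and ``l`` must already lie
    in ``j``; the result makes the oriented cycle of ``j`` close at ``k``.
    """
    try:
        ski = graph.sign(("vertex", k_vertex), ("edge", i_edge))
        skl = graph.sign(("vertex", k_vertex), ("edge", l_edge))
        slj = graph.sign(("edge", l_edge), ("polygon", j_polygon))
    except KeyError:
        raise MatchError("invalid sign context") from None
    return -ski * skl * slj


# ------------------------------------------------------------------- templates

T1_TRANSFORMATION = TransformationGraph(
    kind="T1",
    deletions=(("v1", "e2"), ("v2", "e3"), ("e5", "p3"), ("e5", "p4")),
    creations=(
        ("v1", "e3", ("eq6", "v2")),
        ("v2", "e2", ("eq6", "v1")),
        ("e5", "p1", ("eq7", "v2", "e2")),
        ("e5", "p2", ("eq7", "v1", "e3")),
    ),
)

#: role map identifying the T1 roles inside the ET transformation
T1_TO_ET_ROLES = {"v1": "v1", "v2": "v2", "e1": "e1", "e2": "e2", "e3": "e3",
                  "e4": "e4", "e5": "e7", "p3": "p1", "p4": "p2",
                  "p1": "p4", "p2": "p5"}

ET_TRANSFORMATION = TransformationGraph(
    kind="ET",
    deletions=(("v1", "e2"), ("v1", "e5"), ("v2", "e3"), ("v2", "e6"),
               ("e7", "p1"), ("e7", "p2"), ("e7", "p3")),
    new_nodes=(
        ("v3", "vertex", ("e5", "e6"), ()),
        ("e8", "edge", ("v2", "p6", "p7"), ("v3",)),
        ("e9", "edge", ("v1", "p8", "p9"), ("v3",)),
        ("p10", "polygon", ("c4", "c5"), ("e8", "e9")),
    ),
    creations=(
        ("v1", "e3", ("eq6", "v2")),
        ("v2", "e2", ("eq6", "v1")),
        ("v3", "e5", ("eq6", "v1")),
        ("v3", "e6", ("eq6", "v2")),
        ("v2", "e8", ("const", 1)), ("v3", "e8", ("const", -1)),
        ("v1", "e9", ("const", 1)), ("v3", "e9", ("const", -1)),
        ("e7", "p4", ("eq7", "v2", "e2")),
        ("e7", "p5", ("eq7", "v1", "e3")),
        ("e8", "p6", ("eq7", "v3", "e5")),
        ("e8", "p7", ("eq7", "v3", "e6")),
        ("e9", "p8", ("eq7", "v3", "e5")),
        ("e9", "p9", ("eq7", "v3", "e6")),
        ("e7", "p10", ("const", 1)),
        ("e8", "p10", ("eq7", "v2", "e7")),
        ("e9", "p10", ("eq7", "v1", "e7")),
        ("p10", "c4", ("eq7", "e7", "p4")),
        ("p10", "c5", ("eq7", "e7", "p5")),
    ),
)

TE_TRANSFORMATION = TransformationGraph(
    kind="TE",
    deletions=(("v1", "e3"), ("v1", "e9"), ("v2", "e2"), ("v2", "e8"),
               ("v3", "e5"), ("v3", "e6"), ("v3", "e8"), ("v3", "e9"),
               ("e7", "p4"), ("e7", "p5"), ("e7", "p10"),
               ("e8", "p6"), ("e8", "p7"), ("e8", "p10"),
               ("e9", "p8"), ("e9", "p9"), ("e9", "p10"),
               ("p10", "c4"), ("p10", "c5")),
    creations=(
        ("v1", "e2", ("eq6", "v2")),
        ("v1", "e5", ("eq6", "v3")),
        ("v2", "e3", ("eq6", "v1")),
        ("v2", "e6", ("eq6", "v3")),
        ("e7", "p1", ("eq7", "v2", "e3")),
        ("e7", "p2", ("eq7", "v1", "e2")),
        ("e7", "p3", ("eq7", "v1", "e5")),
    ),
    removed_nodes=("v3", "e8", "e9", "p10"),
)

EV_TRANSFORMATION = TransformationGraph(
    kind="EV",
    deletions=(("v1", "e7"), ("v2", "e7"), ("v2", "e3"), ("v2", "e4"),
               ("v2", "e6"), ("e7", "p1"), ("e7", "p2"), ("e7", "p3")),
    creations=(
        ("v1", "e3", ("eq6", "v2")),
        ("v1", "e4", ("eq6", "v2")),
        ("v1", "e6", ("eq6", "v2")),
    ),
    removed_nodes=("e7", "v2"),
)

VT_TRANSFORMATION = TransformationGraph(
    kind="VT",
    deletions=(("v1", "e2"), ("v1", "e4"), ("v1", "e5"), ("v1", "e6")),
    new_nodes=(
        ("v2", "vertex", ("e2", "e4"), ()),
        ("v3", "vertex", ("e5", "e6"), ()),
        ("e7", "edge", ("p4", "p5"), ("v2",)),
        ("e8", "edge", ("p6", "p7"), ("v2", "v3")),
        ("e9", "edge", ("p8", "p9"), ("v3",)),
        ("p10", "polygon", ("c4", "c5"), ("e7", "e8", "e9")),
    ),
    creations=(
        ("v2", "e2", ("eq6", "v1")),
        ("v2", "e4", ("eq6", "v1")),
        ("v3", "e5", ("eq6", "v1")),
        ("v3", "e6", ("eq6", "v1")),
        ("v1", "e7", ("const", 1)), ("v2", "e7", ("const", -1)),
        ("v2", "e8", ("const", 1)), ("v3", "e8", ("const", -1)),
        ("v1", "e9", ("const", 1)), ("v3", "e9", ("const", -1)),
        ("e7", "p4", ("eq7", "v2", "e2")),
        ("e7", "p5", ("eq7", "v2", "e4")),
        ("e8", "p6", ("eq7", "v3", "e5")),
        ("e8", "p7", ("eq7", "v3", "e6")),
        ("e9", "p8", ("eq7", "v3", "e5")),
        ("e9", "p9", ("eq7", "v3", "e6")),
        ("e7", "p10", ("const", 1)),
        ("e8", "p10", ("eq7", "v2", "e7")),
        ("e9", "p10", ("eq7", "v1", "e7")),
        ("p10", "c4", ("eq7", "e7", "p4")),
        ("p10", "c5", ("eq7", "e7", "p5")),
    ),
)

TV_TRANSFORMATION = TransformationGraph(
    kind="TV",
    deletions=(("v1", "e7"), ("v2", "e7"), ("v2", "e8"), ("v3", "e8"),
               ("v1", "e9"), ("v3", "e9"),
               ("v2", "e2"), ("v2", "e4"), ("v3", "e5"), ("v3", "e6"),
               ("e7", "p4"), ("e7", "p5"), ("e7", "p10"),
               ("e8", "p6"), ("e8", "p7"), ("e8", "p10"),
               ("e9", "p8"), ("e9", "p9"), ("e9", "p10"),
               ("p10", "c4"), ("p10", "c5")),
    creations=(
        ("v1", "e2", ("eq6", "v2")),
        ("v1", "e4", ("eq6", "v2")),
        ("v1", "e5", ("eq6", "v3")),
        ("v1", "e6", ("eq6", "v3")),
    ),
    removed_nodes=("v2", "v3", "e7", "e8", "e9", "p10"),
)

VE_TRANSFORMATION = TransformationGraph(
    kind="VE",
    deletions=(("v1", "e3"), ("v1", "e4"), ("v1", "e6")),
    new_nodes=(
        ("v2", "vertex", ("e3", "e4", "e6"), ()),
        ("e7", "edge", ("p1", "p2", "p3"), ("v2",)),
    ),
    creations=(
        ("v2", "e3", ("eq6", "v1")),
        ("v2", "e4", ("eq6", "v1")),
        ("v2", "e6", ("eq6", "v1")),
        ("v1", "e7", ("const", 1)), ("v2", "e7", ("const", -1)),
        ("e7", "p1", ("eq7", "v2", "e3")),
        ("e7", "p2", ("eq7", "v2", "e4")),
        ("e7", "p3", ("eq7", "v2", "e6")),
    ),
)


# -------------------------------------------------------------------- matching

def _only(items, what: str):
    items = list(items)
    if len(items) != 1:
        raise MatchError(f"pattern not matched: expected one {what}, found {len(items)}")
    return items[0]


def _common_polygons(g: GVMGraph, e1: int, e2: int, exclude=()) -> list[int]:
    return [p for p in g.edge_polygons(e1)
            if p in g.edge_polygons(e2) and p not in exclude]


def _common_cells(g: GVMGraph, p1: int, p2: int) -> list[int]:
    return [c for c in g.polygon_cells(p1) if c in g.polygon_cells(p2)]


def _pick_order(items, rng, override, what):
    items = sorted(items)
    if override is not None:
        if sorted(override) != items:
            raise MatchError(f"pattern not matched: {what} override does not match")
        return list(override)
    if rng is not None:
        items = list(items)
        rng.shuffle(items)
    return items


def match_E(g: GVMGraph, edge: int, rng=None, labeling=None,
            side_order=None) -> MatchedSubgraph:
    """Bind the state-E neighbourhood of a (short) edge.

    ``labeling`` optionally fixes the (v1, v2) choice that is otherwise
    random; ``side_order`` likewise fixes the order of the polygons sharing
    the edge.  In a 2D tiling only the T1 sub-pattern roles bind.
    """
    if edge not in g.edges:
        raise MatchError(f"pattern not matched: no edge {edge}")
    vs = g.edge_vertices(edge)
    if len(vs) != 2:
        raise MatchError("pattern not matched: edge lacks two vertices")
    v1, v2 = _pick_order(vs, rng, labeling, "vertex")
    sides = g.edge_polygons(edge)
    need = 3 if g.dim == 3 else 2
    if len(sides) != need:
        raise MatchError(
            f"pattern not matched: edge {edge} lies in {len(sides)} polygons")
    sides = _pick_order(sides, rng, side_order, "side polygon")
    if len(g.vertex_edges(v1)) != need + 1 or len(g.vertex_edges(v2)) != need + 1:
        raise MatchError("pattern not matched: endpoint degree")
    roles = {"v1": v1, "v2": v2, "e7": edge}
    a_roles = ("e1", "e2", "e5")
    b_roles = ("e3", "e4", "e6")
    a, b = [], []
    for i, p in enumerate(sides):
        roles[f"p{i + 1}"] = p
        pe = set(g.polygon_edges(p))
        a_i = _only((set(g.vertex_edges(v1)) & pe) - {edge}, f"edge of v1 in side {p}")
        b_i = _only((set(g.vertex_edges(v2)) & pe) - {edge}, f"edge of v2 in side {p}")
        roles[a_roles[i]] = a_i
        roles[b_roles[i]] = b_i
        a.append(a_i)
        b.append(b_i)
    pairs = [(0, 1)] if need == 2 else [(0, 1), (1, 2), (0, 2)]
    cap_v1 = ("p4", "p6", "p8")
    cap_v2 = ("p5", "p7", "p9")
    for k, (i, j) in enumerate(pairs):
        roles[cap_v1[k]] = _only(_common_polygons(g, a[i], a[j], exclude=sides),
                                 "cap polygon at v1")
        roles[cap_v2[k]] = _only(_common_polygons(g, b[i], b[j], exclude=sides),
                                 "cap polygon at v2")
    if g.dim == 3:
        c1 = _only(_common_cells(g, roles["p1"], roles["p2"]), "cell of p1,p2")
        c2 = _only(_common_cells(g, roles["p1"], roles["p3"]), "cell of p1,p3")
        c3 = _only(_common_cells(g, roles["p2"], roles["p3"]), "cell of p2,p3")
        c4 = _only(set(g.polygon_cells(roles["p4"])) - {c1}, "end cell at v1")
        c5 = _only(set(g.polygon_cells(roles["p5"])) - {c1}, "end cell at v2")
        caps4 = set(g.cell_polygons(c4))
        caps5 = set(g.cell_polygons(c5))
        if (roles["p6"] not in caps4 or roles["p8"] not in caps4
                or roles["p7"] not in caps5 or roles["p9"] not in caps5
                or len({c1, c2, c3, c4, c5}) != 5):
            raise MatchError("pattern not matched: inconsistent cell neighbourhood")
        roles.update(c1=c1, c2=c2, c3=c3, c4=c4, c5=c5)
    return MatchedSubgraph("E", roles, ("edge", edge))


def match_T(g: GVMGraph, polygon: int, rng=None, labeling=None,
            end_cells=None) -> MatchedSubgraph:
    """Bind the state-T neighbourhood of a triangular polygon (3D)."""
    if polygon not in g.polygons:
        raise MatchError(f"pattern not matched: no polygon {polygon}")
    tri_edges = g.polygon_edges(polygon)
    if len(tri_edges) != 3:
        raise MatchError("pattern not matched: polygon is not a triangle")
    if g.dim != 3:
        raise MatchError("pattern not matched: TE requires a 3D graph")
    tri_vs = g.polygon_vertex_cycle(polygon)
    v1, v2, v3 = _pick_order(tri_vs, rng, labeling, "triangle vertex")

    def tri_edge(a_, b_):
        return _only(set(g.vertex_edges(a_)) & set(g.vertex_edges(b_)) & set(tri_edges),
                     "triangle edge")

    e7, e8, e9 = tri_edge(v1, v2), tri_edge(v2, v3), tri_edge(v1, v3)
    c4, c5 = _pick_order(g.polygon_cells(polygon), rng, end_cells, "cell of triangle")
    if len({c4, c5}) != 2:
        raise MatchError("pattern not matched: triangle without two cells")
    caps4 = set(g.cell_polygons(c4))
    caps5 = set(g.cell_polygons(c5))
    roles = {"v1": v1, "v2": v2, "v3": v3, "e7": e7, "e8": e8, "e9": e9,
             "p10": polygon, "c4": c4, "c5": c5}
    for e_role, p4_role, p5_role in (("e7", "p4", "p5"), ("e8", "p6", "p7"),
                                     ("e9", "p8", "p9")):
        others = set(g.edge_polygons(roles[e_role])) - {polygon}
        if len(others) != 2:
            raise MatchError("pattern not matched: triangle edge polygon count")
        roles[p4_role] = _only(others & caps4, "cap polygon in c4")
        roles[p5_role] = _only(others & caps5, "cap polygon in c5")
    for v, e_in_c4, e_in_c5, caps_c4 in (
            (v1, "e1", "e3", ("p4", "p8")),
            (v2, "e2", "e4", ("p4", "p6")),
            (v3, "e5", "e6", ("p6", "p8"))):
        spare = set(g.vertex_edges(v)) - {e7, e8, e9}
        if len(spare) != 2:
            raise MatchError("pattern not matched: triangle vertex degree")
        cap = set(g.polygon_edges(roles[caps_c4[0]]))
        roles[e_in_c4] = _only(spare & cap, "spare edge on c4 side")
        roles[e_in_c5] = _only(spare - {roles[e_in_c4]}, "spare edge on c5 side")
    roles["p1"] = _only(_common_polygons(g, roles["e1"], roles["e3"]), "side p1")
    roles["p2"] = _only(_common_polygons(g, roles["e2"], roles["e4"]), "side p2")
    roles["p3"] = _only(_common_polygons(g, roles["e5"], roles["e6"]), "side p3")
    roles["c1"] = _only(_common_cells(g, roles["p1"], roles["p2"]), "cell c1")
    roles["c2"] = _only(_common_cells(g, roles["p1"], roles["p3"]), "cell c2")
    roles["c3"] = _only(_common_cells(g, roles["p2"], roles["p3"]), "cell c3")
    return MatchedSubgraph("T", roles, ("polygon", polygon))


def admissible_partitions(g: GVMGraph, vertex: int) -> list[tuple[int, int, int]]:
    """Triples of polygons at a 6-fold vertex whose edge pairs partition it."""
    ves = set(g.vertex_edges(vertex))
    cand = {}
    for e in ves:
        for p in g.edge_polygons(e):
            pair = frozenset(set(g.polygon_edges(p)) & ves)
            if len(pair) == 2:
                cand[p] = pair
    out = []
    ps = sorted(cand)
    for i, pa in enumerate(ps):
        for j in range(i + 1, len(ps)):
            pb = ps[j]
            if cand[pa] & cand[pb]:
                continue
            for k in range(j + 1, len(ps)):
                pc = ps[k]
                if len(cand[pa] | cand[pb] | cand[pc]) == 6:
                    out.append((pa, pb, pc))
    return out


def match_V(g: GVMGraph, vertex: int, rng=None, partition=None,
            end_cells=None) -> MatchedSubgraph:
    """Bind the state-V neighbourhood of a six-fold vertex.

    The resolution direction is fixed either by ``partition`` (three
    polygons whose vertex-edge pairs partition the six edges; used by the
    vertex-to-triangle transition) or by ``end_cells`` (the two cells that
    the new edge of a vertex-to-edge transition will point into, which
    determines the partition as the polygons shared with neither cell).
    With neither given, a seeded-random admissible partition is chosen.
    """
    if vertex not in g.vertices:
        raise MatchError(f"pattern not matched: no vertex {vertex}")
    ves = set(g.vertex_edges(vertex))
    if len(ves) != 6:
        raise MatchError("pattern not matched: V state requires a 6-fold vertex")
    if partition is None and end_cells is not None:
        cA, cB = end_cells
        excl = set(g.cell_polygons(cA)) | set(g.cell_polygons(cB))
        polys = {p for e in ves for p in g.edge_polygons(e)}
        partition = tuple(sorted(polys - excl))
        if len(partition) != 3:
            raise MatchError("pattern not matched: end cells do not define a partition")
    options = admissible_partitions(g, vertex)
    if not options:
        raise MatchError("pattern not matched: no admissible resolution partition")
    if partition is not None:
        key = tuple(sorted(partition))
        if key not in options:
            raise MatchError("pattern not matched: partition not admissible")
        chosen = list(partition)
    else:
        idx = rng.integers(len(options)) if rng is not None else 0
        chosen = list(options[int(idx)])
        if rng is not None:
            rng.shuffle(chosen)
    p1, p2, p3 = chosen
    pair1 = sorted(set(g.polygon_edges(p1)) & ves)
    pair2 = sorted(set(g.polygon_edges(p2)) & ves)
    pair3 = sorted(set(g.polygon_edges(p3)) & ves)
    if rng is not None:
        rng.shuffle(pair1)
    e1, e3 = pair1
    # orient pair2 and pair3 so the cap polygons exist
    caps12 = [(x, _common_polygons(g, e1, x, exclude=chosen)) for x in pair2]
    caps12 = [(x, ps) for x, ps in caps12 if len(ps) == 1]
    e2, (p4,) = _only(caps12, "cap polygon p4")
    e4 = _only(set(pair2) - {e2}, "edge e4")
    p5 = _only(_common_polygons(g, e3, e4, exclude=chosen), "cap polygon p5")
    caps23 = [(x, _common_polygons(g, e2, x, exclude=chosen)) for x in pair3]
    caps23 = [(x, ps) for x, ps in caps23 if len(ps) == 1]
    e5, (p6,) = _only(caps23, "cap polygon p6")
    e6 = _only(set(pair3) - {e5}, "edge e6")
    p7 = _only(_common_polygons(g, e4, e6, exclude=chosen), "cap polygon p7")
    p8 = _only(_common_polygons(g, e1, e5, exclude=chosen), "cap polygon p8")
    p9 = _only(_common_polygons(g, e3, e6, exclude=chosen), "cap polygon p9")
    roles = {"v1": vertex, "e1": e1, "e2": e2, "e3": e3, "e4": e4, "e5": e5,
             "e6": e6, "p1": p1, "p2": p2, "p3": p3, "p4": p4, "p5": p5,
             "p6": p6, "p7": p7, "p8": p8, "p9": p9}
    if g.dim == 3:
        c1 = _only(_common_cells(g, p1, p2), "cell c1")
        c2 = _only(_common_cells(g, p1, p3), "cell c2")
        c3 = _only(_common_cells(g, p2, p3), "cell c3")
        c4 = _only(set(g.polygon_cells(p4)) - {c1}, "end cell c4")
        c5 = _only(set(g.polygon_cells(p5)) - {c1}, "end cell c5")
        if (p6 not in g.cell_polygons(c4) or p8 not in g.cell_polygons(c4)
                or p7 not in g.cell_polygons(c5) or p9 not in g.cell_polygons(c5)):
            raise MatchError("pattern not matched: inconsistent cell neighbourhood")
        if end_cells is not None and {c4, c5} != set(end_cells):
            raise MatchError("pattern not matched: end cells inconsistent")
        if end_cells is not None and c4 != end_cells[0]:
            # flip the two ends so c4 is the requested first cell
            roles.update({"e1": e3, "e3": e1, "e2": e4, "e4": e2, "e5": e6,
                          "e6": e5, "p4": p5, "p5": p4, "p6": p7, "p7": p6,
                          "p8": p9, "p9": p8})
            c4, c5 = c5, c4
        roles.update(c1=c1, c2=c2, c3=c3, c4=c4, c5=c5)
    return MatchedSubgraph("V", roles, ("vertex", vertex))


def match_T1(g: GVMGraph, edge: int, rng=None, labeling=None,
             side_order=None) -> MatchedSubgraph:
    """Bind the planar T1 neighbourhood of an edge of a 2D tiling."""
    if g.dim != 2:
        raise MatchError("pattern not matched: T1 requires a 2D graph")
    if edge not in g.edges:
        raise MatchError(f"pattern not matched: no edge {edge}")
    vs = g.edge_vertices(edge)
    if len(vs) != 2:
        raise MatchError("pattern not matched: edge lacks two vertices")
    v1, v2 = _pick_order(vs, rng, labeling, "vertex")
    sides = g.edge_polygons(edge)
    if len(sides) != 2:
        raise MatchError(
            f"pattern not matched: edge {edge} lies in {len(sides)} polygons")
    p3, p4 = _pick_order(sides, rng, side_order, "side polygon")
    e1 = _only((set(g.vertex_edges(v1)) & set(g.polygon_edges(p3))) - {edge}, "e1")
    e2 = _only((set(g.vertex_edges(v1)) & set(g.polygon_edges(p4))) - {edge}, "e2")
    e3 = _only((set(g.vertex_edges(v2)) & set(g.polygon_edges(p3))) - {edge}, "e3")
    e4 = _only((set(g.vertex_edges(v2)) & set(g.polygon_edges(p4))) - {edge}, "e4")
    p1 = _only(_common_polygons(g, e1, e2, exclude=(p3, p4)), "far polygon p1")
    p2 = _only(_common_polygons(g, e3, e4, exclude=(p3, p4)), "far polygon p2")
    roles = {"v1": v1, "v2": v2, "e1": e1, "e2": e2, "e3": e3, "e4": e4,
             "e5": edge, "p1": p1, "p2": p2, "p3": p3, "p4": p4}
    return MatchedSubgraph("T1", roles, ("edge", edge))


# -------------------------------------------------------------------- executor

def _lookup_sign(g: GVMGraph, roles, assigned, r1: str, r2: str) -> int:
    if (r1, r2) in assigned:
        return assigned[(r1, r2)]
    return g.sign((_label(r1), roles[r1]), (_label(r2), roles[r2]))


def execute_transformation(g: GVMGraph, tg: TransformationGraph,
                           match: MatchedSubgraph) -> AppliedTransformation:
    """Apply a transformation graph to a matched subgraph (no validation).

    Deletions/creations whose roles are unbound are skipped; new nodes are
    instantiated only when their pre-existing partner roles are all bound.
    Raises :class:`MetagraphError` on structurally impossible operations
    (caller is expected to roll back).
    """
    roles = dict(match.roles)
    rec = AppliedTransformation(kind=tg.kind, roles=roles, anchor=match.anchor)
    created = set()
    for role, label, pre, newp in tg.new_nodes:
        if all(r in roles for r in pre) and all(r in created for r in newp):
            nid = g.add_node(label)
            roles[role] = nid
            created.add(role)
            rec.created_nodes.append((label, nid))
    # resolve all creation signs against the pre-transformation graph
    assigned: dict[tuple[str, str], int] = {}
    concrete = []
    for r1, r2, expr in tg.creations:
        if r1 not in roles or r2 not in roles:
            continue
        op = expr[0]
        if op == "const":
            val = expr[1]
        elif op == "eq6":
            k = expr[1]
            val = _lookup_sign(g, roles, assigned, k, r2)
        elif op == "eq7":
            k, l = expr[1], expr[2]
            val = (-_lookup_sign(g, roles, assigned, k, r1)
                   * _lookup_sign(g, roles, assigned, k, l)
                   * _lookup_sign(g, roles, assigned, l, r2))
        else:  # pragma: no cover
            raise ValueError(f"unknown sign expression {expr!r}")
        assigned[(r1, r2)] = val
        concrete.append((r1, r2, val))
    for r1, r2 in tg.deletions:
        if r1 not in roles or r2 not in roles:
            continue
        src = (_label(r1), roles[r1])
        tgt = (_label(r2), roles[r2])
        sign = g.delete_relation(src, tgt)
        rec.deleted_relations.append((src, tgt, sign))
        rec.role_deletions.append((r1, r2))
    for r1, r2, val in concrete:
        src = (_label(r1), roles[r1])
        tgt = (_label(r2), roles[r2])
        g.add_relation(src, tgt, val)
        rec.created_relations.append((src, tgt, val))
        rec.role_creations.append((r1, r2))
    for role in tg.removed_nodes:
        if role not in roles:
            continue
        label = _label(role)
        nid = roles[role]
        props = dict(g.nodes(label)[nid])
        g.delete_node(label, nid)
        rec.deleted_nodes.append((label, nid, props))
    return rec


def rollback(g: GVMGraph, rec: AppliedTransformation, positions=None) -> None:
    """Reverse an applied transformation exactly (topology and positions)."""
    for src, tgt, _sign in reversed(rec.created_relations):
        g.delete_relation(src, tgt)
    for label, nid in reversed(rec.created_nodes):
        g.delete_node(label, nid)
    for label, nid, props in rec.deleted_nodes:
        g.add_node(label, nid, **props)
    for src, tgt, sign in rec.deleted_relations:
        g.add_relation(src, tgt, sign)
    if positions is not None:
        for vid, old in rec.pos_old.items():
            if old is None:
                positions.pop(vid, None)
            else:
                positions[vid] = np.asarray(old, dtype=float)
        rec.pos_old.clear()


def _role_sets(g, roles):
    polys = {roles[r] for r in roles if r[0] == "p" and roles[r] in g.polygons}
    cells = {roles[r] for r in roles if r[0] == "c" and roles[r] in g.cells}
    edges = {roles[r] for r in roles if r[0] == "e" and roles[r] in g.edges}
    return polys, cells, edges


def _local_report(g, roles):
    """(violations, polygons that are not single cycles) for a role map."""
    polys, cells, edges = _role_sets(g, roles)
    viol = set(g.validate_local(polys, cells, edges))
    cycle_fail = set()
    for p in polys:
        try:
            g.polygon_vertex_cycle(p)
        except Exception:
            cycle_fail.add(p)
    return viol, cycle_fail


def _check_and_maybe_rollback(g, rec, positions, check, pre_report):
    """Reject a transformation that introduced *new* rule violations.

    Violations already present before the transformation (open patch
    boundaries of the printed fixtures, the double square-face adjacency of
    very small periodic crystals) are not held against it.
    """
    if not check:
        return
    pre_viol, pre_cyc = pre_report
    post_viol, post_cyc = _local_report(g, rec.roles)
    new = sorted(post_viol - pre_viol)
    new += [f"polygon {p} is not a single cycle" for p in sorted(post_cyc - pre_cyc)]
    if new:
        rollback(g, rec, positions)
        raise TransformationRejected(new)


# ------------------------------------------------------------------ positions

def _record_move(rec, positions, vid, new):
    if vid not in rec.pos_old:
        rec.pos_old[vid] = (np.array(positions[vid], dtype=float)
                            if vid in positions else None)
    positions[vid] = np.asarray(new, dtype=float)


def _drop_position(rec, positions, vid):
    if vid in positions:
        if vid not in rec.pos_old:
            rec.pos_old[vid] = np.array(positions[vid], dtype=float)
        del positions[vid]


def _perp_basis(n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t1 = np.cross(n, a)
    t1 /= np.linalg.norm(t1)
    return t1, np.cross(n, t1)


def _triangle_placement(mid, n, dirs, l_new):
    """Place three vertices on an equilateral triangle of edge l_new.

    The triangle lies in the plane through ``mid`` perpendicular to ``n``;
    the vertices sit at snapped 120-degree angles chosen to point as close
    as possible toward the requested directions ``dirs`` (one per vertex),
    preserving their cyclic order.
    """
    t1, t2 = _perp_basis(n)
    theta = []
    for d in dirs:
        x, y = float(d @ t1), float(d @ t2)
        theta.append(math.atan2(y, x) if (x * x + y * y) > 1e-24 else 0.0)
    # best common phase for snapped angles preserving the cyclic order
    order = sorted(range(3), key=lambda i: theta[i])
    z = sum(np.exp(1j * (theta[order[k]] - 2 * np.pi * k / 3)) for k in range(3))
    phi0 = np.angle(z)
    rho = l_new / math.sqrt(3.0)
    out = [None, None, None]
    for k in range(3):
        ang = phi0 + 2 * np.pi * k / 3
        out[order[k]] = mid + rho * (math.cos(ang) * t1 + math.sin(ang) * t2)
    return out


# ------------------------------------------------------------------ public API

def _as_match(g, anchor, matcher, match, rng, **kw):
    if match is not None:
        return match
    return matcher(g, anchor, rng=rng, **kw)


def apply_T1(g: GVMGraph, edge: int | None = None, *, match=None, positions=None,
             box: SimulationBox | None = None, l_new: float = 0.05, rng=None,
             check: bool = True) -> AppliedTransformation:
    """Neighbour exchange on an edge of a 2D polygonal tiling."""
    m = _as_match(g, edge, match_T1, match, rng)
    pre = {}
    if positions is not None:
        try:
            r1 = np.asarray(positions[m.roles["v1"]], dtype=float)
            r2 = np.asarray(positions[m.roles["v2"]], dtype=float)
            d = minimum_image(r2 - r1, box)
            pre["mid"] = r1 + 0.5 * d
            pre["cen3"] = polygon_centroid(g, positions, box, m.roles["p3"], 1.0)
            pre["cen4"] = polygon_centroid(g, positions, box, m.roles["p4"], 1.0)
        except TopologyError as err:
            raise TransformationRejected([f"geometry: {err}"]) from None
    pre_report = _local_report(g, m.roles) if check else (set(), set())
    try:
        rec = execute_transformation(g, T1_TRANSFORMATION, m)
    except MetagraphError as err:
        raise TransformationRejected([str(err)]) from None
    if positions is not None:
        for vr, cen in (("v1", pre["cen3"]), ("v2", pre["cen4"])):
            u = minimum_image(cen - pre["mid"], box)
            nrm = np.linalg.norm(u)
            if nrm < 1e-12:
                u = _random_unit(rng)
            else:
                u = u / nrm
            _record_move(rec, positions, m.roles[vr], pre["mid"] + 0.5 * l_new * u)
    _check_and_maybe_rollback(g, rec, positions, check, pre_report)
    return rec


def _random_unit(rng) -> np.ndarray:
    if rng is None:
        return np.array([1.0, 0.0, 0.0])
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def apply_ET(g: GVMGraph, edge: int | None = None, *, match=None, positions=None,
             box: SimulationBox | None = None, l_new: float = 0.05, rng=None,
             check: bool = True) -> AppliedTransformation:
    """Edge-to-triangle transition (reduces to a T1 on a 2D tiling).

    The vanished edge's id is retained as one of the triangle edges; in 3D
    the new triangle is placed in the plane through the old edge midpoint,
    perpendicular to the old edge direction, with each new vertex displaced
    toward (the projection of) the centroid of its side polygon.
    """
    m = _as_match(g, edge, match_E, match, rng)
    pre = {}
    if positions is not None:
        try:
            r1 = np.asarray(positions[m.roles["v1"]], dtype=float)
            r2 = np.asarray(positions[m.roles["v2"]], dtype=float)
            d = minimum_image(r2 - r1, box)
            pre["mid"] = r1 + 0.5 * d
            nn = np.linalg.norm(d)
            pre["n"] = d / nn if nn > 1e-12 else _random_unit(rng)
            for pr in ("p1", "p2", "p3"):
                if pr in m.roles:
                    pre[pr] = polygon_centroid(g, positions, box, m.roles[pr], 1.0)
        except TopologyError as err:
            raise TransformationRejected([f"geometry: {err}"]) from None
    pre_report = _local_report(g, m.roles) if check else (set(), set())
    try:
        rec = execute_transformation(g, ET_TRANSFORMATION, m)
    except MetagraphError as err:
        raise TransformationRejected([str(err)]) from None
    if positions is not None:
        mid, n = pre["mid"], pre["n"]
        if "v3" in rec.roles and rec.roles.get("v3") in g.vertices:
            dirs = [minimum_image(pre[pr] - mid, box) for pr in ("p1", "p2", "p3")]
            pts = _triangle_placement(mid, n, dirs, l_new)
            for vr, pt in zip(("v1", "v2", "v3"), pts):
                _record_move(rec, positions, rec.roles[vr], pt)
        else:  # 2D reduction: plain T1 placement
            for vr, pr, sgn in (("v1", "p1", 1.0), ("v2", "p2", 1.0)):
                u = minimum_image(pre[pr] - mid, box)
                u = u - (u @ n) * n
                nrm = np.linalg.norm(u)
                u = u / nrm if nrm > 1e-12 else _random_unit(rng)
                _record_move(rec, positions, rec.roles[vr], mid + 0.5 * l_new * u)
    _check_and_maybe_rollback(g, rec, positions, check, pre_report)
    return rec


def apply_TE(g: GVMGraph, triangle: int | None = None, *, match=None,
             positions=None, box: SimulationBox | None = None,
             l_new: float = 0.05, rng=None, check: bool = True) -> AppliedTransformation:
    """Triangle-to-edge transition: the cells sharing the triangle separate."""
    m = _as_match(g, triangle, match_T, match, rng)
    pre = {}
    if positions is not None:
        try:
            pre["cen"] = polygon_centroid(g, positions, box, m.roles["p10"], 1.0)
            nrm = polygon_normal(g, positions, box, m.roles["p10"], 1.0)
            # v1 ends on the c4 side; Sigma=+1 means the normal points away from c4
            pre["dir4"] = -nrm * g.sign(("polygon", m.roles["p10"]),
                                        ("cell", m.roles["c4"]))
        except TopologyError as err:
            raise TransformationRejected([f"geometry: {err}"]) from None
    pre_report = _local_report(g, m.roles) if check else (set(), set())
    try:
        rec = execute_transformation(g, TE_TRANSFORMATION, m)
    except MetagraphError as err:
        raise TransformationRejected([str(err)]) from None
    if positions is not None:
        _record_move(rec, positions, rec.roles["v1"],
                     pre["cen"] + 0.5 * l_new * pre["dir4"])
        _record_move(rec, positions, rec.roles["v2"],
                     pre["cen"] - 0.5 * l_new * pre["dir4"])
        _drop_position(rec, positions, rec.roles["v3"])
    _check_and_maybe_rollback(g, rec, positions, check, pre_report)
    return rec


def apply_EV(g: GVMGraph, edge: int | None = None, *, match=None, positions=None,
             box: SimulationBox | None = None, rng=None,
             check: bool = True) -> AppliedTransformation:
    """Edge-to-vertex merge; the merged vertex keeps the v1 role id."""
    m = _as_match(g, edge, match_E, match, rng)
    pre = {}
    if positions is not None:
        r1 = np.asarray(positions[m.roles["v1"]], dtype=float)
        r2 = np.asarray(positions[m.roles["v2"]], dtype=float)
        pre["mid"] = r1 + 0.5 * minimum_image(r2 - r1, box)
    pre_report = _local_report(g, m.roles) if check else (set(), set())
    try:
        rec = execute_transformation(g, EV_TRANSFORMATION, m)
    except MetagraphError as err:
        raise TransformationRejected([str(err)]) from None
    if positions is not None:
        _record_move(rec, positions, rec.roles["v1"], pre["mid"])
        _drop_position(rec, positions, rec.roles["v2"])
    _check_and_maybe_rollback(g, rec, positions, check, pre_report)
    return rec


def apply_VT(g: GVMGraph, vertex: int | None = None, *, match=None,
             partition=None, positions=None, box: SimulationBox | None = None,
             l_new: float = 0.05, rng=None, check: bool = True) -> AppliedTransformation:
    """Vertex-to-triangle resolution of a six-fold vertex.

    The resolution direction (which edge pairs merge onto which new vertex)
    is the partition of the six edges induced by three mutually disjoint
    polygons; pass ``partition`` to fix it (an edge-to-triangle composite
    uses the side polygons of the vanished edge), otherwise a seeded-random
    admissible partition is drawn.
    """
    if match is None:
        match = match_V(g, vertex, rng=rng, partition=partition)
    m = match
    pre = {}
    if positions is not None:
        try:
            mid = np.asarray(positions[m.roles["v1"]], dtype=float)
            pre["mid"] = mid
            dirs = []
            for pr in ("p1", "p2", "p3"):
                cen = polygon_centroid(g, positions, box, m.roles[pr], 1.0)
                dirs.append(minimum_image(cen - mid, box))
            pre["dirs"] = dirs
            n = np.cross(dirs[1] - dirs[0], dirs[2] - dirs[0])
            nn = np.linalg.norm(n)
            pre["n"] = n / nn if nn > 1e-12 else _random_unit(rng)
        except TopologyError as err:
            raise TransformationRejected([f"geometry: {err}"]) from None
    pre_report = _local_report(g, m.roles) if check else (set(), set())
    try:
        rec = execute_transformation(g, VT_TRANSFORMATION, m)
    except MetagraphError as err:
        raise TransformationRejected([str(err)]) from None
    if positions is not None:
        pts = _triangle_placement(pre["mid"], pre["n"], pre["dirs"], l_new)
        for vr, pt in zip(("v1", "v2", "v3"), pts):
            _record_move(rec, positions, rec.roles[vr], pt)
    _check_and_maybe_rollback(g, rec, positions, check, pre_report)
    return rec


def apply_TV(g: GVMGraph, triangle: int | None = None, *, match=None,
             positions=None, box: SimulationBox | None = None, rng=None,
             check: bool = True) -> AppliedTransformation:
    """Triangle-to-vertex merge; the merged vertex keeps the v1 role id."""
    m = _as_match(g, triangle, match_T, match, rng)
    pre = {}
    if positions is not None:
        try:
            pre["cen"] = polygon_centroid(g, positions, box, m.roles["p10"], 1.0)
        except TopologyError as err:
            raise TransformationRejected([f"geometry: {err}"]) from None
    pre_report = _local_report(g, m.roles) if check else (set(), set())
    try:
        rec = execute_transformation(g, TV_TRANSFORMATION, m)
    except MetagraphError as err:
        raise TransformationRejected([str(err)]) from None
    if positions is not None:
        _record_move(rec, positions, rec.roles["v1"], pre["cen"])
        _drop_position(rec, positions, rec.roles["v2"])
        _drop_position(rec, positions, rec.roles["v3"])
    _check_and_maybe_rollback(g, rec, positions, check, pre_report)
    return rec


def apply_VE(g: GVMGraph, vertex: int | None = None, *, match=None,
             end_cells=None, positions=None, box: SimulationBox | None = None,
             l_new: float = 0.05, rng=None, check: bool = True) -> AppliedTransformation:
    """Vertex-to-edge resolution of a six-fold vertex.

    ``end_cells=(cA, cB)`` selects the two cells the new edge will point
    into (the inverse of an edge-to-vertex merge whose end cells they
    were); v1 stays on the cA side.
    """
    if match is None:
        match = match_V(g, vertex, rng=rng, end_cells=end_cells)
    m = match
    pre = {}
    if positions is not None:
        try:
            mid = np.asarray(positions[m.roles["v1"]], dtype=float)
            pre["mid"] = mid
            acc = np.zeros(3)
            for pr in ("p4", "p6", "p8"):
                cen = polygon_centroid(g, positions, box, m.roles[pr], 1.0)
                d = minimum_image(cen - mid, box)
                nrm = np.linalg.norm(d)
                if nrm > 1e-12:
                    acc += d / nrm
            nrm = np.linalg.norm(acc)
            pre["dir"] = acc / nrm if nrm > 1e-12 else _random_unit(rng)
        except TopologyError as err:
            raise TransformationRejected([f"geometry: {err}"]) from None
    pre_report = _local_report(g, m.roles) if check else (set(), set())
    try:
        rec = execute_transformation(g, VE_TRANSFORMATION, m)
    except MetagraphError as err:
        raise TransformationRejected([str(err)]) from None
    if positions is not None:
        mid, u = pre["mid"], pre["dir"]
        l_new_half = 0.5 * l_new
        _record_move(rec, positions, rec.roles["v1"], mid + l_new_half * u)
        _record_move(rec, positions, rec.roles["v2"], mid - l_new_half * u)
    _check_and_maybe_rollback(g, rec, positions, check, pre_report)
    return rec
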