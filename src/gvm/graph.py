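"""Signed-incidence property graph storing the topology of a cell aggregate.

The topology of a space-filling packing of polyhedral cells lives in a
four-level hierarchy of elements::

    Vertex -> Edge -> Polygon -> Cell

connected by directed *is-part-of* relations.  Each relation carries a sign
in {-1, +1} that places the source element in the context of the target:

* vertex->edge  (``s``):      +1 head vertex, -1 tail vertex;
* edge->polygon (``sigma``):  orientation of the edge along the polygon's
  positive traversal direction;
* polygon->cell (``Sigma``):  +1 if the polygon normal (right-hand rule on
  the positive traversal) points away from the cell interior, -1 otherwise.

Only relations between consecutive hierarchy levels are allowed: connecting
equally-labelled nodes, or skipping a level (e.g. vertex->polygon), violates
the schema ("metagraph") and is rejected.  The sign structure makes each
polygon an oriented closed cycle and each cell an oriented closed surface,
which is expressed by two discrete boundary-of-boundary conditions checked
by :meth:`GVMGraph.validate`.

Geometry (vertex coordinates) is deliberately *not* stored here; all
coordinates live in a separate mapping so that topology and geometry can be
tested and manipulated independently.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

__all__ = [
    "LABELS",
    "LEVELS",
    "MetagraphError",
    "TopologyError",
    "GVMGraph",
]

#: hierarchy of node labels, bottom to top
LABELS = ("vertex", "edge", "polygon", "cell")

#: relation levels: pairs of consecutive labels
LEVELS = ("ve", "ep", "pc")

_LEVEL_OF = {("vertex", "edge"): "ve", ("edge", "polygon"): "ep", ("polygon", "cell"): "pc"}
_SRC_LABEL = {"ve": "vertex", "ep": "edge", "pc": "polygon"}
_TGT_LABEL = {"ve": "edge", "ep": "polygon", "pc": "cell"}


class MetagraphError(ValueError):
    """A mutation would violate the metagraph (schema) of the model."""


class TopologyError(ValueError):
    """The graph does not satisfy a topological precondition."""


@dataclass
class _NodeStore:
    """Nodes of one label class with monotone, non-recycled integer ids."""

    props: dict[int, dict] = field(default_factory=dict)
    next_id: int = 1

    def new(self, node_id: int | None = None, **properties) -> int:
        if node_id is None:
            node_id = self.next_id
        if node_id in self.props:
            raise MetagraphError(f"duplicate node id {node_id}")
        self.props[node_id] = dict(properties)
        self.next_id = max(self.next_id, node_id + 1)
        return node_id

    def __contains__(self, node_id: int) -> bool:
        return node_id in self.props

    def __len__(self) -> int:
        return len(self.props)


class GVMGraph:
    """In-memory signed-incidence graph of a 2D or 3D cell aggregate.

    Parameters
    ----------
    dim:
        2 for a planar polygonal tiling (no Cell nodes -- polygons are the
        cells), 3 for a space-filling polyhedral packing.
    """

    def __init__(self, dim: int = 3):
        if dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        self.dim = dim
        self._stores = {lab: _NodeStore() for lab in LABELS}
        # forward and reverse adjacency, sign-valued: fwd["ve"][v][e] = s
        self._fwd = {lv: {} for lv in LEVELS}
        self._rev = {lv: {} for lv in LEVELS}

    # ------------------------------------------------------------------ nodes

    @property
    def vertices(self) -> dict[int, dict]:
        return self._stores["vertex"].props

    @property
    def edges(self) -> dict[int, dict]:
        return self._stores["edge"].props

    @property
    def polygons(self) -> dict[int, dict]:
        return self._stores["polygon"].props

    @property
    def cells(self) -> dict[int, dict]:
        return self._stores["cell"].props

    def nodes(self, label: str) -> dict[int, dict]:
        return self._stores[label].props

    def counts(self) -> tuple[int, int, int, int]:
        """(N_v, N_e, N_p, N_c)."""
        return tuple(len(self._stores[lab]) for lab in LABELS)

    def add_node(self, label: str, node_id: int | None = None, **properties) -> int:
        if label not in LABELS:
            raise MetagraphError(f"unknown label {label!r}")
        if label == "cell" and self.dim == 2:
            raise MetagraphError("cell nodes do not exist in the 2D representation")
        return self._stores[label].new(node_id, **properties)

    def delete_node(self, label: str, node_id: int) -> None:
        """Delete a node; it must have no remaining relations."""
        store = self._stores[label]
        if node_id not in store:
            raise MetagraphError(f"no {label} node {node_id}")
        for lv in LEVELS:
            if _SRC_LABEL[lv] == label and self._fwd[lv].get(node_id):
                raise MetagraphError(f"{label} {node_id} still has {lv} relations")
            if _TGT_LABEL[lv] == label and self._rev[lv].get(node_id):
                raise MetagraphError(f"{label} {node_id} still has {lv} relations")
        del store.props[node_id]

    # -------------------------------------------------------------- relations

    def add_relation(self, source: tuple[str, int], target: tuple[str, int],
                     sign: int) -> None:
        """Create a signed is-part-of relation between existing nodes.

        ``source`` and ``target`` are ``(label, id)`` pairs whose labels must
        be consecutive hierarchy levels; anything else (same label, skipped
        level, reversed direction) is a metagraph violation.
        """
        s_lab, s_id = source
        t_lab, t_id = target
        level = _LEVEL_OF.get((s_lab, t_lab))
        if level is None:
            raise MetagraphError(
                f"relation {s_lab}->{t_lab} is not permitted by the metagraph")
        if sign not in (-1, 1):
            raise MetagraphError(f"sign must be -1 or +1, got {sign}")
        if s_id not in self._stores[s_lab]:
            raise MetagraphError(f"no {s_lab} node {s_id}")
        if t_id not in self._stores[t_lab]:
            raise MetagraphError(f"no {t_lab} node {t_id}")
        fwd = self._fwd[level].setdefault(s_id, {})
        if t_id in fwd:
            raise MetagraphError(f"relation {s_lab} {s_id} -> {t_lab} {t_id} already exists")
        fwd[t_id] = sign
        self._rev[level].setdefault(t_id, {})[s_id] = sign

    def delete_relation(self, source: tuple[str, int], target: tuple[str, int]) -> int:
        """Delete a relation; returns the sign it carried."""
        s_lab, s_id = source
        t_lab, t_id = target
        level = _LEVEL_OF.get((s_lab, t_lab))
        if level is None:
            raise MetagraphError(
                f"relation {s_lab}->{t_lab} is not permitted by the metagraph")
        try:
            sign = self._fwd[level][s_id].pop(t_id)
        except KeyError:
            raise MetagraphError(
                f"no relation {s_lab} {s_id} -> {t_lab} {t_id}") from None
        if not self._fwd[level][s_id]:
            del self._fwd[level][s_id]
        rev = self._rev[level][t_id]
        del rev[s_id]
        if not rev:
            del self._rev[level][t_id]
        return sign

    # convenience sign-valued views -------------------------------------------------

    def edge_vertices(self, e: int) -> dict[int, int]:
        """{vertex id: s} for edge ``e``."""
        return dict(self._rev["ve"].get(e, {}))

    def vertex_edges(self, v: int) -> dict[int, int]:
        return dict(self._fwd["ve"].get(v, {}))

    def polygon_edges(self, p: int) -> dict[int, int]:
        """{edge id: sigma} for polygon ``p``."""
        return dict(self._rev["ep"].get(p, {}))

    def edge_polygons(self, e: int) -> dict[int, int]:
        return dict(self._fwd["ep"].get(e, {}))

    def cell_polygons(self, c: int) -> dict[int, int]:
        """{polygon id: Sigma} for cell ``c``."""
        return dict(self._rev["pc"].get(c, {}))

    def polygon_cells(self, p: int) -> dict[int, int]:
        return dict(self._fwd["pc"].get(p, {}))

    def sign(self, source: tuple[str, int], target: tuple[str, int]) -> int:
        s_lab, s_id = source
        t_lab, t_id = target
        level = _LEVEL_OF[(s_lab, t_lab)]
        return self._fwd[level][s_id][t_id]

    def has_relation(self, source: tuple[str, int], target: tuple[str, int]) -> bool:
        level = _LEVEL_OF.get((source[0], target[0]))
        if level is None:
            return False
        return target[1] in self._fwd[level].get(source[1], {})

    def relations(self):
        """Iterate over all relations as (level, source id, target id, sign)."""
        for lv in LEVELS:
            for s_id, targets in self._fwd[lv].items():
                for t_id, sign in targets.items():
                    yield lv, s_id, t_id, sign

    def relation_set(self) -> set[tuple[str, int, int]]:
        """Unsigned relation triples -- the graph's topology fingerprint."""
        return {(lv, s, t) for lv, s, t, _ in self.relations()}

    # ------------------------------------------------------------------ queries

    def incident(self, label: str, node_id: int, target_label: str) -> set[int]:
        """Elements of ``target_label`` related to a node by monotone traversal.

        Walks is-part-of relations strictly upward (e.g. the cells sharing a
        vertex) or strictly downward (e.g. the vertices of a cell).  The
        hierarchical storage makes this a local breadth-first walk; no
        redundant incidence tables are kept.
        """
        if label not in LABELS or target_label not in LABELS:
            raise MetagraphError("unknown label")
        if node_id not in self._stores[label]:
            raise MetagraphError(f"no {label} node {node_id}")
        i, j = LABELS.index(label), LABELS.index(target_label)
        if i == j:
            return {node_id}
        step = 1 if j > i else -1
        frontier = {node_id}
        for k in range(i, j, step):
            lv = LEVELS[k] if step == 1 else LEVELS[k - 1]
            adj = self._fwd[lv] if step == 1 else self._rev[lv]
            frontier = {nbr for n in frontier for nbr in adj.get(n, {})}
        return frontier

    def edge_endpoints(self, e: int) -> tuple[int, int]:
        """(head, tail) vertex ids of an edge."""
        vs = self._rev["ve"].get(e, {})
        head = [v for v, s in vs.items() if s == +1]
        tail = [v for v, s in vs.items() if s == -1]
        if len(head) != 1 or len(tail) != 1:
            raise TopologyError(f"edge {e} does not have one head and one tail vertex")
        return head[0], tail[0]

    def polygon_vertex_cycle(self, p: int) -> list[int]:
        """One closed traversal of the polygon's vertices.

        The traversal follows the positive orientation fixed by the edge
        signs ``sigma``: an edge with sigma=+1 is walked tail->head, one with
        sigma=-1 head->tail.  Cyclic rotations of the result are equivalent.
        """
        edges = self._rev["ep"].get(p, {})
        if len(edges) < 2:
            raise TopologyError(f"polygon {p} is not a single cycle")
        # start anywhere; walk edge by edge through shared vertices
        e0, sig0 = next(iter(edges.items()))
        head, tail = self.edge_endpoints(e0)
        start, cur = (tail, head) if sig0 == +1 else (head, tail)
        cycle = [start]
        used = {e0}
        while cur != start:
            cycle.append(cur)
            nxt = None
            for e, sig in edges.items():
                if e in used:
                    continue
                try:
                    h, t = self.edge_endpoints(e)
                except TopologyError:
                    raise TopologyError(f"polygon {p} is not a single cycle") from None
                frm, to = (t, h) if sig == +1 else (h, t)
                if frm == cur:
                    if nxt is not None:
                        raise TopologyError(f"polygon {p} is not a single cycle")
                    nxt = (e, to)
            if nxt is None:
                raise TopologyError(f"polygon {p} is not a single cycle")
            used.add(nxt[0])
            cur = nxt[1]
        if len(used) != len(edges):
            raise TopologyError(f"polygon {p} is not a single cycle")
        return cycle

    def euler_characteristic(self) -> int:
        """N_v - N_e + N_p - N_c; zero for a periodic space-filling 3D packing.

        In 2D (no cell nodes) this is N_v - N_e + N_p, which vanishes on the
        torus.
        """
        nv, ne, np_, nc = self.counts()
        return nv - ne + np_ - nc

    # ----------------------------------------------------------------- validate

    def validate(self, boundary_ok: bool = False) -> list[str]:
        """Check every structural invariant; returns a list of violations.

        ``boundary_ok=True`` relaxes the closure checks for deliberately
        open local patches (the printed five-cell neighbourhood fixtures),
        where edges may have a single stored endpoint and cycles/surfaces
        are not closed at the patch boundary.
        """
        out: list[str] = []
        # every edge: exactly two vertices, one head and one tail
        for e in self.edges:
            vs = self._rev["ve"].get(e, {})
            if len(vs) > 2:
                out.append(f"edge {e} has {len(vs)} vertices")
            elif len(vs) == 2:
                if sorted(vs.values()) != [-1, 1]:
                    out.append(f"edge {e} lacks a head/tail sign pair")
            elif not boundary_ok:
                out.append(f"edge {e} has {len(vs)} vertices")
        # rule (i): edge pairs share at most one vertex
        for v in self.vertices:
            es = sorted(self._fwd["ve"].get(v, {}))
            for i, e1 in enumerate(es):
                vs1 = set(self._rev["ve"].get(e1, {}))
                for e2 in es[i + 1:]:
                    shared = vs1 & set(self._rev["ve"].get(e2, {}))
                    if len(shared) > 1:
                        out.append(f"edges {e1} and {e2} share vertices {sorted(shared)}")
        # rule (ii): polygon pairs share at most one edge
        for e in self.edges:
            ps = sorted(self._fwd["ep"].get(e, {}))
            for i, p1 in enumerate(ps):
                es1 = set(self._rev["ep"].get(p1, {}))
                for p2 in ps[i + 1:]:
                    shared = es1 & set(self._rev["ep"].get(p2, {}))
                    if len(shared) > 1:
                        out.append(f"polygons {p1} and {p2} share edges {sorted(shared)}")
        # rule (iii): cell pairs share at most one polygon
        for p in self.polygons:
            cs = sorted(self._fwd["pc"].get(p, {}))
            for i, c1 in enumerate(cs):
                ps1 = set(self._rev["pc"].get(c1, {}))
                for c2 in cs[i + 1:]:
                    shared = ps1 & set(self._rev["pc"].get(c2, {}))
                    if len(shared) > 1:
                        out.append(f"cells {c1} and {c2} share polygons {sorted(shared)}")
        # cycle closure: sum over edges of p at v of s*sigma vanishes
        for p in self.polygons:
            at_vertex: dict[int, int] = {}
            cnt: dict[int, int] = {}
            for e, sig in self._rev["ep"].get(p, {}).items():
                for v, s in self._rev["ve"].get(e, {}).items():
                    at_vertex[v] = at_vertex.get(v, 0) + s * sig
                    cnt[v] = cnt.get(v, 0) + 1
            for v, n in cnt.items():
                if n > 2:
                    out.append(f"polygon {p} visits vertex {v} {n} times")
                elif n == 2:
                    if at_vertex[v] != 0:
                        out.append(f"polygon {p} cycle closure fails at vertex {v}")
                elif not boundary_ok:
                    out.append(f"polygon {p} has an open cycle at vertex {v}")
        # closed surface: sum over polygons of c containing e of sigma*Sigma vanishes
        for c in self.cells:
            at_edge: dict[int, int] = {}
            cnt = {}
            for p, Sig in self._rev["pc"].get(c, {}).items():
                for e, sig in self._rev["ep"].get(p, {}).items():
                    at_edge[e] = at_edge.get(e, 0) + sig * Sig
                    cnt[e] = cnt.get(e, 0) + 1
            for e, n in cnt.items():
                if n > 2:
                    out.append(f"cell {c} has edge {e} on {n} polygons")
                elif n == 2:
                    if at_edge[e] != 0:
                        out.append(f"cell {c} surface closure fails at edge {e}")
                elif not boundary_ok:
                    out.append(f"cell {c} has an open surface at edge {e}")
        return out

    def validate_local(self, polygons: set[int], cells: set[int],
                       edges: set[int]) -> list[str]:
        """Topological-rule and closure checks restricted to a neighbourhood.

        Used after a topological transformation to decide whether it must be
        rolled back; checks exactly the rules of :meth:`validate` but only
        for the supplied elements and their immediate partners.
        """
        out: list[str] = []
        for e in edges:
            if e not in self.edges:
                continue
            vs = self._rev["ve"].get(e, {})
            if len(vs) != 2 or sorted(vs.values()) != [-1, 1]:
                out.append(f"edge {e} malformed")
                continue
            # rule (i) against all edges sharing a vertex with e
            vset = set(vs)
            for v in vs:
                for e2 in self._fwd["ve"].get(v, {}):
                    if e2 == e:
                        continue
                    if len(vset & set(self._rev["ve"].get(e2, {}))) > 1:
                        out.append(f"edges {e} and {e2} share two vertices")
        for p in polygons:
            if p not in self.polygons:
                continue
            es = self._rev["ep"].get(p, {})
            # rule (ii) against polygons sharing an edge with p
            eset = set(es)
            seen: set[int] = set()
            for e in es:
                for p2 in self._fwd["ep"].get(e, {}):
                    if p2 == p or p2 in seen:
                        continue
                    seen.add(p2)
                    if len(eset & set(self._rev["ep"].get(p2, {}))) > 1:
                        out.append(f"polygons {p} and {p2} share two edges")
            # closure
            at_vertex: dict[int, int] = {}
            cnt: dict[int, int] = {}
            for e, sig in es.items():
                for v, s in self._rev["ve"].get(e, {}).items():
                    at_vertex[v] = at_vertex.get(v, 0) + s * sig
                    cnt[v] = cnt.get(v, 0) + 1
            for v, n in cnt.items():
                if n != 2 or at_vertex[v] != 0:
                    out.append(f"polygon {p} not a closed oriented cycle at vertex {v}")
        for c in cells:
            if c not in self.cells:
                continue
            ps = self._rev["pc"].get(c, {})
            pset = set(ps)
            seen = set()
            for p in ps:
                for c2 in self._fwd["pc"].get(p, {}):
                    if c2 == c or c2 in seen:
                        continue
                    seen.add(c2)
                    if len(pset & set(self._rev["pc"].get(c2, {}))) > 1:
                        out.append(f"cells {c} and {c2} share two polygons")
            at_edge: dict[int, int] = {}
            cnt = {}
            for p, Sig in ps.items():
                for e, sig in self._rev["ep"].get(p, {}).items():
                    at_edge[e] = at_edge.get(e, 0) + sig * Sig
                    cnt[e] = cnt.get(e, 0) + 1
            for e, n in cnt.items():
                if n != 2 or at_edge[e] != 0:
                    out.append(f"cell {c} not a closed oriented surface at edge {e}")
        return out

    # ------------------------------------------------------------------- misc

    def copy(self) -> "GVMGraph":
        g = GVMGraph(self.dim)
        for lab in LABELS:
            st = self._stores[lab]
            g._stores[lab].props = {i: dict(pr) for i, pr in st.props.items()}
            g._stores[lab].next_id = st.next_id
        for lv in LEVELS:
            g._fwd[lv] = {s: dict(t) for s, t in self._fwd[lv].items()}
            g._rev[lv] = {s: dict(t) for s, t in self._rev[lv].items()}
        return g

    def __repr__(self) -> str:  # pragma: no cover
        nv, ne, np_, nc = self.counts()
        return f"GVMGraph(dim={self.dim}, N_v={nv}, N_e={ne}, N_p={np_}, N_c={nc})"
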