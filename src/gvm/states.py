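"""Canonical local neighbourhood fixtures: states E, T and V.

The three local configurations that topological transitions interconvert are

* **E** -- a short edge (``e7``) shared by three polygons and surrounded by
  five cells; the starting point of an edge-to-triangle (ET) rearrangement;
* **V** -- the transient six-fold vertex produced when the short edge has
  collapsed (edge-to-vertex, EV);
* **T** -- the new triangular interface (``p10``) produced when the six-fold
  vertex resolves (vertex-to-triangle, VT), shared by the two cells that sat
  at the ends of the vanished edge.

Each state is stored as the explicit list of is-part-of relations of the
five-cell neighbourhood, using the conventional role names ``v1..v3``,
``e1..e9``, ``p1..p10``, ``c1..c5``.  The lists fix the topology only; a
canonical sign assignment satisfying the cycle-closure and closed-surface
conditions is computed by a small GF(2) constraint solve (signs enter the
closure sums only through products, so consistency is a parity problem).
Fixtures are open patches: outer endpoints of the spoke edges are not part
of the neighbourhood, so they must be validated with ``boundary_ok=True``.
"""

from __future__ import annotations

import numpy as np

from .graph import GVMGraph

__all__ = ["STATE_RELATIONS", "build_state_fixture", "solve_signs"]


def _parse(text: str) -> list[tuple[str, int, int]]:
    """Parse 'v1-e1, e1-p4, ...' into (level, source role no., target role no.)."""
    out = []
    for item in text.replace("\n", " ").split(","):
        item = item.strip()
        if not item:
            continue
        a, b = item.split("-")
        lv = a[0] + {"e": "e", "p": "p", "c": "c"}[b[0]]
        lv = {"ve": "ve", "ep": "ep", "pc": "pc"}[a[0] + b[0]]
        out.append((lv, int(a[1:]), int(b[1:])))
    return out


# The five-cell neighbourhood relation lists, one entry per is-part-of
# relation.  State E has 47 relations, state T 59, state V 42.
STATE_RELATIONS: dict[str, list[tuple[str, int, int]]] = {
    "E": _parse(
        "v1-e1, v1-e2, v1-e5, v1-e7, v2-e3, v2-e4, v2-e6, v2-e7,"
        "e1-p1, e1-p4, e1-p8, e2-p2, e2-p4, e2-p6, e3-p1, e3-p5, e3-p9,"
        "e4-p2, e4-p5, e4-p7, e5-p3, e5-p6, e5-p8, e6-p3, e6-p7, e6-p9,"
        "e7-p1, e7-p2, e7-p3,"
        "p1-c1, p1-c2, p2-c1, p2-c3, p3-c2, p3-c3, p4-c1, p4-c4, p5-c1, p5-c5,"
        "p6-c3, p6-c4, p7-c3, p7-c5, p8-c2, p8-c4, p9-c2, p9-c5"
    ),
    "T": _parse(
        "v1-e1, v1-e3, v1-e7, v1-e9, v2-e2, v2-e4, v2-e7, v2-e8,"
        "v3-e5, v3-e6, v3-e8, v3-e9,"
        "e1-p1, e1-p4, e1-p8, e2-p2, e2-p4, e2-p6, e3-p1, e3-p5, e3-p9,"
        "e4-p2, e4-p5, e4-p7, e5-p3, e5-p6, e5-p8, e6-p3, e6-p7, e6-p9,"
        "e7-p4, e7-p5, e7-p10, e8-p6, e8-p7, e8-p10, e9-p8, e9-p9, e9-p10,"
        "p1-c1, p1-c2, p2-c1, p2-c3, p3-c2, p3-c3, p4-c1, p4-c4, p5-c1, p5-c5,"
        "p6-c3, p6-c4, p7-c3, p7-c5, p8-c2, p8-c4, p9-c2, p9-c5, p10-c4, p10-c5"
    ),
    "V": _parse(
        "v1-e1, v1-e2, v1-e3, v1-e4, v1-e5, v1-e6,"
        "e1-p1, e1-p4, e1-p8, e2-p2, e2-p4, e2-p6, e3-p1, e3-p5, e3-p9,"
        "e4-p2, e4-p5, e4-p7, e5-p3, e5-p6, e5-p8, e6-p3, e6-p7, e6-p9,"
        "p1-c1, p1-c2, p2-c1, p2-c3, p3-c2, p3-c3, p4-c1, p4-c4, p5-c1, p5-c5,"
        "p6-c3, p6-c4, p7-c3, p7-c5, p8-c2, p8-c4, p9-c2, p9-c5"
    ),
}

_LABEL_OF_LEVEL = {"ve": ("vertex", "edge"), "ep": ("edge", "polygon"),
                   "pc": ("polygon", "cell")}


def solve_signs(relations: list[tuple[str, int, int]]) -> dict[tuple[str, int, int], int]:
    """Assign closure-consistent signs to a bare relation list.

    Constraints (each a parity equation over sign variables written as
    GF(2) bits, sign = (-1)**bit):

    * an edge with both endpoints present has one head and one tail;
    * where a vertex lies on exactly two edges of a polygon, the two
      s*sigma products are opposite (cycle closure);
    * where an edge lies on exactly two polygons of a cell, the two
      sigma*Sigma products are opposite (closed surface).

    Boundary relations (single endpoint / single polygon) are
    unconstrained.  Free variables are set to +1, which makes the output
    deterministic; any consistent assignment is equivalent up to the
    relabelling freedom of the patch.
    """
    var_index = {rel: i for i, rel in enumerate(relations)}
    n = len(relations)
    rows: list[np.ndarray] = []
    rhs: list[int] = []

    def add_constraint(vars_: list[int], parity: int) -> None:
        row = np.zeros(n, dtype=bool)
        for i in vars_:
            row[i] ^= True
        rows.append(row)
        rhs.append(parity)

    # index helpers
    edge_vs: dict[int, list[tuple[str, int, int]]] = {}
    poly_es: dict[int, list[tuple[str, int, int]]] = {}
    cell_ps: dict[int, list[tuple[str, int, int]]] = {}
    for rel in relations:
        lv, s, t = rel
        if lv == "ve":
            edge_vs.setdefault(t, []).append(rel)
        elif lv == "ep":
            poly_es.setdefault(t, []).append(rel)
        else:
            cell_ps.setdefault(t, []).append(rel)

    for e, rels in edge_vs.items():
        if len(rels) == 2:
            add_constraint([var_index[rels[0]], var_index[rels[1]]], 1)
    for p, rels in poly_es.items():
        # group the polygon's (vertex, edge) incidences by vertex
        by_vertex: dict[int, list[tuple[int, int]]] = {}
        for lv, e, _p in rels:
            for lv2, v, e2 in relations:
                if lv2 == "ve" and e2 == e:
                    by_vertex.setdefault(v, []).append(
                        (var_index[("ve", v, e)], var_index[("ep", e, p)]))
        for v, pairs in by_vertex.items():
            if len(pairs) == 2:
                (s1, g1), (s2, g2) = pairs
                add_constraint([s1, g1, s2, g2], 1)
    for c, rels in cell_ps.items():
        by_edge: dict[int, list[tuple[int, int]]] = {}
        for lv, p, _c in rels:
            for lv2, e, p2 in relations:
                if lv2 == "ep" and p2 == p:
                    by_edge.setdefault(e, []).append(
                        (var_index[("ep", e, p)], var_index[("pc", p, c)]))
        for e, pairs in by_edge.items():
            if len(pairs) == 2:
                (g1, S1), (g2, S2) = pairs
                add_constraint([g1, S1, g2, S2], 1)

    # Gaussian elimination over GF(2)
    A = np.array(rows, dtype=bool) if rows else np.zeros((0, n), dtype=bool)
    b = np.array(rhs, dtype=bool)
    x = np.zeros(n, dtype=bool)
    pivots: list[tuple[int, int]] = []  # (row, col)
    r = 0
    for col in range(n):
        piv = None
        for i in range(r, len(A)):
            if A[i, col]:
                piv = i
                break
        if piv is None:
            continue
        A[[r, piv]] = A[[piv, r]]
        b[[r, piv]] = b[[piv, r]]
        mask = A[:, col].copy()
        mask[r] = False
        A[mask] ^= A[r]
        b[mask] ^= b[r]
        pivots.append((r, col))
        r += 1
    if A[r:].any(axis=1).sum() < (b[r:]).sum():
        raise ValueError("inconsistent sign constraints")
    for i, col in reversed(pivots):
        rest = (A[i] & x).sum() % 2
        x[col] = bool(b[i]) ^ bool(rest)
    return {rel: (-1 if x[i] else +1) for rel, i in var_index.items()}


def build_state_fixture(state: str, signed: bool = True) -> GVMGraph:
    """Build the local five-cell neighbourhood graph for state E, T or V.

    Role numbers are used directly as node ids (``v1`` -> vertex 1, and so
    on).  With ``signed=True`` (default) the canonical closure-consistent
    sign assignment from :func:`solve_signs` is attached; with
    ``signed=False`` all signs are +1 (topology only).
    """
    state = state.upper()
    if state not in STATE_RELATIONS:
        raise ValueError(f"unknown state {state!r}; expected one of E, T, V")
    relations = STATE_RELATIONS[state]
    signs = solve_signs(relations) if signed else {rel: +1 for rel in relations}
    g = GVMGraph(dim=3)
    for lv, s, t in relations:
        s_lab, t_lab = _LABEL_OF_LEVEL[lv]
        if s not in g.nodes(s_lab):
            g.add_node(s_lab, s)
        if t not in g.nodes(t_lab):
            g.add_node(t_lab, t)
        g.add_relation((s_lab, s), (t_lab, t), signs[(lv, s, t)])
    return g
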