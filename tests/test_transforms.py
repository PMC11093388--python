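"""Graph transformations: state interconversion, signs, reduction, rollback."""

import numpy as np
import pytest

import gvm
from gvm import transforms as tr
from gvm.graph import GVMGraph
from gvm.states import STATE_RELATIONS, build_state_fixture
from conftest import mapped_state_relations


def printed(state):
    return {(lv, s, t) for lv, s, t in STATE_RELATIONS[state]}


# ------------------------------------------------ printed-list interconversion

def test_et_reproduces_printed_state_T():
    """47 state-E relations -> 59 state-T relations, exactly as listed."""
    g = build_state_fixture("E")
    m = tr.match_E(g, 7, labeling=(1, 2), side_order=(1, 2, 3))
    rec = tr.apply_ET(g, match=m)
    assert g.relation_set() == printed("T")
    assert g.validate(boundary_ok=True) == []
    assert rec.roles["v3"] == 3 and rec.roles["p10"] == 10


def test_te_inverts_et_to_printed_state_E():
    g = build_state_fixture("T")
    m = tr.match_T(g, 10, labeling=(1, 2, 3), end_cells=(4, 5))
    tr.apply_TE(g, match=m)
    assert g.relation_set() == printed("E")
    assert g.validate(boundary_ok=True) == []


def test_ev_reproduces_printed_state_V():
    g = build_state_fixture("E")
    tr.apply_EV(g, match=tr.match_E(g, 7, labeling=(1, 2), side_order=(1, 2, 3)))
    assert g.relation_set() == printed("V")
    assert g.validate(boundary_ok=True) == []


def test_vt_reproduces_state_T_up_to_roles():
    g = build_state_fixture("V")
    rec = tr.apply_VT(g, 1, partition=(1, 2, 3))
    assert g.relation_set() == mapped_state_relations("T", rec.roles)
    assert g.validate(boundary_ok=True) == []


def test_tv_and_ve_invert_vt_and_ev():
    g = build_state_fixture("T")
    tr.apply_TV(g, match=tr.match_T(g, 10, labeling=(1, 2, 3), end_cells=(4, 5)))
    assert g.relation_set() == printed("V")
    rec = tr.apply_VE(g, 1, end_cells=(4, 5))
    assert g.relation_set() == mapped_state_relations("E", rec.roles)
    assert g.validate(boundary_ok=True) == []


def test_ev_then_vt_composes_to_et():
    """An edge-to-vertex merge followed by a vertex-to-triangle resolution
    along the old side polygons equals the one-shot ET transformation."""
    g = build_state_fixture("E")
    m = tr.match_E(g, 7, labeling=(1, 2), side_order=(1, 2, 3))
    sides = (m.roles["p1"], m.roles["p2"], m.roles["p3"])
    rec_ev = tr.apply_EV(g, match=m)
    rec_vt = tr.apply_VT(g, rec_ev.roles["v1"], partition=sides)
    assert g.relation_set() == mapped_state_relations("T", rec_vt.roles)
    assert g.validate(boundary_ok=True) == []


def test_labeling_freedom_is_immaterial():
    """Both random v1/v2 labelings give the printed topology up to roles."""
    for labeling in ((1, 2), (2, 1)):
        g = build_state_fixture("E")
        m = tr.match_E(g, 7, labeling=labeling, side_order=(1, 2, 3))
        rec = tr.apply_ET(g, match=m)
        assert g.relation_set() == mapped_state_relations("T", rec.roles)
        assert g.validate(boundary_ok=True) == []


def test_element_count_deltas():
    deltas = {"ET": (1, 2, 1, 0), "EV": (-1, -1, 0, 0), "VT": (2, 3, 1, 0)}
    for kind, expected in deltas.items():
        src = {"ET": "E", "EV": "E", "VT": "V"}[kind]
        g = build_state_fixture(src)
        before = g.counts()
        if kind == "ET":
            tr.apply_ET(g, match=tr.match_E(g, 7, labeling=(1, 2), side_order=(1, 2, 3)))
        elif kind == "EV":
            tr.apply_EV(g, match=tr.match_E(g, 7, labeling=(1, 2), side_order=(1, 2, 3)))
        else:
            tr.apply_VT(g, 1, partition=(1, 2, 3))
        delta = tuple(b - a for a, b in zip(before, g.counts()))
        assert delta == expected
        assert g.euler_characteristic() == build_state_fixture(src).euler_characteristic()


# ----------------------------------------------------------------- sign rules

def test_sign_new_vertex_edge_inherits_prior_sign():
    g = build_state_fixture("E")
    s23 = g.sign(("vertex", 2), ("edge", 3))
    assert tr.sign_new_vertex_edge(g, 2, 3) == s23
    with pytest.raises(tr.MatchError, match="sign source missing"):
        tr.sign_new_vertex_edge(g, 1, 3)  # v1 is not on e3 in state E


@pytest.mark.parametrize("s25,s22,sig21,expected", [
    (+1, +1, +1, -1), (+1, -1, +1, +1), (-1, +1, +1, +1), (+1, +1, -1, +1),
    (-1, -1, -1, +1), (-1, -1, +1, -1),
])
def test_sign_new_edge_polygon_closure_rule(s25, s22, sig21, expected):
    """sigma'_{5,1} = -s'_{2,5} s'_{2,2} sigma_{2,1}, checked element-wise."""
    g = GVMGraph(dim=2)
    v2 = g.add_node("vertex")
    e2, e5 = g.add_node("edge"), g.add_node("edge")
    p1 = g.add_node("polygon")
    g.add_relation(("vertex", v2), ("edge", e2), s22)
    g.add_relation(("vertex", v2), ("edge", e5), s25)
    g.add_relation(("edge", e2), ("polygon", p1), sig21)
    assert tr.sign_new_edge_polygon(g, e5, p1, v2, e2) == expected


def test_created_edges_keep_one_head_one_tail(hex44):
    g, pos, box = hex44
    rng = np.random.default_rng(3)
    applied = 0
    for _ in range(30):
        e = sorted(g.edges)[int(rng.integers(len(g.edges)))]
        try:
            tr.apply_T1(g, e, positions=pos, box=box, rng=rng)
            applied += 1
        except tr.TransformationRejected:
            continue
        for eid in g.edges:
            assert sorted(g.edge_vertices(eid).values()) == [-1, 1]
        assert g.validate() == []
    assert applied >= 10


# ------------------------------------------------------------- 2D reduction

def test_t1_transformation_is_et_restricted_to_2d(hex44):
    """The executed 2D ET transformation graph equals the T1 transformation
    graph under the role identification, and is a subgraph of the 3D ET
    template."""
    g, pos, box = hex44
    edge = sorted(g.edges)[5]
    vs = sorted(g.edge_vertices(edge))
    sides = sorted(g.edge_polygons(edge))

    g_et = g.copy()
    m = tr.match_E(g_et, edge, labeling=vs, side_order=sides)
    assert all(r not in m.roles for r in ("p3", "e5", "e6", "c1", "c4"))
    rec_et = tr.apply_ET(g_et, match=m)
    assert not rec_et.created_nodes  # no triangle roles materialize in 2D

    g_t1 = g.copy()
    m1 = tr.match_T1(g_t1, edge, labeling=vs, side_order=sides)
    rec_t1 = tr.apply_T1(g_t1, match=m1)

    remap = tr.T1_TO_ET_ROLES
    dels_t1 = {(remap[a], remap[b]) for a, b in rec_t1.role_deletions}
    cres_t1 = {(remap[a], remap[b]) for a, b in rec_t1.role_creations}
    assert dels_t1 == set(rec_et.role_deletions)
    assert cres_t1 == set(rec_et.role_creations)
    # the executed transformation is contained in the full 3D template
    assert set(rec_et.role_deletions) <= set(tr.ET_TRANSFORMATION.deletions)
    assert cres_t1 <= {(a, b) for a, b, _ in tr.ET_TRANSFORMATION.creations}
    # and both routes produce the identical graph
    assert g_et.relation_set() == g_t1.relation_set()
    assert sorted(g_et.relations()) == sorted(g_t1.relations())


def test_two_t1s_restore_adjacency(hex44):
    g, pos, box = hex44
    edge = sorted(g.edges)[0]

    def adjacency(graph):
        return {frozenset(graph.edge_polygons(e)) for e in graph.edges}

    before = adjacency(g)
    tr.apply_T1(g, edge, positions=pos, box=box)
    assert adjacency(g) != before
    tr.apply_T1(g, edge, positions=pos, box=box)
    assert adjacency(g) == before
    assert g.validate() == []


def test_t1_requires_2d_and_interior_edge(kelvin16):
    g3, _, _ = kelvin16
    with pytest.raises(tr.MatchError):
        tr.match_T1(g3, sorted(g3.edges)[0])


# ----------------------------------------------------- 3D round trips, checks

def test_et_te_roundtrip_on_crystal(kelvin16):
    g, pos, box = kelvin16
    rng = np.random.default_rng(11)

    def cell_adjacency(graph):
        return {frozenset(graph.polygon_cells(p)) for p in graph.polygons
                if len(graph.polygon_cells(p)) == 2}

    before_counts = g.counts()
    before_adj = cell_adjacency(g)
    baseline = set(g.validate())
    e = sorted(g.edges)[int(rng.integers(len(g.edges)))]
    rec = tr.apply_ET(g, e, positions=pos, box=box, rng=rng)
    assert g.counts() == tuple(np.add(before_counts, (1, 2, 1, 0)))
    tri = rec.roles["p10"]
    tr.apply_TE(g, tri, positions=pos, box=box, rng=rng)
    assert g.counts() == before_counts
    assert cell_adjacency(g) == before_adj
    assert set(g.validate()) == baseline
    assert g.euler_characteristic() == 0


def test_rejected_transformation_is_fully_reversed(kelvin16):
    """An ET on a triangle edge would leave a two-edge polygon; it must be
    reversed without a trace."""
    g, pos, box = kelvin16
    rng = np.random.default_rng(5)
    rec = tr.apply_ET(g, sorted(g.edges)[10], positions=pos, box=box, rng=rng)
    tri = rec.roles["p10"]
    snapshot = sorted(g.relations())
    pos_snapshot = {v: p.copy() for v, p in pos.items()}
    tri_edge = sorted(g.polygon_edges(tri))[0]
    with pytest.raises(tr.TransformationRejected):
        tr.apply_ET(g, tri_edge, positions=pos, box=box, rng=rng)
    assert sorted(g.relations()) == snapshot
    assert set(pos) == set(pos_snapshot)
    assert all(np.array_equal(pos[v], pos_snapshot[v]) for v in pos)


def test_match_errors():
    gV = build_state_fixture("V")
    with pytest.raises(tr.MatchError):
        tr.match_V(gV, 1, partition=(4, 5, 3))  # p4, p5 overlap on no pair
    g16, _, _ = gvm.kelvin_lattice(2, 2, 2)
    v = sorted(g16.vertices)[0]  # 4-fold vertex: no V state
    with pytest.raises(tr.MatchError):
        tr.match_V(g16, v)
    p = sorted(g16.polygons)[0]  # square, not a triangle
    with pytest.raises(tr.MatchError):
        tr.match_T(g16, p)


def test_admissible_partitions_of_state_V():
    g = build_state_fixture("V")
    parts = tr.admissible_partitions(g, 1)
    assert (1, 2, 3) in parts and len(parts) == 4


# -------------------------------------------------------------- repositioning

def test_reposition_after_et(kelvin16):
    g, pos, box = kelvin16
    rng = np.random.default_rng(2)
    e = sorted(g.edges)[42]
    h, t = g.edge_endpoints(e)
    d_old = gvm.minimum_image(pos[h] - pos[t], box)
    mid = pos[t] + 0.5 * d_old
    l_new = 0.05
    rec = tr.apply_ET(g, e, positions=pos, box=box, l_new=l_new, rng=rng)
    tri = rec.roles["p10"]
    lengths = []
    coords = []
    for te in g.polygon_edges(tri):
        a, b = g.edge_endpoints(te)
        dv = gvm.minimum_image(pos[a] - pos[b], box)
        lengths.append(np.linalg.norm(dv))
    assert all(0.04 <= L <= 0.06 for L in lengths)
    # triangle normal parallel to the vanished edge direction
    n = gvm.polygon_normal(g, pos, box, tri)
    cosang = abs(n @ d_old) / np.linalg.norm(d_old)
    assert cosang > 1 - 1e-9
    # triangle centroid at the old midpoint
    cen = gvm.polygon_centroid(g, pos, box, tri)
    assert np.linalg.norm(gvm.minimum_image(cen - mid, box)) < 1e-9


def test_reposition_after_ev(kelvin16):
    g, pos, box = kelvin16
    e = sorted(g.edges)[7]
    h, t = g.edge_endpoints(e)
    mid = pos[t] + 0.5 * gvm.minimum_image(pos[h] - pos[t], box)
    rec = tr.apply_EV(g, e, positions=pos, box=box)
    merged = rec.roles["v1"]
    assert np.linalg.norm(gvm.minimum_image(pos[merged] - mid, box)) < 1e-12
    assert rec.roles["v2"] not in pos


# ------------------------------------------------------ randomized event storm

def test_random_transformation_storm_preserves_invariants(kelvin16):
    """Random valid ET/TE events never introduce topological-rule or
    closure violations and conserve the Euler characteristic."""
    g, pos, box = kelvin16
    rng = np.random.default_rng(7)
    baseline = set(g.validate())
    applied = 0
    rejected = 0
    for _ in range(400):
        triangles = [p for p in g.polygons if len(g.polygon_edges(p)) == 3]
        if triangles and rng.random() < 0.5:
            anchor = triangles[int(rng.integers(len(triangles)))]
            fn = tr.apply_TE
        else:
            eids = sorted(g.edges)
            anchor = eids[int(rng.integers(len(eids)))]
            fn = tr.apply_ET
        try:
            fn(g, anchor, positions=pos, box=box, rng=rng)
            applied += 1
        except (tr.TransformationRejected, tr.MatchError):
            rejected += 1
        assert g.euler_characteristic() == 0
    assert applied > 100
    assert set(g.validate()) - baseline == set()
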