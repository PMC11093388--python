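"""Signed-incidence graph: schema enforcement, queries, validation."""

import pytest

import gvm
from gvm.graph import GVMGraph, MetagraphError, TopologyError
from gvm.states import STATE_RELATIONS, build_state_fixture


@pytest.mark.parametrize("src,tgt", [
    ("vertex", "polygon"),   # level skipping is forbidden
    ("vertex", "cell"),
    ("edge", "cell"),
    ("vertex", "vertex"),    # equally labelled nodes may not connect
    ("polygon", "polygon"),
    ("edge", "vertex"),      # reversed direction
])
def test_metagraph_forbids_invalid_relations(src, tgt):
    g = GVMGraph(dim=3)
    ids = {lab: g.add_node(lab) for lab in ("vertex", "edge", "polygon", "cell")}
    with pytest.raises(MetagraphError):
        g.add_relation((src, ids[src]), (tgt, ids[tgt]), +1)


def test_relation_lifecycle_roundtrip():
    g = GVMGraph(dim=3)
    v = g.add_node("vertex")
    e = g.add_node("edge")
    g.add_relation(("vertex", v), ("edge", e), +1)
    assert g.sign(("vertex", v), ("edge", e)) == +1
    with pytest.raises(MetagraphError):
        g.add_relation(("vertex", v), ("edge", e), -1)  # duplicate
    before = sorted(g.relations())
    assert g.delete_relation(("vertex", v), ("edge", e)) == +1
    g.add_relation(("vertex", v), ("edge", e), +1)
    assert sorted(g.relations()) == before
    with pytest.raises(MetagraphError):
        g.delete_relation(("vertex", v), ("edge", 999))


def test_node_ids_monotone_never_recycled():
    g = GVMGraph(dim=3)
    a = g.add_node("vertex")
    b = g.add_node("vertex")
    g.delete_node("vertex", b)
    c = g.add_node("vertex")
    assert c > b > a


@pytest.mark.parametrize("state,counts,n_rel", [
    ("E", (2, 7, 9, 5), 47),
    ("T", (3, 9, 10, 5), 59),
    ("V", (1, 6, 9, 5), 42),
])
def test_state_fixtures_match_printed_lists(state, counts, n_rel):
    g = build_state_fixture(state)
    assert g.counts() == counts
    assert len(list(g.relations())) == n_rel == len(STATE_RELATIONS[state])
    # canonical signs satisfy every closure constraint of the open patch
    assert g.validate(boundary_ok=True) == []


def test_incident_examples_from_state_lists():
    g = build_state_fixture("E")
    assert g.incident("edge", 7, "polygon") == {1, 2, 3}
    # v1 reaches the three cells around the edge plus the cap cell at its
    # own end; the cell capping the far (v2) end does not contain v1
    assert g.incident("vertex", 1, "cell") == {1, 2, 3, 4}
    assert g.incident("cell", 5, "vertex") == {2}
    lone = g.add_node("vertex")
    assert g.incident("vertex", lone, "edge") == set()


@pytest.mark.parametrize("state", ["E", "T", "V"])
def test_incident_agrees_with_brute_force(state):
    """Hierarchical traversal equals transitive closure over the raw list."""
    g = build_state_fixture(state)
    rels = STATE_RELATIONS[state]
    up = {"v": {}, "e": {}, "p": {}}
    pref = {"ve": ("v", "e"), "ep": ("e", "p"), "pc": ("p", "c")}
    for lv, s, t in rels:
        a, b = pref[lv]
        up[a].setdefault(s, set()).add((b, t))
    label_of = {"v": "vertex", "e": "edge", "p": "polygon", "c": "cell"}
    chain = ["v", "e", "p", "c"]
    for lv, s, t in rels:
        a, _ = pref[lv]
        frontier = {(a, s)}
        for step in range(chain.index(a), 3):
            frontier = {nbr for lab, n in frontier
                        for nbr in up[lab].get(n, set())}
            target_label = chain[step + 1]
            expected = {n for lab, n in frontier}
            got = g.incident(label_of[a], s, label_of[target_label])
            assert got == expected


def test_polygon_vertex_cycle_on_closed_polygons(kelvin16):
    g, _, _ = kelvin16
    for p in list(g.polygons)[:20]:
        cyc = g.polygon_vertex_cycle(p)
        assert len(cyc) == len(g.polygon_edges(p))
        assert len(set(cyc)) == len(cyc)
    gT = build_state_fixture("T")
    assert set(gT.polygon_vertex_cycle(10)) == {1, 2, 3}


def test_polygon_cycle_rejects_two_gon():
    g = GVMGraph(dim=2)
    v1, v2 = g.add_node("vertex"), g.add_node("vertex")
    e1, e2 = g.add_node("edge"), g.add_node("edge")
    p = g.add_node("polygon")
    for e in (e1, e2):
        g.add_relation(("vertex", v1), ("edge", e), +1)
        g.add_relation(("vertex", v2), ("edge", e), -1)
        g.add_relation(("edge", e), ("polygon", p), +1)
    with pytest.raises(TopologyError):
        g.polygon_vertex_cycle(p)
    assert any("share" in v for v in g.validate(boundary_ok=True))


def test_euler_characteristic():
    assert GVMGraph(dim=3).euler_characteristic() == 0
    g, _, _ = gvm.kelvin_lattice(4, 4, 4)
    assert g.counts() == (768, 1536, 896, 128)
    assert g.euler_characteristic() == 0
    # element-count change of the edge-to-triangle transition, from the
    # printed lists: (+1, +2, +1, 0), so Euler characteristic is conserved
    dE = [b - a for a, b in zip(build_state_fixture("E").counts(),
                                build_state_fixture("T").counts())]
    assert dE == [1, 2, 1, 0]


def test_validate_reports_sign_and_sharing_violations():
    g = GVMGraph(dim=3)
    v1, v2 = g.add_node("vertex"), g.add_node("vertex")
    e = g.add_node("edge")
    g.add_relation(("vertex", v1), ("edge", e), +1)
    g.add_relation(("vertex", v2), ("edge", e), +1)  # two head signs
    assert any("head/tail" in msg for msg in g.validate())

    g2 = GVMGraph(dim=3)
    vs = [g2.add_node("vertex") for _ in range(4)]
    es = [g2.add_node("edge") for _ in range(2)]
    ps = [g2.add_node("polygon") for _ in range(2)]
    for e_id, (a, b) in zip(es, [(0, 1), (2, 3)]):
        g2.add_relation(("vertex", vs[a]), ("edge", e_id), +1)
        g2.add_relation(("vertex", vs[b]), ("edge", e_id), -1)
        for p in ps:  # both polygons contain both edges: rule (ii)
            g2.add_relation(("edge", e_id), ("polygon", p), +1)
    assert any("polygons" in msg and "share" in msg
               for msg in g2.validate(boundary_ok=True))


def test_sign_solver_property_on_random_subpatches():
    """Any sub-patch of a realizable neighbourhood admits a closure-
    consistent sign assignment, and the solver finds one."""
    from hypothesis import given, settings, strategies as st
    from gvm.states import solve_signs

    rels = STATE_RELATIONS["T"]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.sets(st.sampled_from(range(len(rels))), min_size=1))
    def check(idx):
        subset = [rels[i] for i in sorted(idx)]
        signs = solve_signs(subset)
        assert set(signs.values()) <= {-1, +1}
        g = GVMGraph(dim=3)
        labels = {"ve": ("vertex", "edge"), "ep": ("edge", "polygon"),
                  "pc": ("polygon", "cell")}
        for lv, s, t in subset:
            sl, tl = labels[lv]
            if s not in g.nodes(sl):
                g.add_node(sl, s)
            if t not in g.nodes(tl):
                g.add_node(tl, t)
            g.add_relation((sl, s), (tl, t), signs[(lv, s, t)])
        assert g.validate(boundary_ok=True) == []

    check()
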