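"""Interconvert the canonical local states E, T and V by graph transformations.

Builds the five-cell neighbourhood of a short edge (state E), runs the
edge-to-triangle (ET) transformation on it, and shows that the resulting
relation set is exactly the state-T neighbourhood; the triangle-to-edge
(TE) transformation inverts it.
"""

import gvm
from gvm import transforms as tr
from gvm.states import STATE_RELATIONS

g = gvm.build_state_fixture("E")
print(f"state E: N_v,N_e,N_p,N_c = {g.counts()}, "
      f"{len(list(g.relations()))} is-part-of relations")

match = tr.match_E(g, 7, labeling=(1, 2), side_order=(1, 2, 3))
rec = tr.apply_ET(g, match=match)
print(f"after ET: counts = {g.counts()}, "
      f"{len(list(g.relations()))} relations "
      f"(new vertex v3 -> id {rec.roles['v3']}, triangle -> id {rec.roles['p10']})")

expected_T = {(lv, s, t) for lv, s, t in STATE_RELATIONS["T"]}
print("relation set equals the printed state-T list:",
      g.relation_set() == expected_T)
print("closure invariants satisfied:",
      g.validate(boundary_ok=True) == [])

tr.apply_TE(g, rec.roles["p10"],
            match=tr.match_T(g, rec.roles["p10"],
                             labeling=(1, 2, rec.roles["v3"]), end_cells=(4, 5)))
expected_E = {(lv, s, t) for lv, s, t in STATE_RELATIONS["E"]}
print("TE inverts ET back to the state-E list:",
      g.relation_set() == expected_E)

# The interpretation: before ET, the two cells capping the edge ends (c4,
# c5) are separated; after ET they share the new triangular interface.
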