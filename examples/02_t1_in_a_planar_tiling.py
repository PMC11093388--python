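"""A T1 neighbour exchange in a 2D tiling, and its 3D generalization.

Runs the 3D edge-to-triangle transformation on a honeycomb tiling and shows
that only the planar T1 sub-transformation executes: the triangle roles
cannot bind in 2D, so the two transformations coincide.
"""

import gvm
from gvm import transforms as tr

g, pos, box = gvm.hex_tiling_2d(4, 4)
edge = sorted(g.edges)[5]
p_before = sorted(g.edge_polygons(edge))
print(f"honeycomb: {g.counts()[:3]} (vertices, edges, polygons); "
      f"edge {edge} is shared by polygons {p_before}")

vs = sorted(g.edge_vertices(edge))
g_et = g.copy()
rec_et = tr.apply_ET(g_et, match=tr.match_E(g_et, edge, labeling=vs,
                                            side_order=p_before))
g_t1 = g.copy()
rec_t1 = tr.apply_T1(g_t1, match=tr.match_T1(g_t1, edge, labeling=vs,
                                             side_order=p_before))

print("polygons sharing the edge after the exchange:",
      sorted(g_t1.edge_polygons(edge)))
remap = tr.T1_TO_ET_ROLES
same = ({(remap[a], remap[b]) for a, b in rec_t1.role_deletions}
        == set(rec_et.role_deletions)) and \
       ({(remap[a], remap[b]) for a, b in rec_t1.role_creations}
        == set(rec_et.role_creations))
print("executed ET transformation (2D) == T1 transformation:", same)
print("graphs after both routes identical:",
      sorted(g_et.relations()) == sorted(g_t1.relations()))
print("no nodes were created in 2D (no triangle roles):",
      rec_et.created_nodes == [])

# The edge has rotated: the two polygons that shared it are now separated
# and the previously separated pair shares it instead.
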