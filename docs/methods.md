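# Methods

## The model

`gvm` simulates space-filling aggregates of polyhedral cells (3D) and
polygonal tilings (2D) in the vertex-model framework: cell shapes are
parametrized by vertex positions `r_i` in a periodic box, and the topology
of the cell-interface network is stored separately from the geometry, in a
four-level signed-incidence property graph

```
Vertex --s--> Edge --sigma--> Polygon --Sigma--> Cell
```

Each *is-part-of* relation carries a contextual sign: `s = +/-1` marks the
head/tail vertex of an edge, `sigma` the orientation of an edge along its
polygon's positive traversal, and `Sigma` whether the polygon normal
(right-hand rule) points out of or into the cell.  Only relations between
consecutive levels are legal; higher-order incidence (e.g. which cells
share a vertex) is answered by traversal, never stored redundantly.  Two
discrete boundary-of-boundary conditions make the sign structure
meaningful and are enforced throughout:

* **cycle closure** — at every vertex lying on two edges of a polygon,
  `s·sigma` sums to zero (each polygon is a single oriented cycle);
* **surface closure** — at every edge lying on two polygons of a cell,
  `sigma·Sigma` sums to zero (each cell is an oriented closed surface).

### Mechanics

The potential energy is interfacial tension plus volume elasticity,

```
W = sum_polygons Gamma_p A_p + kappa_V sum_cells (V_l - V0_l)^2 ,
```

with polygon areas defined by the fan triangulation about the polygon
centroid and cell volumes by summing signed tetrahedra over
outward-oriented faces.  Forces are the exact analytic gradients of these
definitions (including the centroid terms), so energy and force are
consistent to machine precision; the test suite checks both against
central finite differences at 1e-5 relative tolerance.  Vertices follow
overdamped first-order dynamics `eta dr/dt = F^c + F^a` integrated with
forward Euler.

The active force pulls along edges (tricellular junctions): each edge
carries a tension `gamma` performing Ornstein–Uhlenbeck dynamics with
baseline `gamma0`, relaxation time `tau_m` and long-time standard
deviation `sigma` (Euler–Maruyama discretization; at `dt = 0.005`,
`tau_m = 1` the stationary-variance discretization bias is +0.25%, well
inside the statistical tolerances used in tests).

### Topological transitions as graph transformations

All cell rearrangements are expressed as declarative transformation
graphs: a list of relation deletions and signed relation creations over a
fixed set of *roles* (`v1..v3`, `e1..e9`, `p1..p10`, `c1..c5`).  Pattern
matching binds roles to concrete nodes around an anchor (a short edge, a
triangle, or a six-fold vertex); the transformation engine then executes
the lists, resolving the signs of created relations at apply time:

* a vertex that replaces another on an edge inherits its sign
  (`s'_{i,j} = s_{k,j}`);
* a new edge-in-polygon (or polygon-in-cell) sign is the unique value
  that restores cycle (surface) closure at the shared vertex (edge),
  `sigma'_{i,j} = -s'_{k,i} s'_{k,l} sigma_{l,j}`.

The implemented transitions are the elementary edge-to-vertex (EV),
vertex-to-triangle (VT), triangle-to-vertex (TV) and vertex-to-edge (VE)
events, their composites ET (= EV then VT) and TE (= TV then VE), and the
planar T1.  ET and TE are stored as single templates equal to the exact
difference of the canonical E/T neighbourhood relation lists; the test
suite verifies that executing EV followed by VT (with the resolution
partition inherited from the vanished edge's side polygons) produces the
identical topology.  We chose the single-template form as primary because
the dimensional reduction is then immediate: roles whose defining elements
do not exist stay unbound and their operations are skipped, so applying ET
to a 2D tiling executes exactly the T1 transformation graph (asserted by
explicit graph equality).

**Resolution directions.** A six-fold vertex admits (generically) four
partitions of its edges into three polygon-aligned pairs; a VT must choose
one, and a VE must choose the two "end" cells of the new edge.  Inside the
ET/TE composites these choices are fixed by the matched neighbourhood
(side polygons of the vanished edge; cells that shared the vanished
triangle), making the composites deterministic given the match.
Standalone VT/VE take the choice as an argument or draw a seeded-random
admissible one.

**Rule enforcement and rollback.** After every transformation the affected
neighbourhood is checked against the topological rules (edge pairs share
at most one vertex, polygon pairs at most one edge, cell pairs at most one
polygon) and both closure conditions; a violating transformation is
reversed exactly (topology and positions) from its recorded operation log
and reported.  The check is *delta-based*: only violations not already
present before the transformation cause a rollback.  This matters for two
legitimate situations: the canonical five-cell neighbourhood fixtures are
open patches (their boundary is not closed), and very small periodic
crystals (e.g. the 16-cell Kelvin lattice, where every cell meets its
square-face neighbour through both periodic images) violate the
cell-sharing rule intrinsically.  Aggregates of 54 cells and larger are
strictly clean and are tested as such.

## Periodic geometry

Vertex positions are stored unwrapped (free-floating); every geometric
quantity is computed in locally consistent frames built from minimum-image
displacements.  Polygons are unwrapped edge-by-edge along their cycle;
cells by a breadth-first walk over their edges, which stays coherent as
long as individual edges are much shorter than half the box (true by
orders of magnitude in all supported configurations).  The public
`unwrap_*` helpers enforce a half-box span bound by default; the internal
vectorized engine relaxes the bound to the full box, which small
disordered packings (32 cells) require.  Cell volumes are computed with
centroid-anchored tetrahedra after unwrapping; for a closed surface this
equals the origin-anchored form, and anchor independence is asserted in
tests (divergence identity).

A `GeometryCache` flattens polygon cycles and outward-oriented cell-face
fans into index arrays once per topology change; areas, volumes, energies,
forces and edge lengths are then pure vectorized expressions of the packed
position array.

## Transition detection

After each Euler step, edges shorter than `l_th` whose length decreased
since the previous step (backward difference) become candidates, processed
in seeded-random order.  A candidate belonging to a triangle whose three
edges are all shorter than `l_th` and whose area decreased triggers a TE
on the triangle; otherwise the edge attempts an ET (a T1 in 2D).  An ET on
an edge of a triangle necessarily violates rule (i) and is rejected by the
rollback machinery — this is the expected, logged mechanism by which
triangles are funnelled into TE instead.  Repositioning after a
transformation places new elements on the scale `l_new`: the new triangle
of an ET is an equilateral triangle of edge `l_new` in the plane through
the vanished edge's midpoint perpendicular to its direction, with vertices
at 120-degree-snapped angles pointing as nearly as possible toward their
side-polygon centroids; a TE places the two new vertices at the triangle
centroid ± `l_new/2` along its normal, oriented so each vertex moves into
its end cell.  New edges start at the baseline tension `gamma0`.

Defaults (all exposed in configuration): `dt = 0.005`, `l_th = 0.03`,
`l_new = 0.05`, `Gamma = 1`, `kappa_V = 100`, `V0 = 1`, `eta = 1`,
`tau_m = 1`, `gamma0 = 0`.  Volumes are normalized to `V0 = 1`; the other
values are conventional choices of this class of models (the published
study does not print them) and were fixed before any sweep was run.

## Generators (the synthetic world)

* **Kelvin crystal** — the Voronoi packing of the BCC lattice, built
  analytically from the truncated-octahedron template (24 vertices at the
  permutations of `(0, a/4, a/2)`), replicated `n_x × n_y × n_z` times
  with two cells per cubic cell of side `a = (2 V0)^(1/3)`.  At least two
  replications per axis are required (a single replication identifies a
  cell's opposite faces through the boundary).  Signs are assigned
  geometrically: `sigma` from the construction cycle, `Sigma` from the
  outward-normal test; both closures then hold by construction.
* **Disordered packing** — random sequential addition of `N` equal hard
  spheres (default diameter 0.8 of the mean centre spacing
  `(V/N)^(1/3)`), periodic Voronoi tessellation via the 27-image trick,
  Voronoi vertices merged across images within `1e-7 L`.  At diameter
  fraction 0.9 RSA saturates before placing 128 spheres, so the usable
  density window above the 0.8 default is narrow.
* **Honeycomb tiling** — a periodic 2D hexagonal tiling (unit cell area
  normalized), used for the planar-reduction and T1 tests.

What the generators do *not* emulate: polydispersity, non-equilibrium
initial tension states, and any boundary effects (everything is fully
periodic).  A green test on these worlds establishes the correctness of
the topology engine and mechanics, not quantitative agreement with any
particular tissue.

## Known limitations and finite-size effects

* The order-disorder sweep mandated for desk-scale acceptance uses a
  16-cell aggregate.  Its order parameter `1 - f14` is quantized in steps
  of `2/16 = 0.125`, so the onset criterion "exceeds 0.05" detects the
  first persistent rearrangement; the measured onset (`sigma* ≈ 0.055`,
  bracket (0.05, 0.10)) is therefore strongly finite-size-shifted below
  the value published for 128 cells (0.17).  A 128-cell run with the same
  parameters stays far more ordered at `sigma = 0.10` than the 16-cell
  system does (`examples/06_finite_size_of_the_transition.py` computes
  both side by side), consistent with a finite-size shift rather than a
  mechanics discrepancy.
* The seed-averaged fraction of 14-faced cells in the disordered packing
  is 0.168 ± 0.008 at the default sphere diameter fraction 0.8; the
  published value (0.234) is a single 128-cell realization at an
  unpublished RSA density (its own sampling standard deviation is about
  0.037), and `f14` increases with RSA density.  We do not tune the
  density toward the published number.
* Rollback-mediated rejections are frequent at high noise (many short
  edges re-attempt transitions while unresolved); this mirrors the
  reported behaviour that many transitions are reversible and re-trigger.
* The integrator is plain forward Euler; no adaptive stepping.  A
  divergent step (displacement beyond half the box) aborts with a
  diagnostic rather than silently aliasing through the periodic images.
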