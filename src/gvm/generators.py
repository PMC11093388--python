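"""Initial configurations: Kelvin crystal, disordered sphere-Voronoi, 2D tiling.

Three generators cover the configurations needed for crystalline and
disordered simulations and for planar tests:

* :func:`kelvin_lattice` -- the body-centred-cubic Voronoi packing of
  truncated octahedra (14 faces: 8 regular hexagons and 6 squares), built
  analytically from the Wigner-Seitz template of the BCC lattice;
* :func:`rsa_voronoi` -- a disordered packing obtained by random sequential
  addition of equal hard spheres in a periodic box followed by the periodic
  Voronoi tessellation of the sphere centres;
* :func:`hex_tiling_2d` -- a periodic honeycomb for planar T1 tests.

All outputs carry closure-consistent signs assigned geometrically: each
polygon's positive direction follows its construction cycle, edge head/tail
follows first traversal, and the polygon-in-cell sign is +1 when the cycle
normal points away from the cell centre.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.spatial import Voronoi, cKDTree

from .graph import GVMGraph
from .geometry import SimulationBox, minimum_image

__all__ = ["kelvin_lattice", "rsa_voronoi", "rsa_points", "hex_tiling_2d"]


# ---------------------------------------------------------------- assembling

def _assemble(cells, vert_coords, box: SimulationBox, dim: int = 3,
              v0s=None) -> tuple[GVMGraph, dict[int, np.ndarray]]:
    """Build a signed graph from per-cell face cycles of global vertex keys.

    ``cells``: list of (centre, faces) where each face is a list of vertex
    keys in cyclic geometric order; ``vert_coords``: key -> representative
    (wrapped) coordinate.  For ``dim=2`` pass a single pseudo-cell holding
    all polygons; no Cell nodes are created.
    """
    g = GVMGraph(dim)
    vid: dict = {}
    positions: dict[int, np.ndarray] = {}
    for key, coord in vert_coords.items():
        v = g.add_node("vertex")
        vid[key] = v
        positions[v] = np.asarray(coord, dtype=float)
    edge_id: dict = {}
    poly_id: dict = {}
    poly_cycle: dict = {}
    for ci, (center, faces) in enumerate(cells):
        center = np.asarray(center, dtype=float)
        if dim == 3:
            props = {"v0": v0s[ci]} if v0s is not None else {}
            c = g.add_node("cell", **props)
        for face in faces:
            key = frozenset(face)
            if key in poly_id:
                p = poly_id[key]
            else:
                p = g.add_node("polygon")
                poly_id[key] = p
                poly_cycle[key] = list(face)
                n = len(face)
                for i in range(n):
                    a, b = face[i], face[(i + 1) % n]
                    ek = frozenset((a, b))
                    if ek in edge_id:
                        e = edge_id[ek]
                        sigma = g.sign(("vertex", vid[b]), ("edge", e))
                    else:
                        e = g.add_node("edge")
                        edge_id[ek] = e
                        g.add_relation(("vertex", vid[b]), ("edge", e), +1)
                        g.add_relation(("vertex", vid[a]), ("edge", e), -1)
                        sigma = +1
                    g.add_relation(("edge", e), ("polygon", p), sigma)
            if dim == 3:
                cyc = poly_cycle[key]
                coords = np.array([center + minimum_image(vert_coords[k] - center, box)
                                   for k in cyc])
                cen = coords.mean(axis=0)
                u = coords - cen
                normal = np.cross(u, np.roll(u, -1, axis=0)).sum(axis=0)
                Sigma = +1 if float(normal @ (cen - center)) > 0 else -1
                g.add_relation(("polygon", p), ("cell", c), Sigma)
    return g, positions


def _angle_sorted(coords: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Indices sorting coplanar points cyclically around ``axis``."""
    cen = coords.mean(axis=0)
    axis = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ axis) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    t1 = np.cross(axis, ref)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(axis, t1)
    rel = coords - cen
    return np.argsort(np.arctan2(rel @ t2, rel @ t1))


# ------------------------------------------------------------- Kelvin lattice

def _kelvin_template(a: float):
    """Vertices and faces of the truncated octahedron of the BCC lattice
    with cubic lattice constant ``a`` (cell volume a^3/2)."""
    vs = []
    for perm in itertools.permutations(range(3)):
        for s1 in (-1, 1):
            for s2 in (-1, 1):
                v = np.zeros(3)
                v[perm[0]] = 0.0
                v[perm[1]] = s1 * a / 4
                v[perm[2]] = s2 * a / 2
                vs.append(tuple(np.round(v, 12)))
    verts = np.array(sorted(set(vs)))
    assert len(verts) == 24
    faces = []
    for axis in range(3):
        for s in (-1, 1):
            sel = verts[np.abs(verts[:, axis] - s * a / 2) < 1e-9]
            normal = np.zeros(3)
            normal[axis] = s
            faces.append(sel[_angle_sorted(sel, normal)])
    for sx, sy, sz in itertools.product((-1, 1), repeat=3):
        normal = np.array([sx, sy, sz], dtype=float)
        sel = verts[np.abs(verts @ normal - 3 * a / 4) < 1e-9]
        faces.append(sel[_angle_sorted(sel, normal)])
    return faces  # 6 squares then 8 hexagons


def kelvin_lattice(n_x: int, n_y: int, n_z: int, v0: float = 1.0):
    """Periodic Kelvin (truncated-octahedron) crystal with 2*n_x*n_y*n_z cells.

    Returns ``(graph, positions, box)``.  Every cell has volume ``v0``;
    the box is the cubic supercell of the underlying BCC lattice.
    """
    if min(n_x, n_y, n_z) < 2:
        # with a single replication a cell's opposite faces wrap onto the
        # same polygon, which is not a valid closed-surface packing
        raise ValueError("kelvin_lattice requires at least 2 replications per axis")
    a = (2.0 * v0) ** (1.0 / 3.0)
    box = SimulationBox((n_x * a, n_y * a, n_z * a))
    faces_template = _kelvin_template(a)
    quarter = a / 4.0
    mods = (4 * n_x, 4 * n_y, 4 * n_z)

    def vkey(coord):
        q = np.round(coord / quarter).astype(int)
        return tuple(int(q[i]) % mods[i] for i in range(3))

    vert_coords = {}
    cells = []
    for i in range(n_x):
        for j in range(n_y):
            for k in range(n_z):
                for off in (np.zeros(3), np.array([0.5, 0.5, 0.5]) * a):
                    center = np.array([i, j, k]) * a + off
                    faces = []
                    for tpl in faces_template:
                        cyc = []
                        for vtx in tpl:
                            coord = center + vtx
                            key = vkey(coord)
                            if key not in vert_coords:
                                vert_coords[key] = np.array(key) * quarter
                            cyc.append(key)
                        faces.append(cyc)
                    cells.append((center, faces))
    g, positions = _assemble(cells, vert_coords, box, dim=3,
                             v0s=[v0] * len(cells))
    return g, positions, box


# --------------------------------------------------------------- RSA Voronoi

def rsa_points(n: int, diameter: float, box: SimulationBox, rng,
               max_attempts: int | None = None) -> np.ndarray:
    """Random sequential addition of ``n`` equal hard spheres (periodic)."""
    L = box.L
    pts: list[np.ndarray] = []
    attempts = 0
    cap = max_attempts or 20000 * n
    while len(pts) < n:
        if attempts >= cap:
            raise RuntimeError(
                f"random sequential addition saturated at {len(pts)}/{n} spheres")
        attempts += 1
        x = rng.random(3) * L
        if pts:
            d = minimum_image(np.asarray(pts) - x, box)
            if np.min(np.einsum("ij,ij->i", d, d)) < diameter * diameter:
                continue
        pts.append(x)
    return np.asarray(pts)


def rsa_voronoi(n: int, diameter_fraction: float = 0.8, seed=None,
                v0: float = 1.0, rng=None, merge_tol: float = 1e-7):
    """Disordered packing: periodic Voronoi diagram of RSA sphere centres.

    The box is a cube of volume ``n * v0``; the sphere diameter is
    ``diameter_fraction`` times the mean centre spacing ``(v0)**(1/3)``.
    Returns ``(graph, positions, box)``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    L = (n * v0) ** (1.0 / 3.0)
    box = SimulationBox((L, L, L))
    diameter = diameter_fraction * v0 ** (1.0 / 3.0)
    sites = rsa_points(n, diameter, box, rng)

    shifts = np.array(list(itertools.product((-1, 0, 1), repeat=3)), dtype=float) * L
    # central copy first so sites 0..n-1 are the originals
    order = np.argsort(np.einsum("ij,ij->i", shifts, shifts), kind="stable")
    shifts = shifts[order]
    all_pts = (sites[None, :, :] + shifts[:, None, :]).reshape(-1, 3)
    vor = Voronoi(all_pts)

    # merge Voronoi vertices across periodic images
    used = sorted({iv for (i, j), ridge in zip(vor.ridge_points, vor.ridge_vertices)
                   if (i < n or j < n) and -1 not in ridge for iv in ridge})
    coords = vor.vertices[np.array(used)]
    wrapped = coords - np.floor(coords / L) * L
    tree = cKDTree(wrapped, boxsize=L)
    pairs = tree.query_pairs(r=merge_tol * L)
    parent = list(range(len(used)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in pairs:
        parent[find(i)] = find(j)
    local = {iv: k for k, iv in enumerate(used)}
    key_of = {iv: find(local[iv]) for iv in used}
    vert_coords = {}
    for iv in used:
        vert_coords.setdefault(key_of[iv], wrapped[local[iv]])

    faces_of_cell: dict[int, list[list[int]]] = {i: [] for i in range(n)}
    for (i, j), ridge in zip(vor.ridge_points, vor.ridge_vertices):
        if -1 in ridge:
            continue
        for site in (i, j):
            if site < n:
                pts = vor.vertices[np.array(ridge)]
                axis = all_pts[j] - all_pts[i]
                cyc_order = _angle_sorted(pts, axis)
                cyc = [key_of[ridge[t]] for t in cyc_order]
                # collapse vertices merged into the same id
                clean = [k for t, k in enumerate(cyc) if k != cyc[t - 1]]
                if len(clean) >= 3:
                    faces_of_cell[site].append(clean)

    # interior faces are produced once from each side; deduplicate per cell
    cells = []
    for i in range(n):
        seen = set()
        faces = []
        for f in faces_of_cell[i]:
            k = frozenset(f)
            if k not in seen:
                seen.add(k)
                faces.append(f)
        cells.append((sites[i], faces))
    g, positions = _assemble(cells, vert_coords, box, dim=3, v0s=[v0] * n)
    return g, positions, box


# ------------------------------------------------------------------ 2D tiling

def hex_tiling_2d(n_x: int, n_y: int, area: float = 1.0):
    """Periodic honeycomb tiling with n_x * n_y hexagonal cells (n_y even).

    Polygons are the cells of the 2D representation; the graph has no Cell
    nodes.  Returns ``(graph, positions, box)``.
    """
    if n_y % 2:
        raise ValueError("n_y must be even for a periodic honeycomb")
    s = (2.0 * area / (3.0 * np.sqrt(3.0))) ** 0.5
    w = np.sqrt(3.0) * s
    box = SimulationBox((n_x * w, n_y * 1.5 * s, 1.0),
                        periodic=(True, True, False))
    corner_offsets = [np.array([np.cos(np.pi / 6 + k * np.pi / 3),
                                np.sin(np.pi / 6 + k * np.pi / 3), 0.0]) * s
                      for k in range(6)]

    def vkey(coord):
        qx = int(np.round(2 * coord[0] / w)) % (2 * n_x)
        qy = int(np.round(2 * coord[1] / s)) % (3 * n_y)
        return (qx, qy)

    vert_coords = {}
    faces = []
    for j in range(n_y):
        for i in range(n_x):
            center = np.array([(i + 0.5 * (j % 2)) * w, j * 1.5 * s, 0.0])
            cyc = []
            for off in corner_offsets:
                coord = center + off
                key = vkey(coord)
                if key not in vert_coords:
                    c2 = coord.copy()
                    c2[0] -= np.floor(c2[0] / box.L[0]) * box.L[0]
                    c2[1] -= np.floor(c2[1] / box.L[1]) * box.L[1]
                    vert_coords[key] = c2
                cyc.append(key)
            faces.append(cyc)
    g, positions = _assemble([(np.zeros(3), faces)], vert_coords, box, dim=2)
    return g, positions, box
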