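"""Periodic-box geometry: areas, volumes, analytic gradients, energy, forces.

All coordinates live in a rectangular box, periodic per axis.  Vertex
positions are stored *unwrapped* (free-floating); every geometric quantity
is computed on locally consistent coordinates obtained from minimum-image
displacements, so the stored values may drift outside [0, L) harmlessly.

The mechanical model assigns each cell-cell interface (polygon) a uniform
surface tension and each cell a quadratic volume-elasticity term::

    W = sum_polygons Gamma_p A_p + kappa_V * sum_cells (V_l - V0_l)^2

Forces on vertices are the exact negative gradients of W; the analytic
gradient formulas are written against the fan triangulation of each polygon
about its centroid, which is also how areas and volumes are defined, so
force and energy are consistent to machine precision (verified against
finite differences in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import GVMGraph, TopologyError

__all__ = [
    "SimulationBox",
    "MechanicsParams",
    "minimum_image",
    "unwrap_polygon",
    "unwrap_cell",
    "polygon_centroid",
    "polygon_area",
    "polygon_normal",
    "polygon_area_gradient",
    "cell_volume",
    "cell_surface_area",
    "cell_volume_gradient",
    "energy",
    "conservative_forces",
    "conservative_force",
    "shape_parameter",
    "GeometryCache",
]


@dataclass(frozen=True)
class SimulationBox:
    """Rectangular simulation box, periodic per axis."""

    lengths: tuple[float, float, float]
    periodic: tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self):
        if any(L <= 0 for L in self.lengths):
            raise ValueError("box lengths must be positive")

    @property
    def L(self) -> np.ndarray:
        return np.asarray(self.lengths, dtype=float)

    @property
    def volume(self) -> float:
        return float(np.prod(self.L))


def minimum_image(delta: np.ndarray, box: SimulationBox) -> np.ndarray:
    """Minimum-image displacement(s); works on (..., 3) arrays."""
    delta = np.asarray(delta, dtype=float)
    L = box.L
    shift = np.where(box.periodic, np.round(delta / L), 0.0)
    return delta - shift * L


@dataclass
class MechanicsParams:
    """Mechanical parameters of the tension-plus-volume-elasticity energy.

    Attributes
    ----------
    surface_tension:
        Interface tension Gamma (energy/area), uniform by default; per-polygon
        overrides via ``tension_table``.
    kappa_v:
        Volume-elasticity modulus kappa_V (energy/volume^2).
    v0:
        Default preferred cell volume; a cell node's ``v0`` property, if
        present, takes precedence.
    eta:
        Vertex friction coefficient (force*time/length) of the overdamped
        dynamics; must be positive.
    """

    surface_tension: float = 1.0
    kappa_v: float = 100.0
    v0: float = 1.0
    eta: float = 1.0
    tension_table: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.kappa_v < 0 or self.eta <= 0 or self.v0 <= 0:
            raise ValueError("require kappa_v >= 0, eta > 0, v0 > 0")

    def polygon_tension(self, pid: int) -> float:
        return self.tension_table.get(pid, self.surface_tension)


# --------------------------------------------------------------- local frames

def _cycle_coords(cycle: list[int], positions, box: SimulationBox) -> np.ndarray:
    """Coordinates of a vertex cycle, unwrapped sequentially from its start."""
    out = np.empty((len(cycle), 3))
    out[0] = positions[cycle[0]]
    for i in range(1, len(cycle)):
        step = minimum_image(np.asarray(positions[cycle[i]]) -
                             np.asarray(positions[cycle[i - 1]]), box)
        out[i] = out[i - 1] + step
    return out


def unwrap_polygon(graph: GVMGraph, positions, box: SimulationBox, p: int,
                   max_span_fraction: float = 0.5) -> tuple[list[int], np.ndarray]:
    """(cycle, coords): the polygon's vertex cycle in one consistent frame.

    Raises if the unwrapped polygon spans more than ``max_span_fraction``
    of the box in any axis; at the default one half the plain minimum-image
    convention is unambiguous, and the cycle itself is unwrapped edge by
    edge so larger (but sub-box) elements remain coherent when the caller
    relaxes the bound.
    """
    cycle = graph.polygon_vertex_cycle(p)
    coords = _cycle_coords(cycle, positions, box)
    span = coords.max(axis=0) - coords.min(axis=0)
    if np.any(span > max_span_fraction * box.L * (1 + 1e-9)):
        raise TopologyError(f"polygon {p}: geometry too large for minimum image")
    return cycle, coords


def unwrap_cell(graph: GVMGraph, positions, box: SimulationBox, c: int,
                max_span_fraction: float = 0.5) -> dict[int, np.ndarray]:
    """Locally consistent coordinates of all vertices of a cell.

    Breadth-first walk over the cell's edges, unwrapping each step by
    minimum image; coherent as long as individual edges are much shorter
    than half the box.
    """
    polys = graph.cell_polygons(c)
    edges: set[int] = set()
    for p in polys:
        edges.update(graph.polygon_edges(p))
    adj: dict[int, list[int]] = {}
    for e in edges:
        vs = list(graph.edge_vertices(e))
        if len(vs) != 2:
            raise TopologyError(f"cell {c}: open surface (edge {e})")
        adj.setdefault(vs[0], []).append(vs[1])
        adj.setdefault(vs[1], []).append(vs[0])
    root = next(iter(adj))
    coords = {root: np.asarray(positions[root], dtype=float)}
    queue = [root]
    while queue:
        v = queue.pop()
        for w in adj[v]:
            if w not in coords:
                step = minimum_image(np.asarray(positions[w]) -
                                     np.asarray(positions[v]), box)
                coords[w] = coords[v] + step
                queue.append(w)
    if len(coords) != len(adj):
        raise TopologyError(f"cell {c}: vertex network not connected")
    span = (np.array([max(x[i] for x in coords.values()) -
                      min(x[i] for x in coords.values()) for i in range(3)]))
    if np.any(span > max_span_fraction * box.L * (1 + 1e-9)):
        raise TopologyError(f"cell {c}: geometry too large for minimum image")
    return coords


# ------------------------------------------------------- per-element geometry

def polygon_centroid(graph, positions, box, p: int,
                     max_span_fraction: float = 0.5) -> np.ndarray:
    """Mean of the minimum-image-unwrapped cycle vertices."""
    _, coords = unwrap_polygon(graph, positions, box, p, max_span_fraction)
    return coords.mean(axis=0)


def _fan_areas(coords: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """(total area, per-triangle cross products w_mu, centroid)."""
    c = coords.mean(axis=0)
    u = coords - c
    w = np.cross(u, np.roll(u, -1, axis=0))
    return 0.5 * np.linalg.norm(w, axis=1).sum(), w, c


def polygon_area(graph, positions, box, p: int) -> float:
    """Fan-triangulated area about the polygon centroid.

    Valid for non-planar polygons: the area is the sum of the norms of the
    triangle elements spanned by consecutive vertices and the centroid.
    """
    cycle, coords = unwrap_polygon(graph, positions, box, p)
    if len(cycle) < 3:
        raise TopologyError(f"polygon {p} is degenerate (<3 vertices)")
    return _fan_areas(coords)[0]


def polygon_normal(graph, positions, box, p: int,
                   max_span_fraction: float = 0.5) -> np.ndarray:
    """Area-weighted unit normal by the right-hand rule on the positive cycle."""
    _, coords = unwrap_polygon(graph, positions, box, p, max_span_fraction)
    _, w, _ = _fan_areas(coords)
    n = w.sum(axis=0)
    nn = np.linalg.norm(n)
    if nn == 0:
        raise TopologyError(f"polygon {p} has vanishing normal")
    return n / nn


def polygon_area_gradient(graph, positions, box, p: int, v: int) -> np.ndarray:
    """d(area)/d(position of vertex v), including the centroid terms."""
    cycle, coords = unwrap_polygon(graph, positions, box, p)
    if v not in cycle:
        raise TopologyError(f"vertex {v} is not part of polygon {p}")
    n = len(cycle)
    c = coords.mean(axis=0)
    u = coords - c
    unext = np.roll(u, -1, axis=0)
    w = np.cross(u, unext)
    wn = np.linalg.norm(w, axis=1)
    ok = wn > 0
    ga = np.zeros_like(u)
    gb = np.zeros_like(u)
    ga[ok] = np.cross(unext[ok], w[ok]) / (2 * wn[ok, None])
    gb[ok] = np.cross(w[ok], u[ok]) / (2 * wn[ok, None])
    i = cycle.index(v)
    grad = ga[i] + gb[(i - 1) % n] - (ga + gb).sum(axis=0) / n
    return grad


def _oriented_cell_faces(graph: GVMGraph, c: int):
    """Yield (pid, cycle) with cycles oriented outward (normal away from cell)."""
    for p, Sig in graph.cell_polygons(c).items():
        cycle = graph.polygon_vertex_cycle(p)
        yield p, (cycle if Sig == +1 else cycle[::-1])


def cell_volume(graph, positions, box, c: int) -> float:
    """Volume as a sum of tetrahedra over outward-oriented face fans."""
    coords = unwrap_cell(graph, positions, box, c, max_span_fraction=1.0)
    ref = np.mean(list(coords.values()), axis=0)
    vol = 0.0
    for p, cycle in _oriented_cell_faces(graph, c):
        r = np.array([coords[v] for v in cycle]) - ref
        cf = r.mean(axis=0)
        vol += np.sum(np.cross(r, np.roll(r, -1, axis=0)) @ cf) / 6.0
    return float(vol)


def cell_surface_area(graph, positions, box, c: int) -> float:
    return sum(polygon_area(graph, positions, box, p)
               for p in graph.cell_polygons(c))


def cell_volume_gradient(graph, positions, box, c: int, v: int) -> np.ndarray:
    """d(volume)/d(position of vertex v) for an outward-oriented closed cell."""
    coords = unwrap_cell(graph, positions, box, c, max_span_fraction=1.0)
    if v not in coords:
        raise TopologyError(f"vertex {v} is not part of cell {c}")
    ref = np.mean(list(coords.values()), axis=0)
    grad = np.zeros(3)
    for p, cycle in _oriented_cell_faces(graph, c):
        if v not in cycle:
            continue
        n = len(cycle)
        r = np.array([coords[w] for w in cycle]) - ref
        rnext = np.roll(r, -1, axis=0)
        cf = r.mean(axis=0)
        i = cycle.index(v)
        grad += np.cross(r, rnext).sum(axis=0) / (6.0 * n)
        grad += np.cross(rnext[i], cf) / 6.0
        grad += np.cross(cf, r[(i - 1) % n]) / 6.0
    return grad


# -------------------------------------------------------------- cached engine

class GeometryCache:
    """Vectorized geometry engine for a fixed topology.

    Builds flat index arrays (polygon corner lists, outward-oriented cell
    face corner lists, edge endpoint lists) and per-element minimum-image
    offsets once; areas, volumes, energies and forces are then pure numpy
    expressions of the packed position array.  Rebuild after every
    topological change.
    """

    def __init__(self, graph: GVMGraph, positions, box: SimulationBox):
        self.graph = graph
        self.box = box
        self.vids = list(graph.vertices)
        self.vidx = {v: i for i, v in enumerate(self.vids)}
        self.pos = np.array([positions[v] for v in self.vids], dtype=float)
        if self.pos.size:
            self.pos = self.pos.reshape(len(self.vids), 3)

        # --- edges
        self.eids = list(graph.edges)
        self.eidx = {e: i for i, e in enumerate(self.eids)}
        heads, tails = [], []
        for e in self.eids:
            h, t = graph.edge_endpoints(e)
            heads.append(self.vidx[h])
            tails.append(self.vidx[t])
        self.e_head = np.array(heads, dtype=np.intp)
        self.e_tail = np.array(tails, dtype=np.intp)

        # --- polygon corners
        self.pids = list(graph.polygons)
        self.pidx = {p: i for i, p in enumerate(self.pids)}
        self.cycles = {}
        cv, cnv, cpoly, offa, offb = [], [], [], [], []
        self.p_nverts = np.zeros(len(self.pids), dtype=np.intp)
        L = box.L
        for j, p in enumerate(self.pids):
            cycle = graph.polygon_vertex_cycle(p)
            self.cycles[p] = cycle
            n = len(cycle)
            self.p_nverts[j] = n
            offs = [np.zeros(3)]
            for i in range(1, n):
                d = np.asarray(positions[cycle[i]]) - np.asarray(positions[cycle[i - 1]])
                shift = np.where(box.periodic, np.round(d / L), 0.0)
                offs.append(offs[-1] - shift * L)
            for i in range(n):
                cv.append(self.vidx[cycle[i]])
                cnv.append(self.vidx[cycle[(i + 1) % n]])
                cpoly.append(j)
                offa.append(offs[i])
                offb.append(offs[(i + 1) % n])
        self.c_v = np.array(cv, dtype=np.intp)
        self.c_nv = np.array(cnv, dtype=np.intp)
        self.c_poly = np.array(cpoly, dtype=np.intp)
        self.c_offa = np.array(offa, dtype=float).reshape(-1, 3)
        self.c_offb = np.array(offb, dtype=float).reshape(-1, 3)

        # --- cell face corners (outward oriented, cell-coherent frames)
        self.cids = list(graph.cells)
        self.cidx = {c: i for i, c in enumerate(self.cids)}
        fv_a, fv_b, f_offa, f_offb, f_cell, f_face = [], [], [], [], [], []
        face_nverts = []
        face_counter = 0
        self.cell_polys = []
        for k, c in enumerate(self.cids):
            coords = unwrap_cell(graph, positions, box, c, max_span_fraction=1.0)
            off = {v: coords[v] - np.asarray(positions[v]) for v in coords}
            self.cell_polys.append(list(graph.cell_polygons(c)))
            for p, cycle in _oriented_cell_faces(graph, c):
                n = len(cycle)
                face_nverts.append(n)
                for i in range(n):
                    a, b = cycle[i], cycle[(i + 1) % n]
                    fv_a.append(self.vidx[a])
                    fv_b.append(self.vidx[b])
                    f_offa.append(off[a])
                    f_offb.append(off[b])
                    f_cell.append(k)
                    f_face.append(face_counter)
                face_counter += 1
        self.f_a = np.array(fv_a, dtype=np.intp)
        self.f_b = np.array(fv_b, dtype=np.intp)
        self.f_offa = np.array(f_offa, dtype=float).reshape(-1, 3)
        self.f_offb = np.array(f_offb, dtype=float).reshape(-1, 3)
        self.f_cell = np.array(f_cell, dtype=np.intp)
        self.f_face = np.array(f_face, dtype=np.intp)
        self.face_nverts = np.array(face_nverts, dtype=np.intp)
        self.n_faces = face_counter

    # ------------------------------------------------------------- quantities

    def edge_vectors(self, pos: np.ndarray | None = None) -> np.ndarray:
        pos = self.pos if pos is None else pos
        return minimum_image(pos[self.e_head] - pos[self.e_tail], self.box)

    def edge_lengths(self, pos: np.ndarray | None = None) -> np.ndarray:
        return np.linalg.norm(self.edge_vectors(pos), axis=1)

    def _poly_frames(self, pos):
        ra = pos[self.c_v] + self.c_offa
        rb = pos[self.c_nv] + self.c_offb
        cen = np.zeros((len(self.pids), 3))
        np.add.at(cen, self.c_poly, ra)
        cen /= self.p_nverts[:, None]
        return ra, rb, cen

    def polygon_areas(self, pos: np.ndarray | None = None) -> np.ndarray:
        pos = self.pos if pos is None else pos
        ra, rb, cen = self._poly_frames(pos)
        w = np.cross(ra - cen[self.c_poly], rb - cen[self.c_poly])
        wn = np.linalg.norm(w, axis=1)
        areas = np.zeros(len(self.pids))
        np.add.at(areas, self.c_poly, 0.5 * wn)
        return areas

    def polygon_centroids(self, pos: np.ndarray | None = None) -> np.ndarray:
        pos = self.pos if pos is None else pos
        return self._poly_frames(pos)[2]

    def _cell_frames(self, pos):
        ra = pos[self.f_a] + self.f_offa
        rb = pos[self.f_b] + self.f_offb
        cen = np.zeros((self.n_faces, 3))
        np.add.at(cen, self.f_face, ra)
        cen /= self.face_nverts[:, None]
        return ra, rb, cen

    def cell_volumes(self, pos: np.ndarray | None = None) -> np.ndarray:
        pos = self.pos if pos is None else pos
        ra, rb, cen = self._cell_frames(pos)
        contrib = np.einsum("ij,ij->i", np.cross(ra, rb), cen[self.f_face]) / 6.0
        vols = np.zeros(len(self.cids))
        np.add.at(vols, self.f_cell, contrib)
        return vols

    def cell_surface_areas(self, pos: np.ndarray | None = None) -> np.ndarray:
        areas = self.polygon_areas(pos)
        out = np.zeros(len(self.cids))
        for k, polys in enumerate(self.cell_polys):
            out[k] = sum(areas[self.pidx[p]] for p in polys)
        return out

    # ------------------------------------------------------- energy and force

    def _tensions(self, params: MechanicsParams) -> np.ndarray:
        if not params.tension_table:
            return np.full(len(self.pids), params.surface_tension)
        return np.array([params.polygon_tension(p) for p in self.pids])

    def _v0(self, params: MechanicsParams) -> np.ndarray:
        return np.array([self.graph.cells[c].get("v0", params.v0)
                         for c in self.cids])

    def energy(self, pos: np.ndarray | None = None,
               params: MechanicsParams | None = None) -> float:
        pos = self.pos if pos is None else pos
        params = params or MechanicsParams()
        surf = float(self._tensions(params) @ self.polygon_areas(pos))
        if not self.cids:
            return surf
        dv = self.cell_volumes(pos) - self._v0(params)
        return surf + params.kappa_v * float(dv @ dv)

    def conservative_forces(self, pos: np.ndarray | None = None,
                            params: MechanicsParams | None = None) -> np.ndarray:
        """-dW/dr for every vertex, analytic."""
        pos = self.pos if pos is None else pos
        params = params or MechanicsParams()
        force = np.zeros_like(pos)

        # surface-tension term
        gam = self._tensions(params)[self.c_poly]
        ra, rb, cen = self._poly_frames(pos)
        u = ra - cen[self.c_poly]
        un = rb - cen[self.c_poly]
        w = np.cross(u, un)
        wn = np.linalg.norm(w, axis=1)
        safe = np.where(wn > 1e-300, wn, 1.0)
        ga = np.cross(un, w) / (2 * safe[:, None])
        gb = np.cross(w, u) / (2 * safe[:, None])
        ga[wn <= 1e-300] = 0.0
        gb[wn <= 1e-300] = 0.0
        np.add.at(force, self.c_v, -gam[:, None] * ga)
        np.add.at(force, self.c_nv, -gam[:, None] * gb)
        psum = np.zeros((len(self.pids), 3))
        np.add.at(psum, self.c_poly, ga + gb)
        corr = (psum / self.p_nverts[:, None])[self.c_poly]
        np.add.at(force, self.c_v, gam[:, None] * corr)

        # volume-elasticity term
        if self.cids:
            dv = self.cell_volumes(pos) - self._v0(params)
            q = 2.0 * params.kappa_v * dv  # dW/dV
            ra, rb, cen = self._cell_frames(pos)
            qf = q[self.f_cell][:, None]
            cf = cen[self.f_face]
            cross_ab = np.cross(ra, rb)
            fsum = np.zeros((self.n_faces, 3))
            np.add.at(fsum, self.f_face, cross_ab)
            np.add.at(force, self.f_a,
                      -qf * (np.cross(rb, cf) / 6.0 +
                             (fsum / (6.0 * self.face_nverts[:, None]))[self.f_face]))
            np.add.at(force, self.f_b, -qf * np.cross(cf, ra) / 6.0)
        return force

    def shape_factors(self, pos: np.ndarray | None = None) -> np.ndarray:
        """Per-cell S_l / V_l^(2/3)."""
        S = self.cell_surface_areas(pos)
        V = self.cell_volumes(pos)
        return S / np.maximum(V, 1e-300) ** (2.0 / 3.0)


# --------------------------------------------------------------- functional API

def energy(graph, positions, box, params: MechanicsParams | None = None) -> float:
    """Total potential energy of the aggregate."""
    return GeometryCache(graph, positions, box).energy(params=params)


def conservative_forces(graph, positions, box,
                        params: MechanicsParams | None = None) -> dict[int, np.ndarray]:
    cache = GeometryCache(graph, positions, box)
    F = cache.conservative_forces(params=params)
    return {v: F[i] for i, v in enumerate(cache.vids)}


def conservative_force(graph, positions, box, v: int,
                       params: MechanicsParams | None = None) -> np.ndarray:
    return conservative_forces(graph, positions, box, params)[v]


def shape_parameter(graph, positions, box) -> float:
    """Mean dimensionless cell shape factor q = <S_l / V_l^(2/3)>."""
    cache = GeometryCache(graph, positions, box)
    return float(cache.shape_factors().mean())
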