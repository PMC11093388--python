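"""Periodic geometry: areas, volumes, analytic gradients, energy, forces."""

import numpy as np
import pytest

import gvm
from gvm.geometry import (GeometryCache, MechanicsParams, SimulationBox,
                          minimum_image)
from gvm.graph import GVMGraph, TopologyError

Q_KELVIN = (6 + 12 * np.sqrt(3.0)) / (8 * np.sqrt(2.0)) ** (2.0 / 3.0)


@pytest.fixture
def perturbed16(kelvin16):
    g, pos, box = kelvin16
    rng = np.random.default_rng(0)
    for v in pos:
        pos[v] = pos[v] + 0.02 * rng.standard_normal(3)
    return g, pos, box


def _square_polygon(straddle=False):
    """One unit square in a unit box, optionally straddling the x boundary."""
    g = GVMGraph(dim=2)
    box = SimulationBox((4.0, 4.0, 4.0))
    x0 = 3.92 if straddle else 1.0  # 3.92 + 0.16 wraps across x = 4
    pts = [np.array([x0, 1.0, 0.0]), np.array([(x0 + 0.16) % 4.0, 1.0, 0.0]),
           np.array([(x0 + 0.16) % 4.0, 1.16, 0.0]), np.array([x0, 1.16, 0.0])]
    vs = [g.add_node("vertex") for _ in pts]
    p = g.add_node("polygon")
    for i in range(4):
        e = g.add_node("edge")
        g.add_relation(("vertex", vs[(i + 1) % 4]), ("edge", e), +1)
        g.add_relation(("vertex", vs[i]), ("edge", e), -1)
        g.add_relation(("edge", e), ("polygon", p), +1)
    return g, dict(zip(vs, pts)), box, p


def test_unwrap_handles_boundary_straddling():
    g, pos, box, p = _square_polygon(straddle=True)
    cycle, coords = gvm.unwrap_polygon(g, pos, box, p)
    span = coords.max(axis=0) - coords.min(axis=0)
    assert np.allclose(span[:2], [0.16, 0.16], atol=1e-12)
    assert gvm.polygon_area(g, pos, box, p) == pytest.approx(0.16 * 0.16)
    # a polygon wider than half the box is rejected under the default bound
    g2 = GVMGraph(dim=2)
    xs = [0.0, 1.5, 3.0, 3.0, 1.5, 0.0]
    ys = [0.0, 0.0, 0.0, 0.5, 0.5, 0.5]
    pts = [np.array([x, y, 0.0]) for x, y in zip(xs, ys)]
    vs = [g2.add_node("vertex") for _ in pts]
    p2 = g2.add_node("polygon")
    for i in range(6):
        e = g2.add_node("edge")
        g2.add_relation(("vertex", vs[(i + 1) % 6]), ("edge", e), +1)
        g2.add_relation(("vertex", vs[i]), ("edge", e), -1)
        g2.add_relation(("edge", e), ("polygon", p2), +1)
    with pytest.raises(TopologyError, match="too large"):
        gvm.unwrap_polygon(g2, dict(zip(vs, pts)), box, p2)


def test_polygon_area_and_centroid_basics():
    g, pos, box, p = _square_polygon()
    assert gvm.polygon_area(g, pos, box, p) == pytest.approx(0.0256)
    assert np.allclose(gvm.polygon_centroid(g, pos, box, p),
                       [1.08, 1.08, 0.0])


def test_kelvin_face_areas(kelvin16):
    """Square faces of the unit-volume truncated octahedron have area a^2,
    hexagons (3 sqrt(3)/2) a^2, with a = (8 sqrt 2)^(-1/3)."""
    g, pos, box = kelvin16
    a = (8 * np.sqrt(2.0)) ** (-1.0 / 3.0)
    for p in list(g.polygons)[:30]:
        n = len(g.polygon_edges(p))
        area = gvm.polygon_area(g, pos, box, p)
        expected = a * a if n == 4 else 1.5 * np.sqrt(3.0) * a * a
        assert area == pytest.approx(expected, rel=1e-12)


def test_nonplanar_quad_matches_fan_triangulation_oracle():
    g, pos, box, p = _square_polygon()
    cycle = g.polygon_vertex_cycle(p)
    pos[cycle[0]] = pos[cycle[0]] + np.array([0.0, 0.0, 0.11])  # butterfly lift
    coords = np.array([pos[v] for v in cycle])
    c = coords.mean(axis=0)
    oracle = sum(0.5 * np.linalg.norm(np.cross(coords[i] - c,
                                               coords[(i + 1) % 4] - c))
                 for i in range(4))
    assert gvm.polygon_area(g, pos, box, p) == pytest.approx(oracle, rel=1e-12)


def test_area_gradient_matches_finite_differences(perturbed16):
    g, pos, box = perturbed16
    h = 1e-6
    rng = np.random.default_rng(1)
    pids = sorted(g.polygons)
    for p in rng.choice(pids, size=5, replace=False):
        p = int(p)
        cycle = g.polygon_vertex_cycle(p)
        v = cycle[int(rng.integers(len(cycle)))]
        grad = gvm.polygon_area_gradient(g, pos, box, p, v)
        for k in range(3):
            pp = {w: x.copy() for w, x in pos.items()}
            pp[v][k] += h
            ap = gvm.polygon_area(g, pp, box, p)
            pp[v][k] -= 2 * h
            am = gvm.polygon_area(g, pp, box, p)
            fd = (ap - am) / (2 * h)
            assert grad[k] == pytest.approx(fd, rel=1e-5, abs=1e-8)
        # translation invariance: per-polygon gradients sum to zero
        total = sum(gvm.polygon_area_gradient(g, pos, box, p, w) for w in cycle)
        assert np.allclose(total, 0.0, atol=1e-10)
    with pytest.raises(TopologyError):
        gvm.polygon_area_gradient(g, pos, box, pids[0], -1)


def test_cube_cell_volume_and_gradient(unit_cube):
    g, pos, box = unit_cube
    c = next(iter(g.cells))
    assert gvm.cell_volume(g, pos, box, c) == pytest.approx(1.0, rel=1e-12)
    assert gvm.cell_surface_area(g, pos, box, c) == pytest.approx(6.0, rel=1e-12)
    h = 1e-6
    v = next(iter(g.vertices))
    grad = gvm.cell_volume_gradient(g, pos, box, c, v)
    for k in range(3):
        pp = {w: x.copy() for w, x in pos.items()}
        pp[v][k] += h
        vp = gvm.cell_volume(g, pp, box, c)
        pp[v][k] -= 2 * h
        vm = gvm.cell_volume(g, pp, box, c)
        assert grad[k] == pytest.approx((vp - vm) / (2 * h), rel=1e-5, abs=1e-9)


def test_cell_volumes_partition_the_box(perturbed16):
    g, pos, box = perturbed16
    cache = GeometryCache(g, pos, box)
    vols = cache.cell_volumes()
    assert vols.sum() == pytest.approx(box.volume, rel=1e-12)
    assert (vols > 0).all()
    # functional route agrees with the vectorized cache
    for c in list(g.cells)[:4]:
        assert gvm.cell_volume(g, pos, box, c) == pytest.approx(
            vols[cache.cidx[c]], rel=1e-12)


def test_forces_match_energy_finite_differences(perturbed16):
    g, pos, box = perturbed16
    params = MechanicsParams(surface_tension=1.0, kappa_v=100.0, v0=1.0)
    cache = GeometryCache(g, pos, box)
    F = cache.conservative_forces(params=params)
    h = 1e-6
    rng = np.random.default_rng(2)
    for i in rng.integers(len(cache.vids), size=6):
        for k in range(3):
            p1 = cache.pos.copy()
            p1[i, k] += h
            p2 = cache.pos.copy()
            p2[i, k] -= h
            fd = -(cache.energy(p1, params) - cache.energy(p2, params)) / (2 * h)
            assert F[i, k] == pytest.approx(fd, rel=1e-5, abs=1e-6)
    assert np.allclose(F.sum(axis=0), 0.0, atol=1e-10)


def test_perfect_kelvin_is_force_free(kelvin16):
    g, pos, box = kelvin16
    cache = GeometryCache(g, pos, box)
    F = cache.conservative_forces(params=MechanicsParams())
    assert np.abs(F).max() < 1e-10


def test_energy_terms(kelvin16):
    g, pos, box = kelvin16
    cache = GeometryCache(g, pos, box)
    areas = cache.polygon_areas().sum()
    p1 = MechanicsParams(surface_tension=1.0)
    p2 = MechanicsParams(surface_tension=2.0)
    # all volumes at V0: the energy is exactly the tension-weighted area
    assert cache.energy(params=p1) == pytest.approx(areas, rel=1e-12)
    assert cache.energy(params=p2) == pytest.approx(2 * areas, rel=1e-12)
    # per-polygon overrides take precedence over the uniform tension
    special = sorted(g.polygons)[0]
    p3 = MechanicsParams(surface_tension=1.0, tension_table={special: 3.0})
    a0 = cache.polygon_areas()[cache.pidx[special]]
    assert cache.energy(params=p3) == pytest.approx(areas + 2 * a0, rel=1e-12)


def test_shape_parameter(kelvin16):
    g, pos, box = kelvin16
    q = gvm.shape_parameter(g, pos, box)
    assert q == pytest.approx(Q_KELVIN, rel=1e-12)
    assert q > (36 * np.pi) ** (1.0 / 3.0)  # isoperimetric lower bound
    # scale invariance
    pos2 = {v: 2.0 * x for v, x in pos.items()}
    box2 = SimulationBox(tuple(2.0 * L for L in box.lengths))
    assert gvm.shape_parameter(g, pos2, box2) == pytest.approx(q, rel=1e-12)


def test_energy_translation_invariance(perturbed16):
    g, pos, box = perturbed16
    shift = np.array([0.3, -1.2, 0.7])
    pos2 = {v: x + shift for v, x in pos.items()}
    assert gvm.energy(g, pos2, box) == pytest.approx(gvm.energy(g, pos, box),
                                                     rel=1e-12)
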