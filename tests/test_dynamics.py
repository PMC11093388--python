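"""Overdamped integration, OU tension noise, transition detection."""

import numpy as np
import pytest

import gvm
from gvm.dynamics import (IntegratorConfig, InstabilityError, Simulation,
                          TensionParams, active_force, ou_step)
from gvm.geometry import GeometryCache, MechanicsParams, SimulationBox, minimum_image
from gvm.graph import GVMGraph


def test_ou_noiseless_limit_is_exponential_relaxation():
    p = TensionParams(gamma0=0.5, tau_m=2.0, sigma=0.0)
    gamma, dt = 3.0, 0.01
    for _ in range(10):
        gamma = ou_step(gamma, dt, p, None)
    # Euler discretization of exponential decay toward gamma0
    expected = 0.5 + 2.5 * (1 - dt / 2.0) ** 10
    assert gamma == pytest.approx(expected, rel=1e-12)


def test_ou_stationary_statistics_and_autocorrelation():
    """Long-run mean gamma0, variance sigma^2, lag-tau autocorrelation 1/e."""
    p = TensionParams(gamma0=0.2, tau_m=1.0, sigma=0.4)
    rng = np.random.default_rng(123)
    dt, nsteps, npar = 0.01, 120_000, 8
    gamma = np.full(npar, p.gamma0)
    lag = int(round(p.tau_m / dt))
    trace = np.empty((nsteps, npar))
    for i in range(nsteps):
        gamma = ou_step(gamma, dt, p, rng)
        trace[i] = gamma
    samples = trace[nsteps // 10:]
    flat = samples.ravel()
    # standard error of the mean for correlated samples ~ sigma*sqrt(2*tau/T)
    assert flat.mean() == pytest.approx(p.gamma0, abs=4 * 0.4 * np.sqrt(
        2 * p.tau_m / (nsteps * dt * npar)))
    assert flat.var() == pytest.approx(p.sigma ** 2, rel=0.05)
    x = samples[:-lag].ravel() - flat.mean()
    y = samples[lag:].ravel() - flat.mean()
    rho = (x * y).mean() / flat.var()
    assert rho == pytest.approx(np.exp(-1.0), abs=0.05)


def test_active_force_single_edge_is_contractile():
    g = GVMGraph(dim=3)
    v1, v2 = g.add_node("vertex"), g.add_node("vertex")
    e = g.add_node("edge")
    g.add_relation(("vertex", v1), ("edge", e), +1)
    g.add_relation(("vertex", v2), ("edge", e), -1)
    box = SimulationBox((10.0, 10.0, 10.0))
    pos = {v1: np.array([1.0, 0.0, 0.0]), v2: np.array([3.5, 0.0, 0.0])}
    gamma = {e: 0.7}
    F1 = active_force(g, pos, box, gamma, v1)
    F2 = active_force(g, pos, box, gamma, v2)
    assert np.allclose(F1, [0.7, 0, 0]) and np.allclose(F2, [-0.7, 0, 0])


def test_active_force_vanishes_on_uniform_kelvin(kelvin16):
    g, pos, box = kelvin16
    gamma = {e: 0.3 for e in g.edges}
    for v in list(g.vertices)[:8]:
        assert np.linalg.norm(active_force(g, pos, box, gamma, v)) < 1e-12


def test_active_force_is_gradient_of_length_energy(kelvin16):
    g, pos, box = kelvin16
    rng = np.random.default_rng(4)
    for v in pos:
        pos[v] = pos[v] + 0.02 * rng.standard_normal(3)
    gamma = {e: float(rng.normal(0.0, 0.3)) for e in g.edges}

    def length_energy(positions):
        tot = 0.0
        for e in g.edges:
            h, t = g.edge_endpoints(e)
            tot += gamma[e] * np.linalg.norm(
                minimum_image(positions[h] - positions[t], box))
        return tot

    h_fd = 1e-6
    for v in list(g.vertices)[:4]:
        F = active_force(g, pos, box, gamma, v)
        for k in range(3):
            pp = {w: x.copy() for w, x in pos.items()}
            pp[v][k] += h_fd
            ep = length_energy(pp)
            pp[v][k] -= 2 * h_fd
            em = length_energy(pp)
            assert F[k] == pytest.approx(-(ep - em) / (2 * h_fd),
                                         rel=1e-5, abs=1e-7)


def test_zero_noise_descent_and_friction_scaling(kelvin16):
    g, pos, box = kelvin16
    rng = np.random.default_rng(0)
    for v in pos:
        pos[v] = pos[v] + 0.02 * rng.standard_normal(3)

    sim = Simulation(g.copy(), pos, box)
    energies = [sim.energy()]
    for _ in range(40):
        sim.step()
        energies.append(sim.energy())
    assert all(b <= a + 1e-12 for a, b in zip(energies, energies[1:]))
    assert energies[-1] < energies[0]

    # doubling the friction halves the first displacement
    sim1 = Simulation(g.copy(), pos, box, mech=MechanicsParams(eta=1.0))
    sim2 = Simulation(g.copy(), pos, box, mech=MechanicsParams(eta=2.0))
    start = sim1.cache.pos.copy()
    sim1.step()
    sim2.step()
    d1 = sim1.cache.pos - start
    d2 = sim2.cache.pos - start
    assert np.allclose(d2, 0.5 * d1, atol=1e-14)


def test_kelvin_with_zero_noise_never_rearranges(kelvin16):
    g, pos, box = kelvin16
    sim = Simulation(g, pos, box, tension=TensionParams(sigma=0.0))
    sim.run(t_max=1.0)
    assert sim.events == []
    assert gvm.order_parameter(sim.graph) == 0.0


def _shrink_edge(sim, e, target):
    """Move an edge's endpoints symmetrically to the requested length."""
    h, t = sim.graph.edge_endpoints(e)
    ih, it = sim.cache.vidx[h], sim.cache.vidx[t]
    d = minimum_image(sim.cache.pos[ih] - sim.cache.pos[it], sim.box)
    mid = sim.cache.pos[it] + 0.5 * d
    u = d / np.linalg.norm(d)
    sim.cache.pos[ih] = mid + 0.5 * target * u
    sim.cache.pos[it] = mid - 0.5 * target * u


def test_detection_requires_short_and_contracting(kelvin16):
    g, pos, box = kelvin16
    cfg = IntegratorConfig(dt=0.005, l_th=0.03, l_new=0.02, seed=9)
    sim = Simulation(g, pos, box, config=cfg)
    e = sorted(g.edges)[17]
    # prime the backward-difference cache, then shrink the edge
    assert sim.detect_and_apply_transitions() == []
    _shrink_edge(sim, e, 0.9 * cfg.l_th)
    events = sim.detect_and_apply_transitions()
    assert [ev["type"] for ev in events] == ["ET"]
    assert sim.n_et == 1
    # a short edge that is *growing* must not trigger
    g2, pos2, box2 = gvm.kelvin_lattice(2, 2, 2)
    sim2 = Simulation(g2, pos2, box2, config=cfg)
    e2 = sorted(sim2.graph.edges)[3]
    _shrink_edge(sim2, e2, 0.5 * cfg.l_th)
    sim2.detect_and_apply_transitions()
    _shrink_edge(sim2, e2, 0.9 * cfg.l_th)
    assert sim2.detect_and_apply_transitions() == []


def test_shrinking_triangle_triggers_one_te_not_three_et(kelvin16):
    g, pos, box = kelvin16
    cfg = IntegratorConfig(dt=0.005, l_th=0.03, l_new=0.05, seed=10)
    sim = Simulation(g, pos, box, config=cfg)
    assert sim.detect_and_apply_transitions() == []
    _shrink_edge(sim, sorted(g.edges)[40], 0.9 * cfg.l_th)
    (ev,) = sim.detect_and_apply_transitions()
    assert ev["type"] == "ET"
    # the newly created interface is the small (edge length l_new) triangle
    lengths = {e: L for e, L in zip(sim.cache.eids, sim.cache.edge_lengths())}
    (tri,) = [p for p in sim.graph.polygons
              if len(sim.graph.polygon_edges(p)) == 3
              and all(lengths[e] < 0.1 for e in sim.graph.polygon_edges(p))]
    # prime caches (records the triangle area), then shrink the triangle
    # uniformly about its centroid so all edges contract below threshold
    sim.detect_and_apply_transitions()
    verts = {v for e in sim.graph.polygon_edges(tri)
             for v in sim.graph.edge_vertices(e)}
    idx = [sim.cache.vidx[v] for v in verts]
    cen = sim.cache.pos[idx].mean(axis=0)
    sim.cache.pos[idx] = cen + 0.4 * (sim.cache.pos[idx] - cen)
    events = sim.detect_and_apply_transitions()
    assert [e2["type"] for e2 in events] == ["TE"]
    assert sim.n_te == 1 and sim.n_et == 1


def test_event_log_is_bit_reproducible(kelvin16):
    runs = []
    for _ in range(2):
        cfg = gvm.SimConfig(initial=("kelvin", 2, 2, 2),
                            tension=TensionParams(sigma=0.4),
                            integrator=IntegratorConfig(dt=0.005, seed=42),
                            t_max=3.0, record_every=100, seed=42)
        runs.append(gvm.run_simulation(cfg))
    assert runs[0].events == runs[1].events
    assert runs[0].timeseries.equals(runs[1].timeseries)
    p0 = runs[0].positions
    p1 = runs[1].positions
    assert set(p0) == set(p1)
    assert all(np.array_equal(p0[v], p1[v]) for v in p0)


def test_instability_is_reported(kelvin16):
    g, pos, box = kelvin16
    rng = np.random.default_rng(0)
    for v in pos:
        pos[v] = pos[v] + 0.05 * rng.standard_normal(3)
    sim = Simulation(g, pos, box, config=IntegratorConfig(dt=50.0))
    with pytest.raises(InstabilityError, match="smaller dt"):
        for _ in range(50):
            sim.step()
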