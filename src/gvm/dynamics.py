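"""Overdamped vertex dynamics with fluctuating active junctional tensions.

Vertices follow first-order (inertia-free) dynamics

    eta * dr_i/dt = F_i^c + F_i^a,

integrated with forward Euler.  The conservative force is the exact
gradient of the tension + volume-elasticity energy (:mod:`gvm.geometry`);
the active force pulls along every edge (tricellular junction) with a
per-edge tension gamma that performs Ornstein-Uhlenbeck dynamics

    dgamma/dt = -(gamma - gamma0)/tau_m + xi(t),
    <xi(t) xi(t')> = (2 sigma^2 / tau_m) delta(t - t'),

so gamma relaxes to gamma0 on timescale tau_m with long-time standard
deviation sigma (Euler-Maruyama discretization).

After every integration step, edges shorter than the threshold l_th whose
length is decreasing trigger an edge-to-triangle transition; if such an
edge belongs to a triangle whose edges are all short and whose area is
shrinking, the whole triangle is converted to an edge instead.  Length and
area rates are backward finite differences between consecutive accepted
steps.  A transition that would break a topological rule is rolled back
and logged as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import GeometryCache, MechanicsParams, SimulationBox, minimum_image
from .graph import GVMGraph
from . import transforms as tr

__all__ = ["TensionParams", "IntegratorConfig", "ou_step", "active_force",
           "Simulation", "InstabilityError"]


class InstabilityError(RuntimeError):
    """Non-finite positions encountered; reduce the time step."""


@dataclass
class TensionParams:
    """Ornstein-Uhlenbeck parameters of the active junctional tension."""

    gamma0: float = 0.0   # baseline tension
    tau_m: float = 1.0    # myosin-turnover relaxation time
    sigma: float = 0.0    # long-time standard deviation

    def __post_init__(self):
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")


@dataclass
class IntegratorConfig:
    """Time stepping and transition-detection thresholds."""

    dt: float = 0.005
    l_th: float = 0.03    # edges shorter than this may rearrange
    l_new: float = 0.05   # length scale of newly created edges
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0 or self.l_th <= 0 or self.l_new <= 0:
            raise ValueError("dt, l_th and l_new must be positive")


def ou_step(gamma, dt: float, params: TensionParams, rng) -> np.ndarray:
    """One Euler-Maruyama update of the tension(s); works element-wise."""
    gamma = np.asarray(gamma, dtype=float)
    drift = -(dt / params.tau_m) * (gamma - params.gamma0)
    if params.sigma == 0.0:
        return gamma + drift
    amp = np.sqrt(2.0 * params.sigma ** 2 * dt / params.tau_m)
    return gamma + drift + amp * rng.standard_normal(gamma.shape)


def active_force(graph: GVMGraph, positions, box: SimulationBox,
                 tension: dict[int, float], v: int) -> np.ndarray:
    """Active force on one vertex: -sum over incident edges of gamma * grad L.

    The length gradient at an endpoint is the unit vector pointing from the
    other endpoint toward it (minimum image), so positive tension is
    contractile.
    """
    F = np.zeros(3)
    for e in graph.vertex_edges(v):
        other = [w for w in graph.edge_vertices(e) if w != v]
        if len(other) != 1:
            continue
        d = minimum_image(np.asarray(positions[v]) - np.asarray(positions[other[0]]),
                          box)
        L = np.linalg.norm(d)
        if L > 0:
            F -= tension.get(e, 0.0) * d / L
    return F


class Simulation:
    """Time-stepping engine coupling mechanics, noise and rearrangements.

    All randomness (tension noise, candidate ordering, role labelling)
    draws from the single generator constructed from ``config.seed``, so a
    run is reproducible bit for bit from its configuration.
    """

    def __init__(self, graph: GVMGraph, positions: dict[int, np.ndarray],
                 box: SimulationBox, mech: MechanicsParams | None = None,
                 tension: TensionParams | None = None,
                 config: IntegratorConfig | None = None,
                 rng: np.random.Generator | None = None):
        self.graph = graph
        self.positions = {v: np.asarray(x, dtype=float)
                          for v, x in positions.items()}
        self.box = box
        self.mech = mech or MechanicsParams()
        self.tension_params = tension or TensionParams()
        self.config = config or IntegratorConfig()
        self.rng = rng if rng is not None else np.random.default_rng(self.config.seed)
        self.time = 0.0
        self.tension = {e: self.tension_params.gamma0 for e in graph.edges}
        self.events: list[dict] = []
        self.n_et = 0
        self.n_te = 0
        self.n_rolled_back = 0
        self._prev_len: dict[int, float] = {}
        self._prev_area: dict[int, float] = {}
        self._sweep_prev_area: dict[int, float] = {}
        self._rebuild()

    # ------------------------------------------------------------- bookkeeping

    def _rebuild(self) -> None:
        self.cache = GeometryCache(self.graph, self.positions, self.box)
        self.gamma = np.array([self.tension[e] for e in self.cache.eids])

    def _sync_positions(self) -> None:
        for i, v in enumerate(self.cache.vids):
            self.positions[v] = self.cache.pos[i].copy()

    def _sync_tension(self) -> None:
        for i, e in enumerate(self.cache.eids):
            self.tension[e] = float(self.gamma[i])

    # ------------------------------------------------------------------ forces

    def _active_forces(self, pos: np.ndarray) -> np.ndarray:
        d = self.cache.edge_vectors(pos)           # head - tail
        L = np.linalg.norm(d, axis=1)
        unit = np.divide(d, L[:, None], out=np.zeros_like(d), where=L[:, None] > 0)
        F = np.zeros_like(pos)
        np.add.at(F, self.cache.e_head, -self.gamma[:, None] * unit)
        np.add.at(F, self.cache.e_tail, self.gamma[:, None] * unit)
        return F

    def forces(self, pos: np.ndarray | None = None) -> np.ndarray:
        pos = self.cache.pos if pos is None else pos
        return self.cache.conservative_forces(pos, self.mech) + self._active_forces(pos)

    def energy(self) -> float:
        return self.cache.energy(params=self.mech)

    # ------------------------------------------------------------------- steps

    def step(self) -> list[dict]:
        """Advance one time step; returns the topological events performed."""
        cfg = self.config
        pos = self.cache.pos
        F = self.forces(pos)
        disp = (cfg.dt / self.mech.eta) * F
        # displacements beyond half the box alias through the periodic
        # minimum image; treat them as a blown-up integration, not geometry
        if (not np.all(np.isfinite(disp))
                or (np.abs(disp).max(initial=0.0) > 0.5 * float(self.box.L.min()))):
            raise InstabilityError(
                f"divergent vertex displacement at t={self.time:.4f}; "
                "consider a smaller dt")
        pos += disp
        if not np.all(np.isfinite(pos)):
            raise InstabilityError(
                f"non-finite vertex position at t={self.time:.4f}; "
                "consider a smaller dt")
        self.gamma = ou_step(self.gamma, cfg.dt, self.tension_params, self.rng)
        self.time += cfg.dt
        return self.detect_and_apply_transitions()

    def run(self, t_max: float, observer=None, observe_every: int = 0) -> None:
        """Iterate steps until ``self.time >= t_max``.

        ``observer(sim)`` is called every ``observe_every`` steps (and once
        at the start and end) when provided.
        """
        nstep = 0
        if observer is not None:
            observer(self)
        while self.time < t_max - 1e-12:
            self.step()
            nstep += 1
            if observer is not None and observe_every and nstep % observe_every == 0:
                observer(self)
        self._sync_positions()
        self._sync_tension()
        if observer is not None and (not observe_every or nstep % observe_every):
            observer(self)

    # -------------------------------------------------------------- transitions

    def _triangle_of(self, e: int) -> int | None:
        """A triangle polygon containing ``e`` that meets the TE criteria."""
        cfg = self.config
        for p in self.graph.edge_polygons(e):
            edges = self.graph.polygon_edges(p)
            if len(edges) != 3:
                continue
            prev_area = self._sweep_prev_area.get(p)
            if prev_area is None:
                continue
            lengths = []
            ok = True
            for e2 in edges:
                h, t = self.graph.edge_endpoints(e2)
                d = minimum_image(self.positions[h] - self.positions[t], self.box)
                L = float(np.linalg.norm(d))
                if L >= cfg.l_th:
                    ok = False
                    break
                lengths.append(L)
            if not ok:
                continue
            from .geometry import polygon_area
            if polygon_area(self.graph, self.positions, self.box, p) < prev_area:
                return p
        return None

    def detect_and_apply_transitions(self) -> list[dict]:
        """One sweep of threshold-based rearrangements after a step.

        Edges shorter than ``l_th`` with negative backward-difference
        length rate are processed in seeded-random order; each flagged edge
        triggers a triangle-to-edge transition when it lies in a shrinking
        all-short triangle, otherwise an edge-to-triangle transition.
        Violating transformations are reversed and logged.
        """
        cfg = self.config
        lengths = self.cache.edge_lengths()
        eids = self.cache.eids
        candidates = []
        for i, e in enumerate(eids):
            prev = self._prev_len.get(e)
            if prev is not None and lengths[i] < cfg.l_th and lengths[i] < prev:
                candidates.append(e)
        # refresh backward-difference caches for the next step; the sweep
        # below must still see the *previous* step's triangle areas
        self._prev_len = {e: float(lengths[i]) for i, e in enumerate(eids)}
        areas = self.cache.polygon_areas()
        self._sweep_prev_area = self._prev_area
        self._prev_area = {p: float(areas[j]) for j, p in enumerate(self.cache.pids)
                           if len(self.graph.polygon_edges(p)) == 3}
        if not candidates:
            return []
        self.rng.shuffle(candidates)
        self._sync_positions()
        done: list[dict] = []
        changed = False
        for e in candidates:
            if e not in self.graph.edges:
                continue
            h, t = self.graph.edge_endpoints(e)
            d = minimum_image(self.positions[h] - self.positions[t], self.box)
            if np.linalg.norm(d) >= cfg.l_th:
                continue
            tri = self._triangle_of(e) if self.graph.dim == 3 else None
            kind = "TE" if tri is not None else ("ET" if self.graph.dim == 3 else "T1")
            try:
                if kind == "TE":
                    rec = tr.apply_TE(self.graph, tri, positions=self.positions,
                                      box=self.box, l_new=cfg.l_new, rng=self.rng)
                elif kind == "ET":
                    rec = tr.apply_ET(self.graph, e, positions=self.positions,
                                      box=self.box, l_new=cfg.l_new, rng=self.rng)
                else:
                    rec = tr.apply_T1(self.graph, e, positions=self.positions,
                                      box=self.box, l_new=cfg.l_new, rng=self.rng)
            except (tr.TransformationRejected, tr.MatchError) as err:
                self.n_rolled_back += 1
                self.events.append({"time": self.time, "type": f"{kind}-rejected",
                                    "anchor": e, "detail": str(err)})
                continue
            cells = sorted({rec.roles[r] for r in rec.roles if r.startswith("c")})
            event = {"time": self.time, "type": kind,
                     "anchor": tri if kind == "TE" else e, "cells": cells}
            self.events.append(event)
            done.append(event)
            if kind == "TE":
                self.n_te += 1
            else:
                self.n_et += 1
            # tension bookkeeping: new edges start at the baseline tension
            for label, nid in rec.created_nodes:
                if label == "edge":
                    self.tension[nid] = self.tension_params.gamma0
            for label, nid, _props in rec.deleted_nodes:
                if label == "edge":
                    self.tension.pop(nid, None)
            for e_old in list(self._prev_len):
                if e_old not in self.graph.edges:
                    del self._prev_len[e_old]
            changed = True
            self._rebuild()
        if changed:
            # lengths of surviving edges are re-measured next step
            self._prev_area = {p: a for p, a in self._prev_area.items()
                               if p in self.graph.polygons}
        return done
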