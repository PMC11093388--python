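"""Order/disorder observables for aggregates of polyhedral cells.

The ordered reference state is the Kelvin crystal, in which every cell has
exactly 14 faces; the order parameter ``1 - f14`` measures the fraction of
cells that deviate from it, with ``f14 = N_14 / N_c``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import GeometryCache, SimulationBox
from .graph import GVMGraph

__all__ = ["f14", "order_parameter", "edge_length_distribution",
           "TransitionEstimate", "estimate_transition_point"]


def f14(graph: GVMGraph) -> float:
    """Fraction of cells with exactly 14 faces (polygon->cell relations)."""
    if not graph.cells:
        raise ValueError("f14 requires a 3D graph with cells")
    n14 = sum(1 for c in graph.cells if len(graph.cell_polygons(c)) == 14)
    return n14 / len(graph.cells)


def order_parameter(graph: GVMGraph) -> float:
    """1 - f14: zero for the Kelvin crystal, positive for disorder."""
    return 1.0 - f14(graph)


def edge_length_distribution(graph: GVMGraph, positions, box: SimulationBox,
                             bins=50, range=None):
    """Normalized histogram (density, bin edges) of minimum-image edge lengths."""
    cache = GeometryCache(graph, positions, box)
    lengths = cache.edge_lengths()
    return np.histogram(lengths, bins=bins, range=range, density=True)


@dataclass
class TransitionEstimate:
    """Interpolated onset of the order parameter along a noise sweep."""

    sigma_star: float | None
    bracket: tuple[float, float]
    monotone: bool


def estimate_transition_point(sigmas, order_params, threshold: float = 0.05
                              ) -> TransitionEstimate:
    """Smallest noise magnitude at which the order parameter exceeds a
    threshold, linearly interpolated between sweep grid points.

    Returns the crossing estimate together with the bracketing grid
    interval; ``monotone`` is False when the sweep re-enters the ordered
    regime after the first crossing (noisy sweep - trust the bracket, not
    the point).
    """
    sig = np.asarray(sigmas, dtype=float)
    val = np.asarray(order_params, dtype=float)
    if sig.shape != val.shape or sig.ndim != 1 or len(sig) < 2:
        raise ValueError("need matching 1D sweep arrays with >= 2 points")
    order = np.argsort(sig)
    sig, val = sig[order], val[order]
    above = val > threshold
    if not above.any():
        return TransitionEstimate(None, (float(sig[-1]), np.inf), True)
    i = int(np.argmax(above))
    if i == 0:
        return TransitionEstimate(float(sig[0]), (0.0, float(sig[0])), True)
    s0, s1 = sig[i - 1], sig[i]
    v0, v1 = val[i - 1], val[i]
    frac = (threshold - v0) / (v1 - v0) if v1 != v0 else 0.5
    sigma_star = float(s0 + frac * (s1 - s0))
    monotone = bool(above[i:].all())
    return TransitionEstimate(sigma_star, (float(s0), float(s1)), monotone)
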