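import numpy as np
import pytest

import gvm
from gvm.generators import _assemble
from gvm.geometry import SimulationBox


def copy_state(state):
    g, pos, box = state
    return g.copy(), {v: np.array(p) for v, p in pos.items()}, box


@pytest.fixture(scope="session")
def _kelvin16_master():
    return gvm.kelvin_lattice(2, 2, 2)


@pytest.fixture
def kelvin16(_kelvin16_master):
    """Fresh 16-cell Kelvin crystal (graph, positions, box)."""
    return copy_state(_kelvin16_master)


@pytest.fixture(scope="session")
def _kelvin128_master():
    return gvm.kelvin_lattice(4, 4, 4)


@pytest.fixture
def kelvin128(_kelvin128_master):
    """Fresh 128-cell Kelvin crystal."""
    return copy_state(_kelvin128_master)


@pytest.fixture
def hex44():
    """4x4 periodic honeycomb (2D mode)."""
    return gvm.hex_tiling_2d(4, 4)


@pytest.fixture
def unit_cube():
    """A single closed cubic cell (volume 1) in a large box."""
    box = SimulationBox((10.0, 10.0, 10.0))
    corners = list(np.ndindex(2, 2, 2))
    coords = {c: np.array(c, dtype=float) + 4.0 for c in corners}
    # faces as outward-orderable cycles (orientation fixed by the assembler)
    faces = [
        [(0, 0, 0), (0, 1, 0), (1, 1, 0), (1, 0, 0)],  # z = 0
        [(0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)],  # z = 1
        [(0, 0, 0), (1, 0, 0), (1, 0, 1), (0, 0, 1)],  # y = 0
        [(0, 1, 0), (0, 1, 1), (1, 1, 1), (1, 1, 0)],  # y = 1
        [(0, 0, 0), (0, 0, 1), (0, 1, 1), (0, 1, 0)],  # x = 0
        [(1, 0, 0), (1, 1, 0), (1, 1, 1), (1, 0, 1)],  # x = 1
    ]
    center = np.full(3, 4.5)
    g, pos = _assemble([(center, faces)], coords, box, dim=3, v0s=[1.0])
    return g, pos, box


def relation_signature(g):
    """Canonical (relation, sign) multiset for graph-equality assertions."""
    return sorted(g.relations())


def mapped_state_relations(state, roles):
    """Printed state relation list mapped through a role->id dictionary."""
    prefix = {"ve": ("v", "e"), "ep": ("e", "p"), "pc": ("p", "c")}
    out = set()
    for lv, s, t in gvm.STATE_RELATIONS[state]:
        a, b = prefix[lv]
        out.add((lv, roles.get(a + str(s), s), roles.get(b + str(t), t)))
    return out
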