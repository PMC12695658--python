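import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cablegrad.mechanisms import ChannelSpec, standard_hh_channels
from cablegrad.morphology import Section, build_cell_from_sections
from cablegrad.solver import NetworkModel, StepCurrent


@pytest.fixture
def passive_cell():
    """Single-compartment passive cell (leak to −65 mV) with a recording."""
    model = NetworkModel()
    model.add_cell(build_cell_from_sections([Section("soma", 20.0, 10.0, 1)]))
    model.insert_channel(0, ChannelSpec("leak", gbar=0.0003, e_rev=-65.0))
    model.record(0, 0)
    return model


@pytest.fixture
def hh_cell():
    """Single-compartment Hodgkin–Huxley cell with somatic recording."""
    model = NetworkModel()
    model.add_cell(build_cell_from_sections([Section("soma", 20.0, 10.0, 1)]))
    for spec in standard_hh_channels().values():
        model.insert_channel(0, spec)
    model.record(0, 0)
    return model


def make_random_tree_system(n, seed, complex_ok=False):
    """A random symmetric diagonally dominant tree system."""
    rng = np.random.default_rng(seed)
    parent = np.full(n, -1)
    for i in range(1, n):
        parent[i] = rng.integers(0, i)
    off = np.zeros(n)
    off[1:] = -rng.uniform(0.1, 1.0, n - 1)
    diag = rng.uniform(0.5, 1.5, n)
    # diagonal dominance: add |incident off-diagonal| mass
    for i in range(1, n):
        diag[i] += abs(off[i])
        diag[parent[i]] += abs(off[i])
    rhs = rng.normal(size=n)
    dense = np.diag(diag)
    for i in range(1, n):
        dense[i, parent[i]] = off[i]
        dense[parent[i], i] = off[i]
    return diag, off, rhs, parent, dense
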