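import numpy as np
import pytest

from spathaz.core_data import AdjacencyGraph
from spathaz.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def lattice6():
    return AdjacencyGraph.lattice(6, 6)


@pytest.fixture(scope="session")
def toy_km():
    """The four-child worked example: deaths at 1, 2, 4; censored at 3."""
    return np.array([1.0, 2.0, 3.0, 4.0]), np.array([1, 1, 0, 1])


@pytest.fixture(scope="session")
def small_cohort():
    """One modest lognormal cohort with truth, shared across read-only tests."""
    ds, truth = simulate_dataset(SimulationConfig(n_children=800, seed=11))
    return ds, truth


def random_toy_survival(rng, n_max=40):
    """Random small censored dataset for oracle cross-checks."""
    n = rng.integers(3, n_max)
    times = np.round(rng.uniform(0.5, 60.0, n), 1)
    events = rng.integers(0, 2, n)
    if events.sum() == 0:
        events[0] = 1
    return times, events
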