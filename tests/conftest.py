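import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rocreport as rr

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def perfect_data():
    """Perfectly separated classes: positives {3,4,5}, negatives {1,2}."""
    return rr.from_arrays([3, 4, 5, 1, 2], [1, 1, 1, 0, 0])


@pytest.fixture
def identical_data():
    """Exchangeable classes: both {1,2}."""
    return rr.from_arrays([1, 2, 1, 2], [1, 1, 0, 0])


@pytest.fixture
def tied_data():
    """Positives {3,4,5}, negatives {1,2,3}: one cross-class tie."""
    return rr.from_arrays([3, 4, 5, 1, 2, 3], [1, 1, 1, 0, 0, 0])


@pytest.fixture(scope="session")
def nafld_cohort():
    """One default-configuration simulated cohort (n=300, fixed seed)."""
    return rr.simulate_cohort(rr.SimulationConfig(seed=20240410))


def random_dataset(rng, n_max=30, n_min=2):
    """A random small dataset with both classes non-empty."""
    m = int(rng.integers(n_min, n_max // 2 + 1))
    n = int(rng.integers(n_min, n_max // 2 + 1))
    # mixture of continuous values and small integers to exercise ties
    if rng.random() < 0.5:
        pos = rng.normal(1.0, 1.0, m).round(1)
        neg = rng.normal(0.0, 1.0, n).round(1)
    else:
        pos = rng.integers(0, 6, m).astype(float)
        neg = rng.integers(0, 6, n).astype(float)
    return rr.from_arrays(
        np.concatenate([pos, neg]),
        np.concatenate([np.ones(m, int), np.zeros(n, int)]),
    )
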