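import numpy as np
import pytest
from hypothesis import settings

from wqsmix.synthetic import simulate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cohort200():
    """Small synthetic cohort shared by fast tests (n=200, fixed seed)."""
    cohort, quantiles = simulate_cohort(n=200, seed=11)
    return cohort, quantiles


@pytest.fixture(scope="session")
def cohort678():
    """Study-scale synthetic cohort (n=678, fixed seed)."""
    cohort, quantiles = simulate_cohort(n=678, seed=5)
    return cohort, quantiles


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
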