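import numpy as np
import pytest
from hypothesis import settings

from mitomr import CohortConfig, simulate_cohort

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """Shared medium-size cohort at default generative settings."""
    return simulate_cohort(CohortConfig(n_samples=1500, n_variants=60, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
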