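import numpy as np
import pytest

from langnet.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """Reduced cohort for fast structural tests (not the study conditions)."""
    return CohortConfig(
        group_sizes={"LFG": 5, "LTG": 5, "RFG": 5, "RTG": 5, "HC": 8},
        n_timepoints=120,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
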