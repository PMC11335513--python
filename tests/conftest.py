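import numpy as np
import pytest

from ssmmed.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort160():
    """Default planted cohort at the study's sample size."""
    return generate_cohort(CohortConfig(n_subjects=160, seed=7))


@pytest.fixture(scope="session")
def cohort500_low_noise():
    """Larger, low-noise cohort used for pattern-recovery tests."""
    config = CohortConfig(
        n_subjects=500, seed=11, region_noise_sd=0.01, hcy_loading=0.8
    )
    return generate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
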