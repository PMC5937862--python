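import numpy as np
import pytest

from chlorosom.synthetic import sample_cohort


@pytest.fixture(scope="session")
def cohort20():
    """Five-group cohort, 20 samples per group, shared across tests."""
    return sample_cohort(n_per_group=20, seed=7)


@pytest.fixture(scope="session")
def cohort_noiseless():
    """Small noise-free cohort for exact-recovery style checks."""
    return sample_cohort(n_per_group=10, seed=3, noise_sd=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
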