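import numpy as np
import pytest

from spinemark import SpineGenParams, default_profiles, generate_cohort


@pytest.fixture(scope="session")
def noiseless_params():
    """Small zero-jitter cohort parameters (exact geometric oracle)."""
    return SpineGenParams(n_cases=25, jitter_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_params):
    return generate_cohort(noiseless_params, default_profiles(5, seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
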