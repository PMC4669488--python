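import numpy as np
import pytest

from hepscale import cohort_to_frame, default_cohort_spec, generate_cohort


@pytest.fixture(scope="session")
def cohort78():
    """Calibrated 78-donor synthetic cohort at a fixed seed."""
    return generate_cohort(default_cohort_spec(n_donors=78, seed=0))


@pytest.fixture(scope="session")
def cohort78_frame(cohort78):
    return cohort_to_frame(cohort78)


@pytest.fixture
def small_cohort():
    return generate_cohort(default_cohort_spec(n_donors=8, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
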