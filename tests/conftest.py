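import numpy as np
import pytest

from riskerror import (
    DEFAULT_COEFFICIENTS,
    DEFAULT_COHORTS,
    ErrorSpecification,
    simulate_cohort,
)

# Fixed base seed for every stochastic test in the suite.
BASE_SEED = 2026


@pytest.fixture
def rng():
    return np.random.default_rng(BASE_SEED)


@pytest.fixture(params=["male", "female"])
def sex(request):
    return request.param


@pytest.fixture
def params(sex):
    return DEFAULT_COHORTS[sex]


@pytest.fixture
def coeffs(sex):
    return DEFAULT_COEFFICIENTS[sex]


@pytest.fixture
def male_params():
    return DEFAULT_COHORTS["male"]


@pytest.fixture
def female_params():
    return DEFAULT_COHORTS["female"]


@pytest.fixture
def male_coeffs():
    return DEFAULT_COEFFICIENTS["male"]


@pytest.fixture
def female_coeffs():
    return DEFAULT_COEFFICIENTS["female"]


@pytest.fixture
def no_error_cohort(params, coeffs):
    """One error-free cohort at the default parameters of the given sex."""
    return simulate_cohort(params, ErrorSpecification(), coeffs, BASE_SEED)
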