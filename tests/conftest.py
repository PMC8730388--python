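import pytest

from ckdscreen import CRNStream, generate_fixture_parameters
from ckdscreen.population import build_initial_population, derive_renal_age_profiles

SEED = 1


@pytest.fixture(scope="session")
def params():
    """Fixture parameter set; treated as immutable by all tests."""
    return generate_fixture_parameters(SEED)


@pytest.fixture(scope="session")
def profile(params):
    return derive_renal_age_profiles(params, 20_000, CRNStream(SEED))


@pytest.fixture(scope="session")
def initial_pop(params, profile):
    """Shared initial cohort; tests must clone() before advancing it."""
    return build_initial_population(20_000, params, profile, CRNStream(SEED))
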