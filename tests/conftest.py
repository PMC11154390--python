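import pytest
from hypothesis import HealthCheck, settings

from stickydisk import DEFAULT_CONSTANTS

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def constants():
    return DEFAULT_CONSTANTS


@pytest.fixture(scope="session")
def rt0(constants):
    return constants.rt0


@pytest.fixture(scope="session")
def study_betas(constants):
    """Attraction parameters of the three homologues at 293.15 K."""
    from stickydisk import beta_parameter
    return {n: beta_parameter(n, 293.15, constants).beta_total
            for n in (1, 2, 3)}
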