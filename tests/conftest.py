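import pytest
from hypothesis import HealthCheck, settings

from synflux import (
    CommunityFluxModel,
    assemble_model,
    get_culture,
    load_table1,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

QUAD = ("Rc", "Mh", "Mc", "Dv")


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def quad_control(table1):
    return get_culture(table1, species=QUAD, sulfate=False)


@pytest.fixture(scope="session")
def quad_sulfate(table1):
    return get_culture(table1, species=QUAD, sulfate=True)


@pytest.fixture(scope="session")
def control_model(quad_control):
    return CommunityFluxModel.from_observation(quad_control)


@pytest.fixture(scope="session")
def sulfate_model(quad_sulfate):
    return CommunityFluxModel.from_observation(quad_sulfate)


@pytest.fixture(scope="session")
def full_community():
    return assemble_model(QUAD, sulfate_present=True)


@pytest.fixture(scope="session")
def control_community():
    return assemble_model(QUAD, sulfate_present=False)
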