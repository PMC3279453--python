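import pytest
from hypothesis import HealthCheck, settings

from daly_iaq import core_data

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def demographics():
    return core_data.load_demographics()


@pytest.fixture(scope="session")
def concentrations():
    return core_data.load_concentrations()


@pytest.fixture(scope="session")
def cr_entries():
    return core_data.load_cr_functions()


@pytest.fixture(scope="session")
def stroke_strata():
    return core_data.load_stroke_strata()


@pytest.fixture(scope="session")
def attributed_outcomes():
    return core_data.load_attributed_outcomes()
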