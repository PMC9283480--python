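import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import radioswitch as rs

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    # the fixtures used inside @given tests are immutable constructors, so
    # sharing one instance across examples is safe
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def params() -> rs.SwitchParameters:
    """Default switch parameters (γ in water at 37 °C)."""
    return rs.SwitchParameters()


@pytest.fixture
def gr() -> rs.RadiationSource:
    return rs.GAMMA_SOURCE


@pytest.fixture
def water() -> rs.SolutionConditions:
    return rs.WATER


@pytest.fixture
def n2o() -> rs.SolutionConditions:
    return rs.SolutionConditions(gas="N2O")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
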