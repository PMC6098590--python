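import pytest
from hypothesis import HealthCheck, settings

from oxyaccess import (
    AccessModel,
    DemandParams,
    PopulationState,
    StrengthBands,
    calibrate_kinetics,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def kin():
    """Arrhenius parameters calibrated from the default stability anchors."""
    return calibrate_kinetics()


@pytest.fixture(scope="session")
def bands():
    return StrengthBands()


@pytest.fixture
def pop():
    return PopulationState()


@pytest.fixture
def anchored_model():
    return AccessModel(mode="anchored_linear")


@pytest.fixture
def demand():
    return DemandParams()
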