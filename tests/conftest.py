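import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

from efws.synth import (
    ProteinModel,
    WaterModel,
    default_q_values,
    default_temperatures,
)


@pytest.fixture(scope="session")
def temperatures():
    return default_temperatures()


@pytest.fixture(scope="session")
def q_values():
    return default_q_values()


@pytest.fixture
def water_model():
    return WaterModel(noise_sigma=0.0)


@pytest.fixture
def protein_model():
    return ProteinModel(noise_sigma=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
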