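import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sticklesim.params import BioenergeticsParams, ModelConfig, MortalityParams

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def bio() -> BioenergeticsParams:
    return BioenergeticsParams()


@pytest.fixture
def model_config() -> ModelConfig:
    return ModelConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
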