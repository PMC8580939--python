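import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from surgseg import ModelConfig

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_config():
    """A full multi-stage network small enough for finite differences."""
    return ModelConfig(n_layers=2, in_dim=5, channels=6, pool=3, d_k=4, d_v=3,
                      ffn_hidden=7, n_gestures=4, n_skills=3)


@pytest.fixture
def small_config():
    """A fast but non-trivial configuration for behavioural tests."""
    return ModelConfig(n_layers=3, in_dim=8, channels=8, pool=4, d_k=4, d_v=4,
                      ffn_hidden=16, n_gestures=10, n_skills=3)
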