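import numpy as np
import pytest

from neurotc import ModelConfig, PerturbationConfig, build_network


@pytest.fixture(scope="session")
def small_config() -> ModelConfig:
    """64-neuron model for fast unit tests."""
    return ModelConfig.with_size(64, n_steps=1500, transient=300)


@pytest.fixture(scope="session")
def small_network(small_config):
    return build_network(small_config, seed=1234)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250923)


@pytest.fixture
def unperturbed() -> PerturbationConfig:
    return PerturbationConfig()
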