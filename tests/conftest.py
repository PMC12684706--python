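import numpy as np
import pytest

from fastscode import OptimizerConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_noiseless():
    """Tiny noiseless instance drawn from the model class itself."""
    return generate(G=12, C=25, D=2, noise_sd=0.0, seed=7)


@pytest.fixture
def small_config():
    return OptimizerConfig(D=2, iterations=30, candidate_batch=8, seed=3)
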