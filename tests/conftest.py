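import numpy as np
import pytest

from voival import SimConfig, ValidationSample, generate_sample


@pytest.fixture
def toy_sample() -> ValidationSample:
    """Four subjects with two classified positive at z = 0.5 (one TP, one FP)."""
    return ValidationSample(y=[1, 0, 1, 0], pi=[0.9, 0.8, 0.1, 0.2])


@pytest.fixture(scope="session")
def sim_sample_500() -> ValidationSample:
    """A correct-model validation sample of n = 500 from the default mechanism."""
    return generate_sample(SimConfig(n=500, seed=3))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
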