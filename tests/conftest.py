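import numpy as np
import pytest

from rsacoupling import EpochSpec, UniformSignal, generate_epoch


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def linear_epoch():
    """A strongly linearly coupled synthetic epoch (fixed seed)."""
    epoch, truth = generate_epoch(
        EpochSpec(gain_linear=1.0, gain_quadratic=0.0, noise_lf=0.1, seed=7)
    )
    return epoch


@pytest.fixture(scope="session")
def quadratic_epoch():
    """A purely quadratically coupled synthetic epoch (fixed seed)."""
    epoch, truth = generate_epoch(
        EpochSpec(gain_linear=0.0, gain_quadratic=1.0, noise_lf=0.3, seed=11)
    )
    return epoch


def sinusoid(freq, fs=2.0, n=600, label="resp"):
    t = np.arange(n) / fs
    return UniformSignal(np.sin(2 * np.pi * freq * t), fs, label)
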