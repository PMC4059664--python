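import numpy as np
import pytest

from mp2rage import (
    AcquisitionProtocol,
    make_phantom,
    simulate_acquisition,
)


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def phantom64():
    return make_phantom((64, 64, 64), seed=0)


@pytest.fixture(scope="session")
def noisy_pair(phantom64, protocol):
    """Default noisy acquisition of the default phantom."""
    return simulate_acquisition(phantom64, protocol, seed=1)


@pytest.fixture(scope="session")
def clean_pair(phantom64, protocol):
    """Noise-free acquisition of the default phantom."""
    return simulate_acquisition(phantom64, protocol, noise_sigma=0.0, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_signal_pairs(rng, n):
    """Broadly distributed random complex signal pairs (log-scale amplitudes)."""
    scale = 10.0 ** rng.uniform(-3, 3, size=(2, n))
    z = rng.standard_normal((2, n)) + 1j * rng.standard_normal((2, n))
    s = scale * z
    return s[0], s[1]
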