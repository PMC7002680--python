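import numpy as np
import pytest

from seerpy import SpectralImage, make_wavelength_axis


@pytest.fixture
def axis32():
    return make_wavelength_axis(410.5, 8.9, 32)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_cube(axis32, rng):
    """Small random nonnegative cube."""
    data = rng.random((1, 12, 10, 32))
    return SpectralImage(data=data, axis=axis32)


def delta_cube(channel: int, shape=(1, 4, 4), n_channels: int = 32):
    """Cube whose every pixel is a delta spectrum at one channel."""
    data = np.zeros(shape + (n_channels,))
    data[..., channel] = 1.0
    return SpectralImage(data=data, axis=make_wavelength_axis(410.5, 8.9, n_channels))
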