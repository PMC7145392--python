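import numpy as np
import pytest

from headnet.preprocess import EpochArray
from headnet.spectral import multitaper_fft


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_epochs(rng):
    """40 epochs x 6 channels of independent white noise at 500 Hz."""
    labels = [f"C{i + 1:02d}" for i in range(6)]
    return EpochArray(rng.standard_normal((40, 6, 1000)), 500.0, labels)


@pytest.fixture
def noise_spectra(noise_epochs):
    return multitaper_fft(noise_epochs)
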