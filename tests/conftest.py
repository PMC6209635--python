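import numpy as np
import pytest

from ramansync.spectra_io import Spectrum


@pytest.fixture
def axis2048():
    return np.linspace(175.0, 2700.0, 2048)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def peak_rich(axis: np.ndarray, seed: int = 0, n_peaks: int = 10) -> np.ndarray:
    """A noiseless multi-band signal for lag-estimation tests."""
    rng = np.random.default_rng(seed)
    lo, hi = axis[0] + 100, axis[-1] - 100
    y = np.zeros_like(axis)
    for _ in range(n_peaks):
        c = rng.uniform(lo, hi)
        h = rng.uniform(0.3, 1.0)
        w = rng.uniform(4.0, 10.0)
        y += h * np.exp(-0.5 * ((axis - c) / w) ** 2)
    return y


@pytest.fixture
def peak_spectrum(axis2048):
    return Spectrum(axis2048, peak_rich(axis2048, seed=7))
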