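import numpy as np
import pytest

from texshape.filterbanks import FilterBankSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec():
    """Cheap 4-orientation, 2-band spec for kernel-level tests."""
    return FilterBankSpec(n_orientations=4, n_frequencies=2,
                          freq_min=0.06, freq_max=0.2)


@pytest.fixture
def std_spec():
    return FilterBankSpec()


def grating(size, theta, freq, phase=0.0):
    """Sinusoidal grating whose stripes are oriented along theta."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    u = xx * np.cos(theta + np.pi / 2) + yy * np.sin(theta + np.pi / 2)
    return 0.5 + 0.5 * np.sin(2 * np.pi * freq * u + phase)


@pytest.fixture
def make_grating():
    return grating
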