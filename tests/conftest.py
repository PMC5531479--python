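import numpy as np
import pytest

from tfca import SmoothingKernel, ZAMDConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """Reduced ZAMD grid for properties that do not depend on the full-size
    window lengths (keeps Monte-Carlo property tests fast)."""
    return ZAMDConfig(l_h=31, l_g=41, n_freq_bins=64, fs=2.0)


@pytest.fixture
def small_kernel():
    """Smoothing kernel scaled to the reduced grid (same proportions of the
    default kernel relative to its grid's resolution)."""
    return SmoothingKernel(sigma_t=3.0, sigma_f=0.05)
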