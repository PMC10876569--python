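import numpy as np
import pytest

from chlcomplex import PixelSeries, SyntheticSpec, generate_series


@pytest.fixture
def lognormal_series() -> PixelSeries:
    """A gap-free lognormal white-noise chlorophyll-like series."""
    spec = SyntheticSpec(n_days=2000, seasonal_amplitude=1.0, noise_cv=0.4,
                         spike_rate=0.0, gap_fraction=0.0, seed=42)
    return generate_series(spec)


@pytest.fixture
def gappy_series() -> PixelSeries:
    """A chlorophyll-like series with 50% bursty gaps."""
    spec = SyntheticSpec(n_days=3000, seed=7)
    return generate_series(spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
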