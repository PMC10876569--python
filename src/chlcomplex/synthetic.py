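"""Synthetic inputs for the complexity pipeline.

Two families of generators live here:

* :func:`generate_series` emulates the statistical structure of a
  satellite chlorophyll-a pixel record — positively skewed (lognormal)
  marginals around a median level, an optional multiplicative seasonal
  cycle, rare multiplicative spikes, and bursty missing-data gaps
  (random singletons plus geometric-length cloud-like blocks).

* :func:`generate_brownian` / :func:`generate_fbm` produce canonical
  stochastic processes with known graph fractal dimension (1.5 for
  Brownian motion, 2 - H for fractional Brownian motion with Hurst
  exponent H), used to validate the box-counting estimator.

All randomness flows through ``numpy.random.default_rng`` (PCG64) with
explicit integer seeds; equal seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import DEFAULT_START_DATE, PixelSeries, ValidationError

__all__ = [
    "SyntheticSpec",
    "generate_series",
    "generate_brownian",
    "generate_fbm",
    "constant_increment_series",
]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a chlorophyll-like synthetic pixel series.

    Attributes
    ----------
    n_days
        Number of daily steps (the 1998-2022 record has 9131).
    base_level
        Median chlorophyll in mg m^-3; the lognormal noise and the
        seasonal cycle are both median-neutral, so the marginal median
        of the output is ~``base_level``.
    seasonal_amplitude
        Peak-to-trough ratio of the multiplicative annual (365.25 d)
        cycle; 1 disables seasonality.
    noise_cv
        Coefficient of variation of the multiplicative lognormal noise.
    spike_rate
        Expected number of spike days per year.
    spike_factor
        Multiplier applied on spike days (> 1).
    gap_fraction
        Overall fraction of missing days in [0, 1).
    gap_block_length
        Mean length (days) of contiguous missing blocks.
    gap_block_share
        Fraction of the missing-day budget allocated to blocks (the
        rest are i.i.d. singleton gaps).
    seed
        RNG seed; generation is bit-reproducible.
    """

    n_days: int = 9131
    base_level: float = 0.2
    seasonal_amplitude: float = 2.0
    noise_cv: float = 0.35
    spike_rate: float = 2.0
    spike_factor: float = 5.0
    gap_fraction: float = 0.5
    gap_block_length: float = 5.0
    gap_block_share: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_days < 2:
            raise ValidationError("n_days: must be >= 2")
        if not self.base_level > 0:
            raise ValidationError("base_level: must be > 0")
        if self.seasonal_amplitude < 1:
            raise ValidationError("seasonal_amplitude: must be >= 1")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv: must be >= 0")
        if self.spike_rate < 0:
            raise ValidationError("spike_rate: must be >= 0")
        if self.spike_rate > 0 and not self.spike_factor > 1:
            raise ValidationError("spike_factor: must be > 1")
        if not 0 <= self.gap_fraction < 1:
            raise ValidationError("gap_fraction: must be in [0, 1)")
        if self.gap_block_length < 1:
            raise ValidationError("gap_block_length: must be >= 1")
        if not 0 <= self.gap_block_share <= 1:
            raise ValidationError("gap_block_share: must be in [0, 1]")


def generate_series(spec: SyntheticSpec) -> PixelSeries:
    """Generate one chlorophyll-like daily pixel series from ``spec``.

    The clean signal is ``base_level * seasonal(t) * lognormal_noise``,
    spikes multiply it by ``spike_factor``, and gaps are imposed last so
    that the missing fraction hits ``gap_fraction`` to within rounding.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_days
    t = np.arange(n)

    # multiplicative seasonal cycle, exp(c*sin) with peak/trough ratio = amplitude
    if spec.seasonal_amplitude > 1:
        half_log = 0.5 * np.log(spec.seasonal_amplitude)
        season = np.exp(half_log * np.sin(2 * np.pi * t / DAYS_PER_YEAR))
    else:
        season = np.ones(n)

    # median-neutral lognormal noise with the requested CV
    if spec.noise_cv > 0:
        sigma = np.sqrt(np.log1p(spec.noise_cv**2))
        noise = np.exp(sigma * rng.standard_normal(n))
    else:
        noise = np.ones(n)

    values = spec.base_level * season * noise

    if spec.spike_rate > 0:
        p_spike = spec.spike_rate / DAYS_PER_YEAR
        spikes = rng.random(n) < p_spike
        values = np.where(spikes, values * spec.spike_factor, values)

    if spec.gap_fraction > 0:
        mask = _gap_mask(rng, n, spec.gap_fraction, spec.gap_block_length,
                         spec.gap_block_share)
        values = np.where(mask, np.nan, values)

    return PixelSeries(values=values, start_date=DEFAULT_START_DATE,
                       pixel_id=f"synthetic-{spec.seed}")


def _gap_mask(rng: np.random.Generator, n: int, gap_fraction: float,
              block_length: float, block_share: float) -> np.ndarray:
    """Missingness mask: geometric-length blocks plus i.i.d. singletons.

    Blocks are placed at uniform starts with geometric lengths (mean
    ``block_length``) until they cover ``block_share`` of the target
    budget; singleton gaps then top the total up to exactly
    ``round(gap_fraction * n)`` missing days (overlap-safe).
    """
    target = int(round(gap_fraction * n))
    mask = np.zeros(n, dtype=bool)
    block_budget = block_share * target
    p_geom = min(1.0, 1.0 / block_length)
    # cap defends against pathological overlap; budget is hit far earlier
    for _ in range(4 * n):
        if mask.sum() >= block_budget:
            break
        start = int(rng.integers(0, n))
        length = int(rng.geometric(p_geom))
        mask[start:start + length] = True
    still_observed = np.flatnonzero(~mask)
    deficit = target - int(mask.sum())
    if deficit > 0:
        extra = rng.choice(still_observed, size=min(deficit, still_observed.size - 1),
                           replace=False)
        mask[extra] = True
    return mask


def generate_brownian(n: int, seed: int, step_sd: float = 1.0) -> PixelSeries:
    """Standard Brownian-motion sample path: cumulative sum of i.i.d.
    Gaussian increments, starting at 0, no missing values.

    The graph of such a path has box-counting dimension 1.5; values may
    be negative, so downstream consumers must not assume positivity.
    """
    if n < 2:
        raise ValidationError("n: must be >= 2")
    if step_sd < 0:
        raise ValidationError("step_sd: must be >= 0")
    rng = np.random.default_rng(seed)
    increments = step_sd * rng.standard_normal(n - 1)
    values = np.concatenate([[0.0], np.cumsum(increments)])
    return PixelSeries(values=values, pixel_id=f"bm-{seed}")


def generate_fbm(n: int, hurst: float, seed: int) -> PixelSeries:
    """Exact fractional Brownian motion path of length ``n``.

    Uses Davies-Harte circulant embedding of the fractional Gaussian
    noise covariance (exact in distribution); the path starts at 0 and
    Var(B_H(k)) = k^(2H) in index units. The graph dimension is 2 - H.
    """
    if not 0 < hurst < 1:
        raise ValidationError("hurst: must be in (0, 1)")
    if n < 2:
        raise ValidationError("n: must be >= 2")
    rng = np.random.default_rng(seed)
    fgn = _fgn_sample(n - 1, hurst, rng)
    values = np.concatenate([[0.0], np.cumsum(fgn)])
    return PixelSeries(values=values, pixel_id=f"fbm-{hurst}-{seed}")


def _fgn_autocov(m: int, hurst: float) -> np.ndarray:
    """Autocovariance of unit-variance fractional Gaussian noise, lags 0..m."""
    k = np.arange(m + 1, dtype=float)
    h2 = 2.0 * hurst
    return 0.5 * ((k + 1) ** h2 - 2 * k**h2 + np.abs(k - 1) ** h2)


def _fgn_sample(m: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """One fGn sample of length m via circulant embedding (Cholesky fallback)."""
    gamma = _fgn_autocov(m, hurst)
    # first row of the 2m-circulant: gamma(0..m), gamma(m-1..1)
    c = np.concatenate([gamma, gamma[m - 1:0:-1]])
    lam = np.fft.fft(c).real
    if lam.min() < -1e-8 * lam.max():
        # negative eigenvalue: embedding not valid (does not occur for fGn,
        # kept as a guard) — use the exact O(m^3) route
        cov = np.empty((m, m))
        idx = np.arange(m)
        cov[:] = gamma[np.abs(idx[:, None] - idx[None, :])]
        chol = np.linalg.cholesky(cov)
        return chol @ rng.standard_normal(m)
    lam = np.clip(lam, 0.0, None)
    m2 = 2 * m
    xi = rng.standard_normal(m2) + 1j * rng.standard_normal(m2)
    x = np.sqrt(m2) * np.fft.ifft(np.sqrt(lam) * xi)
    return x.real[:m]


def constant_increment_series(n: int, start: float = 1.0,
                              step: float = 0.001) -> PixelSeries:
    """Arithmetic series values[k] = start + k*step; every daily change
    equals ``step``, so its elasticity is 0 by the degenerate convention."""
    if n < 2:
        raise ValidationError("n: must be >= 2")
    if not start > 0:
        raise ValidationError("start: must be > 0")
    if not step > 0:
        raise ValidationError("step: must be > 0")
    values = start + step * np.arange(n, dtype=float)
    return PixelSeries(values=values, pixel_id="constant-increment")
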