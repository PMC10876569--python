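"""Data-sufficiency filters, outlier removal, bootstrap gap-filling and
temporal aggregation applied to a pixel series before metric computation.

The pipeline's ordering convention: the elasticity statistic runs on the
*raw* series (no outlier removal, no filling); the fractal dimension runs
on the cleaned series (3-SD outlier removal, then bootstrap gap fill).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd

from .series import PixelSeries, ValidationError

__all__ = [
    "QCReport",
    "coverage_filter",
    "count_daily_change_samples",
    "remove_outliers",
    "bootstrap_fill",
    "aggregate_series",
]


@dataclass(frozen=True)
class QCReport:
    """Per-pixel quality-control summary, serializable to one CSV row."""

    n_days_total: int
    n_observed: int
    coverage_fraction: float
    n_daily_change_samples: int
    n_outliers_removed: int
    passed_coverage: bool
    passed_consecutive: bool

    def to_row(self) -> dict:
        return asdict(self)

    @staticmethod
    def frame(reports: list["QCReport"]) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in reports])


def coverage_filter(series: PixelSeries, min_fraction: float = 0.20) -> bool:
    """True iff strictly more than ``min_fraction`` of days are observed.

    The default 20% cut-off on a 25-year daily record demands ~1,826
    observed days. The inequality is strict: exactly 20% fails.
    """
    return series.coverage_fraction > min_fraction


def count_daily_change_samples(series: PixelSeries) -> int:
    """Number of consecutive-day pairs (t, t+1) with both days observed.

    This is the sample size available to the daily-change statistic; the
    elasticity gate requires at least 400 such pairs.
    """
    obs = series.observed
    return int(np.count_nonzero(obs[:-1] & obs[1:]))


def remove_outliers(series: PixelSeries, k: float = 3.0) -> tuple[PixelSeries, QCReport]:
    """Mark observations more than ``k`` sample SDs from the mean as missing.

    Single pass: the mean and SD are computed once over the observed
    values, then every observation with ``|v - mean| > k*SD`` becomes
    missing. A constant series (SD = 0) loses nothing, since no value
    strictly exceeds a zero-width band.
    """
    obs_values = series.observed_values()
    if obs_values.size < 2:
        raise ValidationError("series: need >= 2 observed values for outlier removal")
    mean = obs_values.mean()
    sd = obs_values.std(ddof=1)
    outlier = series.observed & (np.abs(series.values - mean) > k * sd)
    cleaned = series.with_values(np.where(outlier, np.nan, series.values))
    n_removed = int(outlier.sum())
    report = QCReport(
        n_days_total=series.n_days,
        n_observed=series.n_observed,
        coverage_fraction=series.coverage_fraction,
        n_daily_change_samples=count_daily_change_samples(series),
        n_outliers_removed=n_removed,
        passed_coverage=coverage_filter(series),
        passed_consecutive=count_daily_change_samples(series) >= 400,
    )
    return cleaned, report


def bootstrap_fill(series: PixelSeries, seed: int) -> PixelSeries:
    """Fill every gap with a draw (with replacement) from the observed values.

    Observed positions are preserved bit-exactly; each missing day gets an
    independent uniform draw from the multiset of observed values, so the
    filled series has a complete record without importing values from
    outside the pixel's own distribution.
    """
    obs_values = series.observed_values()
    if obs_values.size == 0:
        raise ValidationError("series: cannot bootstrap-fill an all-missing series")
    gaps = series.missing
    if not gaps.any():
        return series
    rng = np.random.default_rng(seed)
    fill = rng.choice(obs_values, size=int(gaps.sum()), replace=True)
    values = series.values.copy()
    values[gaps] = fill
    return series.with_values(values)


def aggregate_series(series: PixelSeries, window_days: int) -> PixelSeries:
    """Average into non-overlapping windows of ``window_days`` steps.

    Each window's value is the mean of its observed days, missing when the
    window holds no observation. The output is indexed at window
    resolution (``step_days`` multiplies accordingly).
    """
    if window_days < 1:
        raise ValidationError("window_days: must be >= 1")
    if window_days == 1:
        return series
    n = series.n_days
    n_windows = int(np.ceil(n / window_days))
    padded = np.full(n_windows * window_days, np.nan)
    padded[:n] = series.values
    blocks = padded.reshape(n_windows, window_days)
    with np.errstate(invalid="ignore"):
        counts = np.count_nonzero(~np.isnan(blocks), axis=1)
        sums = np.nansum(blocks, axis=1)
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return replace(series, values=means,
                   step_days=series.step_days * window_days)
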