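"""Annual metrics, decadal percent change, window-deviation estimates and
traditional variability measures.

Annual gates follow the record-density rules for a 25-year daily record:
mean chlorophyll and the fractal dimension need at least 100 observed
days in the year; the elasticity needs at least 100 *consecutive*
observed days (it lives on day-to-day change, so contiguity matters).
Gated-out metrics are NaN, never exceptions, so grid runs keep going.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elasticity import elasticity
from .fractal import fractal_dimension
from .qc import bootstrap_fill, remove_outliers
from .series import GateError, PixelSeries, ValidationError

__all__ = [
    "AnnualSummary",
    "GridField",
    "annual_summary",
    "annual_table",
    "global_mean_ci",
    "percent_change",
    "window_deviation",
    "variability_metrics",
]

MIN_DAYS_ANNUAL = 100          # days observed in the year (mean chl, FD)
MIN_CONSECUTIVE_ANNUAL = 100   # longest observed run in the year (elasticity)


@dataclass(frozen=True)
class AnnualSummary:
    """Per-year metric triplet; a NaN metric means its gate failed."""

    year: int
    mean_chl: float
    elasticity: float
    fd: float
    n_days: int
    n_consecutive_max: int


@dataclass(frozen=True)
class GridField:
    """A 2-D lat/lon raster of one metric; NaN marks failed-gate pixels."""

    values: np.ndarray
    metric_name: str
    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (self.lat.size, self.lon.size):
            raise ValidationError("values: shape must match (lat, lon) lengths")

    def to_dataarray(self):
        import xarray as xr

        return xr.DataArray(
            self.values,
            dims=("lat", "lon"),
            coords={"lat": ("lat", self.lat, {"units": "degrees_north"}),
                    "lon": ("lon", self.lon, {"units": "degrees_east"})},
            name=self.metric_name,
        )


def annual_summary(series: PixelSeries, year: int, seed: int = 0,
                   n_pairs: int = 1000,
                   fill_within_year: bool = True) -> AnnualSummary:
    """Metrics for one calendar year of a daily pixel series.

    The year's sub-series is extracted first; mean chlorophyll is the
    plain mean of observed values (before any resampling).  The fractal
    dimension runs on the cleaned sub-series (3-SD outlier removal then
    bootstrap gap fill, both within the year when ``fill_within_year``).
    The elasticity runs on the raw sub-series with thresholds drawn
    from the sub-series median.
    """
    sub = series.year_slice(year)
    n_days = sub.n_observed
    n_run = sub.longest_observed_run()
    mean_chl = float(np.nan)
    fd_val = float(np.nan)
    elas_val = float(np.nan)
    if n_days >= MIN_DAYS_ANNUAL:
        mean_chl = float(sub.observed_values().mean())
        try:
            cleaned, _ = remove_outliers(sub)
            filled = bootstrap_fill(cleaned if fill_within_year else sub,
                                    seed=seed)
            fd_val = fractal_dimension(filled).dimension
        except ValidationError:
            pass
    if n_run >= MIN_CONSECUTIVE_ANNUAL:
        try:
            fit = elasticity(sub, seed=seed, n_pairs=n_pairs, min_change_samples=0)
            if fit.defined:
                elas_val = fit.beta1
        except ValidationError:
            pass
    return AnnualSummary(year=year, mean_chl=mean_chl, elasticity=elas_val,
                         fd=fd_val, n_days=n_days, n_consecutive_max=n_run)


def annual_table(series: PixelSeries, years: range, seed: int = 0,
                 n_pairs: int = 1000):
    """AnnualSummary rows for ``years`` as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for i, year in enumerate(years):
        s = annual_summary(series, year, seed=seed + i, n_pairs=n_pairs)
        rows.append(vars(s))
    return pd.DataFrame(rows)


def global_mean_ci(values: np.ndarray) -> tuple[float, float, float, int]:
    """Mean with a 1.96 x SE 95% confidence interval over non-missing values."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValidationError("values: need >= 2 non-missing values")
    mean = float(v.mean())
    se = float(v.std(ddof=1) / np.sqrt(v.size))
    return mean, mean - 1.96 * se, mean + 1.96 * se, int(v.size)


def percent_change(rho_start: float, rho_end: float) -> float:
    """Percent change 100 * (rho_end - rho_start) / rho_start.

    The decadal maps compare 2003 against 2022; an undefined baseline
    (0 or NaN) yields NaN rather than an exception.
    """
    if np.isnan(rho_start) or np.isnan(rho_end) or rho_start == 0:
        return float(np.nan)
    return float((rho_end - rho_start) / rho_start * 100.0)


def window_deviation(series: PixelSeries, seed: int, window_days: int = 4000,
                     n_trials: int = 30, n_pairs: int = 1000,
                     ) -> tuple[float, float, int, int]:
    """Standard error of both complexity metrics over random windows.

    Draws ``n_trials`` uniformly random start positions (with
    replacement; windows may overlap), recomputes the elasticity on the
    raw window and the fractal dimension on the cleaned, gap-filled
    window, and returns ``(se_elasticity, se_fd, n_elas, n_fd)`` where
    the SEs are SD/sqrt(n) over the trials whose gates passed and the
    n's count those trials.  An SE over fewer than 2 valid trials is NaN.
    """
    if series.n_days < window_days:
        raise ValidationError("series: shorter than the requested window")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, series.n_days - window_days + 1, size=n_trials)
    elas_vals, fd_vals = [], []
    for i, s0 in enumerate(starts):
        window = series.with_values(series.values[s0:s0 + window_days])
        trial_seed = int(rng.integers(0, 2**31 - 1))
        try:
            fit = elasticity(window, seed=trial_seed, n_pairs=n_pairs)
            if fit.defined:
                elas_vals.append(fit.beta1)
        except (ValidationError, GateError):
            pass
        try:
            cleaned, _ = remove_outliers(window)
            filled = bootstrap_fill(cleaned, seed=trial_seed)
            fd_vals.append(fractal_dimension(filled).dimension)
        except ValidationError:
            pass

    def _se(vals: list[float]) -> float:
        if len(vals) < 2:
            return float(np.nan)
        return float(np.std(vals, ddof=1) / np.sqrt(len(vals)))

    return _se(elas_vals), _se(fd_vals), len(elas_vals), len(fd_vals)


def variability_metrics(series: PixelSeries) -> dict:
    """Traditional variability measures of a pixel record.

    Returns mean, SD, relative SD (SD/mean) over observed values, and
    the average seasonal amplitude: for each year with data, the range
    (max - min) of that year's monthly means (months with >= 1
    observation), averaged across years.  Fields that cannot be
    computed are NaN.
    """
    obs = series.observed_values()
    out = {"mean": float(np.nan), "sd": float(np.nan), "rsd": float(np.nan),
           "seasonal_amplitude": float(np.nan)}
    if obs.size < 2:
        return out
    out["mean"] = float(obs.mean())
    out["sd"] = float(obs.std(ddof=1))
    out["rsd"] = out["sd"] / out["mean"] if out["mean"] != 0 else float(np.nan)

    dates = series.dates()
    years = dates.astype("datetime64[Y]").astype(int) + 1970
    months = dates.astype("datetime64[M]").astype(int) % 12
    amplitudes = []
    for year in np.unique(years):
        in_year = (years == year) & series.observed
        if not in_year.any():
            continue
        monthly = []
        for m in np.unique(months[in_year]):
            sel = in_year & (months == m)
            monthly.append(series.values[sel].mean())
        if len(monthly) >= 2:
            amplitudes.append(max(monthly) - min(monthly))
    if amplitudes:
        out["seasonal_amplitude"] = float(np.mean(amplitudes))
    return out
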