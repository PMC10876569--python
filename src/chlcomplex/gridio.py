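"""Gridded NetCDF ingest, per-pixel pipeline driver, and writers.

The reader accepts a minimal GlobColour-style dialect: a NetCDF file
holding one chlorophyll variable with (time, lat, lon) axes (any axis
order; transposed on read), a daily-or-coarser strictly increasing time
axis, and NaN or a ``_FillValue``/``missing_value`` sentinel for
missing observations.  All NetCDF I/O uses xarray's ``scipy`` engine
(NetCDF3), so files written here round-trip everywhere scipy exists.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd
import xarray as xr

from .elasticity import elasticity
from .fractal import fractal_dimension
from .qc import (bootstrap_fill, count_daily_change_samples,
                 coverage_filter, remove_outliers)
from .series import DEFAULT_START_DATE, GateError, PixelSeries, ValidationError
from .trends import GridField

__all__ = ["GridDataset", "PipelineConfig", "read_grid", "write_grid",
           "series_to_grid", "run_pipeline", "read_series_csv",
           "write_series_csv"]

log = logging.getLogger("chlcomplex")

NETCDF_ENGINE = "scipy"


@dataclass
class PipelineConfig:
    """Every tunable of the per-pixel pipeline; the canonical analysis
    constants are the defaults, never hard-coded at point of use.

    ``master_seed`` drives all randomness: each pixel derives its own
    independent stream from (master_seed, pixel index), so results are
    reproducible yet pixels are independent of grid iteration order.
    """

    coverage_min_fraction: float = 0.20
    min_change_samples: int = 400
    n_pairs: int = 1000
    outlier_sd: float = 3.0
    master_seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load from a plain-text key-value (YAML) file; unknown keys error."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"config: unknown keys {sorted(unknown)}; "
                                  f"expected a subset of {sorted(known)}")
        return cls(**raw)

    def echo(self) -> str:
        return "\n".join(f"{k} = {v}" for k, v in vars(self).items())


@dataclass
class GridDataset:
    """Handle to a (time, lat, lon) chlorophyll array with calendar anchor."""

    data: xr.DataArray
    start_date: datetime.date

    @property
    def lat(self) -> np.ndarray:
        return self.data["lat"].values

    @property
    def lon(self) -> np.ndarray:
        return self.data["lon"].values

    @property
    def n_days(self) -> int:
        return int(self.data.sizes["time"])

    def pixel(self, i_lat: int, i_lon: int) -> PixelSeries:
        values = np.asarray(self.data.isel(lat=i_lat, lon=i_lon).values,
                            dtype=float)
        return PixelSeries(values=values, start_date=self.start_date,
                           lat=float(self.lat[i_lat]), lon=float(self.lon[i_lon]),
                           pixel_id=f"{i_lat}:{i_lon}")

    def iter_pixels(self) -> Iterator[tuple[int, int, PixelSeries]]:
        for i in range(self.lat.size):
            for j in range(self.lon.size):
                yield i, j, self.pixel(i, j)


def read_grid(path, variable_name: str = "CHL1_mean") -> GridDataset:
    """Open a gridded chlorophyll NetCDF file.

    The named variable must carry (time, lat, lon) axes in any order;
    the time axis is normalized to an integer day index anchored at its
    first timestamp.  A missing variable or axis raises a format error
    listing what the file actually contains.
    """
    ds = xr.open_dataset(path, engine=NETCDF_ENGINE, decode_times=True)
    if variable_name not in ds:
        raise ValidationError(
            f"file: variable {variable_name!r} not found; file has "
            f"{sorted(ds.data_vars)}")
    da = ds[variable_name]
    needed = {"time", "lat", "lon"}
    if set(da.dims) != needed:
        raise ValidationError(
            f"file: variable {variable_name!r} has axes {tuple(da.dims)}; "
            f"expected {sorted(needed)} in any order")
    da = da.transpose("time", "lat", "lon")
    times = pd.to_datetime(da["time"].values)
    if len(times) > 1:
        dt = np.diff(times.values).astype("timedelta64[D]").astype(int)
        if (dt <= 0).any():
            raise ValidationError("file: time axis must be strictly increasing")
    start = times[0].date()
    return GridDataset(data=da.load(), start_date=start)


def write_grid(path, values: np.ndarray, lat: np.ndarray, lon: np.ndarray,
               start_date: datetime.date = DEFAULT_START_DATE,
               variable_name: str = "CHL1_mean") -> None:
    """Write a (time, lat, lon) chlorophyll cube to NetCDF (scipy engine)."""
    n_time = values.shape[0]
    times = pd.date_range(start=start_date, periods=n_time, freq="D")
    ds = xr.Dataset(
        {variable_name: (("time", "lat", "lon"), values,
                         {"units": "mg m-3", "long_name": "chlorophyll-a concentration"})},
        coords={"time": times,
                "lat": ("lat", lat, {"units": "degrees_north"}),
                "lon": ("lon", lon, {"units": "degrees_east"})},
    )
    ds.to_netcdf(path, engine=NETCDF_ENGINE)


def series_to_grid(series_list: list[list[PixelSeries]], lat: np.ndarray,
                   lon: np.ndarray,
                   start_date: datetime.date = DEFAULT_START_DATE) -> np.ndarray:
    """Stack a lat-major nested list of equal-length series into a cube."""
    n_time = series_list[0][0].n_days
    cube = np.full((n_time, len(lat), len(lon)), np.nan)
    for i, row in enumerate(series_list):
        for j, s in enumerate(row):
            cube[:, i, j] = s.values
    return cube


def _pixel_seed(master_seed: int, i_lat: int, i_lon: int) -> int:
    """Stable per-pixel seed independent of iteration order."""
    ss = np.random.SeedSequence(entropy=master_seed,
                                spawn_key=(i_lat, i_lon))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_pipeline(dataset: GridDataset,
                 config: Optional[PipelineConfig] = None
                 ) -> tuple[pd.DataFrame, dict[str, GridField]]:
    """Full-record complexity metrics for every pixel of a grid.

    Per pixel: coverage gate -> elasticity on the raw series (400
    change-sample gate) and fractal dimension on the cleaned series
    (3-SD outlier removal then bootstrap fill).  Failed-gate pixels
    come out NaN in the rasters — the analysis' "white pixels".

    Returns a per-pixel table and rasters for elasticity, fractal
    dimension and mean chlorophyll.  Deterministic under
    ``config.master_seed``.
    """
    config = config or PipelineConfig()
    n_lat, n_lon = dataset.lat.size, dataset.lon.size
    elas = np.full((n_lat, n_lon), np.nan)
    fd = np.full((n_lat, n_lon), np.nan)
    mean_chl = np.full((n_lat, n_lon), np.nan)
    rows = []
    counters = {"pixels": 0, "passed_coverage": 0, "passed_consecutive": 0,
                "elasticity_ok": 0, "fd_ok": 0}
    for i, j, series in dataset.iter_pixels():
        counters["pixels"] += 1
        seed = _pixel_seed(config.master_seed, i, j)
        passed_cov = coverage_filter(series, config.coverage_min_fraction)
        n_changes = count_daily_change_samples(series)
        passed_consec = n_changes >= config.min_change_samples
        row = {"i_lat": i, "i_lon": j, "lat": series.lat, "lon": series.lon,
               "pixel_id": series.pixel_id,
               "n_observed": series.n_observed,
               "coverage_fraction": series.coverage_fraction,
               "n_daily_change_samples": n_changes,
               "passed_coverage": passed_cov,
               "passed_consecutive": passed_consec,
               "elasticity": np.nan, "beta2": np.nan, "n_pairs_used": 0,
               "degenerate": False, "fd": np.nan, "fd_se": np.nan,
               "n_outliers_removed": 0}
        if passed_cov:
            counters["passed_coverage"] += 1
            mean_chl[i, j] = series.observed_values().mean()
            if passed_consec:
                counters["passed_consecutive"] += 1
                try:
                    fit = elasticity(series, seed=seed, n_pairs=config.n_pairs,
                                     min_change_samples=config.min_change_samples)
                    if fit.defined:
                        elas[i, j] = fit.beta1
                        counters["elasticity_ok"] += 1
                    row.update(elasticity=fit.beta1, beta2=fit.beta2,
                               n_pairs_used=fit.n_pairs_used,
                               degenerate=fit.degenerate)
                except (ValidationError, GateError) as err:
                    log.warning("pixel %s: elasticity failed: %s",
                                series.pixel_id, err)
            try:
                cleaned, report = remove_outliers(series, k=config.outlier_sd)
                filled = bootstrap_fill(cleaned, seed=seed)
                est = fractal_dimension(filled)
                fd[i, j] = est.dimension
                counters["fd_ok"] += 1
                row.update(fd=est.dimension, fd_se=est.slope_se,
                           n_outliers_removed=report.n_outliers_removed)
            except ValidationError as err:
                log.warning("pixel %s: fractal dimension failed: %s",
                            series.pixel_id, err)
        rows.append(row)
    log.info("pipeline counters: %s", counters)
    fields = {
        "elasticity": GridField(elas, "elasticity", dataset.lat, dataset.lon),
        "fractal_dimension": GridField(fd, "fractal_dimension",
                                       dataset.lat, dataset.lon),
        "mean_chl": GridField(mean_chl, "mean_chl", dataset.lat, dataset.lon),
    }
    return pd.DataFrame(rows), fields


def write_series_csv(path, series: PixelSeries) -> None:
    """Single-series CSV (date,value); missing days have empty values."""
    pd.DataFrame({"date": series.dates().astype(str),
                  "value": series.values}).to_csv(path, index=False)


def read_series_csv(path) -> PixelSeries:
    """Read a (date,value) CSV as written by :func:`write_series_csv`."""
    # round_trip parsing keeps write->read bit-exact for float values
    df = pd.read_csv(path, parse_dates=["date"], float_precision="round_trip")
    if df.empty:
        raise ValidationError("file: empty series CSV")
    start = df["date"].iloc[0].date()
    return PixelSeries(values=df["value"].to_numpy(dtype=float),
                       start_date=start)
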