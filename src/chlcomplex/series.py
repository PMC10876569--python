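"""Core time-series container shared by every stage of the pipeline.

A :class:`PixelSeries` is one pixel's record on a regular time grid:
a float array with NaN marking missing days, anchored to a calendar
date. Missing days are *marked*, never dropped, so integer position k
always means "k steps after ``start_date``".
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["PixelSeries", "ValidationError", "GateError", "DEFAULT_START_DATE"]

#: Calendar anchor used throughout: day index 0 is 1998-01-01.
DEFAULT_START_DATE = datetime.date(1998, 1, 1)


class ValidationError(ValueError):
    """An input violated a documented precondition; the message names the field."""


class GateError(RuntimeError):
    """A data-sufficiency gate (coverage, consecutive samples, ...) was not met."""


@dataclass(frozen=True)
class PixelSeries:
    """One pixel's chlorophyll-like record on a regular daily (or coarser) grid.

    Parameters
    ----------
    values
        Concentrations (mg m^-3 for chlorophyll) with ``np.nan`` marking
        missing steps.  Generators of canonical stochastic processes
        (Brownian motion, fBm) also use this container, so values are not
        required to be positive here; stages that assume positivity
        (thresholding on the median) validate it themselves.
    start_date
        Calendar date of index 0.
    step_days
        Sampling interval in days; 1 for daily data, >1 after temporal
        aggregation.
    lat, lon
        Pixel-centre coordinates in decimal degrees (optional).
    pixel_id
        Opaque identifier used for per-pixel seed derivation and output
        bookkeeping.
    """

    values: np.ndarray
    start_date: datetime.date = DEFAULT_START_DATE
    step_days: int = 1
    lat: Optional[float] = None
    lon: Optional[float] = None
    pixel_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise ValidationError("values: expected a 1-D array")
        if arr.size == 0:
            raise ValidationError("values: series is empty")
        if self.step_days < 1:
            raise ValidationError("step_days: must be >= 1")
        object.__setattr__(self, "values", arr)

    # -- masks and counts -------------------------------------------------
    @property
    def missing(self) -> np.ndarray:
        """Boolean mask, True where the day has no observation."""
        return np.isnan(self.values)

    @property
    def observed(self) -> np.ndarray:
        return ~self.missing

    @property
    def n_days(self) -> int:
        return int(self.values.size)

    @property
    def n_observed(self) -> int:
        return int(np.count_nonzero(self.observed))

    @property
    def coverage_fraction(self) -> float:
        return self.n_observed / self.n_days

    def observed_values(self) -> np.ndarray:
        """The observed values, in time order, gaps removed."""
        return self.values[self.observed]

    # -- calendar helpers --------------------------------------------------
    def dates(self) -> np.ndarray:
        """Calendar dates of each index as numpy datetime64[D]."""
        start = np.datetime64(self.start_date.isoformat())
        return start + np.arange(self.n_days) * np.timedelta64(self.step_days, "D")

    def year_slice(self, year: int) -> "PixelSeries":
        """Sub-series covering calendar ``year`` (daily series only)."""
        if self.step_days != 1:
            raise ValidationError("year_slice: requires a daily series")
        d0 = (datetime.date(year, 1, 1) - self.start_date).days
        d1 = (datetime.date(year + 1, 1, 1) - self.start_date).days
        d0c, d1c = max(d0, 0), min(d1, self.n_days)
        if d1c <= d0c:
            raise ValidationError(f"year_slice: series does not span year {year}")
        return replace(
            self,
            values=self.values[d0c:d1c],
            start_date=self.start_date + datetime.timedelta(days=d0c),
        )

    def with_values(self, values: np.ndarray) -> "PixelSeries":
        """Copy of this series with ``values`` replaced (same length not enforced)."""
        return replace(self, values=np.asarray(values, dtype=float))

    def longest_observed_run(self) -> int:
        """Length of the longest unbroken run of observed steps."""
        obs = self.observed
        if not obs.any():
            return 0
        # run-length encode the mask
        padded = np.concatenate(([False], obs, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, stops = edges[::2], edges[1::2]
        return int((stops - starts).max())
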