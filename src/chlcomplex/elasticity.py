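"""Threshold-elasticity of a chlorophyll time series.

The statistic measures how sensitive the count of daily chlorophyll
*increases* above a threshold is to the threshold itself.  For a pair of
thresholds tau1 < tau2 (each a fraction of the series median), with
exceedance counts X1, X2:

    eps = tau2/tau1 - 1          (relative threshold difference)
    N   = X2/X1 - 1              (relative count difference, in [-1, 0])

and the elasticity is the absolute slope beta1 of the OLS fit

    log|N| = -beta1 * log(eps) + beta2

over many random threshold pairs.  A rough, threshold-sensitive series
(irregular daily change) yields high beta1; a series whose daily changes
are all equal has no threshold sensitivity and beta1 = 0 by convention.

The statistic is scale-free: thresholds are drawn as fractions
u ~ U[0.01, 0.50] of the series median and eps is formed from the
fraction ratio, so multiplying the series by any positive constant
leaves the fit bit-identical (counts compare scaled differences against
identically scaled thresholds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .qc import count_daily_change_samples
from .series import GateError, PixelSeries, ValidationError

__all__ = [
    "ThresholdPairs",
    "ElasticityFit",
    "daily_change",
    "count_exceedances",
    "relative_differences",
    "draw_threshold_pairs",
    "elasticity",
]

#: Threshold range as fractions of the series median.
TAU_MIN_FRACTION = 0.01
TAU_MAX_FRACTION = 0.50


@dataclass(frozen=True)
class ThresholdPairs:
    """Paired threshold draws, canonicalized so tau1 < tau2 elementwise.

    ``frac1``/``frac2`` are the draws as fractions of the median (the
    scale-free representation used for eps); ``tau1``/``tau2`` are the
    absolute thresholds in mg m^-3 used for exceedance counting.
    """

    frac1: np.ndarray
    frac2: np.ndarray
    median: float
    seed: int

    @property
    def tau1(self) -> np.ndarray:
        return self.frac1 * self.median

    @property
    def tau2(self) -> np.ndarray:
        return self.frac2 * self.median

    @property
    def n_pairs(self) -> int:
        return int(self.frac1.size)


@dataclass(frozen=True)
class ElasticityFit:
    """Result of the elasticity regression.

    ``beta1`` is the elasticity (absolute slope, >= 0), ``beta2`` the
    intercept.  ``degenerate`` flags the all-changes-equal convention
    (every pair had X1 == X2, i.e. zero threshold sensitivity), in which
    case beta1 is exactly 0.  When too few valid pairs remain and the
    series is not degenerate, beta1 and beta2 are NaN.
    """

    beta1: float
    beta2: float
    n_pairs_used: int
    n_pairs_total: int
    degenerate: bool = False

    @property
    def defined(self) -> bool:
        return not np.isnan(self.beta1)


def daily_change(series: PixelSeries) -> np.ndarray:
    """First differences diff[t] = value[t+1] - value[t].

    A difference is NaN (missing) when either endpoint is missing —
    gaps in the original series carry forward into the change series.
    """
    if series.n_days < 2:
        raise ValidationError("series: need >= 2 days for daily change")
    return np.diff(series.values)


def count_exceedances(diffs: np.ndarray, tau: float) -> int:
    """Number of non-missing daily changes strictly greater than ``tau``.

    Only increases count: negative changes can never exceed a positive
    threshold, and ties at the threshold do not count (strict ">").
    """
    if not tau > 0:
        raise ValidationError("tau: must be > 0")
    with np.errstate(invalid="ignore"):
        return int(np.count_nonzero(diffs > tau))


def relative_differences(tau1: np.ndarray, tau2: np.ndarray,
                         x1: np.ndarray, x2: np.ndarray):
    """Relative threshold and count differences for each pair.

    Returns ``(eps, n, valid)`` where ``eps = tau2/tau1 - 1``,
    ``n = x2/x1 - 1`` and ``valid`` is False where the pair cannot enter
    the regression: X1 = 0 (division undefined; with tau1 < tau2 this
    forces X2 = 0 too) or N = 0 (log undefined).  Invalidity is a flag,
    never an exception.
    """
    tau1 = np.asarray(tau1, dtype=float)
    tau2 = np.asarray(tau2, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    eps = tau2 / tau1 - 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        n = np.where(x1 > 0, x2 / np.where(x1 > 0, x1, 1.0) - 1.0, np.nan)
    valid = (x1 > 0) & (x2 != x1) & (eps > 0)
    return eps, n, valid


def draw_threshold_pairs(median: float, n_pairs: int, seed: int) -> ThresholdPairs:
    """Draw ``n_pairs`` threshold pairs uniformly from 1%-50% of ``median``.

    Two independent uniform vectors are paired elementwise, then each
    pair is reordered so tau1 < tau2 (making eps > 0).
    """
    if not median > 0:
        raise ValidationError("median: must be > 0")
    if n_pairs < 1:
        raise ValidationError("n_pairs: must be >= 1")
    rng = np.random.default_rng(seed)
    u1 = rng.uniform(TAU_MIN_FRACTION, TAU_MAX_FRACTION, size=n_pairs)
    u2 = rng.uniform(TAU_MIN_FRACTION, TAU_MAX_FRACTION, size=n_pairs)
    lo = np.minimum(u1, u2)
    hi = np.maximum(u1, u2)
    return ThresholdPairs(frac1=lo, frac2=hi, median=float(median), seed=seed)


def elasticity(series: PixelSeries, seed: int, n_pairs: int = 1000,
               min_change_samples: int = 400,
               min_valid_pairs: int = 10) -> ElasticityFit:
    """Elasticity of ``series`` from ``n_pairs`` random threshold pairs.

    Runs on the raw series: no outlier removal, no gap filling.  The
    data-sufficiency gate requires at least ``min_change_samples``
    consecutive-day change samples (400 for full records; annual runs
    gate on consecutive coverage instead and pass 0 here).

    Raises
    ------
    GateError
        If the change-sample gate is unmet.
    ValidationError
        If the series median is not positive.
    """
    n_changes = count_daily_change_samples(series)
    if n_changes < min_change_samples:
        raise GateError(
            f"daily-change samples {n_changes} < required {min_change_samples}")
    obs = series.observed_values()
    median = float(np.median(obs))
    if not median > 0:
        raise ValidationError("series: median of observed values must be > 0")

    pairs = draw_threshold_pairs(median, n_pairs, seed)
    diffs = daily_change(series)
    finite = diffs[~np.isnan(diffs)]
    # exceedance counts for both threshold vectors at once; sorting makes
    # the per-threshold count a binary search (strict ">" == side="right")
    sorted_diffs = np.sort(finite)
    x1 = finite.size - np.searchsorted(sorted_diffs, pairs.tau1, side="right")
    x2 = finite.size - np.searchsorted(sorted_diffs, pairs.tau2, side="right")
    eps, n_rel, valid = relative_differences(pairs.frac1, pairs.frac2, x1, x2)

    n_used = int(valid.sum())
    if n_used < min_valid_pairs:
        # degenerate convention: every pair shows zero sensitivity
        # (X1 == X2, including the all-zero case) -> elasticity 0
        no_sensitivity = (x2 == x1)
        if bool(np.all(no_sensitivity[~valid])) and n_used == 0:
            return ElasticityFit(beta1=0.0, beta2=0.0, n_pairs_used=0,
                                 n_pairs_total=n_pairs, degenerate=True)
        return ElasticityFit(beta1=float("nan"), beta2=float("nan"),
                             n_pairs_used=n_used, n_pairs_total=n_pairs)

    log_eps = np.log(eps[valid])
    log_absn = np.log(np.abs(n_rel[valid]))
    fit = stats.linregress(log_eps, log_absn)
    return ElasticityFit(beta1=float(abs(fit.slope)), beta2=float(fit.intercept),
                         n_pairs_used=n_used, n_pairs_total=n_pairs)
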