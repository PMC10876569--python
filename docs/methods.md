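# Methods

## Scope and data model

`chlcomplex` computes per-pixel complexity metrics for daily
chlorophyll-a records. The unit of analysis is a `PixelSeries`: a
float array with one slot per calendar day (NaN = missing, days are
never dropped), anchored at a start date (day index 0 = 1998-01-01 by
convention, giving 9,131 days through 2023-01-01). Calendar handling
avoids leap-day special cases by indexing days as integers; the
seasonal period is 365.25 days.

## Elasticity

Daily change is the first difference of the series; a difference is
missing when either endpoint is. Thresholds are drawn as two
independent uniform vectors of fractions u ∈ [0.01, 0.50] of the
series median (n_pairs = 1000 by default), paired elementwise and
reordered so τ₁ < τ₂ within each pair. For each pair, X₁ and X₂ count
daily changes strictly greater than τ₁ = u₁·m and τ₂ = u₂·m
(m = median of observed values). Increases only: negative changes
never exceed a positive threshold, and ties do not count.

The regression is OLS of log|N| on log ε with ε = τ₂/τ₁ − 1 and
N = X₂/X₁ − 1; the elasticity is |slope|. Because τ₁ < τ₂ forces
X₂ ≤ X₁, N lies in [−1, 0] and the logarithm is taken of |N|; the
reported elasticity is therefore non-negative by construction.

Numerical conventions:

- ε is computed from the fraction ratio u₂/u₁ − 1 (identical to
  τ₂/τ₁ − 1 in exact arithmetic). This makes the fit bit-identical
  under rescaling of the series by any positive constant, which the
  test-suite asserts exactly; computing ε from the absolute thresholds
  would leak float rounding of the median into the regression.
- Pairs with X₁ = 0 (ratio undefined; X₂ = 0 follows) or X₂ = X₁
  (N = 0, log undefined) are dropped, not imputed.
- Degenerate convention: if *no* pair is valid and every pair shows
  zero sensitivity (X₁ = X₂, including the all-zero case that arises
  when every threshold exceeds a constant daily step), the elasticity
  is exactly 0. This reproduces the canonical fact that an arithmetic
  series has no threshold sensitivity.
- Fewer than 10 valid pairs without the degenerate pattern → NaN
  result (flagged, never raised), so grid runs continue.
- Gate: at least 400 consecutive-day change samples for full records.
  Annual runs (≤ 366 days) instead gate on ≥100 consecutive observed
  days and pass `min_change_samples=0`.

The elasticity runs on the raw series: no outlier removal, no gap
filling, no significance screening.

## Box-counting fractal dimension

The gap-free series graph is normalized affinely into the unit square
(time → [0,1], values → [0,1] by (v − min)/(max − min)), making the
estimate exactly invariant under affine transforms of the values. The
unit square is partitioned into 2ᵏ × 2ᵏ half-open cells (top
row/rightmost column closed). Graph covering is the default: every
cell intersected by the piecewise-linear graph is counted, using the
fact that a function graph restricted to one column is connected, so
each column contributes one contiguous row interval. Boundary
handling is exact — a supremum that lands on a grid line at a column's
open right edge does not occupy the row above — which makes the unit
diagonal occupy exactly 2ᵏ cells and lets tests compare against
brute-force enumeration cell-for-cell. A points-only mode exists for
comparison.

Scales: k = 2 … ⌊log₂ n⌋ − 2 (the finest grid keeps ≥4 samples per
column on average). The dimension is the OLS slope of log₂(count) on
k, with its standard error reported. Scales whose count exceeds half
of the 4ᵏ cells are *saturated* — the count is pinned near grid
capacity rather than reflecting the curve's scaling — and are excluded
from the fit (at least the 3 finest scales are always kept; all counts
are still reported for audit). Without this guard a sampled smooth
sine reads ≈1.10 instead of ≈1.01, because its coarse columns fold
several oscillations together.

Known bias: box-counting the polyline of a *finitely sampled* rough
path underestimates the continuous-path dimension. Within a column of
m samples the sampled range falls short of the continuous range by a
factor that shrinks with m (≈0.8 at m = 4), so the finest retained
scales undercount and tilt the slope down. At n = 8192 the estimator
reads Brownian motion at ≈1.39 (theory 1.5) and fBm(H) at ≈(2 − H) −
0.1…0.15; the ordering across H and the ≤2 embedding bound are
preserved. The independent variogram/madogram estimator
(`variogram_dimension`, slope of log E|X(t+h) − X(t)| over small lags)
recovers 2 − H to ±0.01 on the same paths and serves as the
cross-check in the test-suite. Absolute dimension values should
therefore be compared within this estimator, not across estimators.

Degenerate input: a constant series is a horizontal line and returns
dimension 1 exactly.

## QC and preprocessing

- Coverage filter: strictly more than 20% of days observed (exactly
  20% fails), ≈1,826 days on a 25-year record.
- Change-sample gate: ≥400 consecutive-day observed pairs, counted
  anywhere in the record (not one unbroken run).
- Outlier removal: single pass; mean and sample SD (ddof = 1) over
  observed values computed once; observations with |v − mean| > 3·SD
  become missing. A constant series (SD = 0) loses nothing under the
  strict inequality.
- Bootstrap gap fill: every missing day gets an independent draw with
  replacement from the observed-value multiset; observed days are
  preserved bit-exactly.
- Temporal aggregation: non-overlapping windows, mean of observed
  days, missing when a window holds none.

Order of operations: elasticity ← raw series; fractal dimension ←
outlier removal → bootstrap fill. Annual metrics apply the same
cleaning within the year's sub-series (a switch disables
within-year filling), and annual thresholds derive from the annual
sub-series median.

## Annual metrics, trends, windows

- Annual gates: mean [chl-a] and dimension need ≥100 observed days in
  the year; elasticity needs a ≥100-day unbroken observed run
  (contiguity read from the contrast with the plain "days sampled"
  wording of the other gate). Failed gates yield NaN fields.
- Global summaries: mean ± 1.96×SE (SD/√n, ddof = 1).
- Percent change: 100·(ρ_end − ρ_start)/ρ_start, default years
  2003 → 2022; zero or missing baseline → NaN.
- Window deviation: 30 random 4000-day windows (starts uniform, with
  replacement, overlap allowed), each metric recomputed under its own
  gates; reported as SD/√(valid trials). Fewer than 2 valid trials →
  NaN.
- Traditional variability: mean, SD, relative SD over observed values;
  seasonal amplitude = per-year range of monthly means (months with
  ≥1 observation), averaged over years — the record contains no
  unambiguous definition of "average seasonal amplitude", so this
  plain reading is adopted and documented here.

## Synthetic generator

`generate_series` emulates the statistical structure the analysis
assumes, not ocean physics: values are
base_level × exp(½·log A·sin(2πt/365.25)) × lognormal(CV), spikes
multiply by spike_factor on Bernoulli days (rate per year), and gaps
are imposed last as a mixture of geometric-length blocks (bursty cloud
cover; mean length and budget share configurable) topped up by
singleton gaps to hit the target fraction exactly (±1% asserted at
record lengths). Defaults: 9,131 days, median 0.2 mg m⁻³, seasonal
ratio 2, CV 0.35, 2 spikes/yr ×5, 50% gaps with mean block length 5.
What it does not emulate: spatial correlation between pixels, sensor
changeovers, retrieval-error structure, trends or regime shifts —
passing tests on these series validates the estimators' contracts, not
geophysical conclusions.

`generate_brownian` is a cumulative sum of i.i.d. Gaussian increments;
`generate_fbm` uses Davies–Harte circulant embedding of the fGn
covariance (exact in distribution; Cholesky fallback guards the
never-observed negative-eigenvalue case). All generators take explicit
integer seeds into `numpy.random.default_rng` (PCG64); nothing touches
global RNG state. Grid runs derive per-pixel seeds from
(master_seed, i_lat, i_lon) via `SeedSequence`, so results are
independent of pixel iteration order.

## Gridded runs and I/O

NetCDF I/O is pinned to xarray's scipy engine (NetCDF3). The reader
accepts a single chlorophyll variable with (time, lat, lon) axes in
any order, strictly increasing daily-or-coarser time, NaN or sentinel
missing values; anything else is a loud format error naming what was
found. Per-pixel results serialize to CSV (round-trip float parsing),
rasters to NetCDF with CF-style coordinates. Pipeline counters log how
many pixels passed each gate so masked ("white") pixels are auditable.

## Problem sizes

The validation suite uses n = 8192 paths with 30 seeds for dimension
anchors, 1000–3000-day series for elasticity and QC properties, and
3×3 to 10×10 grids for pipeline gating; the full suite runs in well
under a minute, and the anchor recomputation script in seconds.

## Known limitations

- The box-count dimension carries the finite-sampling bias quantified
  above; values are comparable within this estimator only.
- The elasticity's threshold-pair law (elementwise pairing of two
  uniform draws, reordered) is one defensible reading of "two uniform
  distributions of thresholds, 1000 values each"; other pairings give
  slightly different β₁ on the same data.
- Seasonal amplitude attenuates the true peak-to-trough range by the
  monthly-averaging factor sinc(1/12) and month-sampling offsets.
- No spatial statistics: pixels are processed independently.
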