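"""Coverage gates, outlier removal, bootstrap gap filling, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chlcomplex import (PixelSeries, SyntheticSpec, ValidationError,
                        aggregate_series, bootstrap_fill,
                        count_daily_change_samples, coverage_filter,
                        fractal_dimension, generate_series, remove_outliers)


def series_with_coverage(n_total: int, n_observed: int) -> PixelSeries:
    v = np.full(n_total, np.nan)
    v[:n_observed] = 1.0
    return PixelSeries(values=v)


class TestCoverageFilter:
    def test_thirty_percent_passes(self):
        assert coverage_filter(series_with_coverage(9131, 2740))

    def test_ten_percent_fails(self):
        assert not coverage_filter(series_with_coverage(9131, 913))

    def test_exactly_twenty_percent_fails_strict_inequality(self):
        # "greater than 20%" — the boundary itself is excluded
        assert not coverage_filter(series_with_coverage(1000, 200))
        assert coverage_filter(series_with_coverage(1000, 201))


class TestCountDailyChangeSamples:
    def test_fully_observed_series(self):
        s = PixelSeries(values=np.ones(401))
        assert count_daily_change_samples(s) == 400

    def test_alternating_observed_missing_gives_zero(self):
        v = np.ones(100)
        v[::2] = np.nan
        assert count_daily_change_samples(PixelSeries(values=v)) == 0

    def test_runs_of_three_and_five(self):
        v = np.full(12, np.nan)
        v[0:3] = 1.0   # run of 3 -> 2 pairs
        v[6:11] = 1.0  # run of 5 -> 4 pairs
        assert count_daily_change_samples(PixelSeries(values=v)) == 6


class TestRemoveOutliers:
    def test_extreme_spike_removed(self):
        v = np.ones(1001)
        v[500] = 1000.0
        cleaned, report = remove_outliers(PixelSeries(values=v))
        assert np.isnan(cleaned.values[500])
        assert report.n_outliers_removed == 1

    def test_constant_series_unchanged(self):
        s = PixelSeries(values=np.full(100, 2.5))
        cleaned, report = remove_outliers(s)
        assert report.n_outliers_removed == 0
        np.testing.assert_array_equal(cleaned.values, s.values)

    def test_gaussian_tail_mass_near_quarter_percent(self, rng):
        # P(|Z| > 3) ~ 0.0027 for Gaussian data, single-pass removal
        removed = []
        for _ in range(50):
            v = rng.standard_normal(5000) + 10.0
            _, report = remove_outliers(PixelSeries(values=v))
            removed.append(report.n_outliers_removed / 5000)
        assert np.mean(removed) == pytest.approx(0.0027, abs=0.001)

    def test_non_outlier_values_bit_exact(self, gappy_series):
        cleaned, _ = remove_outliers(gappy_series)
        kept = cleaned.observed
        np.testing.assert_array_equal(cleaned.values[kept],
                                      gappy_series.values[kept])

    def test_all_missing_rejected(self):
        with pytest.raises(ValidationError):
            remove_outliers(PixelSeries(values=np.array([np.nan, np.nan])))


class TestBootstrapFill:
    def test_gap_free_series_returned_unchanged(self, lognormal_series):
        assert bootstrap_fill(lognormal_series, seed=0) is lognormal_series

    def test_filled_values_from_observed_multiset(self, gappy_series):
        filled = bootstrap_fill(gappy_series, seed=1)
        assert not filled.missing.any()
        observed_set = set(gappy_series.observed_values())
        fill_vals = filled.values[gappy_series.missing]
        assert set(fill_vals) <= observed_set

    def test_observed_positions_bit_exact(self, gappy_series):
        filled = bootstrap_fill(gappy_series, seed=2)
        obs = gappy_series.observed
        np.testing.assert_array_equal(filled.values[obs],
                                      gappy_series.values[obs])

    def test_seed_contract(self, gappy_series):
        a = bootstrap_fill(gappy_series, seed=3)
        b = bootstrap_fill(gappy_series, seed=3)
        c = bootstrap_fill(gappy_series, seed=4)
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_fill_distribution_converges_to_observed(self):
        # KS-style: with many gaps the fill ECDF approaches the observed ECDF
        from scipy import stats

        spec = SyntheticSpec(n_days=9131, gap_fraction=0.7, seed=21)
        s = generate_series(spec)
        filled = bootstrap_fill(s, seed=5)
        d = stats.ks_2samp(filled.values[s.missing], s.observed_values())
        assert d.statistic < 0.03

    def test_all_missing_rejected(self):
        with pytest.raises(ValidationError):
            bootstrap_fill(PixelSeries(values=np.array([np.nan, np.nan])), 0)


class TestAggregateSeries:
    def test_window_one_is_identity(self, gappy_series):
        assert aggregate_series(gappy_series, 1) is gappy_series

    def test_window_of_three_means(self):
        s = PixelSeries(values=np.array([1.0, 2, 3, 4, 5, 6]))
        agg = aggregate_series(s, 3)
        np.testing.assert_allclose(agg.values, [2.0, 5.0])
        assert agg.step_days == 3

    def test_window_with_gaps_uses_observed_mean(self):
        s = PixelSeries(values=np.array([1.0, np.nan, 3, np.nan, np.nan, np.nan]))
        agg = aggregate_series(s, 3)
        assert agg.values[0] == pytest.approx(2.0)
        assert np.isnan(agg.values[1])

    def test_invalid_window_rejected(self, gappy_series):
        with pytest.raises(ValidationError):
            aggregate_series(gappy_series, 0)

    def test_aggregation_smooths_on_average(self):
        # weekly-averaged seasonal series have lower fractal dimension
        # than daily ones, as a trend over seeds (not per instance)
        deltas = []
        for seed in range(8):
            spec = SyntheticSpec(n_days=4096, gap_fraction=0.0, seed=seed)
            s = generate_series(spec)
            daily = fractal_dimension(s).dimension
            weekly = fractal_dimension(aggregate_series(s, 7)).dimension
            deltas.append(daily - weekly)
        assert np.mean(deltas) > 0


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1),
       st.floats(min_value=0.05, max_value=0.9))
def test_fill_then_observe_roundtrip_property(seed, gap_fraction):
    """bootstrap_fill never alters observed values, for any gap pattern."""
    spec = SyntheticSpec(n_days=400, gap_fraction=gap_fraction, seed=seed % 1000)
    s = generate_series(spec)
    if s.n_observed == 0:
        return
    filled = bootstrap_fill(s, seed=seed)
    obs = s.observed
    np.testing.assert_array_equal(filled.values[obs], s.values[obs])
    assert not np.isnan(filled.values).any()
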