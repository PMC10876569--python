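"""Elasticity statistic: daily changes, exceedance counts, the log-log
regression, its degenerate convention and exact scale invariance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chlcomplex import (GateError, PixelSeries, SyntheticSpec, ValidationError,
                        constant_increment_series, count_exceedances,
                        daily_change, draw_threshold_pairs, elasticity,
                        generate_series, relative_differences)
from chlcomplex.elasticity import TAU_MAX_FRACTION, TAU_MIN_FRACTION


def oracle_elasticity(series, seed, n_pairs):
    """Independent brute-force re-implementation: explicit per-pair loops
    and closed-form OLS sums, sharing only the RNG draw convention."""
    obs = series.values[~np.isnan(series.values)]
    median = float(np.median(obs))
    rng = np.random.default_rng(seed)
    u1 = rng.uniform(TAU_MIN_FRACTION, TAU_MAX_FRACTION, size=n_pairs)
    u2 = rng.uniform(TAU_MIN_FRACTION, TAU_MAX_FRACTION, size=n_pairs)
    diffs = np.diff(series.values)
    diffs = diffs[~np.isnan(diffs)]
    xs, ys = [], []
    for a, b in zip(u1, u2):
        lo, hi = (a, b) if a < b else (b, a)
        x1 = sum(1 for d in diffs if d > lo * median)
        x2 = sum(1 for d in diffs if d > hi * median)
        if x1 == 0 or x2 == x1:
            continue
        eps = hi / lo - 1.0
        n_rel = x2 / x1 - 1.0
        xs.append(np.log(eps))
        ys.append(np.log(abs(n_rel)))
    xs, ys = np.array(xs), np.array(ys)
    n = xs.size
    sxx = np.sum((xs - xs.mean()) ** 2)
    sxy = np.sum((xs - xs.mean()) * (ys - ys.mean()))
    slope = sxy / sxx
    intercept = ys.mean() - slope * xs.mean()
    return abs(slope), intercept, n


class TestDailyChange:
    def test_first_differences(self):
        s = PixelSeries(values=np.array([1.0, 2.0, 4.0]))
        np.testing.assert_allclose(daily_change(s), [1.0, 2.0])

    def test_gaps_carry_forward(self):
        s = PixelSeries(values=np.array([1.0, np.nan, 4.0]))
        d = daily_change(s)
        assert np.isnan(d).all() and d.size == 2

    def test_constant_increment_series_constant_diffs(self):
        s = constant_increment_series(50, start=1.0, step=0.5)
        np.testing.assert_allclose(daily_change(s), 0.5)


class TestCountExceedances:
    @pytest.mark.parametrize("tau,expected", [(0.25, 2), (0.6, 0)])
    def test_strict_exceedance_counts(self, tau, expected):
        diffs = np.array([0.5, -0.2, 0.3])
        assert count_exceedances(diffs, tau) == expected

    def test_ties_do_not_count(self):
        assert count_exceedances(np.array([0.3, 0.3]), 0.3) == 0

    def test_order_free(self, rng):
        diffs = rng.standard_normal(500)
        assert (count_exceedances(diffs, 0.4)
                == count_exceedances(diffs[::-1], 0.4)
                == count_exceedances(rng.permutation(diffs), 0.4))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-2, 2, allow_nan=False), min_size=1, max_size=60),
           st.floats(0.01, 1.0), st.floats(0.01, 1.0))
    def test_monotone_in_threshold(self, diffs, t1, t2):
        lo, hi = min(t1, t2), max(t1, t2) + 1e-9
        d = np.array(diffs)
        assert count_exceedances(d, lo) >= count_exceedances(d, hi)


class TestRelativeDifferences:
    def test_epsilon_formula(self):
        eps, _, _ = relative_differences([0.1], [0.2], [10], [5])
        assert eps[0] == pytest.approx(1.0)

    def test_count_ratio_formula(self):
        _, n, _ = relative_differences([0.1], [0.2], [100], [50])
        assert n[0] == pytest.approx(-0.5)

    def test_zero_x1_flags_invalid(self):
        _, _, valid = relative_differences([0.1], [0.2], [0], [0])
        assert not valid[0]

    def test_equal_counts_flag_invalid(self):
        _, _, valid = relative_differences([0.1], [0.2], [7], [7])
        assert not valid[0]


class TestThresholdPairs:
    def test_canonical_order_and_range(self):
        pairs = draw_threshold_pairs(median=0.4, n_pairs=1000, seed=8)
        assert np.all(pairs.frac1 < pairs.frac2)
        assert pairs.tau1.min() >= TAU_MIN_FRACTION * 0.4
        assert pairs.tau2.max() <= TAU_MAX_FRACTION * 0.4

    def test_invalid_median_rejected(self):
        with pytest.raises(ValidationError):
            draw_threshold_pairs(median=0.0, n_pairs=10, seed=0)


class TestElasticity:
    def test_constant_increment_series_elasticity_zero(self):
        s = constant_increment_series(1000, start=1.0, step=0.001)
        fit = elasticity(s, seed=123)
        assert fit.beta1 == 0.0
        assert fit.degenerate
        assert fit.n_pairs_used == 0

    def test_gate_on_change_samples(self):
        s = constant_increment_series(300)
        with pytest.raises(GateError):
            elasticity(s, seed=0)

    def test_beta1_nonnegative_on_synthetic_series(self):
        for seed in range(5):
            spec = SyntheticSpec(n_days=2000, gap_fraction=0.3, seed=seed)
            fit = elasticity(generate_series(spec), seed=seed)
            assert fit.beta1 >= 0
            assert fit.n_pairs_used <= fit.n_pairs_total

    @pytest.mark.parametrize("c", [0.1, 10.0])
    def test_scale_invariance_bit_identical(self, c, lognormal_series):
        base = elasticity(lognormal_series, seed=99)
        scaled = elasticity(lognormal_series.with_values(
            c * lognormal_series.values), seed=99)
        assert scaled.beta1 == base.beta1
        assert scaled.beta2 == base.beta2
        assert scaled.n_pairs_used == base.n_pairs_used

    def test_matches_independent_oracle(self, lognormal_series):
        fit = elasticity(lognormal_series, seed=17, n_pairs=200)
        b1, b2, n_used = oracle_elasticity(lognormal_series, seed=17,
                                           n_pairs=200)
        assert fit.n_pairs_used == n_used
        assert fit.beta1 == pytest.approx(b1, rel=1e-12)
        assert fit.beta2 == pytest.approx(b2, rel=1e-12)

    def test_heavier_spikes_raise_mean_elasticity(self):
        # rougher daily change (more spikes) -> higher elasticity, over seeds
        def mean_beta(spike_rate):
            vals = []
            for seed in range(10):
                spec = SyntheticSpec(n_days=3000, gap_fraction=0.0,
                                     spike_rate=spike_rate, spike_factor=6.0,
                                     seed=seed)
                vals.append(elasticity(generate_series(spec), seed=seed).beta1)
            return np.mean(vals)

        assert mean_beta(20.0) > mean_beta(0.0)

    def test_nonpositive_median_rejected(self):
        v = np.concatenate([-np.ones(300), np.full(301, -0.5)])
        with pytest.raises(ValidationError):
            elasticity(PixelSeries(values=v), seed=0)

    def test_raw_series_used_despite_spikes(self, lognormal_series):
        # spikes change the fit (no outlier removal happens internally)
        v = lognormal_series.values.copy()
        v[::100] *= 50.0
        spiked = elasticity(lognormal_series.with_values(v), seed=5)
        plain = elasticity(lognormal_series, seed=5)
        assert spiked.beta1 != plain.beta1
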