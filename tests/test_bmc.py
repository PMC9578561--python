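"""Monotonization, BMR crossing, bootstrap BMC machinery."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from planartox.bmc import (ACTIVE, INACTIVE, LOW_CENSORED, BMRScan,
                           ConcentrationResponse, bmc_at_threshold,
                           bootstrap_bmcs, child_seed, estimate_bmc,
                           estimate_bmcs, monotonize, most_sensitive_bmc,
                           select_bmr, summarize_bmc, BMCResult)


def brute_force_monotonize(curve, grid):
    """Pointwise-maximal monotone curve dominated by the clipped input.

    Exhaustive search over all grid-valued candidate curves: feasible
    candidates are non-decreasing with 0 <= y_i <= max(x_i, 0); the oracle
    returns the one minimizing the total (L1) correction, which is unique
    because the pointwise maximum of the feasible set is itself feasible.
    """
    x = np.clip(np.asarray(curve, float), 0.0, None)
    best, best_cost = None, math.inf
    for cand in itertools.product(grid, repeat=len(x)):
        y = np.array(cand, dtype=float)
        if np.any(np.diff(y) < 0) or np.any(y > x):
            continue
        cost = float(np.sum(x - y))
        if cost < best_cost:
            best, best_cost = y, cost
    return best


class TestMonotonize:
    def test_top_down_clipping(self):
        assert monotonize([0, 30, 20, 50]).tolist() == [0, 20, 20, 50]

    def test_already_monotone_unchanged(self):
        assert monotonize([0, 10, 40, 80]).tolist() == [0, 10, 40, 80]

    def test_opposite_sign_zeroed_first(self):
        assert monotonize([-5, 30, 20, 50]).tolist() == [0, 20, 20, 50]

    def test_negative_direction_flips_sign(self):
        assert monotonize([5, -30, -20, -50], "-").tolist() == [0, 20, 20, 50]

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            monotonize([])

    def test_agrees_with_brute_force_oracle_on_grid_curves(self):
        grid = (0.0, 20.0, 40.0)
        for n in (2, 3, 4):
            for cand in itertools.product((-20.0,) + grid, repeat=n):
                expected = brute_force_monotonize(cand, grid)
                assert monotonize(list(cand)).tolist() == expected.tolist()

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=1,
                    max_size=12))
    def test_idempotent_monotone_and_conservative(self, curve):
        out = monotonize(curve)
        assert np.all(np.diff(out) >= 0)
        assert np.all(out >= 0)
        assert np.all(out <= np.clip(curve, 0.0, None) + 1e-12)
        assert np.allclose(monotonize(out), out)


class TestBmcAtThreshold:
    def test_log_interpolated_crossing(self):
        v, s = bmc_at_threshold([0, 10, 40, 80, 90], [1, 3.16, 10, 31.6, 100], 25)
        assert s == ACTIVE
        assert v == pytest.approx(10 ** 0.75, rel=1e-3)

    def test_flat_curve_inactive(self):
        v, s = bmc_at_threshold([0, 0, 0, 0], [1, 2, 3, 4], 10)
        assert s == INACTIVE and math.isnan(v)

    def test_low_censored_at_lowest_concentration(self):
        v, s = bmc_at_threshold([20, 30, 40], [1, 2, 4], 10)
        assert s == LOW_CENSORED and v == 1.0

    def test_nondecreasing_in_bmr(self):
        curve = [0, 5, 20, 45, 80]
        conc = [1, 3.16, 10, 31.6, 100]
        values = []
        for bmr in np.arange(5, 80, 5):
            v, s = bmc_at_threshold(curve, conc, bmr)
            if s == ACTIVE:
                values.append(v)
        assert np.all(np.diff(values) >= 0)


class TestBootstrapBmcs:
    def test_zero_variance_gives_identical_samples(self, quarter_log_series):
        hill = 100 * quarter_log_series ** 2 / (quarter_log_series ** 2 + 100)
        cr = ConcentrationResponse("m", quarter_log_series,
                                   [np.full(8, h) for h in hill],
                                   "continuous", "+")
        values, statuses = bootstrap_bmcs(cr, 50.0, 50, seed=0)
        point, _ = bmc_at_threshold(cr.point_curve(), quarter_log_series, 50.0)
        assert np.allclose(values, point)
        assert (statuses == ACTIVE).all()

    def test_reproducible_given_seed(self, quarter_log_series, rng):
        samples = [rng.normal(20, 5, 12) for _ in quarter_log_series]
        cr = ConcentrationResponse("m", quarter_log_series, samples,
                                   "continuous", "+")
        v1, s1 = bootstrap_bmcs(cr, 15.0, 40, seed=9)
        v2, s2 = bootstrap_bmcs(cr, 15.0, 40, seed=9)
        assert np.array_equal(v1, v2, equal_nan=True)

    def test_binary_resampling_uses_worm_labels(self, quarter_log_series):
        # all-affected top half, none below: deterministic incidence curve
        samples = [np.zeros(24) if c < 3 else np.ones(24)
                   for c in quarter_log_series]
        cr = ConcentrationResponse("m", quarter_log_series, samples, "binary")
        values, statuses = bootstrap_bmcs(cr, 50.0, 30, seed=1)
        assert (statuses == ACTIVE).all()
        assert np.allclose(values, values[0])

    def test_hill_truth_recovery_at_fixed_bmr(self, quarter_log_series):
        """Median bootstrap BMC over 20 screens lands within 0.2 log10 of
        the analytic crossing for a Hill curve (Rmax 100, h 2, EC50 10)."""
        rng = np.random.default_rng(7)
        hill = 100 * quarter_log_series ** 2 / (quarter_log_series ** 2 + 100)
        medians = []
        for i in range(20):
            samples = [h + rng.normal(0, 30, 24) for h in hill]
            cr = ConcentrationResponse("m", quarter_log_series, samples,
                                       "continuous", "+")
            values, statuses = bootstrap_bmcs(cr, 50.0, 200,
                                              seed=child_seed(7, i))
            ok = statuses == ACTIVE
            medians.append(np.median(np.log10(values[ok])))
        # BMR 50 on this curve crosses exactly at EC50 = 10 uM
        assert np.median(medians) == pytest.approx(1.0, abs=0.2)


class TestSelectBmr:
    def test_flat_variance_recommends_smallest_threshold(self, quarter_log_series):
        hill = 100 * quarter_log_series ** 2 / (quarter_log_series ** 2 + 100)
        cr = ConcentrationResponse("m", quarter_log_series,
                                   [np.full(8, h) for h in hill],
                                   "continuous", "+")
        scan = BMRScan.for_class("standard", B_select=50)
        sel = select_bmr(cr, scan, seed=0)
        assert sel.bmr == 5.0

    def test_manual_override_bypasses_scan(self, quarter_log_series):
        cr = ConcentrationResponse("m", quarter_log_series,
                                   [np.zeros(8)] * 10, "continuous", "+")
        scan = BMRScan.for_class("standard", B_select=20)
        sel = select_bmr(cr, scan, seed=0, manual_bmr=10.0)
        assert sel.bmr == 10.0 and sel.manual

    def test_pure_noise_is_unestimable_or_floor(self, quarter_log_series, rng):
        # nothing crosses: every threshold >50% censored -> no recommendation
        samples = [rng.normal(0, 1, 24) for _ in quarter_log_series]
        cr = ConcentrationResponse("m", quarter_log_series, samples,
                                   "continuous", "+")
        scan = BMRScan.for_class("standard", B_select=50)
        sel = select_bmr(cr, scan, seed=0)
        assert sel.bmr is None

    def test_invariant_to_b_with_zero_noise(self, quarter_log_series):
        hill = 100 * quarter_log_series ** 2 / (quarter_log_series ** 2 + 100)
        cr = ConcentrationResponse("m", quarter_log_series,
                                   [np.full(8, h) for h in hill],
                                   "continuous", "+")
        scan_small = BMRScan.for_class("standard", B_select=10)
        scan_big = BMRScan.for_class("standard", B_select=200)
        assert (select_bmr(cr, scan_small, 0).bmr
                == select_bmr(cr, scan_big, 1).bmr)


class TestSummarize:
    def test_identical_samples_collapse_percentiles(self):
        values = np.full(100, 3.16)
        statuses = np.array([ACTIVE] * 100)
        res = summarize_bmc(values, statuses)
        assert res.p5_uM == res.median_uM == res.p95_uM == pytest.approx(3.16)
        assert res.status == ACTIVE

    def test_majority_censored_is_inactive(self):
        values = np.concatenate([np.full(40, 1.0), np.full(60, np.nan)])
        statuses = np.array([ACTIVE] * 40 + [INACTIVE] * 60)
        res = summarize_bmc(values, statuses)
        assert res.status == INACTIVE

    def test_lognormal_percentiles_match_closed_form(self, rng):
        mu, sigma = 0.5, 0.3  # log10 scale
        logs = rng.normal(mu, sigma, 1000)
        res = summarize_bmc(10.0 ** logs, np.array([ACTIVE] * 1000))
        from scipy.stats import norm
        for q, got in [(0.05, res.p5_uM), (0.5, res.median_uM),
                       (0.95, res.p95_uM)]:
            expected = 10.0 ** (mu + sigma * norm.ppf(q))
            assert got == pytest.approx(expected, rel=0.08)

    def test_percentile_ordering(self, rng):
        logs = rng.normal(0, 1, 500)
        res = summarize_bmc(10.0 ** logs, np.array([ACTIVE] * 500))
        assert res.p5_uM <= res.median_uM <= res.p95_uM


class TestMostSensitive:
    def make(self, median, status=ACTIVE):
        return BMCResult("m", "+", 10, median, median, median, status, 0.0)

    def test_single_active(self):
        assert most_sensitive_bmc([self.make(3.0)]).median_uM == 3.0

    def test_none_active(self):
        assert most_sensitive_bmc([self.make(3.0, INACTIVE)]) is None

    def test_picks_lowest_active(self):
        results = [self.make(5.0), self.make(0.7), self.make(2.0, INACTIVE)]
        assert most_sensitive_bmc(results).median_uM == 0.7


def test_measure_level_selection_shares_bmr(quarter_log_series, rng):
    hill = 100 * quarter_log_series ** 2 / (quarter_log_series ** 2 + 100)
    crs = [ConcentrationResponse("m", quarter_log_series,
                                 [h + rng.normal(0, 30, 24) for h in hill],
                                 "continuous", "+") for _ in range(5)]
    scan = BMRScan.for_class("standard", B_select=50, B_final=100)
    results, sel = estimate_bmcs(crs, scan, seed=4)
    assert len(results) == 5
    assert all(r.bmr == sel.bmr for r in results)
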