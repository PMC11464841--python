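"""Tests for exact binomial endpoints, KM survival and sample size."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from imccn import (ValidationError, clopper_pearson, endpoint_report,
                   generate_trial_table, inflate_for_dropout, km_estimator,
                   one_prop_sample_size, summarize_response)


def cp_bisection_oracle(successes, n, level=0.95, tol=1e-12):
    """Independent oracle: invert the binomial tail tests by bisection."""
    alpha = 1 - level

    def solve(f, lo, hi):
        while hi - lo > tol:
            mid = (lo + hi) / 2
            if f(mid):
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    lower = 0.0 if successes == 0 else solve(
        lambda p: stats.binom.sf(successes - 1, n, p) < alpha / 2, 0.0, 1.0)
    upper = 1.0 if successes == n else solve(
        lambda p: stats.binom.cdf(successes, n, p) >= alpha / 2, 0.0, 1.0)
    return lower, upper


class TestClopperPearson:
    def test_trial_orr_interval(self):
        ci = clopper_pearson(18, 36, 0.95)
        assert ci.as_percent() == (50.0, 32.9, 67.1)

    def test_trial_dcr_interval(self):
        ci = clopper_pearson(30, 36, 0.95)
        assert ci.as_percent() == (83.3, 67.2, 93.6)

    def test_boundary_conventions(self):
        assert clopper_pearson(0, 10).lower == 0.0
        assert clopper_pearson(10, 10).upper == 1.0

    def test_one_of_ten_to_four_decimals(self):
        ci = clopper_pearson(1, 10, 0.95)
        assert round(ci.lower, 4) == 0.0025
        assert round(ci.upper, 4) == 0.4450

    @pytest.mark.parametrize("x,n", [(0, 5), (1, 10), (3, 10), (18, 36),
                                     (30, 36), (49, 50), (25, 25)])
    def test_matches_bisection_oracle(self, x, n):
        ci = clopper_pearson(x, n)
        lo, hi = cp_bisection_oracle(x, n)
        assert abs(ci.lower - lo) < 1e-6
        assert abs(ci.upper - hi) < 1e-6

    def test_invalid_counts_rejected(self):
        for bad in [(-1, 10), (11, 10), (0, 0)]:
            with pytest.raises(ValidationError):
                clopper_pearson(*bad)

    def test_exact_coverage_is_conservative(self):
        """Exact coverage (by summing the binomial pmf over covering counts)
        is at least nominal for a grid of p and n."""
        for n in (20, 50):
            intervals = [clopper_pearson(x, n) for x in range(n + 1)]
            for p in (0.05, 0.3, 0.5, 0.8):
                pmf = stats.binom.pmf(np.arange(n + 1), n, p)
                cover = [ci.lower <= p <= ci.upper for ci in intervals]
                assert (pmf * cover).sum() >= 0.95 - 1e-12


class TestSummarizeResponse:
    @staticmethod
    def _trial_fas():
        responses = ["PR"] * 18 + ["SD"] * 12 + ["PD"] * 6
        return pd.DataFrame({"best_response": responses, "fas": True})

    def test_trial_counts_reproduce_rates(self):
        rep = summarize_response(self._trial_fas(), "fas")
        assert rep["n"] == 36
        assert rep["orr"].as_percent() == (50.0, 32.9, 67.1)
        assert rep["dcr"].as_percent() == (83.3, 67.2, 93.6)
        assert rep["counts"]["SD"] == 12

    def test_orr_never_exceeds_dcr(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            t = generate_trial_table(30, seed=seed)
            rep = summarize_response(t, "fas")
            assert rep["orr"].estimate <= rep["dcr"].estimate

    def test_all_ne_warns(self):
        t = pd.DataFrame({"best_response": ["NE"] * 5})
        with pytest.warns(UserWarning):
            rep = summarize_response(t)
        assert rep["orr"].estimate == 0.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            summarize_response(pd.DataFrame({"best_response": [], "fas": []}),
                               "fas")


class TestKaplanMeier:
    def test_four_events_product_limit_by_hand(self):
        km = km_estimator([1, 2, 3, 4], [1, 1, 1, 1])
        steps = [km.rate_at(t) for t in (1, 2, 3, 4)]
        np.testing.assert_allclose(steps, [0.75, 0.5, 0.25, 0.0])
        assert km.median == 2.0

    def test_no_events_curve_stays_at_one(self):
        km = km_estimator([5, 6, 7], [0, 0, 0])
        assert km.median is None
        assert km.rate_at(100) == 1.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(5, 40)
        km = km_estimator(times, np.ones(40))
        for t in np.quantile(times, [0.2, 0.5, 0.9]):
            assert km.rate_at(t) == pytest.approx((times > t).mean())

    def test_mismatched_inputs_rejected(self):
        with pytest.raises(ValidationError):
            km_estimator([1, 2], [1])


class TestSampleSize:
    def test_trial_design_returns_35(self):
        assert one_prop_sample_size(0.278, 0.50, 0.05, 0.80) == 35

    def test_dropout_inflation_returns_39(self):
        assert inflate_for_dropout(35, 0.10) == 39

    def test_monotone_in_power(self):
        lo = one_prop_sample_size(0.278, 0.50, 0.05, 0.50)
        hi = one_prop_sample_size(0.278, 0.50, 0.05, 0.80)
        assert lo < hi

    def test_hand_evaluated_formula_case(self):
        # z_{0.975}=1.959964, z_{0.90}=1.281552:
        # ((1.959964*sqrt(.3*.7)+1.281552*sqrt(.25))/0.2)^2 = 59.21 -> 60
        assert one_prop_sample_size(0.30, 0.50, 0.05, 0.90) == 60

    def test_exact_mode_reaches_requested_power(self):
        n = one_prop_sample_size(0.278, 0.50, 0.05, 0.80, method="exact")
        c = int(stats.binom.isf(0.025, n, 0.278)) + 1
        assert stats.binom.sf(c - 1, n, 0.50) >= 0.80

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            one_prop_sample_size(0.3, 0.3)
        with pytest.raises(ValidationError):
            inflate_for_dropout(10, 1.0)

    def test_dropout_identities(self):
        assert inflate_for_dropout(12, 0.0) == 12
        assert inflate_for_dropout(10, 0.5) == 20


def test_endpoint_report_on_synthetic_trial():
    t = generate_trial_table(36, seed=5)
    rep = endpoint_report(t, "fas")
    assert rep["n"] == 36
    assert 0 <= rep["orr_percent"][0] <= 100
    assert "median_pfs_months" in rep
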