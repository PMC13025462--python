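"""Kaplan-Meier, log-rank, cutpoint selection and univariable Cox."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mitosig import survival as surv


class TestKaplanMeier:
    def test_product_limit_by_hand(self):
        km = surv.km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(km.event_times, [1, 2, 3])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_stays_at_one(self):
        km = surv.km_estimate([2, 4, 9], [0, 0, 0])
        assert len(km.event_times) == 0
        np.testing.assert_allclose(km.survival_at([1, 5, 10]), 1.0)

    def test_censoring_time_beyond_last_event_is_irrelevant(self):
        a = surv.km_estimate([1, 2, 3, 4], [1, 1, 1, 0])
        b = surv.km_estimate([1, 2, 3, 99], [1, 1, 1, 0])
        np.testing.assert_allclose(b.survival_at(a.event_times),
                                   a.survival_at(a.event_times))

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10, size=40).round(1) + 0.1
        km = surv.km_estimate(t, np.ones_like(t))
        for u in km.event_times:
            assert km.survival_at(u) == pytest.approx((t > u).mean())


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [1, 0, 1, 1, 0, 1]
        g = [0, 0, 0, 1, 1, 1]
        res = surv.logrank_test(t, e, g)
        assert res.chi_sq == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_single_event_time_closed_form(self):
        # one death among n1+n2 at risk: O1-E1 = d1 - d*n1/n,
        # V = d*(n1/n)*(n2/n)*(n-d)/(n-1)
        t = [5, 5, 5, 5, 5, 5]
        e = [1, 0, 0, 0, 0, 0]
        g = [1, 1, 0, 0, 0, 0]
        res = surv.logrank_test(t, e, g)
        n1, n, d = 2, 6, 1
        oe = 1 - d * n1 / n
        v = d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        assert res.chi_sq == pytest.approx(oe ** 2 / v)

    def test_matches_independent_oe_v_summation(self, rng):
        for _ in range(15):
            n = int(rng.integers(6, 21))
            t = rng.exponential(5, n).round(1) + 0.1
            e = (rng.random(n) < 0.7).astype(int)
            g = (rng.random(n) < 0.5).astype(int)
            if e.sum() == 0 or len(np.unique(g)) < 2:
                continue
            res = surv.logrank_test(t, e, g)
            chi = _brute_force_logrank(t, e, g)
            assert res.chi_sq == pytest.approx(chi, abs=1e-10)

    def test_agrees_with_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        t = rng.exponential(12, 60) + 0.01
        e = (rng.random(60) < 0.8).astype(int)
        g = (rng.random(60) < 0.4).astype(int)
        ours = surv.logrank_test(t, e, g)
        ref = ll_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert ours.chi_sq == pytest.approx(ref.test_statistic, rel=1e-9)
        assert ours.p == pytest.approx(ref.p_value, rel=1e-9)

    def test_requires_events(self):
        with pytest.raises(ValueError, match="event"):
            surv.logrank_test([1, 2], [0, 0], [0, 1])


def _brute_force_logrank(t, e, g):
    """Independent O/E/V summation coded directly from the definition."""
    t = np.asarray(t, float)
    e = np.asarray(e, bool)
    g = np.asarray(g).astype(bool)
    num = 0.0
    var = 0.0
    for u in sorted(set(t[e])):
        at_risk = t >= u
        n = at_risk.sum()
        n1 = (at_risk & g).sum()
        d = (e & (t == u)).sum()
        d1 = (e & (t == u) & g).sum()
        num += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return num ** 2 / var


class TestMedianSplit:
    def test_even_split(self):
        np.testing.assert_array_equal(surv.median_split([1, 2, 3, 4]),
                                      ["low", "low", "high", "high"])

    def test_ties_at_median_go_low(self):
        np.testing.assert_array_equal(surv.median_split([1, 2, 2, 5]),
                                      ["low", "low", "low", "high"])

    def test_partitions_everyone(self, rng):
        v = rng.normal(size=37)
        labels = surv.median_split(v)
        assert set(labels) == {"low", "high"}
        assert len(labels) == 37

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            surv.median_split([3, 3, 3])


class TestMaxstat:
    def _hazard_split_data(self, seed=0, n=40, beta=1.5):
        gen = np.random.default_rng(seed)
        score = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        t = gen.exponential(1.0 / (0.05 * np.exp(beta * score)))
        e = np.ones(n)
        return score, t, e

    def test_planted_separation_found(self):
        score, t, e = self._hazard_split_data(seed=1)
        res = surv.maxstat_cutpoint(score + 0.0, t, e)
        assert 0.0 <= res.cutpoint < 1.0

    def test_exhaustive_scan_is_the_brute_force(self, rng):
        n = 50
        score = rng.normal(size=n)
        t = rng.exponential(10, n) + 0.1
        e = (rng.random(n) < 0.8).astype(int)
        res = surv.maxstat_cutpoint(score, t, e)
        lo, hi = np.quantile(score, (0.1, 0.9))
        best = max(
            ((c, surv.logrank_test(t, e, score > c).chi_sq)
             for c in np.unique(score)
             if lo <= c <= hi and c < score.max()),
            key=lambda pair: pair[1])
        assert res.cutpoint == pytest.approx(best[0])
        assert res.max_chi_sq == pytest.approx(best[1], abs=1e-10)

    def test_translation_equivariance(self, rng):
        score = rng.normal(size=30)
        t = rng.exponential(5, 30) + 0.1
        e = np.ones(30)
        a = surv.maxstat_cutpoint(score, t, e)
        b = surv.maxstat_cutpoint(score + 7.5, t, e)
        assert b.cutpoint == pytest.approx(a.cutpoint + 7.5)
        assert b.max_chi_sq == pytest.approx(a.max_chi_sq)

    def test_logrank_at_cutpoint_reproduces_statistic(self, rng):
        score = rng.normal(size=25)
        t = rng.exponential(8, 25) + 0.1
        e = (rng.random(25) < 0.7).astype(int)
        res = surv.maxstat_cutpoint(score, t, e)
        again = surv.logrank_test(t, e, res.groups(score) == "high")
        assert again.chi_sq == pytest.approx(res.max_chi_sq, abs=1e-12)

    def test_permutation_p_between_zero_and_one(self):
        score, t, e = self._hazard_split_data(seed=2)
        res = surv.maxstat_cutpoint(score, t, e, n_permutations=200, seed=1)
        assert 0 < res.p_permutation <= 1
        assert res.p_permutation >= res.p_naive / 50  # adjusted p not smaller scale

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            surv.maxstat_cutpoint([1, 2, 3], [1, 2, 3], [1, 1, 1])


class TestCox:
    def test_recovers_true_hazard_ratio(self):
        gen = np.random.default_rng(123)
        n = 500
        x = (gen.random(n) < 0.5).astype(float)
        t = gen.exponential(1.0 / (0.02 * np.exp(np.log(2.0) * x)))
        res = surv.cox_univariable(t, np.ones(n), x)
        assert 1.7 < res.hr < 2.3
        assert res.ci95[0] < res.hr < res.ci95[1]

    def test_affine_reparameterization(self, rng):
        n = 120
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.05 * np.exp(0.5 * x)))
        a = surv.cox_univariable(t, np.ones(n), x)
        b = surv.cox_univariable(t, np.ones(n), 10 * x)
        assert b.log_hr == pytest.approx(a.log_hr / 10, rel=1e-6)

    def test_breslow_equals_efron_without_ties(self, rng):
        n = 80
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.05 * np.exp(0.7 * x)))  # continuous: no ties
        e = (rng.random(n) < 0.8).astype(int)
        ours = surv.cox_univariable(t, e, x, ties="breslow")
        ref = surv.cox_univariable(t, e, x, ties="efron")
        assert ours.log_hr == pytest.approx(ref.log_hr, abs=1e-5)
        assert ours.se == pytest.approx(ref.se, rel=1e-4)

    def test_null_coverage(self):
        cover = 0
        for seed in range(50):
            gen = np.random.default_rng(4000 + seed)
            n = 100
            x = (gen.random(n) < 0.5).astype(float)
            t = gen.exponential(20, n)
            res = surv.cox_univariable(t, np.ones(n), x)
            if res.ci95[0] <= 1.0 <= res.ci95[1]:
                cover += 1
        assert cover >= 45

    def test_monotone_likelihood_flagged(self):
        # all events in the high-covariate group, complete risk separation
        t = np.r_[np.arange(1, 11), np.arange(20, 30)] * 1.0
        e = np.r_[np.ones(10), np.zeros(10)]
        x = np.r_[np.ones(10), np.zeros(10)]
        res = surv.cox_univariable(t, e, x)
        assert not res.converged

    def test_requires_two_events_and_varying_covariate(self):
        with pytest.raises(ValueError, match="2 events"):
            surv.cox_univariable([1, 2, 3], [1, 0, 0], [0, 1, 0])
        with pytest.raises(ValueError, match="vary"):
            surv.cox_univariable([1, 2, 3], [1, 1, 1], [1, 1, 1])


def test_days_to_months_uses_julian_convention():
    assert surv.days_to_months(30.4375) == pytest.approx(1.0)
    assert surv.days_to_months(365.25) == pytest.approx(12.0)


def test_drop_missing_survival(tiny_cohort):
    data, _, _ = tiny_cohort
    samples = data.samples.copy()
    samples.iloc[0, samples.columns.get_loc("os_time")] = np.nan
    samples.iloc[0, samples.columns.get_loc("os_event")] = np.nan
    kept, n_dropped = surv.drop_missing_survival(samples)
    assert n_dropped == 1
    assert len(kept) == len(samples) - 1
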