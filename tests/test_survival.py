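"""Kaplan-Meier, log-rank, Cox, and the categorical/continuous tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from spatialtme import (UsageError, ValidationError, build_clinicopath_table,
                        chi_square_test, cox_fit, fisher_exact_test,
                        km_estimate, km_split_analysis, logrank_test,
                        mann_whitney_test)


class TestKmEstimate:
    def test_hand_product_limit(self):
        # events at 6, 7, 15; censored at 10: S(7) = (3/4)(2/3) = 0.5
        km = km_estimate([6, 7, 10, 15], [True, True, False, True])
        assert km.survival_at(7) == pytest.approx(0.5)
        assert km.survival_at(6) == pytest.approx(0.75)
        assert km.survival_at(5) == 1.0
        assert km.survival_at(20) == pytest.approx(0.0)

    def test_no_events_flat_at_one(self):
        km = km_estimate([5, 10, 20], [False, False, False])
        assert km.survival_at(60) == 1.0
        assert km.survival_at_60 == pytest.approx(100.0)

    def test_all_events_equal_empirical_survivor(self, rng):
        t = np.sort(rng.uniform(1, 50, size=15))
        km = km_estimate(t, np.ones(15, bool))
        for x in t:
            assert km.survival_at(x) == pytest.approx((t > x).mean())

    def test_monotone_and_bounded(self, rng):
        t = rng.exponential(20, 40)
        e = rng.uniform(size=40) < 0.6
        if not e.any():
            e[0] = True
        km = km_estimate(t, e)
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert np.all((km.survival >= 0) & (km.survival <= 1))
        # survival at 60 equals S at the last event time ≤ 60
        past = km.times[km.times <= 60]
        if past.size:
            assert km.survival_at_60 == pytest.approx(
                100 * km.survival[len(past) - 1])

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([-1.0], [True])


def _hand_logrank(ta, ea, tb, eb):
    """Independent log-rank tabulation at each distinct event time."""
    ta, tb = np.asarray(ta, float), np.asarray(tb, float)
    ea, eb = np.asarray(ea, bool), np.asarray(eb, bool)
    times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    o_minus_e = 0.0
    var = 0.0
    for t in times:
        n1 = (ta >= t).sum()
        n2 = (tb >= t).sum()
        d1 = ((ta == t) & ea).sum()
        d2 = ((tb == t) & eb).sum()
        n, d = n1 + n2, d1 + d2
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return o_minus_e, var


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [3.0, 8.0, 12.0]
        e = [True, False, True]
        res = logrank_test(t, e, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_six_subject_hand_tabulation(self):
        ta, ea = [2.0, 5.0, 9.0], [True, True, False]
        tb, eb = [3.0, 7.0, 11.0], [True, False, True]
        res = logrank_test(ta, ea, tb, eb)
        o_e, var = _hand_logrank(ta, ea, tb, eb)
        assert res.statistic == pytest.approx(o_e ** 2 / var, rel=1e-9)

    def test_random_fixtures_match_hand_tabulation(self, rng):
        for _ in range(10):
            ta = rng.exponential(20, 12)
            tb = rng.exponential(30, 15)
            ea = rng.uniform(size=12) < 0.7
            eb = rng.uniform(size=15) < 0.7
            if ea.sum() + eb.sum() == 0:
                continue
            res = logrank_test(ta, ea, tb, eb)
            o_e, var = _hand_logrank(ta, ea, tb, eb)
            assert res.statistic == pytest.approx(o_e ** 2 / var, rel=1e-8)

    def test_empty_group_rejected(self):
        with pytest.raises(UsageError):
            logrank_test([], [], [1.0], [True])


def _grid_search_beta(times, events, x):
    """Maximize the (no-ties) Cox partial likelihood on a fine beta grid."""
    order = np.argsort(times)
    times, events, x = times[order], events[order], x[order]
    betas = np.arange(-4.0, 4.0, 1e-4)
    ll = np.zeros_like(betas)
    for i in np.flatnonzero(events):
        risk = times >= times[i]
        n0 = np.sum(risk & (x == 0))
        n1 = np.sum(risk & (x == 1))
        ll += betas * x[i] - np.log(n0 + n1 * np.exp(betas))
    return betas[np.argmax(ll)]


class TestCox:
    def test_identical_groups_hr_one(self):
        df = pd.DataFrame({
            "rfs_months": [5.0, 10.0, 20.0, 40.0] * 2,
            "event": [1, 1, 0, 1] * 2,
            "grp": [0.0] * 4 + [1.0] * 4,
        })
        res = cox_fit(df, "grp")
        assert res.hr == pytest.approx(1.0, abs=1e-6)

    def test_eight_subject_grid_search_oracle(self):
        times = np.array([3.0, 5.0, 8.0, 11.0, 14.0, 20.0, 26.0, 33.0])
        events = np.array([1, 1, 0, 1, 1, 1, 0, 1], bool)
        x = np.array([1, 1, 1, 0, 1, 0, 0, 0], float)
        df = pd.DataFrame({"rfs_months": times, "event": events, "grp": x})
        res = cox_fit(df, "grp")
        beta_grid = _grid_search_beta(times, events, x)
        assert res.extra["beta"] == pytest.approx(beta_grid, abs=1e-4)
        assert res.ci_low < res.hr < res.ci_high

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"rfs_months": [1.0, 2.0], "event": [1, 1],
                           "grp": [1.0, 1.0]})
        with pytest.raises(UsageError):
            cox_fit(df, "grp")

    def test_complete_separation_flagged(self):
        # all events in one group, censoring in the other, disjoint times
        df = pd.DataFrame({
            "rfs_months": [1.0, 2.0, 3.0, 50.0, 55.0, 60.0],
            "event": [1, 1, 1, 0, 0, 0],
            "grp": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0],
        })
        res = cox_fit(df, "grp")
        assert not res.converged
        assert res.hr is None


class TestContingencyTests:
    def test_fisher_two_by_two_enumeration(self):
        res = fisher_exact_test([[2, 0], [0, 2]])
        assert res.p == pytest.approx(1 / 3)

    def test_balanced_table_p_one(self):
        for a in (1, 3, 7):
            t = [[a, a], [a, a]]
            assert fisher_exact_test(t).p == pytest.approx(1.0)
            assert chi_square_test(t).p == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_summation(self, rng):
        """Classical two-sided rule: sum of probabilities ≤ observed."""
        for _ in range(30):
            a, b, c, d = rng.integers(0, 16, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            n = a + b + c + d
            rv = hypergeom(n, a + b, a + c)
            p_obs = rv.pmf(a)
            ks = np.arange(max(0, a + c - (c + d)), min(a + b, a + c) + 1)
            p = rv.pmf(ks)[rv.pmf(ks) <= p_obs * (1 + 1e-9)].sum()
            assert fisher_exact_test([[a, b], [c, d]]).p == pytest.approx(
                min(p, 1.0), rel=1e-8)

    def test_chi_square_matches_printed_cohort_value(self):
        # vascular invasion 9/40 vs 19/40 across ratio groups
        res = chi_square_test([[9, 19], [31, 21]])
        assert res.p == pytest.approx(0.019, abs=5e-4)
        assert res.method == "chi_square"

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_test([[1, -2], [3, 4]])

    def test_zero_expected_rejected_for_chi_square(self):
        with pytest.raises(UsageError):
            chi_square_test([[0, 0], [3, 4]])


class TestMannWhitney:
    def test_exact_enumeration_small_samples(self):
        res = mann_whitney_test([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(0.1)
        assert res.extra["exact"]

    def test_identical_samples_p_one(self):
        res = mann_whitney_test([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert res.p == pytest.approx(1.0)

    def test_large_or_tied_samples_use_approximation(self, rng):
        a = rng.normal(size=30)
        res = mann_whitney_test(a, rng.normal(size=30))
        assert not res.extra["exact"]

    def test_empty_sample_rejected(self):
        with pytest.raises(UsageError):
            mann_whitney_test([], [1.0])


class TestClinicopathTable:
    def _cohort(self):
        ids = [f"c{i}" for i in range(80)]
        # vascular invasion replicating the printed ratio-group counts
        invasion = (["present"] * 9 + ["absent"] * 31
                    + ["present"] * 19 + ["absent"] * 21)
        df = pd.DataFrame({"case_id": ids,
                           "rfs_months": 60.0, "event": 0,
                           "vascular_invasion": invasion,
                           "age": np.arange(80, dtype=float)})
        labels = pd.Series(["HIGH"] * 40 + ["LOW"] * 40, index=ids)
        return df, labels

    def test_group_percentages_and_tests(self):
        df, labels = self._cohort()
        out = build_clinicopath_table(df, labels,
                                      categorical_vars=["vascular_invasion"],
                                      continuous_vars=["age"])
        pres = out[(out["variable"] == "vascular_invasion")
                   & (out["level"] == "present")].iloc[0]
        assert pres["pct_high"] == pytest.approx(22.5)
        assert pres["pct_low"] == pytest.approx(47.5)
        row0 = out[out["variable"] == "vascular_invasion"].iloc[0]
        assert row0["p_chi_square"] == pytest.approx(0.019, abs=5e-4)
        assert np.isfinite(row0["p_fisher"])
        age = out[out["variable"] == "age"]
        assert np.isfinite(age["p_mann_whitney"]).any()

    def test_single_level_variable_skipped(self):
        df, labels = self._cohort()
        df["mono"] = "x"
        with pytest.warns(UserWarning, match="single level"):
            out = build_clinicopath_table(df, labels, categorical_vars=["mono"])
        assert out["p_chi_square"].isna().all()

    def test_unlabeled_cases_dropped_with_notice(self):
        df, labels = self._cohort()
        with pytest.warns(UserWarning, match="dropped"):
            build_clinicopath_table(df, labels.iloc[:70],
                                    categorical_vars=["vascular_invasion"])


class TestKmSplitAnalysis:
    def test_groups_and_direction(self, rng):
        n = 60
        ids = [f"c{i}" for i in range(n)]
        grp = np.array(["HIGH"] * (n // 2) + ["LOW"] * (n // 2))
        rate = np.where(grp == "LOW", 0.05, 0.01)
        t = rng.exponential(1 / rate)
        df = pd.DataFrame({"case_id": ids,
                           "rfs_months": np.minimum(t, 60.0),
                           "event": (t <= 60.0).astype(int)})
        res = km_split_analysis(df, pd.Series(grp, index=ids))
        assert res["n_high"] == res["n_low"] == 30
        assert res["rfs60_low"] < res["rfs60_high"]
        assert res["cox_low_vs_high"].hr > 1.0
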