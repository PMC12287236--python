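"""Survival layer vs brute-force oracles: KM, log-rank, Cox, c-index, AUC."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from hdspath._nn import breslow_loglik
from hdspath.survstats import (SurvivalRecord, concordance_index, cox_fit,
                               km_curve, km_rate_at, logrank_test,
                               records_to_frame, subgroup_forest,
                               time_dependent_auc)
from tests.conftest import toy_survival


class TestKaplanMeier:
    def test_two_events_by_hand(self):
        curve = km_curve(toy_survival([1, 2], [1, 1]))
        assert km_rate_at(curve, 0.5) == 1.0
        assert km_rate_at(curve, 1) == 0.5
        assert km_rate_at(curve, 2) == 0.0

    def test_all_censored_is_flat_one(self):
        curve = km_curve(toy_survival([3, 5, 8], [0, 0, 0]))
        assert all(s == 1.0 for s in curve.survival)
        assert len(curve.censor_times) == 3

    def test_censoring_product_limit_by_hand(self):
        # times 1, 2+, 3: S(1) = 2/3, S(3) = 0
        curve = km_curve(toy_survival([1, 2, 3], [1, 0, 1]))
        assert km_rate_at(curve, 1) == pytest.approx(2 / 3)
        assert km_rate_at(curve, 2.5) == pytest.approx(2 / 3)
        assert km_rate_at(curve, 3) == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10, 60).round(2)
        curve = km_curve(toy_survival(t, np.ones(60)))
        for q in (2.0, 5.0, 12.0):
            assert km_rate_at(curve, q) == pytest.approx(np.mean(t > q))

    def test_monotone_and_bounded(self, rng):
        t = rng.exponential(10, 50)
        e = rng.integers(0, 2, 50)
        e[0] = 1
        curve = km_curve(toy_survival(t, e))
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert curve.survival.min() >= 0 and curve.survival.max() <= 1.0

    def test_negative_time_query_rejected(self):
        curve = km_curve(toy_survival([1], [1]))
        with pytest.raises(ValueError):
            km_rate_at(curve, -1)


def _brute_logrank_2group(df, group_col="group"):
    """O-E / hypergeometric-variance enumeration over pooled event times."""
    g = sorted(df[group_col].unique())
    o_minus_e, var = 0.0, 0.0
    for t in np.sort(df.loc[df.event == 1, "time"].unique()):
        at_risk = df[df.time >= t]
        d = int(((df.time == t) & (df.event == 1)).sum())
        n = len(at_risk)
        n1 = int((at_risk[group_col] == g[0]).sum())
        d1 = int(((df.time == t) & (df.event == 1)
                  & (df[group_col] == g[0])).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return chi2, stats.chi2.sf(chi2, df=1)


class TestLogrank:
    def test_identical_groups_null(self):
        df = toy_survival([1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1],
                          group=list("AAABBB"))
        res = logrank_test(df)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_matches_brute_force_enumeration(self, rng):
        df = toy_survival([1, 2, 3, 4, 6, 7, 9, 10],
                          [1, 1, 0, 1, 1, 0, 1, 1],
                          group=list("ABABABAB"))
        chi2, p = _brute_logrank_2group(df)
        res = logrank_test(df)
        assert res.statistic == pytest.approx(chi2, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_needs_two_groups_and_events(self):
        with pytest.raises(ValueError):
            logrank_test(toy_survival([1, 2], [1, 1], group=["A", "A"]))
        with pytest.raises(ValueError, match="no events"):
            logrank_test(toy_survival([1, 2], [0, 0], group=["A", "B"]))

    def test_three_group_df(self):
        df = toy_survival(np.arange(1, 13), [1] * 12, group=list("ABC") * 4)
        assert logrank_test(df).df == 2


class TestCox:
    def test_single_covariate_matches_grid_oracle(self):
        df = toy_survival([2, 4, 5, 7, 10], [1, 1, 0, 1, 1],
                          x=[0.2, 1.0, -0.3, 0.6, -1.5])
        fit = cox_fit(df, ["x"])
        x = df["x"].to_numpy()

        def nll(b):
            return -breslow_loglik(b * x, df["time"].to_numpy(),
                                   df["event"].to_numpy())

        res = optimize.minimize_scalar(nll, bounds=(-5, 5), method="bounded",
                                       options={"xatol": 1e-10})
        assert fit.table.loc["x", "beta"] == pytest.approx(res.x, abs=1e-3)
        assert fit.log_likelihood == pytest.approx(-nll(res.x), abs=1e-6)

    def test_hazard_ratio_and_ci_shape(self):
        df = toy_survival([2, 4, 5, 7, 10, 12], [1, 1, 0, 1, 1, 1],
                          x=[1.0, 0.2, -0.3, -0.8, -1.5, 0.4])
        fit = cox_fit(df, ["x"])
        row = fit.table.loc["x"]
        assert row["hr"] == pytest.approx(np.exp(row["beta"]))
        assert row["ci_lower"] < row["hr"] < row["ci_upper"]
        assert "HR" in fit.summary()

    def test_beta_recovery_on_generator(self):
        from hdspath.cohort import simulate_survival

        rng = np.random.default_rng(10)
        x = rng.normal(size=(500, 1))
        sim = simulate_survival(x, [1.0], 0.02, 0.01, seed=10)
        df = sim.rename(columns={})
        df["x"] = x[:, 0]
        fit = cox_fit(df, ["x"])
        assert fit.table.loc["x", "beta"] == pytest.approx(1.0, abs=0.15)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            cox_fit(toy_survival([1, 2, 3], [1, 0, 0], x=[1.0, 2.0, 3.0]),
                    ["x"])

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(toy_survival([1, 2, 3], [1, 1, 1], x=[1.0, 1.0, 1.0]),
                    ["x"])


class TestConcordance:
    def test_perfect_anti_ordering(self):
        df = toy_survival([1, 2, 3, 4], [1, 1, 1, 1])
        assert concordance_index(df, np.array([4.0, 3.0, 2.0, 1.0])) == 1.0

    def test_random_scores_near_half(self, rng):
        df = toy_survival(rng.exponential(10, 2000), np.ones(2000))
        c = concordance_index(df, rng.normal(size=2000))
        assert c == pytest.approx(0.5, abs=0.03)

    def test_censored_example_matches_pair_enumeration(self, rng):
        for _ in range(10):
            n = 50
            t = rng.exponential(10, n)  # continuous: no time ties
            e = rng.integers(0, 2, n)
            e[0] = 1
            s = rng.normal(size=n).round(1)  # induce score ties
            df = toy_survival(t, e)
            num = den = 0.0
            for i in range(n):
                for j in range(n):
                    if t[i] < t[j] and e[i] == 1:
                        den += 1
                        num += (s[i] > s[j]) + 0.5 * (s[i] == s[j])
            assert concordance_index(df, s) == pytest.approx(num / den,
                                                             abs=1e-12)

    def test_negation_complement_without_ties(self, rng):
        t = rng.exponential(10, 30)
        e = rng.integers(0, 2, 30)
        e[:3] = 1
        s = rng.normal(size=30)
        df = toy_survival(t, e)
        assert concordance_index(df, s) + concordance_index(df, -s) \
            == pytest.approx(1.0)

    def test_no_usable_pairs_rejected(self):
        with pytest.raises(ValueError, match="usable"):
            concordance_index(toy_survival([1, 2], [0, 0]), np.array([1.0, 2.0]))


def _cens_km(time, event, at):
    """Product-limit estimate of the censoring survival G(t)."""
    G = 1.0
    for u in np.sort(np.unique(time[event == 0])):
        if u > at:
            break
        G *= 1 - np.sum((time == u) & (event == 0)) / np.sum(time >= u)
    return G


class TestTimeDependentAUC:
    def test_no_censoring_reduces_to_mann_whitney(self, rng):
        t = rng.exponential(20, 80)
        s = rng.normal(size=80) - 0.05 * t
        df = toy_survival(t, np.ones(80))
        out = time_dependent_auc(df, s, horizons=[10.0])
        cases, controls = s[t <= 10.0], s[t > 10.0]
        mw = np.mean([(a > b) + 0.5 * (a == b)
                      for a in cases for b in controls])
        assert out[10.0] == pytest.approx(mw, abs=1e-10)

    def test_perfect_separation(self):
        t = np.array([2.0, 3.0, 4.0, 20.0, 25.0, 30.0])
        s = np.array([6.0, 5.0, 4.0, 3.0, 2.0, 1.0])
        out = time_dependent_auc(toy_survival(t, np.ones(6)), s,
                                 horizons=[10.0])
        assert out[10.0] == 1.0

    def test_censored_matches_ipcw_pair_enumeration(self, rng):
        n = 40
        t_ev = rng.exponential(20, n)   # continuous: no event/censor ties
        t_cn = rng.exponential(30, n)
        time = np.minimum(t_ev, t_cn)
        event = (t_ev <= t_cn).astype(int)
        s = rng.normal(size=n)
        df = toy_survival(time, event)
        h = 10.0
        num = den_cases = 0.0
        controls = np.flatnonzero(time > h)
        for i in range(n):
            if time[i] <= h and event[i]:
                w = 1.0 / _cens_km(time, event, time[i])
                den_cases += w
                for j in controls:
                    num += w * ((s[i] > s[j]) + 0.5 * (s[i] == s[j]))
        expected = num / (den_cases * len(controls))
        out = time_dependent_auc(df, s, horizons=[h])
        assert out[h] == pytest.approx(expected, abs=1e-10)

    def test_horizon_beyond_follow_up_flagged(self):
        df = toy_survival([1, 2, 3], [1, 1, 1])
        out = time_dependent_auc(df, np.array([3.0, 2.0, 1.0]),
                                 horizons=[2.0, 100.0])
        assert np.isnan(out[100.0])
        assert not np.isnan(out[2.0])


class TestSubgroupForest:
    def test_whole_cohort_subgroup_equals_overall_fit(self, rng):
        n = 120
        x = rng.normal(size=n)
        t = rng.exponential(10 * np.exp(-x))
        df = toy_survival(t, np.ones(n), risk=x, all="everyone")
        table = subgroup_forest(df, "risk", ["all"])
        overall = cox_fit(df, ["risk"])
        assert table.loc[0, "hr"] == pytest.approx(overall.hr("risk"))

    def test_uniform_effect_consistent_across_subgroups(self, rng):
        n = 400
        x = rng.normal(size=n)
        t = rng.exponential(10 * np.exp(-x))
        df = toy_survival(t, np.ones(n), risk=x,
                          grp=rng.choice(["a", "b"], size=n))
        table = subgroup_forest(df, "risk", ["grp"])
        assert (table["hr"] > 1).all()
        assert (table["p"] < 0.05).all()
        # CIs overlap for a homogeneous effect
        assert table["ci_lower"].max() < table["ci_upper"].min()

    def test_degenerate_subgroup_skipped_with_reason(self, rng):
        df = toy_survival([1, 2, 3, 4, 5], [1, 1, 1, 1, 1],
                          risk=[0.1, 0.5, 0.3, 0.8, 0.2],
                          grp=["a", "a", "a", "a", "b"])
        table = subgroup_forest(df, "risk", ["grp"])
        row = table[table["level"] == "b"].iloc[0]
        assert "skipped" in row["note"]
        assert np.isnan(row["hr"])


class TestRecords:
    def test_record_validation_and_frame(self):
        recs = [SurvivalRecord("p1", 10.0, 1, covariates={"stage": 2.0}),
                SurvivalRecord("p2", 5.0, 0)]
        df = records_to_frame(recs)
        assert list(df["patient_id"]) == ["p1", "p2"]
        assert df.loc[0, "stage"] == 2.0
        with pytest.raises(ValueError):
            SurvivalRecord("p", -1.0, 1)
        with pytest.raises(ValueError):
            SurvivalRecord("p", 1.0, 2)
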