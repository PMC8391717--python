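import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test

from clical.estimators import (
    concordance_index,
    cox_fit,
    efron_log_likelihood,
    km_estimate,
    log_rank,
    na_cumhaz,
)


class TestKaplanMeier:
    def test_hand_computed_fixture(self, toy_surv):
        km = km_estimate(*toy_surv)
        assert km.at(5) == pytest.approx(2 / 3)
        assert km.at(8) == pytest.approx(1 / 3)
        assert km.at(12) == pytest.approx(1 / 3)  # censoring does not move the step
        assert km.at(4.9) == 1.0

    def test_greenwood_variance_fixture(self, toy_surv):
        km = km_estimate(*toy_surv)
        # S(8)^2 * (1/(3*2) + 1/(2*1))
        assert km.greenwood_variance[-1] == pytest.approx((1 / 3) ** 2 * (1 / 6 + 1 / 2))

    def test_all_censored_flat_one(self, caplog):
        with caplog.at_level("WARNING"):
            km = km_estimate([3, 5, 9], [0, 0, 0])
        assert km.at(100) == 1.0

    def test_single_subject_event(self):
        km = km_estimate([4.0], [1])
        assert km.at(4.0) == 0.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            km_estimate([], [])

    def test_monotone_and_ci_brackets(self, cohort_2000):
        df = cohort_2000[0].data
        km = km_estimate(df["os_months"], df["os_event"])
        assert (np.diff(km.survival) <= 1e-12).all()
        assert ((km.ci_low <= km.survival + 1e-12) & (km.survival <= km.ci_high + 1e-12)).all()
        assert (km.ci_low >= 0).all() and (km.ci_high <= 1).all()

    def test_matches_lifelines(self, cohort_2000):
        from lifelines import KaplanMeierFitter

        df = cohort_2000[0].data
        kmf = KaplanMeierFitter().fit(df["os_months"], df["os_event"])
        km = km_estimate(df["os_months"], df["os_event"])
        for t in (6, 12, 32, 70):
            assert km.at(t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-10
            )


class TestNelsonAalen:
    def test_hand_computed_fixture(self, toy_surv):
        na = na_cumhaz(*toy_surv)
        assert na.at(5) == pytest.approx(1 / 3)
        assert na.at(8) == pytest.approx(1 / 3 + 1 / 2)

    def test_no_events_zero(self):
        na = na_cumhaz([3, 5], [0, 0])
        assert na.at(10) == 0.0

    def test_exponential_limit(self):
        rng = np.random.default_rng(3)
        lam = 0.2
        t = rng.exponential(1 / lam, size=20000)
        na = na_cumhaz(t, np.ones_like(t, dtype=int))
        for horizon in (2.0, 5.0):
            assert na.at(horizon) == pytest.approx(lam * horizon, rel=0.05)

    def test_km_na_inequality(self, cohort_2000):
        # -log S_KM(t) >= H_NA(t) pointwise on the event grid
        df = cohort_2000[0].data
        km = km_estimate(df["os_months"], df["os_event"])
        na = na_cumhaz(df["os_months"], df["os_event"])
        mask = km.survival > 0
        assert (
            -np.log(km.survival[mask]) >= na.cumhaz[mask] - 1e-12
        ).all()


class TestLogRank:
    def test_identical_groups_null(self):
        g = ([1.0, 2.0, 3.0], [1, 1, 0])
        r = log_rank([g, g])
        assert r.chi_square == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_hand_computed_fixture(self):
        # O-E and hypergeometric variance summed over the 4 event times
        r = log_rank([([1, 2], [1, 1]), ([3, 4], [1, 1])])
        assert r.chi_square == pytest.approx(2.8823529411764706, rel=1e-12)
        assert r.df == 1

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            log_rank([([1, 2], [1, 1])])

    def test_matches_lifelines_three_groups(self):
        rng = np.random.default_rng(5)
        times = rng.exponential([1, 1.5, 2.5], size=(60, 3)).T.ravel()
        events = (rng.uniform(size=180) < 0.8).astype(int)
        labels = np.repeat([0, 1, 2], 60)
        r = log_rank(
            [(times[labels == g], events[labels == g]) for g in range(3)]
        )
        ll = multivariate_logrank_test(times, labels, events)
        assert r.chi_square == pytest.approx(ll.test_statistic, rel=1e-9)
        assert r.df == 2
        assert r.p_value == pytest.approx(ll.p_value, rel=1e-9)

    def test_relabeling_invariance(self):
        a = ([1.0, 4.0, 6.0], [1, 0, 1])
        b = ([2.0, 3.0, 9.0], [1, 1, 1])
        assert log_rank([a, b]).chi_square == pytest.approx(
            log_rank([b, a]).chi_square, rel=1e-12
        )

    def test_time_unit_invariance(self):
        a = ([1.0, 4.0, 6.0], [1, 0, 1])
        b = ([2.0, 3.0, 9.0], [1, 1, 1])
        scaled = [([12 * t for t in g[0]], g[1]) for g in (a, b)]
        assert log_rank([a, b]).chi_square == pytest.approx(
            log_rank(scaled).chi_square, rel=1e-12
        )


def _sim_two_group(n, log_hr, seed, censor=2.0):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1 / np.exp(log_hr * x))
    c = rng.uniform(0, censor, n)
    return pd.DataFrame(
        {"x": x, "os_months": np.minimum(t, c), "os_event": (t <= c).astype(int)}
    )


class TestCox:
    def test_constant_covariate_zero_coef(self):
        df = _sim_two_group(100, 0.5, 0)
        df["z"] = 0.0
        fit = cox_fit(df, ["z"])
        assert fit.summary.loc["z", "coef"] == pytest.approx(0.0, abs=1e-8)
        assert fit.summary.loc["z", "hazard_ratio"] == pytest.approx(1.0, abs=1e-8)

    def test_matches_lifelines_continuous(self):
        rng = np.random.default_rng(1)
        n = 400
        x1 = rng.normal(size=n)
        x2 = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / np.exp(0.5 * x1 - 0.7 * x2))
        c = rng.uniform(0, 3, n)
        df = pd.DataFrame(
            {"x1": x1, "x2": x2, "os_months": np.minimum(t, c), "os_event": (t <= c).astype(int)}
        )
        fit = cox_fit(df, ["x1", "x2"])
        cph = CoxPHFitter().fit(
            df.rename(columns={"os_months": "T", "os_event": "E"}), "T", "E"
        )
        assert fit.summary["coef"].to_numpy() == pytest.approx(
            cph.params_.to_numpy(), abs=1e-6
        )
        assert fit.summary["se"].to_numpy() == pytest.approx(
            cph.standard_errors_.to_numpy(), abs=1e-6
        )
        assert fit.log_likelihood == pytest.approx(cph.log_likelihood_, rel=1e-9)

    def test_tied_fixture_brute_force_efron(self):
        df = pd.DataFrame(
            {
                "x": [0.0, 1.0, 1.0, 0.0, 1.0, 0.0],
                "os_months": [2, 2, 2, 3, 4, 5.0],
                "os_event": [1, 1, 1, 1, 0, 1],
            }
        )
        fit = cox_fit(df, ["x"])
        beta = fit.summary["coef"].to_numpy()
        # independent oracle: direct risk-set evaluation of the Efron formula
        xc = df[["x"]].to_numpy() - df[["x"]].to_numpy().mean(axis=0)
        ll = efron_log_likelihood(beta, xc, df["os_months"], df["os_event"])
        assert fit.log_likelihood == pytest.approx(ll, rel=1e-12)
        cph = CoxPHFitter().fit(
            df.rename(columns={"os_months": "T", "os_event": "E"}), "T", "E"
        )
        assert beta == pytest.approx(cph.params_.to_numpy(), abs=1e-7)

    def test_score_equation_residual_at_convergence(self):
        df = _sim_two_group(500, 0.7, 2)
        fit = cox_fit(df, ["x"])
        beta = fit.summary["coef"].to_numpy()
        eps = 1e-5
        xc = df[["x"]].to_numpy() - df[["x"]].to_numpy().mean(axis=0)
        d = (
            efron_log_likelihood(beta + eps, xc, df["os_months"], df["os_event"])
            - efron_log_likelihood(beta - eps, xc, df["os_months"], df["os_event"])
        ) / (2 * eps)
        assert abs(d) < 1e-4  # numerical derivative; analytic residual is ~1e-9

    def test_hazard_ratio_recovery(self):
        df = _sim_two_group(2000, np.log(2), 7)
        fit = cox_fit(df, ["x"])
        hr = fit.summary.loc["x", "hazard_ratio"]
        assert 1.8 < hr < 2.2
        assert fit.summary.loc["x", "ci_low"] < 2 < fit.summary.loc["x", "ci_high"]

    def test_categorical_expansion(self):
        rng = np.random.default_rng(9)
        n = 300
        cat = rng.choice(["a", "b", "c"], n)
        t = rng.exponential(1 / np.exp((cat == "c") * 0.8))
        df = pd.DataFrame({"g": cat, "os_months": t, "os_event": 1})
        fit = cox_fit(df, ["g"])
        assert len(fit.summary) == 2  # reference level dropped

    def test_forest_table_layout(self):
        df = _sim_two_group(100, 0.5, 3)
        t = cox_fit(df, ["x"]).forest_table()
        assert list(t.columns) == ["HR", "CI95_low", "CI95_high", "p"]

    def test_no_events_rejected(self):
        df = pd.DataFrame({"x": [1.0, 0.0], "os_months": [1.0, 2.0], "os_event": [0, 0]})
        with pytest.raises(ValueError):
            cox_fit(df, ["x"])

    def test_separation_flagged_not_fatal(self, caplog):
        df = pd.DataFrame(
            {
                "x": [0.0, 0.0, 0.0, 1.0, 1.0, 1.0],
                "os_months": [1, 2, 3, 10, 11, 12.0],
                "os_event": [1, 1, 1, 1, 1, 1],
            }
        )
        with caplog.at_level("WARNING"):
            fit = cox_fit(df, ["x"])
        assert np.isfinite(fit.summary.loc["x", "coef"])

    def test_time_interaction_covariate(self):
        # strongly time-varying effect -> significant interaction term
        rng = np.random.default_rng(11)
        n = 600
        x = rng.integers(0, 2, n).astype(float)
        # group 1 protected early, harmed late
        t = np.where(x == 1, rng.weibull(3, n) * 2.0, rng.exponential(1.2, n))
        df = pd.DataFrame({"x": x, "os_months": t, "os_event": 1})
        fit = cox_fit(df, ["x"], time_interaction=["x"])
        assert "x:log(t)" in fit.summary.index
        assert fit.summary.loc["x:log(t)", "p_value"] < 0.01


class TestConcordance:
    def test_perfect_ordering(self):
        t = np.array([1, 2, 3, 4, 5.0])
        risk = -t  # shortest survival = highest risk
        assert concordance_index(risk, t, np.ones(5, dtype=int)) == 1.0

    def test_constant_risk_half(self):
        t = np.array([1, 2, 3, 4.0])
        assert concordance_index(np.zeros(4), t, np.ones(4, dtype=int)) == 0.5

    def test_censored_fixture_matches_enumeration(self):
        risk = np.array([3.0, 1.0, 2.0, 2.0, 0.5])
        t = np.array([2.0, 6.0, 4.0, 5.0, 3.0])
        e = np.array([1, 1, 0, 1, 0])
        # exhaustive oracle over ordered pairs
        conc = pairs = 0.0
        for i in range(5):
            for j in range(5):
                if e[i] == 1 and t[i] < t[j]:
                    pairs += 1
                    conc += 1.0 if risk[i] > risk[j] else (0.5 if risk[i] == risk[j] else 0.0)
        assert concordance_index(risk, t, e) == pytest.approx(conc / pairs)

    def test_no_usable_pairs(self):
        with pytest.raises(ValueError):
            concordance_index([1.0], [2.0], [1])

    def test_true_risk_beats_permuted(self):
        wins = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=150)
            t = rng.exponential(1 / np.exp(x))
            c = rng.uniform(0, 2, 150)
            times, events = np.minimum(t, c), (t <= c).astype(int)
            ci_true = concordance_index(x, times, events)
            ci_perm = concordance_index(rng.permutation(x), times, events)
            wins += ci_true > ci_perm
        assert wins >= 48
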