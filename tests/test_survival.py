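"""Kaplan-Meier, log-rank and Cox regression against closed forms and lifelines."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank_test
from lifelines.statistics import multivariate_logrank_test

from nagpipe import survival as sv


def toy_data():
    time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    event = np.array([1, 0, 1, 1, 0, 1])
    return sv.SurvivalData(time=time, event=event)


class TestSurvivalData:
    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            sv.SurvivalData(time=np.array([0.0, 1.0]), event=np.array([1, 0]))

    def test_nonbinary_events_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            sv.SurvivalData(time=np.array([1.0]), event=np.array([2]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            sv.SurvivalData(time=np.array([1.0, 2.0]), event=np.array([1]))


class TestTruncation:
    def test_beyond_horizon_censored_at_horizon(self):
        d = sv.SurvivalData(time=np.array([3.0, 7.2]), event=np.array([1, 1]))
        t = sv.truncate_followup(d, horizon=5.0)
        assert t.time[1] == 5.0 and t.event[1] == 0

    def test_event_at_horizon_kept(self):
        d = sv.SurvivalData(time=np.array([5.0]), event=np.array([1]))
        t = sv.truncate_followup(d, horizon=5.0)
        assert t.time[0] == 5.0 and t.event[0] == 1

    def test_within_horizon_unchanged(self):
        d = toy_data()
        t = sv.truncate_followup(d, horizon=10.0)
        np.testing.assert_array_equal(t.time, d.time)
        np.testing.assert_array_equal(t.event, d.event)


class TestEndpoints:
    def make_clinical(self):
        return pd.DataFrame({
            "sample_id": ["P1", "P2", "P3"],
            "followup_years": [4.0, 2.5, 5.0],
            "death": [1, 0, 0],
            "relapse": [0, 1, 0],
            "relapse_years": [np.nan, 1.0, np.nan],
        })

    def test_os_uses_death(self):
        ep = sv.make_endpoints(self.make_clinical())
        np.testing.assert_array_equal(ep["os"].event, [1, 0, 0])
        np.testing.assert_array_equal(ep["os"].time, [4.0, 2.5, 5.0])

    def test_dfs_uses_earliest_of_relapse_or_death(self):
        ep = sv.make_endpoints(self.make_clinical())
        # P2 relapsed at 1.0y: DFS event at 1.0; P1 died without relapse:
        # DFS event at follow-up time; P3 is event-free.
        np.testing.assert_array_equal(ep["dfs"].event, [1, 1, 0])
        np.testing.assert_array_equal(ep["dfs"].time, [4.0, 1.0, 5.0])

    def test_covariates_preserved(self):
        clinical = self.make_clinical()
        clinical["age"] = [61, 72, 55]
        ep = sv.make_endpoints(clinical)
        assert "age" in ep["os"].covariates.columns
        assert "death" not in ep["os"].covariates.columns


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        d = sv.SurvivalData(time=np.array([1.0, 2.0, 2.5, 3.0]),
                            event=np.array([1, 1, 0, 1]))
        km = sv.kaplan_meier(d.time, d.event)
        # t=1: 4 at risk, 1 event -> 3/4; t=2: 3 at risk -> 3/4 * 2/3 = 1/2;
        # t=3: 1 at risk -> 0
        assert km.survival_at(1.0) == pytest.approx(0.75)
        assert km.survival_at(2.0) == pytest.approx(0.5)
        assert km.survival_at(3.0) == pytest.approx(0.0)

    def test_classic_three_event_example(self):
        km = sv.kaplan_meier([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_event_before_censoring_at_tied_time(self):
        # tie at t=2: the censored subject is still at risk for the event
        km = sv.kaplan_meier([2.0, 2.0], [1, 0])
        assert km.survival_at(2.0) == pytest.approx(0.5)

    def test_matches_lifelines_random_data(self):
        rng = np.random.default_rng(5)
        time = rng.exponential(2.0, 80).round(2) + 0.01
        event = rng.integers(0, 2, 80)
        km = sv.kaplan_meier(time, event)
        kmf = KaplanMeierFitter().fit(time, event)
        for t, s in zip(km.event_times, km.survival):
            assert kmf.predict(t) == pytest.approx(s, abs=1e-10)

    def test_survival_before_first_event_is_one(self):
        d = toy_data()
        km = sv.kaplan_meier(d.time, d.event)
        assert km.survival_at(0.5) == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sv.kaplan_meier([], [])


class TestLogrank:
    def random_groups(self, seed, n=120, k=2):
        rng = np.random.default_rng(seed)
        time = rng.exponential(2.0, n).round(2) + 0.01
        event = rng.integers(0, 2, n)
        group = rng.integers(0, k, n)
        return time, event, group

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_two_group_matches_lifelines(self, seed):
        time, event, group = self.random_groups(seed)
        chi2, p = sv.logrank_test(time, event, group)
        ref = ll_logrank_test(time[group == 0], time[group == 1],
                              event[group == 0], event[group == 1])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-8)
        assert p == pytest.approx(ref.p_value, rel=1e-8)

    def test_three_group_matches_lifelines(self):
        time, event, group = self.random_groups(9, k=3)
        chi2, p = sv.logrank_test(time, event, group)
        ref = multivariate_logrank_test(time, group, event)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-8)
        assert p == pytest.approx(ref.p_value, rel=1e-8)

    def test_identical_groups_give_zero_statistic(self):
        time = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        event = np.array([1, 1, 0, 1, 1, 0])
        group = np.array([0, 0, 0, 1, 1, 1])
        chi2, p = sv.logrank_test(time, event, group)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_single_group_rejected(self):
        d = toy_data()
        with pytest.raises(ValueError, match="two groups"):
            sv.logrank_test(d.time, d.event, np.zeros(6, dtype=int))

    def test_statistic_invariant_to_label_names(self):
        time, event, group = self.random_groups(7)
        named = np.where(group == 0, "low", "high")
        chi2_int, _ = sv.logrank_test(time, event, group)
        chi2_str, _ = sv.logrank_test(time, event, named)
        assert chi2_int == pytest.approx(chi2_str, rel=1e-12)


class TestCoxFit:
    def random_cohort(self, seed=4, n=150, p=3, beta=None):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        beta = np.zeros(p) if beta is None else np.asarray(beta, float)
        lam = 0.3 * np.exp(X @ beta)
        time = rng.exponential(1 / lam)
        cens = rng.exponential(4.0, n)
        obs = np.minimum(time, cens)
        event = (time <= cens).astype(int)
        return X, sv.SurvivalData(time=obs, event=event)

    def test_matches_lifelines_coefficients(self):
        X, d = self.random_cohort(beta=[0.5, -0.3, 0.0])
        fit = sv.cox_fit(d, covariate_names=["a", "b", "c"], X=X)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["T"], df["E"] = d.time, d.event
        cph = CoxPHFitter().fit(df, duration_col="T", event_col="E")
        np.testing.assert_allclose(fit.coef, cph.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.to_numpy(),
                                   atol=1e-5)

    def test_efron_ties_match_lifelines(self):
        X, d = self.random_cohort(seed=6, beta=[0.4, 0.0, -0.4])
        d = sv.SurvivalData(time=np.ceil(d.time * 2) / 2, event=d.event)
        fit = sv.cox_fit(d, X=X, ties="efron")
        df = pd.DataFrame(X, columns=["x0", "x1", "x2"])
        df["T"], df["E"] = d.time, d.event
        cph = CoxPHFitter().fit(df, duration_col="T", event_col="E")
        # lifelines stops on a looser tolerance, hence atol 1e-4; our own
        # gradient at the solution is the sharper optimality check
        np.testing.assert_allclose(fit.coef, cph.params_.to_numpy(), atol=1e-4)
        grad = sv.cox_gradient(fit.coef, X, d.time, d.event, ties="efron")
        assert np.max(np.abs(grad)) < 1e-6

    def test_gradient_zero_at_optimum(self):
        X, d = self.random_cohort(p=1, beta=[0.5])
        fit = sv.cox_fit(d, X=X)
        grad = sv.cox_gradient(fit.coef, X, d.time, d.event)
        assert np.max(np.abs(grad)) < 1e-6

    def test_hazard_ratio_and_ci(self):
        X, d = self.random_cohort(p=1, beta=[0.6])
        fit = sv.cox_fit(d, X=X)
        hr = fit.hazard_ratio[0]
        assert hr == pytest.approx(np.exp(fit.coef[0]))
        assert fit.ci_lower[0] == pytest.approx(
            np.exp(fit.coef[0] - 1.959963984540054 * fit.se[0]))
        assert fit.ci_upper[0] == pytest.approx(
            np.exp(fit.coef[0] + 1.959963984540054 * fit.se[0]))
        assert fit.ci_lower[0] < hr < fit.ci_upper[0]

    def test_loglik_improves_on_null(self):
        X, d = self.random_cohort(p=1, beta=[0.8])
        fit = sv.cox_fit(d, X=X)
        assert fit.loglik > fit.loglik_null

    def test_collinear_design_rejected(self):
        X, d = self.random_cohort(p=2)
        X = np.column_stack([X[:, 0], 2 * X[:, 0]])
        with pytest.raises(ValueError, match="collinear"):
            sv.cox_fit(d, X=X)

    def test_separation_warns(self):
        # binary covariate that perfectly splits early from late deaths:
        # the likelihood is monotone and the coefficient diverges
        time = np.arange(1.0, 21.0)
        event = np.ones(20, dtype=int)
        X = (time > 10).astype(float).reshape(-1, 1)
        with pytest.warns(RuntimeWarning, match="separation"):
            sv.cox_fit(sv.SurvivalData(time=time, event=event), X=X)

    def test_too_few_events_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        d = sv.SurvivalData(time=np.arange(1.0, 11.0),
                            event=np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0]))
        with pytest.raises(ValueError, match="events"):
            sv.cox_fit(d, X=X)

    def test_summary_and_json_round_trip(self):
        import json

        X, d = self.random_cohort(p=2, beta=[0.3, -0.3])
        fit = sv.cox_fit(d, covariate_names=["nag_high", "age"], X=X)
        summ = fit.summary()
        assert list(summ.index) == ["nag_high", "age"]
        payload = json.loads(fit.to_json())
        assert payload["covariates"]["nag_high"]["hr"] == pytest.approx(
            fit.hazard_ratio[0])


class TestScoreTest:
    def test_score_test_equals_logrank_two_groups(self):
        # the identity requires untied event times: with ties the log-rank
        # hypergeometric variance carries an (n-d)/(n-1) factor the Breslow
        # information does not
        rng = np.random.default_rng(21)
        time = rng.exponential(2.0, 100) + 0.01
        event = rng.integers(0, 2, 100)
        group = rng.integers(0, 2, 100)
        chi2_score = sv.cox_score_test(group.astype(float), time, event)
        chi2_lr, _ = sv.logrank_test(time, event, group)
        assert chi2_score == pytest.approx(chi2_lr, rel=1e-10)

    def test_untied_continuous_covariate_runs(self):
        rng = np.random.default_rng(2)
        time = rng.exponential(2.0, 60)
        event = np.ones(60, dtype=int)
        x = rng.normal(size=60)
        chi2 = sv.cox_score_test(x, time, event)
        assert chi2 >= 0


class TestLoglik:
    def test_breslow_loglik_hand_example(self):
        # two subjects, both events, times 1 < 2, eta = (a, b):
        # ll = a - log(e^a + e^b) + b - log(e^b)
        X = np.array([[1.0], [0.0]])
        time = np.array([1.0, 2.0])
        event = np.array([1, 1])
        beta = np.array([0.7])
        a, b = 0.7, 0.0
        expected = a - np.log(np.exp(a) + np.exp(b)) + b - np.log(np.exp(b))
        assert sv.cox_loglik(beta, X, time, event) == pytest.approx(expected)

    def test_breslow_tied_pair_hand_example(self):
        # both events at the same time: ll = a + b - 2*log(e^a + e^b)
        X = np.array([[1.0], [0.0]])
        time = np.array([1.0, 1.0])
        event = np.array([1, 1])
        beta = np.array([0.7])
        a, b = 0.7, 0.0
        expected = a + b - 2 * np.log(np.exp(a) + np.exp(b))
        assert sv.cox_loglik(beta, X, time, event) == pytest.approx(expected)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 3))
        time = rng.exponential(2.0, 40)
        event = rng.integers(0, 2, 40)
        event[0] = 1
        beta = np.array([0.2, -0.4, 0.1])
        grad = sv.cox_gradient(beta, X, time, event)
        eps = 1e-6
        for j in range(3):
            step = np.zeros(3)
            step[j] = eps
            fd = (sv.cox_loglik(beta + step, X, time, event)
                  - sv.cox_loglik(beta - step, X, time, event)) / (2 * eps)
            assert grad[j] == pytest.approx(fd, abs=1e-5)


class TestKmReport:
    def test_long_format_per_group(self):
        rng = np.random.default_rng(3)
        time = rng.exponential(2.0, 60) + 0.05
        event = rng.integers(0, 2, 60)
        group = np.array(["low"] * 30 + ["high"] * 30)
        rep = sv.km_report(time, event, group)
        assert set(rep["group"]) == {"low", "high"}
        assert list(rep.columns) == ["group", "time", "survival",
                                     "at_risk", "events"]
        # survival is nonincreasing within each group
        for g in ("low", "high"):
            s = rep.loc[rep["group"] == g, "survival"].to_numpy()
            assert (np.diff(s) <= 1e-12).all()
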