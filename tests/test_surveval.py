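"""Survival evaluation machinery against hand computations and brute force."""

import numpy as np
import pandas as pd
import pytest

import evosig as es
from evosig.surveval import _km_at
from oracles import (
    brute_harrell,
    brute_ipcw_auc,
    brute_logrank_two_group,
    censored_sample as _censored_sample,
)


# --- tests -------------------------------------------------------------------


class TestKaplanMeier:
    def test_no_events_curve_stays_at_one(self):
        curves = es.km_curve([1.0, 2.0, 3.0], [0, 0, 0])
        assert (curves["all"]["table"]["survival"] == 1.0).all()

    def test_hand_product_limit(self):
        curves = es.km_curve([1.0, 2.0, 3.0], [1, 1, 1])
        surv = curves["all"]["table"]["survival"]
        np.testing.assert_allclose(surv.loc[[1.0, 2.0, 3.0]], [2 / 3, 1 / 3, 0.0])

    def test_censoring_decrements_risk_set_without_step(self):
        curves = es.km_curve([1.0, 2.0, 3.0], [1, 0, 1])
        tab = curves["all"]["table"]
        assert tab.loc[2.0, "survival"] == tab.loc[1.0, "survival"]
        # after losing the censored subject the last event drops the curve to 0
        assert tab.loc[3.0, "survival"] == pytest.approx(0.0)

    def test_nonpositive_times_refused(self):
        with pytest.raises(ValueError):
            es.km_curve([0.0, 1.0], [1, 1])


class TestLogrank:
    def test_identical_groups_score_zero(self):
        t = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        e = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        stat, p = es.logrank(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_matches_hypergeometric_accumulation(self):
        rng = np.random.default_rng(61)
        t = rng.exponential(1, 24).round(2) + 0.01
        e = rng.integers(0, 2, 24)
        e[0] = 1
        g = rng.integers(0, 2, 24)
        stat, _ = es.logrank(t, e, g)
        assert stat == pytest.approx(brute_logrank_two_group(t, e, g), rel=1e-6)

    def test_single_group_refused(self):
        with pytest.raises(ValueError):
            es.logrank([1.0, 2.0], [1, 1], [0, 0])


class TestHarrellC:
    def test_perfect_anti_ordering(self):
        t = np.array([5.0, 4, 3, 2, 1])
        s = np.array([1.0, 2, 3, 4, 5])
        assert es.harrell_c(s, t, np.ones(5, int)) == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(63)
        t = rng.exponential(1, 3000)
        s = rng.normal(size=3000)
        assert es.harrell_c(s, t, np.ones(3000, int)) == pytest.approx(0.5, abs=0.03)

    def test_equals_brute_force_with_censoring(self):
        s, t, e = _censored_sample(30, seed=65, effect=0.5)
        assert es.harrell_c(s, t, e) == pytest.approx(brute_harrell(s, t, e), abs=1e-12)

    def test_complement_identity(self):
        s, t, e = _censored_sample(40, seed=67)
        # no tied scores in a continuous sample: C(s) + C(-s) = 1
        assert es.harrell_c(s, t, e) + es.harrell_c(-s, t, e) == pytest.approx(1.0)

    def test_matches_independent_library_implementation(self):
        from sksurv.metrics import concordance_index_censored

        s, t, e = _censored_sample(200, seed=69, effect=0.8)
        ref = concordance_index_censored(e.astype(bool), t, s)[0]
        assert es.harrell_c(s, t, e) == pytest.approx(ref, abs=1e-12)


class TestTimeDependentAUC:
    def test_no_censoring_reduces_to_empirical_auc(self):
        rng = np.random.default_rng(71)
        t = rng.exponential(1, 300)
        s = -t + rng.normal(0, 0.5, 300)
        horizon = float(np.median(t))
        got = es.time_dependent_auc(s, t, np.ones(300, int), horizon)
        cases, controls = s[t <= horizon], s[t > horizon]
        brute = np.mean(
            [
                (ci > cj) + 0.5 * (ci == cj)
                for ci in cases
                for cj in controls
            ]
        )
        assert got == pytest.approx(brute, abs=1e-12)

    def test_equals_brute_force_ipcw(self):
        s, t, e = _censored_sample(50, seed=73, effect=0.7)
        horizon = float(np.quantile(t, 0.6))
        got = es.time_dependent_auc(s, t, e, horizon)
        assert got == pytest.approx(brute_ipcw_auc(s, t, e, horizon), abs=1e-10)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(75)
        t = rng.exponential(1, 4000)
        e = (rng.uniform(size=4000) < 0.8).astype(int)
        s = rng.normal(size=4000)
        got = es.time_dependent_auc(s, t, e, float(np.median(t)))
        assert got == pytest.approx(0.5, abs=0.03)

    def test_invariant_to_monotone_transform(self):
        s, t, e = _censored_sample(120, seed=77, effect=0.6)
        horizon = float(np.quantile(t, 0.5))
        a = es.time_dependent_auc(s, t, e, horizon)
        b = es.time_dependent_auc(np.exp(2 * s), t, e, horizon)
        assert a == pytest.approx(b, abs=1e-12)

    def test_empty_case_or_control_sets_refused(self):
        with pytest.raises(ValueError):
            es.time_dependent_auc([1.0, 2.0], [5.0, 6.0], [1, 1], 1.0)
        with pytest.raises(ValueError):
            es.time_dependent_auc([1.0, 2.0], [0.5, 0.6], [1, 1], 1.0)


class TestPooling:
    def test_replicated_study_shrinks_se_only(self):
        res = es.pool_hazard_ratios([0.7] * 4, [0.2] * 4)
        assert res.log_hr == pytest.approx(0.7)
        assert res.se == pytest.approx(0.2 / 2)

    def test_hand_inverse_variance_average(self):
        res = es.pool_hazard_ratios([0.0, 1.0], [1.0, 1.0])
        assert res.log_hr == pytest.approx(0.5)

    def test_huge_variance_study_has_no_weight(self):
        base = es.pool_hazard_ratios([0.3, 0.9], [0.1, 0.2])
        padded = es.pool_hazard_ratios([0.3, 0.9, 5.0], [0.1, 0.2, 1e6])
        assert padded.log_hr == pytest.approx(base.log_hr, abs=1e-6)

    def test_nonpositive_se_refused(self):
        with pytest.raises(ValueError):
            es.pool_hazard_ratios([0.1, 0.2], [0.5, 0.0])


class TestPrediction:
    def test_null_model_equals_kaplan_meier(self):
        rng = np.random.default_rng(81)
        n = 400
        df = pd.DataFrame(
            {
                "time": rng.exponential(2, n),
                "event": (rng.uniform(size=n) < 0.7).astype(int),
            }
        )
        fit = es.cox_fit(df, [])
        t0 = float(np.median(df["time"]))
        got = es.predict_survival_prob(fit, None, t0)[0]
        assert got == pytest.approx(
            _km_at(df["time"].to_numpy(), df["event"].to_numpy(), t0), abs=1e-12
        )

    def test_matches_exponential_closed_form(self):
        rng = np.random.default_rng(83)
        n = 4000
        x = rng.integers(0, 2, n).astype(float)
        beta, h0 = np.log(2.0), 0.2
        t = rng.exponential(1 / (h0 * np.exp(beta * x)))
        df = pd.DataFrame({"time": t, "event": 1, "x": x})
        fit = es.cox_fit(df, ["x"])
        for horizon in (1.0, 3.0):
            for xv in (0.0, 1.0):
                pred = es.predict_survival_prob(
                    fit, pd.DataFrame({"x": [xv]}), horizon
                )[0]
                closed = np.exp(-h0 * horizon * np.exp(beta * xv))
                assert pred == pytest.approx(closed, abs=0.03)

    def test_extrapolation_flagged(self):
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 1, 1]})
        fit = es.cox_fit(df, [])
        with pytest.warns(UserWarning, match="follow-up"):
            es.predict_survival_prob(fit, None, 10.0)


class TestCalibration:
    def test_well_specified_model_is_calibrated(self):
        rng = np.random.default_rng(85)
        n = 1000
        x = rng.normal(size=n)
        t_event = rng.exponential(1 / (0.2 * np.exp(0.8 * x)))
        c = rng.uniform(0, 15, n)
        df = pd.DataFrame(
            {
                "time": np.minimum(t_event, c),
                "event": (t_event <= c).astype(int),
                "x": x,
            }
        )
        fit = es.cox_fit(df, ["x"])
        cal = es.calibration_curve(fit, horizon=3.0, n_boot=60, n_bins=3, seed=85)
        err = (cal["observed"] - cal["predicted"]).abs().mean()
        assert err < 0.05
        assert (cal["band_lower"] <= cal["band_upper"]).all()

    def test_constant_prediction_collapses_to_overall_km(self):
        rng = np.random.default_rng(87)
        n = 300
        df = pd.DataFrame(
            {
                "time": rng.exponential(2, n),
                "event": (rng.uniform(size=n) < 0.8).astype(int),
            }
        )
        fit = es.cox_fit(df, [])
        with pytest.warns(UserWarning, match="bin"):
            cal = es.calibration_curve(fit, horizon=1.0, n_boot=5, n_bins=3, seed=1)
        assert len(cal) == 1
        assert cal["observed"].iloc[0] == pytest.approx(
            _km_at(df["time"].to_numpy(), df["event"].to_numpy(), 1.0)
        )


class TestCoxScreen:
    def test_screen_recovers_planted_and_flags_at_alpha(self, small_cohort, small_truth):
        screen = es.cox_screen(small_cohort, genes=list(small_cohort.genes[:20]))
        planted = [g for g in small_truth.signature_genes() if g in screen.index]
        assert screen.loc[planted, "significant"].all()
        assert ((screen["p"] < 0.05) == screen["significant"]).all()

    def test_full_loop_high_risk_group_has_elevated_hazard(
        self, small_cohort, small_truth
    ):
        model = es.fit_cox_signature(small_cohort, small_truth.signature_genes())
        scores = es.score_samples(model, small_cohort.expr)
        groups = es.dichotomize(scores)
        df = pd.DataFrame(
            {
                "time": small_cohort.time,
                "event": small_cohort.event,
                "high": (groups["group"] == "high").astype(float).to_numpy(),
            }
        )
        fit = es.cox_fit(df, ["high"])
        assert fit.summary.loc["high", "hr"] > 1.0
        c = es.harrell_c(scores.to_numpy(), small_cohort.time, small_cohort.event)
        assert c > 0.5
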