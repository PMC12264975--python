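import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from ttescreen._glm import SeparationError, fit_weighted_logit
from ttescreen.estimation import (
    PooledLogisticRisk,
    StabilizedIPTW,
    compute_smd,
    effect_measures,
    estimate_stabilized_weights,
    expand_person_months,
    fit_pooled_logistic,
    iptw_km,
    predict_risk_curve,
)
from ttescreen.trials import TrialCohort, TrialSpec

from conftest import build_snapshot, person


def _ppt(rows):
    """rows: (person_id, pidx, t, arm, event[, sw])"""
    cols = ["person_id", "pidx", "t", "arm", "event", "sw"][: len(rows[0])]
    return pd.DataFrame(rows, columns=cols)


def _sim_ppt(rng, n, T, beta, arm_frac=0.5):
    """Simulate person-period rows from a quadratic-logit hazard."""
    recs = []
    for i in range(n):
        a = int(rng.random() < arm_frac)
        for t in range(1, T + 1):
            h = expit(beta[0] + beta[1] * t + beta[2] * t**2
                      + a * (beta[3] + beta[4] * t + beta[5] * t**2))
            ev = int(rng.random() < h)
            recs.append((f"P{i}", i, t, a, ev))
            if ev:
                break
    return _ppt(recs)


class TestStabilizedWeights:
    def test_two_stratum_closed_form(self):
        """Exact stratum counts make the MLE propensity equal the stratum
        frequency, so the stabilized weights match the hand-computed ratio."""
        x = np.repeat([0, 1], 100)
        arm = np.concatenate([np.repeat([1, 0], [30, 70]), np.repeat([1, 0], [70, 30])])
        cov = pd.DataFrame({"x": x.astype(float), "arm": arm})
        sw = StabilizedIPTW().fit_transform(cov, arm)
        p1 = 0.5
        expected = {
            (0, 1): p1 / 0.3, (0, 0): (1 - p1) / 0.7,
            (1, 1): p1 / 0.7, (1, 0): (1 - p1) / 0.3,
        }
        for (xi, ai), want in expected.items():
            got = sw[(x == xi) & (arm == ai)]
            assert np.allclose(got, want, atol=1e-4)

    def test_randomized_assignment_gives_unit_weights(self):
        rng = np.random.default_rng(0)
        n = 5000
        cov = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
        arm = (rng.random(n) < 0.4).astype(int)
        sw = StabilizedIPTW().fit_transform(cov, arm)
        assert np.mean(np.abs(sw - 1)) < 0.05

    def test_mean_weight_near_one_within_arms(self):
        rng = np.random.default_rng(1)
        n = 2000
        x = rng.normal(size=n)
        arm = (rng.random(n) < expit(0.8 * x)).astype(int)
        cov = pd.DataFrame({"x": x})
        sw = StabilizedIPTW().fit_transform(cov, arm)
        assert abs(sw[arm == 1].mean() - 1) < 0.05
        assert abs(sw[arm == 0].mean() - 1) < 0.05

    def test_perfect_predictor_raises_separation(self):
        arm = np.repeat([0, 1], 50)
        cov = pd.DataFrame({"x": arm.astype(float), "noise": np.zeros(100)})
        with pytest.raises(SeparationError, match="x"):
            StabilizedIPTW().fit(cov, arm)

    def test_single_arm_rejected(self):
        cov = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(ValueError, match="arms"):
            StabilizedIPTW().fit(cov, np.array([1, 1]))

    def test_agrees_with_statsmodels_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        n = 800
        X = rng.normal(size=(n, 3))
        y = (rng.random(n) < expit(X @ [0.5, -0.3, 0.2])).astype(float)
        w = rng.integers(1, 4, size=n).astype(float)
        ours = fit_weighted_logit(np.column_stack([np.ones(n), X]), y, sample_weight=w)
        ref = sm.GLM(y, np.column_stack([np.ones(n), X]),
                     family=sm.families.Binomial(), freq_weights=w).fit()
        assert np.allclose(ours.coef, ref.params, atol=1e-6)


class TestSMD:
    def test_identical_distributions_give_zero(self):
        cov = pd.DataFrame({"x": [1.0, 2.0, 1.0, 2.0], "arm": [1, 1, 0, 0]})
        smd, frac = compute_smd(cov)
        assert smd["x"] == 0.0
        assert frac == 1.0

    def test_binary_prevalence_closed_form(self):
        # prevalences 0.5 vs 0.3: SMD = 0.2 / sqrt((0.25 + 0.21)/2)
        x = np.concatenate([np.repeat([1.0, 0.0], [50, 50]), np.repeat([1.0, 0.0], [30, 70])])
        arm = np.repeat([1, 0], 100)
        smd, _ = compute_smd(pd.DataFrame({"x": x, "arm": arm}))
        assert smd["x"] == pytest.approx(0.2 / np.sqrt(0.23), abs=1e-6)

    def test_zero_variance_nonzero_diff_is_infinite(self):
        cov = pd.DataFrame({"x": [1.0, 1.0, 0.0, 0.0], "arm": [1, 1, 0, 0]})
        smd, frac = compute_smd(cov)
        assert np.isinf(smd["x"])

    def test_balanced_fraction_counts_threshold(self):
        cov = pd.DataFrame(
            {"good": [1.0, 2.0, 1.0, 2.0], "bad": [1.0, 1.0, 0.0, 0.0],
             "arm": [1, 1, 0, 0]}
        )
        _, frac = compute_smd(cov)
        assert frac == 0.5

    def test_weighting_restores_balance(self):
        rng = np.random.default_rng(3)
        n = 4000
        x = (rng.random(n) < 0.4).astype(float)
        arm = (rng.random(n) < expit(-0.5 + 1.2 * x)).astype(int)
        cov = pd.DataFrame({"x": x, "arm": arm})
        raw, _ = compute_smd(cov)
        sw = StabilizedIPTW().fit_transform(cov, arm)
        adj, frac = compute_smd(cov, weights=sw)
        assert raw["x"] > 0.1
        assert adj["x"] < 0.05
        assert frac == 1.0


class TestExpansion:
    def _snapshot(self, death=None, emig=None):
        rows = [("P1", "A02BA02", "2010-01-01", None)]
        p = person("P1", death_year=death[0] if death else None,
                   death_month=death[1] if death else None, emigration=emig)
        return build_snapshot([p], rows, coverage=("2004-01-01", "2020-02-01"))

    def _trial(self, snap):
        init = pd.DataFrame(
            {"person_id": ["P1"], "drug_atc": ["A02BA02"],
             "baseline_date": [pd.Timestamp("2010-01-01")], "arm": ["target"]}
        )
        return TrialCohort(TrialSpec("A02BA02"), init, pd.DataFrame(), True)

    def test_death_in_month_five(self):
        snap = self._snapshot(death=(2010, 5))
        ppt = expand_person_months(self._trial(snap), snap, 96)
        assert list(ppt["t"]) == [1, 2, 3, 4, 5]
        assert list(ppt["event"]) == [0, 0, 0, 0, 1]

    def test_emigration_censors_without_event(self):
        snap = self._snapshot(emig="2010-04-10")
        ppt = expand_person_months(self._trial(snap), snap, 96)
        assert list(ppt["t"]) == [1, 2, 3]
        assert ppt["event"].sum() == 0

    def test_survivor_truncated_at_horizon(self):
        snap = self._snapshot()
        ppt = expand_person_months(self._trial(snap), snap, 96)
        assert len(ppt) == 96
        assert ppt["event"].sum() == 0

    def test_death_before_baseline_is_a_data_error(self):
        snap = self._snapshot(death=(2009, 6))
        with pytest.raises(ValueError, match="death before baseline"):
            expand_person_months(self._trial(snap), snap, 96)

    def test_lag_censors_early_deaths(self):
        snap = self._snapshot(death=(2010, 5))
        ppt = expand_person_months(self._trial(snap), snap, 96, lag_months=12)
        assert len(ppt) == 0  # death in month 5 <= lag: censored at the lag
        late = self._snapshot(death=(2011, 6))
        ppt2 = expand_person_months(self._trial(late), late, 96, lag_months=12)
        assert ppt2["t"].min() == 13
        assert ppt2["event"].sum() == 1


class TestPooledLogistic:
    def test_constant_hazard_recovery(self):
        rng = np.random.default_rng(4)
        b0 = logit(0.02)
        ppt = _sim_ppt(rng, 3000, 24, [b0, 0, 0, 0, 0, 0])
        fit = fit_pooled_logistic(ppt)
        # the quadratic terms are collinear with the intercept, so assert on
        # the identified quantity: the fitted hazard curve itself
        h = fit.predict_hazard(0, 24)
        assert np.all(np.abs(h - 0.02) < 0.005)
        assert abs(fit.coef_[1]) < 0.05
        assert abs(fit.coef_[2]) < 2e-3

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(5)
        ppt = _sim_ppt(rng, 500, 12, [logit(0.03), 0.01, 0, 0.2, 0, 0])
        w = np.ones(len(ppt))
        a = fit_pooled_logistic(ppt, sample_weight=w)
        b = fit_pooled_logistic(ppt, sample_weight=2 * w)
        assert np.allclose(a.coef_, b.coef_, atol=1e-7)

    def test_constant_arm_drops_interaction_terms(self):
        rng = np.random.default_rng(6)
        ppt = _sim_ppt(rng, 400, 12, [logit(0.05), 0, 0, 0, 0, 0], arm_frac=0.0)
        fit = fit_pooled_logistic(ppt)
        assert fit.arm_dropped_
        assert np.all(fit.coef_[3:] == 0)

    def test_no_events_rejected(self):
        ppt = _ppt([("P1", 0, 1, 1, 0), ("P2", 1, 1, 0, 0)])
        with pytest.raises(ValueError, match="no events"):
            fit_pooled_logistic(ppt)

    def test_risk_curve_constant_hazard_closed_form(self):
        curve = predict_risk_curve([logit(0.01), 0, 0, 0, 0, 0], arm=0, horizon=96)
        assert curve[-1] == pytest.approx(1 - 0.99**96, abs=1e-12)
        assert np.all(np.diff(curve) > 0)

    def test_zero_hazard_gives_zero_risk(self):
        curve = predict_risk_curve([-1e9, 0, 0, 0, 0, 0], arm=1, horizon=48)
        assert np.all(curve == 0)

    def test_saturated_time_model_equals_weighted_km(self):
        """With one indicator per month, the pooled logistic MLE hazards are
        the weighted event/at-risk ratios, so cumulative risk equals the
        weighted Kaplan-Meier risk exactly (<=50-person fixture)."""
        rng = np.random.default_rng(7)
        recs = []
        for i in range(50):
            sw = rng.choice([0.5, 1.0, 2.0])
            arm = i % 2
            for t in range(1, 7):
                ev = int(rng.random() < 0.15)
                recs.append((f"P{i}", i, t, arm, ev, sw))
                if ev:
                    break
        ppt = _ppt(recs)
        km = iptw_km(ppt)
        for arm, col in ((1, "survival_target"), (0, "survival_control")):
            sub = ppt[ppt["arm"] == arm]
            T = 6
            # saturated fit: one-hot month design, weighted logistic MLE
            X = np.zeros((len(sub), T))
            X[np.arange(len(sub)), sub["t"].to_numpy() - 1] = 1.0
            fit = fit_weighted_logit(X, sub["event"].to_numpy(dtype=float),
                                     sample_weight=sub["sw"].to_numpy())
            h = expit(fit.coef)
            risk = 1 - np.cumprod(1 - h)
            assert np.allclose(risk, 1 - km[col].to_numpy()[:T], atol=1e-7)


class TestEffectMeasures:
    @pytest.mark.parametrize(
        "target, control, rr2dp",
        [(62.7, 70.5, 0.89), (51.6, 63.5, 0.81), (41.3, 59.0, 0.70)],
    )
    def test_risk_ratio_two_decimals(self, target, control, rr2dp):
        assert round(effect_measures(target, control)["rr"], 2) == rr2dp

    def test_equal_risks(self):
        out = effect_measures(50.0, 50.0)
        assert out["rd"] == 0 and out["rr"] == 1 and out["nnt"] is None

    def test_zero_control_risk_rejected(self):
        with pytest.raises(ValueError):
            effect_measures(10.0, 0.0)

    def test_nnt_rounds_half_up(self):
        assert effect_measures(50.0, 58.0)["nnt"] == 13  # 100/8 = 12.5


class TestIptwKm:
    def test_unit_weights_match_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(8)
        recs = []
        durations, events = [], []
        for i in range(10):
            dur = int(rng.integers(1, 8))
            ev = int(rng.random() < 0.7)
            durations.append(dur)
            events.append(ev)
            for t in range(1, dur + 1):
                recs.append((f"P{i}", i, t, 0, int(ev and t == dur)))
        ppt = _ppt(recs)
        km = iptw_km(ppt)
        ref = KaplanMeierFitter().fit(durations, events)
        for t in km.index:
            assert km["survival_control"].loc[t] == pytest.approx(
                ref.predict(t), abs=1e-9
            )

    def test_no_events_survival_stays_one(self):
        ppt = _ppt([("P1", 0, 1, 1, 0), ("P1", 0, 2, 1, 0), ("P2", 1, 1, 0, 0)])
        km = iptw_km(ppt)
        assert (km == 1.0).all().all()

    def test_all_die_first_month(self):
        ppt = _ppt([("P1", 0, 1, 1, 1), ("P2", 1, 1, 1, 1)])
        km = iptw_km(ppt)
        assert km["survival_target"].loc[1] == 0.0

    def test_pooled_logistic_tracks_km_on_correctly_specified_data(self):
        """Sup-norm agreement within 0.02 between the model risk curve and
        the nonparametric weighted KM risk, n = 5000, quadratic-logit truth."""
        rng = np.random.default_rng(9)
        beta = [logit(0.02), 0.02, -1e-4, -0.3, 0.005, 0]
        ppt = _sim_ppt(rng, 5000, 36, beta)
        fit = fit_pooled_logistic(ppt)
        km = iptw_km(ppt)
        for arm, col in ((1, "survival_target"), (0, "survival_control")):
            model = fit.predict_risk_curve(arm, 36)
            assert np.max(np.abs((1 - model) - km[col].to_numpy())) < 0.02
        assert np.all(np.diff(fit.predict_risk_curve(1, 96)) >= 0)


def test_estimate_stabilized_weights_reports_balance(null_trial_registry):
    from ttescreen.covariates import assemble_covariates
    from ttescreen.trials import build_trial_cohort

    snapshot, _, cases = null_trial_registry
    trial = build_trial_cohort(
        snapshot, cases, TrialSpec("A02BA02", min_target_persons=2, seed=1)
    )
    cov = assemble_covariates(trial, snapshot)
    wc = estimate_stabilized_weights(cov)
    assert (wc.sw > 0).all()
    assert wc.smd_after.median() <= wc.smd_before.median()
    assert 0 <= wc.balanced_fraction <= 1
    # stabilized: mean weight near one within each arm
    arm = cov["arm"].to_numpy()
    assert abs(wc.sw[arm == 1].mean() - 1) < 0.1
    assert abs(wc.sw[arm == 0].mean() - 1) < 0.1
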