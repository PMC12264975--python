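import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ttescreen.cohort import classify_pd_cases
from ttescreen.covariates import assemble_covariates
from ttescreen.estimation import expand_person_months
from ttescreen.screen import (
    bootstrap_trial,
    by_adjust,
    run_screen,
    run_sensitivity,
)
from ttescreen.trials import TrialSpec, build_trial_cohort


def _by_brute_force(p):
    """Direct step-up definition: q_(i) = min_{j>=i} m c(m) p_(j)/j, capped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    c = sum(1.0 / k for k in range(1, m + 1))
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        q[idx] = min(
            min(m * c * p[order[j - 1]] / j for j in range(rank_i, m + 1)), 1.0
        )
    return q


class TestByAdjust:
    def test_single_test_unchanged(self):
        assert by_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_computed_example(self):
        got = by_adjust([0.01, 0.02, 0.04])
        assert got == pytest.approx([0.055, 0.055, 0.0733333], abs=1e-6)

    def test_adjusted_at_least_raw_and_monotone_in_rank(self):
        rng = np.random.default_rng(0)
        p = rng.random(20)
        q = by_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            by_adjust([0.1, 1.2])
        with pytest.raises(ValueError):
            by_adjust([-0.01])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            m = int(rng.integers(1, 51))
            p = np.round(rng.random(m), 4)
            assert np.allclose(by_adjust(p), _by_brute_force(p), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.random(int(rng.integers(2, 30)))
            ref = multipletests(p, method="fdr_by")[1]
            assert np.allclose(by_adjust(p), ref, atol=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_property_agreement_with_definition(self, p):
        assert np.allclose(by_adjust(p), _by_brute_force(p), atol=1e-12)


def _degenerate_cohort(n_target=10, n_control=10):
    """All target persons identical, all control persons identical.

    Every person-month cell rate is then 0 or 1, which saturates the
    logistic hazard: the likelihood has no finite maximum and every
    replicate fails with a separation error."""
    n = n_target + n_control
    cov = pd.DataFrame(
        {
            "person_id": [f"P{i}" for i in range(n)],
            "arm": [1] * n_target + [0] * n_control,
            "x": [0.0] * n,
        }
    )
    rows = []
    for i in range(n):
        arm = int(i < n_target)
        death = 3 if arm else 5
        for t in range(1, death + 1):
            rows.append((f"P{i}", i, t, arm, int(t == death)))
    ppt = pd.DataFrame(rows, columns=["person_id", "pidx", "t", "arm", "event"])
    ppt.attrs["horizon_months"] = 12
    return cov, ppt


def _small_mixed_cohort(near_separating=False, n_per_arm=15):
    """Small cohort with varied death/censoring months (stable fits).

    With ``near_separating`` a binary covariate equals 1 for every target
    person but only one control person, so replicates that drop that one
    control hit quasi-complete separation in the propensity model."""
    rng = np.random.default_rng(12)
    recs, covrows = [], []
    n = 2 * n_per_arm
    for i in range(n):
        arm = int(i < n_per_arm)
        death = int(rng.integers(2, 12)) if rng.random() < 0.7 else None
        end = death if death is not None else 12
        for t in range(1, end + 1):
            recs.append((f"P{i}", i, t, arm, int(death is not None and t == death)))
        x = 1.0 if (arm or (near_separating and i == n_per_arm)) else 0.0
        covrows.append((f"P{i}", arm, x if near_separating else rng.normal()))
    cov = pd.DataFrame(covrows, columns=["person_id", "arm", "x"])
    ppt = pd.DataFrame(recs, columns=["person_id", "pidx", "t", "arm", "event"])
    ppt.attrs["horizon_months"] = 12
    return cov, ppt


class TestBootstrap:
    def test_seed_reproducibility(self, null_trial_registry):
        snapshot, _, cases = null_trial_registry
        trial = build_trial_cohort(
            snapshot, cases, TrialSpec("A02BA02", min_target_persons=2, seed=1)
        )
        cov = assemble_covariates(trial, snapshot)
        ppt = expand_person_months(trial, snapshot, 48)
        a = bootstrap_trial(cov, ppt, B=40, seed=9, horizon=48)
        b = bootstrap_trial(cov, ppt, B=40, seed=9, horizon=48)
        assert np.array_equal(a.rd_samples, b.rd_samples)
        assert a.ci_rd == b.ci_rd and a.p_rd == b.p_rd
        c = bootstrap_trial(cov, ppt, B=40, seed=10, horizon=48)
        assert not np.array_equal(a.rd_samples, c.rd_samples)

    def test_saturated_degenerate_cohort_fails_loudly(self):
        """Identical persons per arm give 0/1 cell rates; the logistic
        hazard has no finite MLE and the bootstrap reports the failure
        instead of returning fabricated intervals."""
        cov, ppt = _degenerate_cohort()
        with pytest.raises(RuntimeError):
            bootstrap_trial(cov, ppt, B=10, seed=0, horizon=12)

    def test_duplicating_every_person_leaves_estimates_unchanged(self):
        from ttescreen.screen import _TrialEngine

        cov, ppt = _small_mixed_cohort()
        eng = _TrialEngine(cov, ppt, 12)
        single = eng.estimate(np.ones(eng.n))
        double = eng.estimate(2 * np.ones(eng.n))
        assert single["rd"] == pytest.approx(double["rd"], abs=1e-8)
        assert single["rr"] == pytest.approx(double["rr"], abs=1e-8)

    def test_ci_endpoints_inside_replicate_range(self, null_trial_registry):
        snapshot, _, cases = null_trial_registry
        trial = build_trial_cohort(
            snapshot, cases, TrialSpec("A02BA02", min_target_persons=2, seed=1)
        )
        cov = assemble_covariates(trial, snapshot)
        ppt = expand_person_months(trial, snapshot, 48)
        boot = bootstrap_trial(cov, ppt, B=60, seed=3, horizon=48)
        assert boot.rd_samples.min() <= boot.ci_rd[0] <= boot.ci_rd[1] <= boot.rd_samples.max()
        # normal-approximation consistency: p < 0.05 iff |rd|/sd > 1.96
        sd = boot.rd_samples.std(ddof=1)
        assert (boot.p_rd < 0.05) == (abs(boot.rd) / sd > 1.959963984540054)

    def test_frequent_replicate_failures_flagged_unreliable(self):
        # dropping the single x=1 control separates the propensity model;
        # that control is absent from ~37% of resamples
        cov, ppt = _small_mixed_cohort(near_separating=True)
        boot = bootstrap_trial(cov, ppt, B=60, seed=0, horizon=12)
        assert boot.n_failed > 6
        assert boot.unreliable

    def test_b_below_two_rejected(self):
        cov, ppt = _small_mixed_cohort()
        with pytest.raises(ValueError):
            bootstrap_trial(cov, ppt, B=1)

    def test_percentile_p_method(self):
        cov, ppt = _small_mixed_cohort()
        boot = bootstrap_trial(cov, ppt, B=30, seed=0, horizon=12,
                               p_method="percentile")
        assert 2 / 30 <= boot.p_rd <= 1


class TestScreen:
    @pytest.fixture(scope="class")
    def screen_result(self, null_trial_registry):
        snapshot, _, cases = null_trial_registry
        res = run_screen(
            snapshot, cases, spec_defaults={"min_target_persons": 50},
            seed=5, B=30, horizon_months=48,
        )
        return res

    def test_hit_rule_never_violated(self, screen_result):
        hits = screen_result[screen_result["hit"].fillna(False)]
        assert (hits["rd"] > 0).all()
        assert (hits["p_rd"] < 0.05).all()
        assert (hits["balanced_fraction"] >= 0.9).all()

    def test_by_adjusted_at_least_raw(self, screen_result):
        ok = screen_result["status"] == "ok"
        assert (screen_result.loc[ok, "p_by"] >= screen_result.loc[ok, "p_rd"] - 1e-12).all()

    def test_enumeration_order_invariance(self, null_trial_registry, screen_result):
        snapshot, _, cases = null_trial_registry
        targets = list(screen_result["target_atc"])[::-1]
        again = run_screen(
            snapshot, cases, spec_defaults={"min_target_persons": 50},
            seed=5, B=30, horizon_months=48, targets=targets,
        )
        merged = screen_result.merge(again, on="target_atc", suffixes=("_a", "_b"))
        ok = (merged["status_a"] == "ok") & (merged["status_b"] == "ok")
        assert np.allclose(merged.loc[ok, "rd_a"], merged.loc[ok, "rd_b"])
        assert np.allclose(merged.loc[ok, "p_rd_a"], merged.loc[ok, "p_rd_b"])

    def test_empty_drug_list(self, null_trial_registry):
        snapshot, _, cases = null_trial_registry
        res = run_screen(snapshot, cases, seed=0, B=10, targets=[])
        assert len(res) == 0

    def test_trial_failures_recorded_not_raised(self, null_trial_registry):
        snapshot, _, cases = null_trial_registry
        res = run_screen(
            snapshot, cases, spec_defaults={"min_target_persons": 50},
            seed=5, B=10, horizon_months=48, targets=["C10AA05"],
        )
        assert res.loc[0, "status"] != "ok"  # no such initiations in this registry
        assert not res.loc[0, "hit"] if "hit" in res.columns else True


class TestSensitivity:
    def test_unknown_variant_rejected(self, null_trial_registry):
        snapshot, _, cases = null_trial_registry
        with pytest.raises(ValueError, match="variant"):
            run_sensitivity(snapshot, cases, "bogus")

    def test_atc2_comparator_restricts_control_prefix(self, null_trial_registry):
        snapshot, _, cases = null_trial_registry
        spec = TrialSpec("A02BA02", comparator_level=2, min_target_persons=2, seed=1)
        trial = build_trial_cohort(snapshot, cases, spec)
        controls = trial.initiations.query("arm == 'control'")
        assert controls["drug_atc"].str.startswith("A02").all()
        assert (controls["drug_atc"].str[:4] != "A02B").all()

    def test_lag_variant_with_only_early_deaths_surfaces_error(self, null_trial_registry):
        snapshot, _, cases = null_trial_registry
        res = run_sensitivity(
            snapshot, cases, "lag_12_months",
            spec_defaults={"min_target_persons": 50}, seed=5, B=20,
            horizon_months=48, targets=["A02BA02"],
        )
        # the lag removes first-year deaths; the trial still runs here
        assert res.loc[0, "status"] in {"ok", "failed: no events in the person-period table"}

    def test_rxrisk_filter_uses_strict_inequality(self):
        from ttescreen.screen import _row_mask

        cov = pd.DataFrame({"rxrisk_index": [2.0, 2.0, 2.0]})
        mask = _row_mask(cov, "rxrisk_below_median", 2.0)
        assert mask.sum() == 0  # all equal to the median: strict '<' removes all

    def test_age_filters(self):
        from ttescreen.screen import _row_mask

        cov = pd.DataFrame(
            {"age_at_initiation": [70.0, 80.0], "age_at_diagnosis": [60.0, 70.0]}
        )
        assert list(_row_mask(cov, "age_lt_75_at_initiation", None)) == [True, False]
        assert list(_row_mask(cov, "age_ge_65_at_diagnosis", None)) == [False, True]

    def test_adjust_unbalanced_variant_runs(self, null_trial_registry):
        snapshot, _, cases = null_trial_registry
        res = run_sensitivity(
            snapshot, cases, "adjust_unbalanced",
            spec_defaults={"min_target_persons": 50}, seed=5, B=20,
            horizon_months=48, targets=["A02BA02"],
        )
        assert res.loc[0, "status"] == "ok"

    def test_general_population_requires_targets(self, null_trial_registry):
        snapshot, _, cases = null_trial_registry
        with pytest.raises(ValueError, match="target list"):
            run_sensitivity(snapshot, cases, "general_population", seed=0)
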