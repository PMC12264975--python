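"""Calibration and recovery experiments on synthetic registries.

Three study conditions exercise the pipeline end to end:

* **Confounded null** — one target trial with strong confounding by
  indication but a null treatment effect.  The unadjusted risk difference
  is materially biased; the IPTW estimate is centred at zero and its 95%
  bootstrap confidence interval should cover zero at close to the nominal
  rate.
* **Known effect** — a protective monthly log-odds effect on the target
  drug, with an exact cohort-weighted oracle for the true marginal 8-year
  risk ratio.  The oracle replays the generator's probabilistic rules
  (covariates, initiation, survival to baseline) for a large simulated
  population and evaluates per-person risks in closed form, so it is
  independent of the weighting/pooled-logistic estimation path.  The
  target and control initiation windows are staggered (target months 1-12,
  control 13-36 after diagnosis) so that arm membership never conditions
  on the outcome process.
* **Screen recovery** — a 12-drug screen with two planted protective
  drugs; the hit list should recover both with few false positives.

Problem sizes here are deliberately desk-scale; the generator itself
scales to larger populations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import classify_pd_cases
from .covariates import assemble_covariates
from .estimation import expand_person_months, fit_pooled_logistic
from .screen import _TrialEngine, bootstrap_trial, run_screen
from .simulate import (
    HazardModel,
    InitiationModel,
    SyntheticConfig,
    _PD_DRUGS,
    generate_registry,
)
from .trials import TrialSpec, build_trial_cohort

__all__ = [
    "confounded_null_config",
    "known_effect_config",
    "screen_demo_config",
    "oracle_true_rr",
    "null_coverage_experiment",
    "effect_recovery_experiment",
    "screen_recovery_experiment",
]

_NULL_PREVALENCES = {8: 0.20, 15: 0.30, 19: 0.25, 40: 0.10, 42: 0.08, 43: 0.10, 45: 0.15}


def confounded_null_config(n_persons: int = 2500, seed: int = 0) -> SyntheticConfig:
    """Null treatment effect, strong confounding by indication.

    Heart failure (category 15) and diabetes (8) drive initiation of the
    target drug and raise the death hazard; the comparators are initiated
    nearly independently of comorbidity.
    """
    return SyntheticConfig(
        n_persons=n_persons,
        drug_catalogue=list(_PD_DRUGS)
        + [("A02BA02", "ranitidine"), ("A02AA04", "magnesium hydroxide"),
           ("A09AA02", "multienzymes")],
        comorbidity_prevalences=dict(_NULL_PREVALENCES),
        initiation_models={
            "A02BA02": InitiationModel(-1.0, {15: 1.5, 8: 0.8}, 0.4, 0.1, (1, 36)),
            "A02AA04": InitiationModel(-1.1, {15: 0.2}, 0.1, 0.0, (1, 36)),
            "A09AA02": InitiationModel(-1.4, {}, 0.0, 0.0, (1, 36)),
        },
        hazard_model=HazardModel(-5.0, 0.8, {15: 1.0, 8: 0.4, 43: 0.9}, {}),
        pd_fraction=0.6,
        pd_onset_window=(12, 100),
        non_pd_initiation=False,
        exclusive_initiation=True,
        emigration_monthly_prob=0.0,
        seed=seed,
    )


def known_effect_config(
    n_persons: int = 4000, theta: float = -0.25, seed: int = 0
) -> SyntheticConfig:
    """One protective target drug against one active comparator."""
    return SyntheticConfig(
        n_persons=n_persons,
        drug_catalogue=list(_PD_DRUGS)
        + [("A02BA02", "ranitidine"), ("A02AA04", "magnesium hydroxide")],
        comorbidity_prevalences={8: 0.20, 15: 0.30},
        initiation_models={
            "A02BA02": InitiationModel(-0.8, {15: 0.6, 8: 0.4}, 0.3, 0.1, (1, 36)),
            "A02AA04": InitiationModel(-0.6, {15: 0.2}, 0.1, 0.0, (1, 36)),
        },
        hazard_model=HazardModel(-5.0, 0.6, {15: 0.7, 8: 0.3}, {"A02BA02": theta}),
        pd_fraction=0.5,
        pd_onset_window=(12, 60),
        non_pd_initiation=False,
        exclusive_initiation=True,
        emigration_monthly_prob=0.0,
        seed=seed,
    )


_SCREEN_DRUGS_12 = [
    "A02AA04", "A02BA02", "A09AA02", "C09CA01", "C10AA05", "J01CE02",
    "J01FA01", "M01AE02", "M02AA15", "N02AX02", "N06AX03", "R05DA01",
]
_PLANTED = ("A02BA02", "C09CA01")


def screen_demo_config(
    n_persons: int = 15_000, theta: float = -0.5, seed: int = 0
) -> SyntheticConfig:
    """Twelve screened drugs, two planted protective effects, the rest null.

    Six anatomical main groups with two to three drugs each supply mutual
    active comparators; initiation is exclusive within a group, so no
    person ever carries both target and comparator fills of one trial.
    """
    w = (1, 36)
    models = {
        "A02BA02": InitiationModel(-1.2, {15: 0.8, 8: 0.4}, 0.3, 0.1, w),
        "A02AA04": InitiationModel(-1.2, {15: 0.3}, 0.2, 0.0, w),
        "A09AA02": InitiationModel(-1.4, {15: 0.3}, 0.2, 0.0, w),
        "C09CA01": InitiationModel(-1.2, {15: 0.7, 19: 0.5}, 0.3, 0.1, w),
        "C10AA05": InitiationModel(-1.1, {19: 0.6, 8: 0.5}, 0.1, 0.2, w),
        "J01CE02": InitiationModel(-1.0, {45: 0.5}, 0.1, 0.0, w),
        "J01FA01": InitiationModel(-1.2, {45: 0.5}, 0.1, 0.0, w),
        "M01AE02": InitiationModel(-1.2, {40: 0.4}, -0.2, 0.0, w),
        "M02AA15": InitiationModel(-1.3, {40: 0.3}, -0.1, 0.0, w),
        "N02AX02": InitiationModel(-1.1, {40: 0.4, 15: 0.3}, 0.2, -0.1, w),
        "N06AX03": InitiationModel(-1.3, {43: 0.6, 42: 0.5}, 0.2, -0.1, w),
        "R05DA01": InitiationModel(-1.2, {45: 0.6}, 0.0, 0.0, w),
        "R05FA02": InitiationModel(-1.3, {45: 0.4}, 0.0, 0.0, w),
    }
    names = {atc: atc.lower() for atc in models}
    return SyntheticConfig(
        n_persons=n_persons,
        drug_catalogue=list(_PD_DRUGS) + [(a, names[a]) for a in sorted(models)],
        comorbidity_prevalences=dict(_NULL_PREVALENCES),
        initiation_models=models,
        hazard_model=HazardModel(
            -5.0, 0.8, {15: 1.0, 8: 0.4, 43: 0.9, 45: 0.3},
            {d: theta for d in _PLANTED},
        ),
        pd_fraction=0.6,
        pd_onset_window=(12, 100),
        non_pd_initiation=False,
        exclusive_initiation=True,
        emigration_monthly_prob=0.0,
        seed=seed,
    )


def oracle_true_rr(
    config: SyntheticConfig,
    target: str,
    control: str,
    horizon: int = 96,
    n: int = 1_000_000,
    seed: int = 1_234_567,
) -> dict:
    """Brute-force cohort-weighted true risks under both interventions.

    Draws ``n`` persons from the generator's covariate/initiation
    distributions, weights each by its probability of entering the trial
    cohort alive (survival to the initiation month under the untreated
    hazard), and evaluates the exact ``horizon``-month risk under target
    and control initiation.  Requires an exclusive-initiation
    configuration (and mirrors its earliest-draw-wins rule), so that arm
    membership never conditions on post-baseline survival: a person is a
    target entrant iff the target drug wins their initiation draw and they
    are alive at its month, and symmetrically for the comparator.
    """
    if not config.exclusive_initiation:
        raise ValueError("oracle requires an exclusive-initiation configuration")
    if target[0] != control[0]:
        raise ValueError("target and control must share the anatomical main group")
    tm = config.initiation_models[target]
    cm = config.initiation_models[control]
    hm = config.hazard_model
    theta = hm.theta.get(target, 0.0)
    rng = np.random.default_rng(seed)
    lo, hi = config.age_range
    age = rng.integers(lo, hi + 1, size=n)
    z = (age - 70.0) / 10.0
    male = (rng.random(n) < 0.5).astype(float)
    cats = sorted(config.comorbidity_prevalences)
    C = {c: (rng.random(n) < config.comorbidity_prevalences[c]).astype(float) for c in cats}

    def _logit(intercept, comorb, age_b, male_b):
        out = np.full(n, intercept, dtype=float)
        for c, b in comorb.items():
            out += b * C[c]
        return out + age_b * z + male_b * male

    h0 = expit(_logit(hm.intercept, hm.comorbidity, hm.age_per_decade, 0.0))
    h1 = expit(_logit(hm.intercept + theta, hm.comorbidity, hm.age_per_decade, 0.0))

    start = pd.Timestamp(config.coverage_start)
    end = pd.Timestamp(config.coverage_end)
    M = (end.year - start.year) * 12 + (end.month - start.month)
    o_lo, o_hi = config.pd_onset_window or (12, M - 48)
    onset = rng.integers(o_lo, o_hi + 1, size=n)
    d = onset + rng.integers(1, 4, size=(n, 3)).sum(axis=1)

    # replay the initiation draws for every drug in the group, then apply
    # the earliest-wins exclusivity rule (ties to the lowest ATC code)
    group = sorted(a for a in config.initiation_models if a[0] == target[0])
    take, month = {}, {}
    for atc in group:
        m = config.initiation_models[atc]
        p = expit(_logit(m.intercept, m.comorbidity, m.age_per_decade, m.male))
        take[atc] = rng.random(n) < p
        month[atc] = d + rng.integers(m.window[0], m.window[1] + 1, size=n)
    stacked = np.stack(
        [np.where(take[a], month[a], np.iinfo(np.int64).max) for a in group]
    )
    winner = stacked.argmin(axis=0)
    kept = {a: take[a] & (winner == j) for j, a in enumerate(group)}

    uT, uC = month[target], month[control]
    s0 = lambda m: (1.0 - h0) ** m
    wT = kept[target] * s0(uT)
    wC = kept[control] * s0(uC)
    w = wT + wC
    r1 = 1.0 - (1.0 - h1) ** horizon
    r0 = 1.0 - (1.0 - h0) ** horizon
    R1 = float(np.average(r1, weights=w))
    R0 = float(np.average(r0, weights=w))
    return {
        "risk_target": 100 * R1,
        "risk_control": 100 * R0,
        "rr": R1 / R0,
        "rd": 100 * (R0 - R1),
    }


def _replicate_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def _single_trial(snapshot, target: str, horizon: int, seed: int):
    """Classify, build the target trial, assemble covariates, expand."""
    cases = classify_pd_cases(snapshot)
    spec = TrialSpec(target, min_target_persons=2, horizon_months=horizon, seed=seed)
    trial = build_trial_cohort(snapshot, cases, spec)
    if not trial.feasible:
        return None
    cov = assemble_covariates(trial, snapshot)
    ppt = expand_person_months(trial, snapshot, horizon)
    return cov, ppt


def null_coverage_experiment(
    n_replicates: int = 200,
    B: int = 200,
    n_persons: int = 2500,
    horizon: int = 48,
    seed: int = 0,
) -> dict:
    """Confounded-null calibration: bias of the unadjusted estimator and
    bootstrap CI coverage of zero for the IPTW estimator."""
    seeds = _replicate_seeds(seed, n_replicates)
    recs = []
    for s in seeds:
        snap, _ = generate_registry(confounded_null_config(n_persons, int(s)))
        built = _single_trial(snap, "A02BA02", horizon, int(s))
        if built is None:
            continue
        cov, ppt = built
        try:
            boot = bootstrap_trial(cov, ppt, B=B, seed=int(s) + 1, horizon=horizon)
        except RuntimeError:
            continue
        unadj = fit_pooled_logistic(ppt)
        rd_unadj = 100 * (
            unadj.predict_risk_curve(0, horizon)[-1]
            - unadj.predict_risk_curve(1, horizon)[-1]
        )
        recs.append(
            {
                "rd": boot.rd,
                "rd_unadjusted": rd_unadj,
                "ci_lo": boot.ci_rd[0],
                "ci_hi": boot.ci_rd[1],
                "covers_zero": boot.ci_rd[0] <= 0.0 <= boot.ci_rd[1],
                "reject": boot.p_rd < 0.05,
            }
        )
    df = pd.DataFrame(recs)
    return {
        "replicates": df,
        "n_completed": len(df),
        "coverage": float(df["covers_zero"].mean()),
        "mean_iptw_rd": float(df["rd"].mean()),
        "mean_unadjusted_rd": float(df["rd_unadjusted"].mean()),
        "reject_rate": float(df["reject"].mean()),
    }


def effect_recovery_experiment(
    n_replicates: int = 100,
    n_persons: int = 4000,
    theta: float = -0.25,
    horizon: int = 96,
    oracle_n: int = 1_000_000,
    seed: int = 0,
) -> dict:
    """Known-effect recovery against the brute-force oracle."""
    config = known_effect_config(n_persons, theta, 0)
    truth = oracle_true_rr(config, "A02BA02", "A02AA04", horizon, n=oracle_n)
    seeds = _replicate_seeds(seed, n_replicates)
    rrs, rds = [], []
    for s in seeds:
        snap, _ = generate_registry(known_effect_config(n_persons, theta, int(s)))
        built = _single_trial(snap, "A02BA02", horizon, int(s))
        if built is None:
            continue
        cov, ppt = built
        engine = _TrialEngine(cov, ppt, horizon)
        est = engine.estimate(np.ones(engine.n))
        rrs.append(est["rr"])
        rds.append(est["rd"])
    return {
        "true_rr": truth["rr"],
        "true_rd": truth["rd"],
        "median_rr": float(np.median(rrs)),
        "median_rd": float(np.median(rds)),
        "n_completed": len(rrs),
        "rr_samples": np.asarray(rrs),
    }


def screen_recovery_experiment(
    n_replicates: int = 20,
    B: int = 100,
    n_persons: int = 8000,
    horizon: int = 48,
    theta: float = -0.5,
    seed: int = 0,
) -> dict:
    """Planted-effect screen: recovery of the two protective drugs."""
    seeds = _replicate_seeds(seed, n_replicates)
    recs = []
    for s in seeds:
        snap, _ = generate_registry(screen_demo_config(n_persons, theta, int(s)))
        cases = classify_pd_cases(snap)
        res = run_screen(
            snap,
            cases,
            spec_defaults={"min_target_persons": 50},
            seed=int(s),
            B=B,
            horizon_months=horizon,
            targets=list(_SCREEN_DRUGS_12),
        )
        hits = set(res.loc[res["hit"].fillna(False), "target_atc"])
        recs.append(
            {
                "tp": len(hits & set(_PLANTED)),
                "fp": len(hits - set(_PLANTED)),
                "n_ok": int((res["status"] == "ok").sum()),
            }
        )
    df = pd.DataFrame(recs)
    return {
        "replicates": df,
        "median_tp": float(df["tp"].median()),
        "median_fp": float(df["fp"].median()),
        "mean_tp": float(df["tp"].mean()),
        "mean_fp": float(df["fp"].mean()),
        "planted": list(_PLANTED),
    }
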