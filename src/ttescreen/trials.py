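"""Emulated-trial cohort construction (active-comparator new-user design).

For one target drug (ATC level 5), the target arm holds each eligible PD
case's first post-diagnosis fill of the drug; the control arm holds
initiations of drugs sharing the target's anatomical main group (ATC
level 1, or level 2 in the stricter comparator variant) but a different
pharmacologic subgroup (level 3).  Eligibility: diagnosed less than five
years before baseline, at least 25 years old at diagnosis, and no fill of
the initiated drug during the two-year washout before baseline.  Persons
with any target-drug fill anywhere in the registry never enter the control
arm; control baselines are restricted to the calendar-year range of the
retained target baselines; each person contributes one control initiation
(earliest eligible, ATC-lexicographic tie-break); and the control arm is
capped by a seeded uniform subsample.  Every drop is logged with a reason
code.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .atc import parse_atc_levels
from .registry import RegistrySnapshot

__all__ = [
    "TrialSpec",
    "TrialCohort",
    "enumerate_screen_drugs",
    "build_trial_cohort",
    "build_general_population_cohort",
]


@dataclasses.dataclass
class TrialSpec:
    target_atc: str
    comparator_level: int = 1
    min_target_persons: int = 100
    max_control_initiations: int = 10_000
    washout_years: float = 2.0
    max_years_since_diagnosis: float = 5.0
    min_age_at_diagnosis: float = 25.0
    horizon_months: int = 96
    seed: int = 0

    def __post_init__(self) -> None:
        if self.comparator_level not in (1, 2):
            raise ValueError("comparator_level must be 1 or 2")
        if self.washout_years <= 0 or self.max_years_since_diagnosis <= 0:
            raise ValueError("washout and diagnosis horizon must be positive")
        levels = parse_atc_levels(self.target_atc)
        if 5 not in levels:
            raise ValueError(f"target_atc must be a level-5 code, got {self.target_atc!r}")


@dataclasses.dataclass
class TrialCohort:
    spec: TrialSpec
    initiations: pd.DataFrame  # person_id, drug_atc, baseline_date, arm[, diagnosis_date]
    exclusion_log: pd.DataFrame  # person_id, drug_atc, reason
    feasible: bool

    @property
    def n_target(self) -> int:
        return int((self.initiations["arm"] == "target").sum())

    @property
    def n_control(self) -> int:
        return int((self.initiations["arm"] == "control").sum())


def enumerate_screen_drugs(
    snapshot: RegistrySnapshot, cases: pd.DataFrame, min_target_persons: int = 100
) -> list[str]:
    """Level-5 drugs with >= ``min_target_persons`` distinct PD initiators.

    Counts persons with at least one post-diagnosis fill; antiparkinsonian
    drugs (prefix N04) are never screened.  Returns a sorted list.
    """
    if cases.empty:
        return []
    rx = snapshot.prescriptions.merge(
        cases[["person_id", "diagnosis_date"]], on="person_id", how="inner"
    )
    rx = rx[rx["dispense_date"] >= rx["diagnosis_date"]]
    atc = rx["atc_code"].astype(str)
    rx = rx[(atc.str.len() == 7) & ~atc.str.startswith("N04")]
    counts = rx.groupby("atc_code")["person_id"].nunique()
    return sorted(counts.index[counts >= min_target_persons])


def _first_post_index_fills(rx: pd.DataFrame) -> pd.DataFrame:
    """First fill per (person, drug) among rows already restricted to
    post-index dates; ties on date are irrelevant (same value)."""
    idx = rx.groupby(["person_id", "atc_code"])["dispense_date"].idxmin()
    return rx.loc[idx].rename(columns={"dispense_date": "baseline_date"})


def _washout_violations(
    candidates: pd.DataFrame, prescriptions: pd.DataFrame, washout_years: float
) -> pd.Series:
    """Boolean per candidate row: a fill of the same drug falls inside the
    half-open washout window [baseline - washout, baseline)."""
    if candidates.empty:
        return pd.Series(False, index=candidates.index)
    fills = prescriptions[["person_id", "atc_code", "dispense_date"]]
    fills = fills[fills["atc_code"].isin(set(candidates["atc_code"]))]
    merged = candidates[["person_id", "atc_code", "baseline_date"]].reset_index().merge(
        fills, on=["person_id", "atc_code"], how="left"
    )
    # same open-ended lookback convention as covariate assembly: a fill
    # exactly `washout` before baseline sits on the boundary, outside it
    lb = merged["baseline_date"] - pd.DateOffset(months=int(round(washout_years * 12)))
    hit = (merged["dispense_date"] > lb) & (merged["dispense_date"] < merged["baseline_date"])
    viol = merged.loc[hit, "index"].unique()
    return pd.Series(candidates.index.isin(viol), index=candidates.index)


def _log(entries: list, person_ids, drug, reason: str) -> None:
    for pid, d in zip(
        person_ids, drug if not isinstance(drug, str) else [drug] * len(person_ids)
    ):
        entries.append({"person_id": pid, "drug_atc": d, "reason": reason})


def _apply_eligibility(
    cand: pd.DataFrame, snapshot: RegistrySnapshot, spec: TrialSpec, log: list
) -> pd.DataFrame:
    """Shared PD-mode eligibility: age at diagnosis, years since diagnosis,
    washout on the initiated drug.  Drops rows, logging the first failing
    reason per row."""
    age_bad = cand["age_at_diagnosis"] < spec.min_age_at_diagnosis
    _log(log, cand.loc[age_bad, "person_id"], cand.loc[age_bad, "atc_code"], "age")
    cand = cand[~age_bad]

    limit = cand["diagnosis_date"] + pd.DateOffset(
        months=int(round(spec.max_years_since_diagnosis * 12))
    )
    late = cand["baseline_date"] >= limit
    _log(log, cand.loc[late, "person_id"], cand.loc[late, "atc_code"], "beyond_5y")
    cand = cand[~late]

    wv = _washout_violations(cand, snapshot.prescriptions, spec.washout_years)
    _log(log, cand.loc[wv, "person_id"], cand.loc[wv, "atc_code"], "washout")
    return cand[~wv]


def post_diagnosis_fills(snapshot: RegistrySnapshot, cases: pd.DataFrame) -> pd.DataFrame:
    """Case fills on/after the diagnosis date; shared across a screen's trials.

    Carries fixed-width ATC prefix columns (``_atc1``..``_atc3``, ``_len7``)
    so per-trial group tests reduce to array equality.
    """
    rx = snapshot.prescriptions.merge(
        cases[["person_id", "diagnosis_date", "age_at_diagnosis"]],
        on="person_id",
        how="inner",
    )
    post = rx[rx["dispense_date"] >= rx["diagnosis_date"]].copy()
    codes = post["atc_code"].to_numpy(dtype="U7")
    post["_atc1"] = codes.astype("U1")
    post["_atc2"] = codes.astype("U3")
    post["_atc3"] = codes.astype("U4")
    post["_len7"] = np.char.str_len(codes) == 7
    return post


def build_trial_cohort(
    snapshot: RegistrySnapshot, cases: pd.DataFrame, spec: TrialSpec,
    _post: pd.DataFrame | None = None,
) -> TrialCohort:
    """Construct one emulated trial cohort for ``spec.target_atc``."""
    log: list[dict] = []
    levels = parse_atc_levels(spec.target_atc)
    group_prefix = levels[spec.comparator_level]
    target_l3 = levels[3]

    post = post_diagnosis_fills(snapshot, cases) if _post is None else _post

    # ---- target arm ----------------------------------------------------
    tgt = _first_post_index_fills(post[post["atc_code"] == spec.target_atc])
    tgt = _apply_eligibility(tgt, snapshot, spec, log)
    target = tgt.assign(arm="target")

    # ---- control candidates -------------------------------------------
    if {"_atc1", "_atc2", "_atc3", "_len7"} <= set(post.columns):
        lvl_col = post["_atc1"] if spec.comparator_level == 1 else post["_atc2"]
        is_ctrl_drug = (
            post["_len7"]
            & (lvl_col == group_prefix)
            & (post["_atc3"] != target_l3)
            & (post["_atc2"] != "N04")
        )
    else:
        atc = post["atc_code"].astype(str)
        is_ctrl_drug = (
            (atc.str.len() == 7)
            & atc.str.startswith(group_prefix)
            & (atc.str[:4] != target_l3)
            & ~atc.str.startswith("N04")
        )
    ctrl = _first_post_index_fills(post[is_ctrl_drug])
    ever_target = set(
        snapshot.prescriptions.loc[
            snapshot.prescriptions["atc_code"] == spec.target_atc, "person_id"
        ]
    )
    tu = ctrl["person_id"].isin(ever_target)
    _log(log, ctrl.loc[tu, "person_id"], ctrl.loc[tu, "atc_code"], "target_user")
    ctrl = ctrl[~tu]
    ctrl = _apply_eligibility(ctrl, snapshot, spec, log)

    # calendar-year range of the retained target baselines
    if len(target):
        years = target["baseline_date"].dt.year
        lo, hi = years.min(), years.max()
        out = ~ctrl["baseline_date"].dt.year.between(lo, hi)
        _log(log, ctrl.loc[out, "person_id"], ctrl.loc[out, "atc_code"], "outside_year_range")
        ctrl = ctrl[~out]

    # one initiation per control person: earliest, then lowest ATC code
    ctrl = ctrl.sort_values(["person_id", "baseline_date", "atc_code"], kind="stable")
    dup = ctrl.duplicated("person_id", keep="first")
    _log(log, ctrl.loc[dup, "person_id"], ctrl.loc[dup, "atc_code"], "secondary_initiation")
    ctrl = ctrl[~dup]

    # seeded uniform subsample when the cap is exceeded
    if len(ctrl) > spec.max_control_initiations:
        ctrl = ctrl.sort_values("person_id", kind="stable")
        rng = np.random.default_rng(spec.seed)
        keep = np.zeros(len(ctrl), dtype=bool)
        keep[rng.choice(len(ctrl), size=spec.max_control_initiations, replace=False)] = True
        _log(log, ctrl.loc[~keep, "person_id"], ctrl.loc[~keep, "atc_code"], "subsampled_out")
        ctrl = ctrl[keep]
    control = ctrl.assign(arm="control")

    cols = ["person_id", "atc_code", "baseline_date", "arm", "diagnosis_date"]
    initiations = (
        pd.concat([target, control], ignore_index=True)[cols]
        .rename(columns={"atc_code": "drug_atc"})
        .sort_values(["arm", "person_id"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    exclusion_log = pd.DataFrame(log, columns=["person_id", "drug_atc", "reason"])
    feasible = len(target) >= 2 and len(control) >= 2
    return TrialCohort(spec, initiations, exclusion_log, feasible)


def build_general_population_cohort(
    snapshot: RegistrySnapshot,
    spec: TrialSpec,
    sample_fraction: float = 0.1,
    control_ratio: int = 4,
    index_date=None,
    min_age_at_index: float = 65.0,
) -> TrialCohort:
    """General-population variant: a seeded person sample aged >= 65 at the
    index date, no diagnosis-linked eligibility, controls subsampled to
    ``control_ratio`` times the target arm."""
    log: list[dict] = []
    levels = parse_atc_levels(spec.target_atc)
    group_prefix = levels[spec.comparator_level]
    target_l3 = levels[3]
    if index_date is None:
        index_date = snapshot.coverage[0] + pd.DateOffset(years=2)
    index_date = pd.Timestamp(index_date)

    persons = snapshot.persons
    birth = pd.to_datetime(
        {"year": persons["birth_year"].astype(int), "month": 1, "day": 1}
    )
    age = (index_date - birth).dt.days / 365.25
    eligible = persons.loc[age >= min_age_at_index, "person_id"].sort_values()
    rng = np.random.default_rng(spec.seed)
    take = rng.random(len(eligible)) < sample_fraction
    sampled = set(eligible[take])

    rx = snapshot.prescriptions
    rx = rx[rx["person_id"].isin(sampled) & (rx["dispense_date"] >= index_date)]

    tgt = _first_post_index_fills(rx[rx["atc_code"] == spec.target_atc])
    wv = _washout_violations(tgt, snapshot.prescriptions, spec.washout_years)
    _log(log, tgt.loc[wv, "person_id"], tgt.loc[wv, "atc_code"], "washout")
    tgt = tgt[~wv]
    target = tgt.assign(arm="target")

    atc = rx["atc_code"].astype(str)
    is_ctrl_drug = (
        (atc.str.len() == 7)
        & atc.str.startswith(group_prefix)
        & (atc.str[:4] != target_l3)
        & ~atc.str.startswith("N04")
    )
    ctrl = _first_post_index_fills(rx[is_ctrl_drug])
    ever_target = set(
        snapshot.prescriptions.loc[
            snapshot.prescriptions["atc_code"] == spec.target_atc, "person_id"
        ]
    )
    tu = ctrl["person_id"].isin(ever_target)
    _log(log, ctrl.loc[tu, "person_id"], ctrl.loc[tu, "atc_code"], "target_user")
    ctrl = ctrl[~tu]
    wv = _washout_violations(ctrl, snapshot.prescriptions, spec.washout_years)
    _log(log, ctrl.loc[wv, "person_id"], ctrl.loc[wv, "atc_code"], "washout")
    ctrl = ctrl[~wv]

    if len(target):
        years = target["baseline_date"].dt.year
        out = ~ctrl["baseline_date"].dt.year.between(years.min(), years.max())
        _log(log, ctrl.loc[out, "person_id"], ctrl.loc[out, "atc_code"], "outside_year_range")
        ctrl = ctrl[~out]

    ctrl = ctrl.sort_values(["person_id", "baseline_date", "atc_code"], kind="stable")
    dup = ctrl.duplicated("person_id", keep="first")
    _log(log, ctrl.loc[dup, "person_id"], ctrl.loc[dup, "atc_code"], "secondary_initiation")
    ctrl = ctrl[~dup]

    cap = min(spec.max_control_initiations, control_ratio * len(target))
    if len(ctrl) > cap:
        ctrl = ctrl.sort_values("person_id", kind="stable")
        keep = np.zeros(len(ctrl), dtype=bool)
        keep[rng.choice(len(ctrl), size=cap, replace=False)] = True
        _log(log, ctrl.loc[~keep, "person_id"], ctrl.loc[~keep, "atc_code"], "subsampled_out")
        ctrl = ctrl[keep]
    control = ctrl.assign(arm="control")

    cols = ["person_id", "atc_code", "baseline_date", "arm"]
    initiations = (
        pd.concat([target, control], ignore_index=True)[cols]
        .rename(columns={"atc_code": "drug_atc"})
        .sort_values(["arm", "person_id"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    exclusion_log = pd.DataFrame(log, columns=["person_id", "drug_atc", "reason"])
    feasible = len(target) >= 2 and len(control) >= 2
    return TrialCohort(spec, initiations, exclusion_log, feasible)
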