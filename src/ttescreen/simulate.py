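"""Synthetic prescription-registry generator with known ground truth.

Emulates the statistical structure the screening pipeline assumes, at a
configurable desk scale:

* latent chronic comorbidities drawn per person, materialized **only** as
  prescriptions of marker drugs mapped to RxRisk categories (covariate
  assembly sees comorbidity exclusively through the prescription channel,
  as in a real registry);
* confounded drug initiation — per-drug logistic models on the latent
  comorbidities, age and sex;
* a discrete-time monthly mortality hazard (logistic) with per-drug
  treatment log-odds effects applied from initiation onward;
* a Parkinson-disease prescription pattern (MAO-B inhibitor fills, or
  levodopa fills with a G20 reimbursement code) that the case classifier
  must recover, plus G20 specialist-care diagnosis records for validation;
* emigration and administrative censoring.

Time is simulated on a whole-month grid and converted to calendar dates
(prescriptions dated the first of their month).  All randomness flows from
a single seed through per-table child streams, so adding a drug to the
catalogue does not perturb unrelated draws.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import expit as _expit

from .covariates import default_rxrisk_mapping
from .registry import RegistrySnapshot

__all__ = [
    "InitiationModel",
    "HazardModel",
    "SyntheticConfig",
    "GroundTruth",
    "default_config",
    "generate_registry",
    "make_toy_fixture",
]


@dataclasses.dataclass
class InitiationModel:
    """Logistic model for whether a person ever initiates a drug.

    logit P(initiate) = intercept + sum_c comorbidity[c]*C_c
                        + age_per_decade*(age-70)/10 + male*1[male]

    ``window`` is the (inclusive) month window, counted from the PD
    diagnosis month, within which the initiation month is drawn uniformly.
    """

    intercept: float
    comorbidity: dict[int, float] = dataclasses.field(default_factory=dict)
    age_per_decade: float = 0.0
    male: float = 0.0
    window: tuple[int, int] = (1, 48)


@dataclasses.dataclass
class HazardModel:
    """Discrete-time monthly death hazard on the logit scale.

    logit h = intercept + age_per_decade*(age-70)/10
              + sum_c comorbidity[c]*C_c + sum_d theta[d]*1[t >= initiation_d]
    """

    intercept: float = -5.2
    age_per_decade: float = 0.8
    comorbidity: dict[int, float] = dataclasses.field(default_factory=dict)
    theta: dict[str, float] = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class SyntheticConfig:
    n_persons: int = 20_000
    coverage_start: str = "2004-01-01"
    coverage_end: str = "2020-02-01"
    drug_catalogue: list[tuple[str, str]] = dataclasses.field(default_factory=list)
    comorbidity_prevalences: dict[int, float] = dataclasses.field(default_factory=dict)
    initiation_models: dict[str, InitiationModel] = dataclasses.field(default_factory=dict)
    hazard_model: HazardModel = dataclasses.field(default_factory=HazardModel)
    pd_fraction: float = 0.25
    levodopa_route_fraction: float = 0.4
    pd_onset_window: tuple[int, int] | None = None  # months; default (12, M-48)
    marker_interval_months: int = 3
    emigration_monthly_prob: float = 0.0002
    g20_recording_prob: float = 1.0
    g20_noise_prob: float = 0.0
    non_pd_initiation: bool = True
    # at most one initiated drug per ATC level-1 group (earliest draw wins,
    # ties to the lowest code): rules out persons holding both target and
    # comparator fills within one trial
    exclusive_initiation: bool = False
    age_range: tuple[int, int] = (50, 85)
    seed: int = 0

    def validate(self) -> None:
        for name, p in [("pd_fraction", self.pd_fraction)] + [
            (f"prevalence[{c}]", p) for c, p in self.comorbidity_prevalences.items()
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        codes = {atc for atc, _ in self.drug_catalogue}
        for atc in set(self.initiation_models) | set(self.hazard_model.theta):
            if atc not in codes:
                raise ValueError(f"model references drug {atc!r} absent from catalogue")
        if self.pd_fraction > 0:
            if not any(c.startswith("N04BD") for c in codes) or not any(
                c.startswith("N04BA") for c in codes
            ):
                raise ValueError(
                    "catalogue must contain N04BD and N04BA drugs when pd_fraction > 0"
                )


@dataclasses.dataclass
class GroundTruth:
    """Latent state emitted alongside a snapshot; never fed to the analysis."""

    theta: dict[str, float]
    comorbidities: pd.DataFrame  # person_id + binary c<id> columns
    pd_pattern: pd.DataFrame  # person_id, route, diagnosis_month
    initiations: pd.DataFrame  # person_id, atc_code, month (materialized fills only)


_PD_DRUGS = [
    ("N04BD01", "selegiline"),
    ("N04BD02", "rasagiline"),
    ("N04BA02", "levodopa and decarboxylase inhibitor"),
]

_SCREEN_DRUGS = [
    ("A02AA04", "magnesium hydroxide"),
    ("A02BA02", "ranitidine"),
    ("A02BC02", "pantoprazole"),
    ("A02BC05", "esomeprazole"),
    ("A09AA02", "multienzymes"),
    ("C09CA01", "losartan"),
    ("C10AA05", "atorvastatin"),
    ("J01CE02", "phenoxymethylpenicillin"),
    ("M01AE02", "naproxen"),
    ("N02AX02", "tramadol"),
    ("N06AX03", "mianserin"),
    ("R05DA01", "ethylmorphine"),
]

# latent comorbidity categories active by default (RxRisk category ids)
_DEFAULT_PREVALENCES = {
    8: 0.20,  # diabetes
    11: 0.18,  # anticoagulation
    13: 0.12,  # anaemia
    15: 0.30,  # heart failure
    19: 0.25,  # ischaemic heart disease
    40: 0.10,  # osteoporosis
    41: 0.05,  # epilepsy
    42: 0.08,  # psychotic illness
    43: 0.10,  # dementia
    45: 0.15,  # chronic airways disease
}

_DEFAULT_HAZARD_COMORBIDITY = {8: 0.35, 13: 0.30, 15: 1.00, 19: 0.30, 43: 0.90}


def default_config(n_persons: int = 20_000, seed: int = 0, **overrides) -> SyntheticConfig:
    """The default synthetic study conditions.

    Roughly 25% of persons follow the PD prescription pattern; ten screen
    drugs across five anatomical main groups; initiation of acid-related
    and cardiovascular drugs is driven by latent heart failure / diabetes /
    dementia, the same conditions that raise the monthly death hazard —
    i.e. genuine confounding by indication.  The baseline monthly hazard
    (intercept -5.2, ~0.55%/month at age 70) yields an 8-year mortality
    around 40% in the PD age range.  All treatment effects are null unless
    overridden through ``hazard_model``.
    """
    init_models = {
        "A02AA04": InitiationModel(-1.6, {15: 0.2}, 0.1, 0.0),
        "A02BA02": InitiationModel(-1.2, {15: 1.5, 8: 0.5}, 0.3, 0.1),
        "A09AA02": InitiationModel(-2.0, {}, 0.0, 0.0),
        "A02BC02": InitiationModel(-1.4, {15: 0.3, 8: 0.3}, 0.2, 0.0),
        "A02BC05": InitiationModel(-1.6, {15: 0.3}, 0.2, 0.0),
        "C09CA01": InitiationModel(-1.5, {15: 0.8, 19: 0.6}, 0.3, 0.1),
        "C10AA05": InitiationModel(-1.3, {19: 0.8, 8: 0.6}, 0.1, 0.2),
        "J01CE02": InitiationModel(-1.0, {45: 0.6}, 0.1, 0.0),
        "M01AE02": InitiationModel(-1.6, {40: 0.4}, -0.2, 0.0),
        "N02AX02": InitiationModel(-1.4, {40: 0.4, 15: 0.3}, 0.2, -0.1),
        "N06AX03": InitiationModel(-1.8, {43: 0.7, 42: 0.5}, 0.2, -0.1),
        "R05DA01": InitiationModel(-1.5, {45: 0.7}, 0.0, 0.0),
    }
    cfg = SyntheticConfig(
        n_persons=n_persons,
        drug_catalogue=list(_PD_DRUGS) + list(_SCREEN_DRUGS),
        comorbidity_prevalences=dict(_DEFAULT_PREVALENCES),
        initiation_models=init_models,
        hazard_model=HazardModel(comorbidity=dict(_DEFAULT_HAZARD_COMORBIDITY)),
        seed=seed,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


def _months_between(start: pd.Timestamp, end: pd.Timestamp) -> int:
    return (end.year - start.year) * 12 + (end.month - start.month)


def _runs(starts: np.ndarray, stops: np.ndarray, step: int):
    """Concatenated arithmetic runs start, start+step, ... <= stop.

    Returns (owner_index, values): ``owner_index[i]`` is the row of the
    run that produced ``values[i]``.
    """
    counts = np.where(stops >= starts, (stops - starts) // step + 1, 0).astype(int)
    owners = np.repeat(np.arange(len(starts)), counts)
    if len(owners) == 0:
        return owners, np.array([], dtype=int)
    offsets = np.arange(counts.sum()) - np.repeat(
        np.concatenate(([0], np.cumsum(counts)[:-1])), counts
    )
    return owners, starts[owners] + offsets * step


def generate_registry(
    config: SyntheticConfig, mapping: pd.DataFrame | None = None
) -> tuple[RegistrySnapshot, GroundTruth]:
    """Draw one synthetic registry snapshot plus its ground truth.

    Deterministic given ``config.seed``; independent random streams per
    table (persons / comorbidities / PD pattern / initiations / markers /
    outcomes / diagnosis records).
    """
    config.validate()
    if mapping is None:
        mapping = default_rxrisk_mapping()
    start = pd.Timestamp(config.coverage_start)
    end = pd.Timestamp(config.coverage_end)
    if start.day != 1:
        raise ValueError("coverage_start must be the first day of a month")
    M = _months_between(start, end)
    if M < 60:
        raise ValueError("coverage window must span at least 60 months")
    n = config.n_persons

    ss = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ["persons", "comorbid", "pd", "init", "markers", "outcome", "npr"],
            ss.spawn(7),
        )
    }

    # ---- persons -------------------------------------------------------
    rng = streams["persons"]
    person_id = np.array([f"P{i:07d}" for i in range(n)])
    lo, hi = config.age_range
    age0 = rng.integers(lo, hi + 1, size=n)  # age at coverage start
    birth_year = start.year - age0
    sex = np.where(rng.random(n) < 0.5, "M", "F")
    edu = rng.choice(
        ["primary", "secondary", "tertiary", "missing"], size=n, p=[0.40, 0.35, 0.20, 0.05]
    )
    if config.emigration_monthly_prob > 0:
        emig_month = rng.geometric(config.emigration_monthly_prob, size=n) - 1
    else:
        emig_month = np.full(n, np.iinfo(np.int64).max)
    z = (age0 - 70.0) / 10.0
    male = (sex == "M").astype(float)

    # ---- latent comorbidities -----------------------------------------
    rng = streams["comorbid"]
    cats = sorted(config.comorbidity_prevalences)
    C = np.zeros((n, len(cats)), dtype=np.int8)
    for j, c in enumerate(cats):
        C[:, j] = rng.random(n) < config.comorbidity_prevalences[c]
    cat_col = {c: j for j, c in enumerate(cats)}

    # ---- PD prescription pattern --------------------------------------
    rng = streams["pd"]
    is_pd = rng.random(n) < config.pd_fraction
    route_levo = rng.random(n) < config.levodopa_route_fraction
    onset_lo, onset_hi = config.pd_onset_window or (12, M - 48)
    onset = rng.integers(onset_lo, max(onset_lo + 1, onset_hi + 1), size=n)
    gaps = rng.integers(1, 4, size=(n, 3))
    fill_months = np.cumsum(np.column_stack([onset, gaps]), axis=1)  # 4 fills
    diag_month = fill_months[:, 3]
    maob_choice = rng.integers(0, 2, size=n)  # which MAO-B product

    # ---- drug initiations ---------------------------------------------
    rng = streams["init"]
    init_flag: dict[str, np.ndarray] = {}
    init_month: dict[str, np.ndarray] = {}
    for atc in sorted(config.initiation_models):
        m = config.initiation_models[atc]
        logit = np.full(n, m.intercept, dtype=float)
        for c, beta in m.comorbidity.items():
            logit += beta * C[:, cat_col[c]]
        logit += m.age_per_decade * z + m.male * male
        takes = rng.random(n) < _expit(logit)
        w0, w1 = m.window
        offs = rng.integers(w0, w1 + 1, size=n)
        month = np.where(is_pd, diag_month + offs, -1)
        if config.non_pd_initiation:
            gp_month = rng.integers(24, M, size=n)
            month = np.where(is_pd, month, gp_month)
        takes &= (month >= 0) & (month < M)
        init_flag[atc] = takes
        init_month[atc] = month

    if config.exclusive_initiation:
        by_group: dict[str, list[str]] = {}
        for atc in sorted(init_flag):
            by_group.setdefault(atc[0], []).append(atc)
        for group_drugs in by_group.values():
            if len(group_drugs) < 2:
                continue
            months = np.stack(
                [np.where(init_flag[a], init_month[a], np.iinfo(np.int64).max)
                 for a in group_drugs]
            )
            winner = months.argmin(axis=0)  # ties -> lowest ATC (sorted order)
            for j, atc in enumerate(group_drugs):
                init_flag[atc] &= winner == j

    # ---- death hazard --------------------------------------------------
    rng = streams["outcome"]
    hm = config.hazard_model
    base_logit = hm.intercept + hm.age_per_decade * z
    for c, beta in hm.comorbidity.items():
        if c in cat_col:
            base_logit += beta * C[:, cat_col[c]]
    logit_mat = np.tile(base_logit[:, None], (1, M))
    for atc, theta in hm.theta.items():
        if theta == 0.0 or atc not in init_flag:
            continue
        rows = np.where(init_flag[atc])[0]
        if len(rows):
            after = np.arange(M)[None, :] >= init_month[atc][rows][:, None]
            logit_mat[rows] += theta * after
    haz = _expit(logit_mat)
    u = rng.random((n, M))
    dies = u < haz
    any_death = dies.any(axis=1)
    death_month = np.where(any_death, dies.argmax(axis=1), np.iinfo(np.int64).max)
    # emigration before death removes the death record and truncates follow-up
    death_recorded = any_death & (death_month <= emig_month) & (death_month < M)
    trunc = np.minimum(np.minimum(death_month, emig_month), M - 1)

    # ---- assemble prescription rows -----------------------------------
    rows_person: list[np.ndarray] = []
    rows_atc: list[np.ndarray] = []
    rows_month: list[np.ndarray] = []
    rows_reimb: list[np.ndarray] = []

    def _emit(pidx: np.ndarray, months: np.ndarray, atc: np.ndarray, reimb=None):
        keep = months <= trunc[pidx]
        pidx, months = pidx[keep], months[keep]
        rows_person.append(pidx)
        rows_month.append(months)
        rows_atc.append(atc[keep] if isinstance(atc, np.ndarray) else np.repeat(atc, len(pidx)))
        rows_reimb.append(
            reimb[keep] if isinstance(reimb, np.ndarray) else np.repeat(reimb, len(pidx))
        )

    # PD pattern fills: four qualifying fills then maintenance every 3 months
    pd_idx = np.where(is_pd)[0]
    if len(pd_idx):
        atc4 = np.where(
            route_levo[pd_idx],
            "N04BA02",
            np.where(maob_choice[pd_idx] == 0, "N04BD01", "N04BD02"),
        )
        reimb4 = np.where(route_levo[pd_idx], "G20", None)
        for k in range(4):
            _emit(pd_idx, fill_months[pd_idx, k], atc4.astype(object), reimb4.astype(object))
        owners, months = _runs(diag_month[pd_idx] + 3, np.minimum(trunc[pd_idx], M - 1), 3)
        _emit(pd_idx[owners], months, atc4.astype(object)[owners], reimb4.astype(object)[owners])

    # screen-drug fills: initiation fill plus three refills two months apart
    for atc in sorted(init_flag):
        idx = np.where(init_flag[atc])[0]
        for k in range(4):
            _emit(idx, init_month[atc][idx] + 2 * k, atc, None)

    # comorbidity marker fills through the prescription channel
    rng = streams["markers"]
    label_by_id = mapping.drop_duplicates("category_id").set_index("category_id")
    marker_code = {c: label_by_id.loc[c, "atc_prefix"] + "AA01" for c in cats}
    step = config.marker_interval_months
    for c in cats:
        idx = np.where(C[:, cat_col[c]] == 1)[0]
        if not len(idx):
            continue
        offsets = rng.integers(0, step, size=len(idx))
        owners, months = _runs(offsets, np.minimum(trunc[idx], M - 1), step)
        _emit(idx[owners], months, marker_code[c], None)

    pidx = np.concatenate(rows_person) if rows_person else np.array([], dtype=int)
    months = np.concatenate(rows_month) if rows_month else np.array([], dtype=int)
    atcs = np.concatenate(rows_atc) if rows_atc else np.array([], dtype=object)
    reimbs = np.concatenate(rows_reimb) if rows_reimb else np.array([], dtype=object)
    month_dates = pd.date_range(start, periods=M, freq="MS")
    month_np = month_dates.to_numpy()
    prescriptions = pd.DataFrame(
        {
            "person_id": person_id[pidx],
            "atc_code": atcs.astype(str),
            "dispense_date": month_np[np.clip(months, 0, M - 1)],
            "reimbursement_icd": reimbs,
        }
    ).sort_values(["person_id", "dispense_date", "atc_code"], kind="stable")
    prescriptions = prescriptions.reset_index(drop=True)

    # ---- specialist-care G20 diagnosis records ------------------------
    rng = streams["npr"]
    recorded = is_pd & (rng.random(n) < config.g20_recording_prob)
    noise = ~is_pd & (rng.random(n) < config.g20_noise_prob)
    dx_person: list[np.ndarray] = []
    dx_month: list[np.ndarray] = []
    for idx_arr, base in [
        (np.where(recorded)[0], diag_month),
        (np.where(noise)[0], np.full(n, 30)),
    ]:
        for k in (0, 2):
            m = base[idx_arr] + k
            keep = m <= trunc[idx_arr]
            dx_person.append(idx_arr[keep])
            dx_month.append(m[keep])
    dxp = np.concatenate(dx_person) if dx_person else np.array([], dtype=int)
    dxm = np.concatenate(dx_month) if dx_month else np.array([], dtype=int)
    diagnoses = pd.DataFrame(
        {
            "person_id": person_id[dxp],
            "icd10_code": "G20",
            "visit_date": month_np[np.clip(dxm, 0, M - 1)] + np.timedelta64(9, "D"),
        }
    ).sort_values(["person_id", "visit_date"]).reset_index(drop=True)

    # ---- persons table -------------------------------------------------
    emig_dates = pd.Series(pd.NaT, index=range(n), dtype="datetime64[ns]")
    has_emig = (emig_month < M) & (~any_death | (emig_month < death_month))
    emig_dates[has_emig] = month_dates[emig_month[has_emig]]
    death_ts = month_dates[np.clip(death_month, 0, M - 1)]
    persons = pd.DataFrame(
        {
            "person_id": person_id,
            "sex": sex,
            "birth_year": birth_year,
            "education_level": edu,
            "emigration_date": emig_dates,
            "death_year": pd.array(
                np.where(death_recorded, death_ts.year, -1), dtype="Int64"
            ),
            "death_month": pd.array(
                np.where(death_recorded, death_ts.month, -1), dtype="Int64"
            ),
        }
    )
    persons.loc[~death_recorded, ["death_year", "death_month"]] = pd.NA

    catalogue = pd.DataFrame(
        list(config.drug_catalogue)
        + [(marker_code[c], f"{label_by_id.loc[c, 'label']} marker") for c in cats],
        columns=["atc_code", "drug_name"],
    ).drop_duplicates("atc_code").sort_values("atc_code").reset_index(drop=True)

    snapshot = RegistrySnapshot(
        prescriptions=prescriptions,
        persons=persons,
        diagnoses=diagnoses,
        catalogue=catalogue,
        coverage=(start, end),
    )

    comorb = pd.DataFrame({"person_id": person_id})
    for c in cats:
        comorb[f"c{c}"] = C[:, cat_col[c]]
    pd_tab = pd.DataFrame(
        {
            "person_id": person_id[pd_idx],
            "route": np.where(route_levo[pd_idx], "levodopa_reimb", "maob"),
            "diagnosis_month": diag_month[pd_idx],
        }
    )
    pd_tab = pd_tab[diag_month[pd_idx] <= trunc[pd_idx]].reset_index(drop=True)
    init_rows = []
    for atc in sorted(init_flag):
        idx = np.where(init_flag[atc] & (init_month[atc] <= trunc))[0]
        init_rows.append(
            pd.DataFrame(
                {"person_id": person_id[idx], "atc_code": atc, "month": init_month[atc][idx]}
            )
        )
    truth = GroundTruth(
        theta=dict(hm.theta),
        comorbidities=comorb,
        pd_pattern=pd_tab,
        initiations=pd.concat(init_rows, ignore_index=True)
        if init_rows
        else pd.DataFrame(columns=["person_id", "atc_code", "month"]),
    )
    return snapshot, truth


# ---------------------------------------------------------------------------
# hand-built micro-fixtures
# ---------------------------------------------------------------------------


def _snapshot_from_rows(persons_rows, rx_rows, dx_rows, coverage, catalogue_codes):
    persons = pd.DataFrame(
        persons_rows,
        columns=[
            "person_id",
            "sex",
            "birth_year",
            "education_level",
            "emigration_date",
            "death_year",
            "death_month",
        ],
    )
    persons["emigration_date"] = pd.to_datetime(persons["emigration_date"])
    persons["death_year"] = persons["death_year"].astype("Int64")
    persons["death_month"] = persons["death_month"].astype("Int64")
    rx = pd.DataFrame(
        rx_rows, columns=["person_id", "atc_code", "dispense_date", "reimbursement_icd"]
    )
    rx["dispense_date"] = pd.to_datetime(rx["dispense_date"])
    dx = pd.DataFrame(dx_rows, columns=["person_id", "icd10_code", "visit_date"])
    dx["visit_date"] = pd.to_datetime(dx["visit_date"])
    catalogue = pd.DataFrame(
        {"atc_code": catalogue_codes, "drug_name": catalogue_codes}
    )
    return RegistrySnapshot(
        prescriptions=rx,
        persons=persons,
        diagnoses=dx,
        catalogue=catalogue,
        coverage=(pd.Timestamp(coverage[0]), pd.Timestamp(coverage[1])),
    )


def make_toy_fixture(name: str) -> RegistrySnapshot:
    """Hand-built micro-snapshots with documented expected behaviour.

    ``classify_basic``
        Ten persons, of whom exactly three satisfy the PD criteria: P01
        (four MAO-B fills), P02 (four levodopa fills with a G20
        reimbursement code), P03 (five MAO-B fills).  P04 has only three
        MAO-B fills; P05 has four levodopa fills but no reimbursement code;
        P06 would qualify but filled an antiparkinsonian drug during the
        exclusion year 2004 (prevalent case); P07-P10 fill unrelated drugs.
    ``washout_edge``
        One PD case whose target-drug fill lies exactly two years before a
        later fill of the same drug: the washout lookback is open at both
        ends (strictly after baseline - 2y, strictly before baseline), so
        the boundary fill is outside the window and the later initiation
        is eligible.
    ``empty``
        Zero persons.
    """
    person = lambda pid, by=1940: (pid, "M", by, "secondary", None, None, None)
    if name == "classify_basic":
        rx = []
        for i, d in enumerate(["2006-01-15", "2006-03-15", "2006-05-15", "2006-07-15"]):
            rx.append(("P01", "N04BD01", d, None))
        for d in ["2007-02-01", "2007-04-01", "2007-06-01", "2007-08-01"]:
            rx.append(("P02", "N04BA02", d, "G20"))
        for d in ["2005-05-01", "2005-06-01", "2005-07-01", "2005-08-01", "2005-09-01"]:
            rx.append(("P03", "N04BD02", d, None))
        for d in ["2006-01-01", "2006-02-01", "2006-03-01"]:
            rx.append(("P04", "N04BD01", d, None))
        for d in ["2006-01-01", "2006-02-01", "2006-03-01", "2006-04-01"]:
            rx.append(("P05", "N04BA02", d, None))
        rx.append(("P06", "N04BA02", "2004-06-01", None))
        for d in ["2006-01-01", "2006-02-01", "2006-03-01", "2006-04-01"]:
            rx.append(("P06", "N04BD01", d, None))
        for pid in ["P07", "P08", "P09", "P10"]:
            rx.append((pid, "A02BA02", "2006-05-01", None))
        dx = [("P01", "G20", "2006-08-01"), ("P01", "G20", "2006-10-01")]
        return _snapshot_from_rows(
            [person(f"P{i:02d}") for i in range(1, 11)],
            rx,
            dx,
            ("2004-01-01", "2010-12-31"),
            ["N04BD01", "N04BD02", "N04BA02", "A02BA02"],
        )
    if name == "washout_edge":
        # diagnosis 2006-04-01; pre-diagnosis target fill exactly two years
        # before the first post-diagnosis fill (the candidate baseline)
        rx = [
            ("P01", "N04BD01", d, None)
            for d in ["2006-01-01", "2006-02-01", "2006-03-01", "2006-04-01"]
        ]
        rx += [("P01", "A02BA02", "2005-03-10", None), ("P01", "A02BA02", "2007-03-10", None)]
        return _snapshot_from_rows(
            [person("P01")],
            rx,
            [],
            ("2004-01-01", "2012-12-31"),
            ["N04BD01", "A02BA02"],
        )
    if name == "empty":
        return _snapshot_from_rows(
            [], [], [], ("2004-01-01", "2010-12-31"), ["N04BD01", "N04BA02"]
        )
    raise KeyError(f"unknown toy fixture {name!r}")
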