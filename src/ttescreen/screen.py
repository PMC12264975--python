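"""Per-trial bootstrap inference and the drug-wide screen.

Each trial's risk difference and risk ratio get 95% percentile confidence
intervals and a p-value from a nonparametric bootstrap (persons resampled
with replacement from the pooled cohort; propensity weights and the pooled
logistic outcome model re-estimated inside every replicate).  Across the
screen, raw p-values are corrected with the Benjamini-Yekutieli step-up
procedure (valid under arbitrary dependence), and a drug is called a hit
when the risk difference favours the target (rd > 0), the nominal p-value
is below 0.05, and at least 90% of covariates are balanced after
weighting.

Bootstrap resampling is implemented through person multiplicity counts:
a replicate draws counts from a multinomial and reuses the precomputed
design matrices with count-scaled weights, which makes refitting both
models per replicate cheap.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from ._glm import ConvergenceError, SeparationError, fit_weighted_logit
from .covariates import (
    assemble_covariates,
    default_rxrisk_mapping,
    top_comorbidities,
)
from .estimation import (
    _COEF_NAMES,
    _time_design,
    compute_smd,
    encode_design,
    expand_person_months,
)
from .trials import (
    TrialCohort,
    TrialSpec,
    build_general_population_cohort,
    build_trial_cohort,
    enumerate_screen_drugs,
    post_diagnosis_fills,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapResult",
    "bootstrap_trial",
    "by_adjust",
    "run_screen",
    "run_sensitivity",
    "SENSITIVITY_VARIANTS",
]

SENSITIVITY_VARIANTS = (
    "adjust_unbalanced",
    "atc2_comparator",
    "age_lt_75_at_initiation",
    "rxrisk_below_median",
    "lag_12_months",
    "age_ge_65_at_diagnosis",
    "general_population",
)


@dataclasses.dataclass
class BootstrapResult:
    B: int
    seed: int
    rd: float  # point estimates, per 100 persons
    rr: float
    risk_target: float
    risk_control: float
    rd_samples: np.ndarray
    rr_samples: np.ndarray
    ci_rd: tuple[float, float]
    ci_rr: tuple[float, float]
    p_rd: float
    n_failed: int
    unreliable: bool


class _TrialEngine:
    """Precomputed design matrices for one trial, supporting fast refits.

    The propensity design is standardized once (an affine reparametrization,
    so fitted propensities are unaffected); each (re)fit supplies per-person
    multiplicity weights.  ``adjust_columns`` optionally adds unbalanced
    covariates as main effects to the outcome model, in which case per-arm
    risks are standardized over the weighted cohort.
    """

    def __init__(
        self,
        covariates: pd.DataFrame,
        ppt: pd.DataFrame,
        horizon: int,
        adjust_columns: list[str] | None = None,
    ):
        self.horizon = horizon
        self.arm = covariates["arm"].to_numpy(dtype=float)
        self.n = len(self.arm)
        enc = encode_design(covariates)
        live = enc.loc[:, enc.std(axis=0) > 0]
        self.ps_names = ["intercept"] + list(live.columns)
        z = (live - live.mean()) / live.std()
        self.Xps = np.column_stack([np.ones(self.n), z.to_numpy(dtype=float)])
        self.pidx = ppt["pidx"].to_numpy()
        self.y = ppt["event"].to_numpy(dtype=float)
        t = ppt["t"].to_numpy()
        arm_rows = ppt["arm"].to_numpy(dtype=float)
        self.Xpl = _time_design(t, arm_rows)
        self.pl_names = list(_COEF_NAMES)
        self.adjust = None
        if adjust_columns:
            cols = [c for c in adjust_columns if c in z.columns]
            if cols:
                self.adjust = z[cols].to_numpy(dtype=float)
                self.Xpl = np.column_stack([self.Xpl, self.adjust[self.pidx]])
                self.pl_names += list(cols)
        if self.adjust is None:
            # the outcome likelihood depends on rows only through
            # (t, arm, event); aggregating person-months into those cells
            # makes per-replicate refits O(#cells) instead of O(#rows)
            tmax = int(t.max()) if len(t) else 1
            self.cell_idx = ((t - 1) * 4 + arm_rows.astype(int) * 2
                             + self.y.astype(int))
            self.n_cells = 4 * tmax
            ct = np.repeat(np.arange(1, tmax + 1), 4)
            ca = np.tile([0.0, 0.0, 1.0, 1.0], tmax)
            self.cell_y = np.tile([0.0, 1.0, 0.0, 1.0], tmax)
            self.cell_X = _time_design(ct, ca)

    def weights(self, person_w: np.ndarray) -> np.ndarray:
        a = self.arm
        if len(np.unique(a[person_w > 0])) < 2:
            raise ValueError("a bootstrap replicate emptied one arm")
        fit = fit_weighted_logit(
            self.Xps, a, sample_weight=person_w, column_names=self.ps_names
        )
        e = fit.predict_proba(self.Xps)
        tolp = 1e-10
        if np.any((a == 1) & (e < tolp) & (person_w > 0)) or np.any(
            (a == 0) & (e > 1 - tolp) & (person_w > 0)
        ):
            raise SeparationError(self.ps_names[int(np.argmax(np.abs(fit.coef[1:]))) + 1])
        p1 = np.average(a, weights=person_w)
        return np.where(a == 1, p1 / e, (1 - p1) / (1 - e))

    def estimate(self, person_w: np.ndarray) -> dict:
        sw = self.weights(person_w)
        comb = sw * person_w
        row_w = comb[self.pidx]
        if self.adjust is None:
            cw = np.bincount(self.cell_idx, weights=row_w, minlength=self.n_cells)
            if (self.cell_y * cw).sum() == 0:
                raise ValueError("no events among resampled persons")
            fit = fit_weighted_logit(self.cell_X, self.cell_y, sample_weight=cw,
                                     column_names=self.pl_names)
        else:
            if self.y[row_w > 0].sum() == 0:
                raise ValueError("no events among resampled persons")
            fit = fit_weighted_logit(self.Xpl, self.y, sample_weight=row_w,
                                     column_names=self.pl_names)
        tgrid = np.arange(1.0, self.horizon + 1)
        b = fit.coef
        risks = {}
        for arm in (1, 0):
            logit_t = b[0] + b[1] * tgrid + b[2] * tgrid**2 + arm * (
                b[3] + b[4] * tgrid + b[5] * tgrid**2
            )
            if self.adjust is None:
                h = expit(logit_t)
                risks[arm] = 1.0 - np.cumprod(1.0 - h)
            else:
                offs = self.adjust @ b[6:]
                h = expit(offs[:, None] + logit_t[None, :])
                surv = np.cumprod(1.0 - h, axis=1)
                risks[arm] = np.average(1.0 - surv, axis=0, weights=comb)
        rt, rc = 100 * risks[1][-1], 100 * risks[0][-1]
        return {
            "risk_target": rt,
            "risk_control": rc,
            "rd": rc - rt,
            "rr": rt / rc,
            "coef": b,
            "curve_target": risks[1],
            "curve_control": risks[0],
            "sw": sw,
        }


def bootstrap_trial(
    covariates: pd.DataFrame,
    ppt: pd.DataFrame,
    B: int = 500,
    seed: int = 0,
    horizon: int = 96,
    p_method: str = "normal",
    adjust_columns: list[str] | None = None,
    max_failed_fraction: float = 0.1,
) -> BootstrapResult:
    """Nonparametric person-level bootstrap of one trial's rd and rr.

    Persons are resampled with replacement from the pooled cohort (arm
    sizes vary across replicates); weights and the outcome model are
    re-estimated per replicate.  CIs are 2.5/97.5 empirical percentiles.
    ``p_method='normal'`` (default) derives a two-sided p-value from the
    bootstrap standard deviation of rd around zero; ``'percentile'`` uses
    the sign-inversion p with granularity 2/B.  Failed replicates
    (separation, non-convergence, emptied arm, no events) are dropped and
    counted; exceeding ``max_failed_fraction`` flags the result unreliable.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    engine = _TrialEngine(covariates, ppt, horizon, adjust_columns)
    point = engine.estimate(np.ones(engine.n))
    rng = np.random.default_rng(seed)
    rd_s, rr_s = [], []
    n_failed = 0
    probs = np.full(engine.n, 1.0 / engine.n)
    for _ in range(B):
        counts = rng.multinomial(engine.n, probs).astype(float)
        try:
            est = engine.estimate(counts)
        except (SeparationError, ConvergenceError, ValueError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        rd_s.append(est["rd"])
        rr_s.append(est["rr"])
    rd_s, rr_s = np.asarray(rd_s), np.asarray(rr_s)
    if len(rd_s) < 2:
        raise RuntimeError("bootstrap produced fewer than 2 successful replicates")
    ci_rd = tuple(np.percentile(rd_s, [2.5, 97.5]))
    ci_rr = tuple(np.percentile(rr_s, [2.5, 97.5]))
    sd = float(rd_s.std(ddof=1))
    if p_method == "normal":
        p_rd = 2 * stats.norm.sf(abs(point["rd"]) / sd) if sd > 0 else float(point["rd"] == 0)
    elif p_method == "percentile":
        frac = min((rd_s <= 0).mean(), (rd_s >= 0).mean())
        p_rd = min(1.0, 2 * max(frac, 1.0 / len(rd_s)))
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return BootstrapResult(
        B=B,
        seed=seed,
        rd=point["rd"],
        rr=point["rr"],
        risk_target=point["risk_target"],
        risk_control=point["risk_control"],
        rd_samples=rd_s,
        rr_samples=rr_s,
        ci_rd=ci_rd,
        ci_rr=ci_rr,
        p_rd=float(p_rd),
        n_failed=n_failed,
        unreliable=n_failed > max_failed_fraction * B,
    )


def by_adjust(pvalues) -> np.ndarray:
    """Benjamini-Yekutieli FDR adjustment (step-up, arbitrary dependence).

    With m tests and c(m) = sum_{k<=m} 1/k, the adjusted value for the
    i-th order statistic is min_{j>=i} m*c(m)*p_(j)/j, capped at 1;
    returned in the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    raw = m * c_m * ranked / np.arange(1, m + 1)
    q = np.minimum(np.minimum.accumulate(raw[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def _derive_seed(master_seed: int, *keys) -> int:
    """Stable per-trial seed keyed by the target ATC, not list position."""
    digest = hashlib.sha256(":".join([str(master_seed), *map(str, keys)]).encode())
    return int.from_bytes(digest.digest()[:4], "big") % (2**31)


def _screen_population_initiations(snapshot, cases) -> pd.DataFrame:
    """All (person, drug) first post-diagnosis initiations across the PD
    population: the reference set for the top-20 comorbidities and the
    screen-wide comorbidity-index median."""
    rx = snapshot.prescriptions.merge(
        cases[["person_id", "diagnosis_date"]], on="person_id", how="inner"
    )
    rx = rx[rx["dispense_date"] >= rx["diagnosis_date"]]
    atc = rx["atc_code"].astype(str)
    rx = rx[(atc.str.len() == 7) & ~atc.str.startswith("N04")]
    idx = rx.groupby(["person_id", "atc_code"])["dispense_date"].idxmin()
    return rx.loc[idx].rename(columns={"dispense_date": "baseline_date"}).reset_index(
        drop=True
    )


def run_screen(
    snapshot,
    cases: pd.DataFrame | None,
    spec_defaults: dict | None = None,
    seed: int = 0,
    B: int = 500,
    horizon_months: int = 96,
    mapping: pd.DataFrame | None = None,
    targets: list[str] | None = None,
    top_k: int = 20,
    lag_months: int = 0,
    adjust_unbalanced: bool = False,
    row_filter=None,
    general_population: bool = False,
    gp_kwargs: dict | None = None,
    p_method: str = "normal",
    alpha: float = 0.05,
    balance_threshold: float = 0.9,
) -> pd.DataFrame:
    """Emulate one trial per drug and rank the screen.

    Returns one row per attempted trial with point estimates, bootstrap
    CIs, raw and BY-adjusted p-values, balance diagnostics and the hit
    flag (rd > 0, p < ``alpha``, balanced fraction >= ``balance_threshold``).
    Individual trial failures are recorded in the ``status`` column and
    never abort the screen.  Per-trial seeds derive from ``seed`` and the
    target ATC code, so results do not depend on enumeration order.
    """
    spec_defaults = dict(spec_defaults or {})
    if mapping is None:
        mapping = default_rxrisk_mapping()
    min_target = spec_defaults.get("min_target_persons", 100)

    if general_population:
        if targets is None:
            raise ValueError("general_population mode requires an explicit target list")
        pop_init = None
        categories = None
        post = None
    else:
        if targets is None:
            targets = enumerate_screen_drugs(snapshot, cases, min_target)
        pop_init = _screen_population_initiations(snapshot, cases)
        categories = top_comorbidities(pop_init, snapshot.prescriptions, mapping, k=top_k)
        post = post_diagnosis_fills(snapshot, cases)

    rxrisk_median = None
    if row_filter == "rxrisk_below_median":
        from .covariates import _lookback_categories, category_weights

        hits = _lookback_categories(pop_init, snapshot.prescriptions, mapping)
        w = category_weights(mapping)
        idx_sum = (
            hits.merge(w.rename("w"), left_on="category_id", right_index=True)
            .groupby("init_idx")["w"]
            .sum()
            .reindex(pop_init.index)
            .fillna(0.0)
        )
        rxrisk_median = float(idx_sum.median())

    rows = []
    for atc in sorted(targets):
        trial_seed = _derive_seed(seed, atc, "trial")
        boot_seed = _derive_seed(seed, atc, "boot")
        rec = {"target_atc": atc, "status": "ok"}
        try:
            spec = TrialSpec(target_atc=atc, seed=trial_seed, **spec_defaults)
            if general_population:
                trial = build_general_population_cohort(
                    snapshot, spec, **(gp_kwargs or {})
                )
            else:
                trial = build_trial_cohort(snapshot, cases, spec, _post=post)
            if not trial.feasible:
                rec["status"] = "infeasible"
                rows.append(rec)
                continue
            cov = assemble_covariates(trial, snapshot, mapping, categories=categories,
                                      k=top_k)
            if general_population and categories is None:
                # in this mode the reference population is the sampled cohort
                categories = cov.attrs["categories"]
            mask = _row_mask(cov, row_filter, rxrisk_median)
            if mask is not None:
                kept = trial.initiations.reset_index(drop=True)[mask]
                trial = TrialCohort(
                    trial.spec, kept.reset_index(drop=True), trial.exclusion_log,
                    feasible=(kept["arm"] == "target").sum() >= 2
                    and (kept["arm"] == "control").sum() >= 2,
                )
                if not trial.feasible:
                    rec["status"] = "infeasible_after_filter"
                    rows.append(rec)
                    continue
                cov = assemble_covariates(trial, snapshot, mapping,
                                          categories=categories, k=top_k)
            ppt = expand_person_months(trial, snapshot, horizon_months, lag_months)

            adjust_cols = None
            # balance is assessed at the point-estimate weights
            engine = _TrialEngine(cov, ppt, horizon_months)
            sw = engine.weights(np.ones(engine.n))
            smd_after, balanced = compute_smd(cov, weights=sw)
            if adjust_unbalanced:
                adjust_cols = list(smd_after.index[smd_after >= 0.1])
            boot = bootstrap_trial(
                cov, ppt, B=B, seed=boot_seed, horizon=horizon_months,
                p_method=p_method, adjust_columns=adjust_cols,
            )
            rec.update(
                n_target=int((cov["arm"] == 1).sum()),
                n_control=int((cov["arm"] == 0).sum()),
                risk_target=boot.risk_target,
                risk_control=boot.risk_control,
                rd=boot.rd,
                rr=boot.rr,
                nnt=int(np.floor(100.0 / boot.rd + 0.5)) if boot.rd > 0 else np.nan,
                ci_rd_lo=boot.ci_rd[0],
                ci_rd_hi=boot.ci_rd[1],
                ci_rr_lo=boot.ci_rr[0],
                ci_rr_hi=boot.ci_rr[1],
                p_rd=boot.p_rd,
                balanced_fraction=balanced,
                max_weight=float(sw.max()),
                n_boot_failed=boot.n_failed,
                unreliable=boot.unreliable,
            )
        except (SeparationError, ConvergenceError, ValueError, RuntimeError) as exc:
            rec["status"] = f"failed: {exc}"
            logger.warning("trial %s failed: %s", atc, exc)
        rows.append(rec)

    out = pd.DataFrame(rows, columns=None if rows else ["target_atc", "status"])
    done = (
        (out["status"] == "ok") & out.get("p_rd", pd.Series(dtype=float)).notna()
        if len(out)
        else pd.Series(dtype=bool)
    )
    out["p_by"] = np.nan
    out["hit"] = False
    if done.any():
        out.loc[done, "p_by"] = by_adjust(out.loc[done, "p_rd"].to_numpy())
        out["hit"] = (
            done
            & (out["rd"] > 0)
            & (out["p_rd"] < alpha)
            & (out["balanced_fraction"] >= balance_threshold)
        )
        out = out.sort_values(["hit", "p_rd"], ascending=[False, True], kind="stable")
    return out.reset_index(drop=True)


def _row_mask(cov: pd.DataFrame, row_filter, rxrisk_median):
    if row_filter is None:
        return None
    if row_filter == "age_lt_75_at_initiation":
        return (cov["age_at_initiation"] < 75).to_numpy()
    if row_filter == "age_ge_65_at_diagnosis":
        return (cov["age_at_diagnosis"] >= 65).to_numpy()
    if row_filter == "rxrisk_below_median":
        return (cov["rxrisk_index"] < rxrisk_median).to_numpy()
    raise ValueError(f"unknown row filter {row_filter!r}")


def run_sensitivity(
    snapshot,
    cases,
    variant: str,
    spec_defaults: dict | None = None,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Re-run the screen with one protocol modification.

    Variants: ``adjust_unbalanced`` (post-weighting unbalanced covariates
    added to the outcome model), ``atc2_comparator`` (controls from the
    same ATC level-2 group), ``age_lt_75_at_initiation``,
    ``rxrisk_below_median`` (strict '<' against the screen-wide median),
    ``lag_12_months`` (one-year lag between initiation and death),
    ``age_ge_65_at_diagnosis``, ``general_population``.
    """
    if variant not in SENSITIVITY_VARIANTS:
        raise ValueError(f"unknown sensitivity variant {variant!r}")
    spec_defaults = dict(spec_defaults or {})
    if variant == "adjust_unbalanced":
        kwargs["adjust_unbalanced"] = True
    elif variant == "atc2_comparator":
        spec_defaults["comparator_level"] = 2
    elif variant in ("age_lt_75_at_initiation", "age_ge_65_at_diagnosis",
                     "rxrisk_below_median"):
        kwargs["row_filter"] = variant
    elif variant == "lag_12_months":
        kwargs["lag_months"] = 12
    elif variant == "general_population":
        kwargs["general_population"] = True
    return run_screen(snapshot, cases, spec_defaults, seed=seed, **kwargs)
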