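"""Estimation core for one emulated trial.

Stabilized inverse-probability-of-treatment weights from a main-effects
logistic propensity model; standardized-mean-difference balance
diagnostics; person-month expansion of follow-up; a weighted pooled
logistic regression of the monthly death indicator on
``{1, t, t^2, A, A*t, A*t^2}`` (a discrete-time hazard model with a full
separate time trend per arm); cumulative risk via the product-limit
identity; risk difference / risk ratio / number needed to treat; and
IPTW-weighted Kaplan-Meier survival curves.

The two model-fitting stages are exposed as scikit-learn style estimators
(:class:`StabilizedIPTW`, :class:`PooledLogisticRisk`); the module-level
functions are thin wrappers over them.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

from ._glm import ConvergenceError, SeparationError, fit_weighted_logit
from .registry import RegistrySnapshot
from .trials import TrialCohort

__all__ = [
    "StabilizedIPTW",
    "PooledLogisticRisk",
    "WeightedCohort",
    "RiskEstimate",
    "encode_design",
    "estimate_stabilized_weights",
    "compute_smd",
    "expand_person_months",
    "fit_pooled_logistic",
    "predict_risk_curve",
    "effect_measures",
    "iptw_km",
]

_META_COLS = ("person_id", "arm")


def encode_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode the covariate table for modelling and balance checks.

    Categorical columns (``sex``, ``education``) are dummy-coded with the
    first level dropped; continuous columns pass through.  ``person_id``
    and ``arm`` are excluded.  Column order is deterministic.
    """
    cols = covariates.drop(columns=[c for c in _META_COLS if c in covariates.columns])
    cat = cols.select_dtypes(include=["object", "category"]).columns
    out = pd.get_dummies(cols, columns=list(cat), drop_first=True, dtype=float)
    return out.astype(float)


class StabilizedIPTW(BaseEstimator):
    """Stabilized inverse-probability-of-treatment weighting.

    Fits a main-effects logistic propensity model of arm on all encoded
    covariates and forms stabilized weights ``sw = P(A=a) / P(A=a | L)``,
    with the numerator the (weighted) marginal arm frequency.  Constant
    covariate columns are dropped from the model (recorded in
    ``dropped_columns_``).  Optional percentile truncation of the weights
    is off by default; the maximum weight is always recorded.

    Attributes (after :meth:`fit`): ``propensity_``, ``stabilized_weights_``,
    ``coef_``, ``feature_names_``, ``dropped_columns_``, ``max_weight_``.
    """

    def __init__(
        self,
        tol: float = 1e-8,
        max_iter: int = 100,
        truncate_percentile: float | None = None,
    ):
        self.tol = tol
        self.max_iter = max_iter
        self.truncate_percentile = truncate_percentile

    def fit(self, X: pd.DataFrame, a, sample_weight=None):
        """``X``: covariate table (raw or pre-encoded); ``a``: 0/1 arm."""
        a = np.asarray(a, dtype=float)
        if len(np.unique(a[~np.isnan(a)])) < 2:
            raise ValueError("both arms must be nonempty to estimate weights")
        enc = encode_design(X) if X.select_dtypes(include="object").shape[1] else X
        enc = enc.drop(columns=[c for c in _META_COLS if c in enc.columns]).astype(float)
        w = np.ones(len(a)) if sample_weight is None else np.asarray(sample_weight, float)

        live = enc.loc[:, enc.std(axis=0) > 0]
        self.dropped_columns_ = [c for c in enc.columns if c not in live.columns]
        self.feature_names_ = ["intercept"] + list(live.columns)
        # standardize internally for IRLS stability; propensities unaffected
        mu, sd = live.mean(axis=0).to_numpy(), live.std(axis=0).to_numpy()
        Z = (live.to_numpy() - mu) / sd
        Xd = np.column_stack([np.ones(len(a)), Z])
        fit = fit_weighted_logit(
            Xd, a, sample_weight=w, tol=self.tol, max_iter=self.max_iter,
            column_names=self.feature_names_,
        )
        e = fit.predict_proba(Xd)
        tolp = 1e-10
        if np.any((a == 1) & (e < tolp)) or np.any((a == 0) & (e > 1 - tolp)):
            raise SeparationError(self.feature_names_[int(np.argmax(np.abs(fit.coef[1:]))) + 1])
        p1 = np.average(a, weights=w)
        sw = np.where(a == 1, p1 / e, (1 - p1) / (1 - e))
        if self.truncate_percentile is not None:
            hi = np.percentile(sw, self.truncate_percentile)
            sw = np.minimum(sw, hi)
        self.propensity_ = e
        self.numerator_ = np.where(a == 1, p1, 1 - p1)
        self.stabilized_weights_ = sw
        self.max_weight_ = float(sw.max())
        self.coef_ = fit.coef
        self.converged_ = fit.converged
        return self

    def fit_transform(self, X, a, sample_weight=None) -> np.ndarray:
        return self.fit(X, a, sample_weight=sample_weight).stabilized_weights_


@dataclasses.dataclass
class WeightedCohort:
    covariates: pd.DataFrame
    propensity: np.ndarray
    sw: np.ndarray
    smd_before: pd.Series
    smd_after: pd.Series
    balanced_fraction: float
    max_weight: float


def compute_smd(
    covariates: pd.DataFrame, arm=None, weights=None, threshold: float = 0.1
) -> tuple[pd.Series, float]:
    """Per-covariate standardized mean differences and the balanced share.

    SMD = |weighted mean difference| / sqrt((v_target + v_control)/2) with
    ``v`` the *unweighted* arm variances (population form).  A column with
    zero pooled variance reports SMD 0 when the means agree and ``inf``
    otherwise.  Returns (SMD series over encoded columns, fraction with
    SMD < ``threshold``).
    """
    if arm is None:
        arm = covariates["arm"]
    a = np.asarray(arm, dtype=float)
    enc = encode_design(covariates)
    w = np.ones(len(a)) if weights is None else np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    X = enc.to_numpy(dtype=float)
    t, c = a == 1, a == 0
    mt = np.average(X[t], axis=0, weights=w[t])
    mc = np.average(X[c], axis=0, weights=w[c])
    vt = X[t].var(axis=0)
    vc = X[c].var(axis=0)
    pooled = np.sqrt((vt + vc) / 2.0)
    diff = np.abs(mt - mc)
    diff[diff < 1e-10] = 0.0  # float noise on constant columns is not imbalance
    with np.errstate(divide="ignore", invalid="ignore"):
        smd = np.where(pooled > 0, diff / pooled, np.where(diff > 0, np.inf, 0.0))
    series = pd.Series(smd, index=enc.columns, name="smd")
    return series, float((series < threshold).mean())


def estimate_stabilized_weights(
    covariates: pd.DataFrame, balance_threshold: float = 0.1, **iptw_kwargs
) -> WeightedCohort:
    """Fit stabilized weights and report balance before/after weighting."""
    arm = covariates["arm"].to_numpy()
    model = StabilizedIPTW(**iptw_kwargs)
    sw = model.fit_transform(covariates, arm)
    before, _ = compute_smd(covariates, arm, None, balance_threshold)
    after, frac = compute_smd(covariates, arm, sw, balance_threshold)
    return WeightedCohort(
        covariates, model.propensity_, sw, before, after, frac, model.max_weight_
    )


def _elapsed_months(later: pd.Series, earlier: pd.Series) -> np.ndarray:
    """Whole months elapsed from ``earlier`` to ``later`` (floor)."""
    lm = later.dt.year * 12 + later.dt.month
    em = earlier.dt.year * 12 + earlier.dt.month
    m = (lm.to_numpy() - em.to_numpy()).astype(int)
    m -= (later.dt.day.to_numpy() < earlier.dt.day.to_numpy()).astype(int)
    return m


def expand_person_months(
    trial: TrialCohort,
    snapshot: RegistrySnapshot,
    horizon_months: int = 96,
    lag_months: int = 0,
) -> pd.DataFrame:
    """One row per person-month at risk: person_id, pidx, t, arm, event.

    Month ``t`` (1-based) spans the half-open interval
    [baseline + (t-1) months, baseline + t months).  A death in month ``d``
    yields rows 1..d with the event flagged on the last; censoring
    (migration, administrative end, or the horizon) yields fully observed
    months only.  With ``lag_months = L``, deaths in months <= L are
    treated as censored at L and follow-up starts at month L+1.
    """
    init = trial.initiations.reset_index(drop=True)
    pid = init["person_id"]
    persons = snapshot.persons.set_index("person_id")
    dd = snapshot.death_dates().reindex(pid)
    emig = persons["emigration_date"].reindex(pid)
    baseline = init["baseline_date"]

    if (dd.to_numpy() < baseline.to_numpy()).any():
        bad = pid[(dd.to_numpy() < baseline.to_numpy())].iloc[0]
        raise ValueError(f"death before baseline for person {bad!r}")

    admin = pd.Series(snapshot.coverage[1], index=pid.index)
    cens_date = pd.concat(
        [admin, pd.Series(emig.to_numpy(), index=pid.index)], axis=1
    ).min(axis=1)
    t_cens = np.minimum(
        _elapsed_months(pd.to_datetime(cens_date), baseline), horizon_months
    )
    has_death = dd.notna().to_numpy()
    t_death = np.full(len(pid), np.iinfo(np.int64).max)
    if has_death.any():
        t_death[has_death] = (
            _elapsed_months(pd.Series(dd.to_numpy()[has_death]),
                            baseline[has_death].reset_index(drop=True)) + 1
        )
    event = has_death & (t_death <= t_cens)
    t_end = np.where(event, t_death, np.maximum(t_cens, 0)).astype(int)

    t_start = np.full(len(pid), 1 + lag_months)
    if lag_months:
        # early deaths become censorings at the lag; they contribute no rows
        early = event & (t_death <= lag_months)
        event = event & ~early
        t_end = np.where(early, lag_months, t_end)
    n_rows = np.maximum(t_end - t_start + 1, 0)
    owners = np.repeat(np.arange(len(pid)), n_rows)
    t = (
        np.arange(n_rows.sum())
        - np.repeat(np.concatenate(([0], np.cumsum(n_rows)[:-1])), n_rows)
        + t_start[owners]
    )
    is_last = np.concatenate([(np.diff(owners) != 0), [True]]) if len(owners) else np.array([], bool)
    ppt = pd.DataFrame(
        {
            "person_id": pid.to_numpy()[owners],
            "pidx": owners,
            "t": t,
            "arm": (init["arm"] == "target").astype(int).to_numpy()[owners],
            "event": (is_last & event[owners]).astype(int),
        }
    )
    ppt.attrs["horizon_months"] = horizon_months
    ppt.attrs["lag_months"] = lag_months
    ppt.attrs["n_persons"] = len(pid)
    return ppt


def _time_design(t: np.ndarray, a: np.ndarray) -> np.ndarray:
    tt = t.astype(float)
    return np.column_stack([np.ones(len(t)), tt, tt**2, a, a * tt, a * tt**2])


_COEF_NAMES = ["beta0", "beta1_t", "beta2_t2", "beta3_a", "beta4_at", "beta5_at2"]


class PooledLogisticRisk(BaseEstimator):
    """Discrete-time hazard model: weighted pooled logistic regression.

    The monthly event indicator is regressed on linear and quadratic time
    and their interactions with the intervention arm.  Per-arm cumulative
    risk follows from the product-limit identity
    ``R_a(t) = 1 - prod_{k<=t} (1 - h_a(k))`` with
    ``h_a(k) = expit(b0 + b1 k + b2 k^2 + a (b3 + b4 k + b5 k^2))``.

    Attributes: ``coef_`` (length 6, arm terms zero when the arm column is
    degenerate), ``arm_dropped_``, ``converged_``.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, ppt: pd.DataFrame, sample_weight=None):
        t = ppt["t"].to_numpy()
        a = ppt["arm"].to_numpy(dtype=float)
        y = ppt["event"].to_numpy(dtype=float)
        w = sample_weight
        if w is None:
            w = ppt["sw"].to_numpy(dtype=float) if "sw" in ppt.columns else np.ones(len(ppt))
        live = np.asarray(w, dtype=float) > 0
        if y[live].sum() == 0:
            raise ValueError("no events in the person-period table")
        self.arm_dropped_ = len(np.unique(a[live])) < 2
        X = _time_design(t, a)
        names = list(_COEF_NAMES)
        if self.arm_dropped_:
            X, names = X[:, :3], names[:3]
        fit = fit_weighted_logit(
            X, y, sample_weight=w, tol=self.tol, max_iter=self.max_iter, column_names=names
        )
        coef = np.zeros(6)
        coef[: len(fit.coef)] = fit.coef
        self.coef_ = coef
        self.converged_ = fit.converged
        self.deviance_ = fit.deviance
        return self

    def predict_hazard(self, arm: int, horizon: int = 96) -> np.ndarray:
        t = np.arange(1, horizon + 1, dtype=float)
        b = self.coef_
        return expit(b[0] + b[1] * t + b[2] * t**2 + arm * (b[3] + b[4] * t + b[5] * t**2))

    def predict_risk_curve(self, arm: int, horizon: int = 96) -> np.ndarray:
        return 1.0 - np.cumprod(1.0 - self.predict_hazard(arm, horizon))


def fit_pooled_logistic(ppt: pd.DataFrame, sample_weight=None, **kwargs) -> PooledLogisticRisk:
    """Thin wrapper: fit :class:`PooledLogisticRisk` on a person-period table."""
    return PooledLogisticRisk(**kwargs).fit(ppt, sample_weight=sample_weight)


def predict_risk_curve(coefficients, arm: int, horizon: int = 96) -> np.ndarray:
    """Cumulative risk curve from raw coefficients (beta0..beta5)."""
    model = PooledLogisticRisk()
    model.coef_ = np.asarray(coefficients, dtype=float)
    model.arm_dropped_ = False
    return model.predict_risk_curve(arm, horizon)


def effect_measures(risk_target_96: float, risk_control_96: float) -> dict:
    """RD / RR / NNT from per-100-person cumulative risks.

    rd = control - target (per 100); rr = target / control;
    nnt = round(100 / rd) reported only when rd > 0.
    """
    if not (0 < risk_control_96 <= 100) or not (0 < risk_target_96 <= 100):
        raise ValueError("risks must be in (0, 100] per 100 persons")
    rd = risk_control_96 - risk_target_96
    rr = risk_target_96 / risk_control_96
    nnt = int(np.floor(100.0 / rd + 0.5)) if rd > 0 else None
    return {"rd": rd, "rr": rr, "nnt": nnt}


def iptw_km(ppt: pd.DataFrame, weights=None) -> pd.DataFrame:
    """Weighted product-limit survival per arm.

    Risk sets and event counts are weighted by the stabilized weights
    (column ``sw``; unit weights reproduce the ordinary Kaplan-Meier
    estimator).  Returns a DataFrame indexed by month with columns
    ``survival_target`` and ``survival_control`` (values in [0,1],
    nonincreasing; months with an empty risk set carry the last value
    forward).
    """
    w = weights
    if w is None:
        w = ppt["sw"].to_numpy(dtype=float) if "sw" in ppt.columns else np.ones(len(ppt))
    w = np.asarray(w, dtype=float)
    horizon = int(ppt.attrs.get("horizon_months", ppt["t"].max() if len(ppt) else 0))
    out = {}
    for arm, label in ((1, "survival_target"), (0, "survival_control")):
        sel = ppt["arm"].to_numpy() == arm
        t = ppt["t"].to_numpy()[sel]
        ev = ppt["event"].to_numpy()[sel] * w[sel]
        at = np.bincount(t, weights=w[sel], minlength=horizon + 1)[1:]
        d = np.bincount(t, weights=ev, minlength=horizon + 1)[1:]
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = np.where(at > 0, 1.0 - d / np.maximum(at, 1e-300), 1.0)
        out[label] = np.cumprod(factor)
    return pd.DataFrame(out, index=pd.RangeIndex(1, horizon + 1, name="month"))


@dataclasses.dataclass
class RiskEstimate:
    """Point estimates for one trial at the risk horizon."""

    risk_target: float  # per 100 persons
    risk_control: float
    rd: float
    rr: float
    nnt: int | None
    coefficients: np.ndarray
    curve_target: np.ndarray
    curve_control: np.ndarray
    balanced_fraction: float
    max_weight: float
    n_target: int
    n_control: int


def estimate_trial_risks(
    covariates: pd.DataFrame,
    ppt: pd.DataFrame,
    horizon_months: int = 96,
    **iptw_kwargs,
) -> tuple[RiskEstimate, WeightedCohort]:
    """Weights + pooled logistic + effect measures for one trial."""
    wc = estimate_stabilized_weights(covariates, **iptw_kwargs)
    sw_rows = wc.sw[ppt["pidx"].to_numpy()]
    model = PooledLogisticRisk().fit(ppt, sample_weight=sw_rows)
    ct = model.predict_risk_curve(1, horizon_months)
    cc = model.predict_risk_curve(0, horizon_months)
    eff = effect_measures(100 * ct[-1], 100 * cc[-1])
    est = RiskEstimate(
        risk_target=100 * ct[-1],
        risk_control=100 * cc[-1],
        rd=eff["rd"],
        rr=eff["rr"],
        nnt=eff["nnt"],
        coefficients=model.coef_,
        curve_target=ct,
        curve_control=cc,
        balanced_fraction=wc.balanced_fraction,
        max_weight=wc.max_weight,
        n_target=int((covariates["arm"] == 1).sum()),
        n_control=int((covariates["arm"] == 0).sum()),
    )
    return est, wc
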