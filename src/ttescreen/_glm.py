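"""Weighted logistic regression via iteratively reweighted least squares.

Shared by the propensity model and the pooled logistic outcome model.  The
convergence rule is a relative deviance change below ``tol`` (default 1e-8,
at most 100 iterations), with step halving when a step increases the
deviance.  Quasi-complete separation — fitted probabilities pinned to 0/1
on the respective outcome classes — raises :class:`SeparationError` naming
the covariate with the largest diverging coefficient.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import expit

__all__ = ["LogitFit", "SeparationError", "ConvergenceError", "fit_weighted_logit"]

_EPS = 1e-12


class SeparationError(RuntimeError):
    def __init__(self, covariate: str):
        self.covariate = covariate
        super().__init__(f"quasi-complete separation; separating covariate: {covariate}")


class ConvergenceError(RuntimeError):
    def __init__(self, trace: list[float]):
        self.trace = trace
        super().__init__(
            f"IRLS did not converge in {len(trace)} iterations; deviance trace tail "
            f"{trace[-3:]}"
        )


@dataclasses.dataclass
class LogitFit:
    coef: np.ndarray
    converged: bool
    n_iter: int
    deviance: float
    column_names: list[str]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return expit(np.asarray(X, dtype=float) @ self.coef)


def _deviance(y, mu, w):
    mu = np.clip(mu, _EPS, 1 - _EPS)
    return -2.0 * np.sum(w * (y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def fit_weighted_logit(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    column_names: list[str] | None = None,
) -> LogitFit:
    """Maximum-likelihood weighted logistic fit.

    ``X`` must include any desired intercept column.  ``sample_weight``
    scales each observation's log-likelihood contribution (frequency or
    importance weights); rows with zero weight are inert.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    if (w < 0).any():
        raise ValueError("sample_weight must be nonnegative")
    names = column_names or [f"x{j}" for j in range(X.shape[1])]

    beta = np.zeros(X.shape[1])
    eta = X @ beta
    mu = expit(eta)
    dev = _deviance(y, mu, w)
    trace = [dev]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        wls = w * mu * (1 - mu)
        # guard against a numerically singular information matrix
        XtWX = (X * wls[:, None]).T @ X
        XtWz = X.T @ (w * (y - mu))
        try:
            step = np.linalg.solve(XtWX + 1e-10 * np.eye(X.shape[1]), XtWz)
        except np.linalg.LinAlgError:
            _raise_separation_or_singular(X, y, w, mu, beta, names)
        new_beta = beta + step
        new_dev = _deviance(y, expit(X @ new_beta), w)
        # step halving keeps the deviance monotone
        halvings = 0
        while new_dev > dev * (1 + 1e-12) + 1e-12 and halvings < 20:
            step /= 2.0
            new_beta = beta + step
            new_dev = _deviance(y, expit(X @ new_beta), w)
            halvings += 1
        beta, dev_prev, dev = new_beta, dev, new_dev
        mu = expit(X @ beta)
        trace.append(dev)
        if abs(dev_prev - dev) <= tol * (abs(dev) + tol):
            converged = True
            break
        if np.max(np.abs(beta)) > 1e3:
            _raise_separation_or_singular(X, y, w, mu, beta, names)
    if not converged:
        _maybe_separation(X, y, w, mu, beta, names)
        raise ConvergenceError(trace)
    _maybe_separation(X, y, w, mu, beta, names)
    return LogitFit(beta, converged, it, dev, list(names))


def _maybe_separation(X, y, w, mu, beta, names):
    live = w > 0
    if not live.any():
        return
    p = mu[live]
    yy = y[live]
    tol = 1e-8
    pinned = ((yy == 1) & (p > 1 - tol)) | ((yy == 0) & (p < tol))
    if pinned.all() and len(p) > 0:
        _raise_separation_or_singular(X, y, w, mu, beta, names)


def _raise_separation_or_singular(X, y, w, mu, beta, names):
    # the separating covariate is the one whose coefficient diverges fastest;
    # report the largest standardized coefficient among non-intercept columns
    sd = X.std(axis=0)
    score = np.abs(beta) * np.where(sd > 0, sd, 0.0)
    j = int(np.argmax(score))
    raise SeparationError(names[j])
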