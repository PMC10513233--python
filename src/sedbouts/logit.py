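"""Logistic regression of group label on sedentary-bout features.

Fits ``ln(p/(1-p)) = b0 + b1*x1 + ... + b5*x5`` by maximum likelihood
(iteratively reweighted least squares) with the label coded 0 = acute
insomnia, 1 = healthy control, features in raw minutes/day and no
interactions.  Standard errors come from the inverse observed information
and p-values are two-sided Wald tests against the normal reference.
Negative slopes therefore mean the probability of being labelled healthy
falls as time in that bout bin rises.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

MAX_ITER = 100
TOL = 1e-8
SEPARATION_NORM = 1e4

DEFAULT_TERMS = (
    "Intercept",
    "sed_bouts_1_3",
    "sed_bouts_4_5",
    "sed_bouts_6_30",
    "sed_bouts_31_60",
    "sed_bouts_gt60",
)


class SeparationWarning(UserWarning):
    """Raised (as a warning) when the labels are perfectly separable."""


@dataclass
class LogisticModel:
    beta: np.ndarray  # intercept first
    se: np.ndarray
    p: np.ndarray
    converged: bool
    n_iter: int
    terms: tuple[str, ...]
    log_likelihood: float


def _log_likelihood(X1: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X1 @ beta
    # log(1 + exp(eta)) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    terms: tuple[str, ...] | None = None,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
) -> LogisticModel:
    """Maximum-likelihood logistic fit by IRLS.

    ``X`` is subjects x features (an intercept column is added
    internally); ``y`` holds binary labels with 1 = healthy control.
    Convergence is declared when the largest absolute coefficient change
    drops below ``tol``.  Perfect separation is detected by a diverging
    coefficient norm; the model is then flagged non-converged and the
    last iterate reported with a :class:`SeparationWarning`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional (subjects x features)")
    if len(y) != X.shape[0]:
        raise ValueError("X and y must have the same number of rows")
    if np.any(np.isnan(X)) or np.any(np.isnan(y)):
        raise ValueError("missing values are not allowed")
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError("y must be coded 0/1")
    if classes.size < 2:
        raise ValueError("degenerate labels: both classes must be present")

    n, k = X.shape
    X1 = np.column_stack([np.ones(n), X])
    if terms is None:
        terms = DEFAULT_TERMS if k == 5 else tuple(
            ["Intercept"] + [f"x{i + 1}" for i in range(k)]
        )
    if len(terms) != k + 1:
        raise ValueError("need one term name per coefficient incl. intercept")

    beta = np.zeros(k + 1)
    converged = False
    separated = False
    n_iter = 0
    ll = _log_likelihood(X1, y, beta)
    for n_iter in range(1, max_iter + 1):
        eta = X1 @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        if np.max(np.abs(y - mu)) < 1e-6:  # every label perfectly predicted
            separated = True
            break
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        WX = X1 * w[:, None]
        try:
            beta_new = np.linalg.solve(X1.T @ WX, X1.T @ (w * z))
        except np.linalg.LinAlgError:
            separated = True
            break
        # step-halving keeps the iterates on a likelihood-increasing path,
        # which matters when the labels are (nearly) separable
        direction = beta_new - beta
        ll_new = _log_likelihood(X1, y, beta_new)
        halvings = 0
        while ll_new < ll - 1e-12 and halvings < 30:
            direction *= 0.5
            beta_new = beta + direction
            ll_new = _log_likelihood(X1, y, beta_new)
            halvings += 1
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        ll = ll_new
        if np.linalg.norm(beta) > SEPARATION_NORM:
            separated = True
            break
        if step < tol:
            converged = True
            break
    if separated:
        warnings.warn(
            "perfect separation detected; estimates reported at last iterate",
            SeparationWarning,
            stacklevel=2,
        )

    eta = X1 @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    info = X1.T @ (X1 * w[:, None])
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * sps.norm.sf(np.abs(zstat))

    return LogisticModel(
        beta=beta,
        se=se,
        p=p,
        converged=converged,
        n_iter=n_iter,
        terms=tuple(terms),
        log_likelihood=_log_likelihood(X1, y, beta),
    )


def coefficient_table(model: LogisticModel) -> pd.DataFrame:
    """Coefficient report: term, estimate, SE, p in fixed order.

    Values are kept at full precision; display rounding is the report
    layer's job.
    """
    return pd.DataFrame(
        {
            "term": list(model.terms),
            "estimate": model.beta,
            "se": model.se,
            "p": model.p,
        }
    )
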