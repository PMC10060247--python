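"""Cross-validated L1-penalized logistic regression shared by the risk and
propensity models.

The fit standardizes covariates to unit variance internally, builds a
50-point logarithmic penalty grid from ``lambda_max`` (the smallest penalty
that zeroes every coefficient) down by a factor ``1e-4``, selects the penalty
minimizing mean k-fold cross-validated deviance, refits on the full data, and
reports coefficients on the original covariate scale.  Deterministic given
``seed`` (fold assignment is the only stochastic ingredient).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .errors import DataError


@dataclass
class LassoLogisticFit:
    intercept: float
    coef: np.ndarray          # original covariate scale
    lambda_: float            # selected per-observation L1 penalty
    lambdas: np.ndarray       # full grid, descending
    cv_deviance: np.ndarray   # mean validation deviance per grid point
    n_nonzero: int


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _fit_at(Z: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    # sklearn's liblinear objective is C * sum(logloss) + ||w||_1, so the
    # per-observation penalty lambda maps to C = 1 / (n * lambda).
    C = 1.0 / (len(y) * lam)
    # liblinear penalizes the intercept via the appended constant feature;
    # a large intercept_scaling makes that penalty negligible.
    clf = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", tol=1e-8, max_iter=5000,
        intercept_scaling=1000.0, random_state=0,
    )
    clf.fit(Z, y)
    return clf


def lasso_logistic_cv(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 3,
    seed: int = 0,
    n_lambdas: int = 50,
    lambda_min_ratio: float = 1e-4,
) -> LassoLogisticFit:
    """Fit L1 logistic regression with k-fold CV penalty selection."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DataError("no_events", "outcome has a single class")
    if counts.min() < folds:
        raise DataError(
            "degenerate_folds",
            f"minority class has {counts.min()} members, fewer than {folds} folds",
        )

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd_safe

    ybar = y.mean()
    lam_max = np.abs(Z.T @ (y - ybar)).max() / n
    if lam_max <= 0:  # all covariates constant
        lam_max = 1e-3
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.zeros(n_lambdas)
    for train, test in skf.split(Z, y):
        for i, lam in enumerate(lambdas):
            clf = _fit_at(Z[train], y[train], lam)
            prob = clf.predict_proba(Z[test])[:, 1]
            dev[i] += _binomial_deviance(y[test], prob)
    dev /= n

    best = int(np.argmin(dev))
    lam_hat = float(lambdas[best])
    clf = _fit_at(Z, y, lam_hat)
    coef_std = clf.coef_.ravel()
    coef = np.where(sd > 0, coef_std / sd_safe, 0.0)
    intercept = float(clf.intercept_[0] - np.sum(coef * mu))
    return LassoLogisticFit(
        intercept=intercept,
        coef=coef,
        lambda_=lam_hat,
        lambdas=lambdas,
        cv_deviance=dev,
        n_nonzero=int(np.count_nonzero(coef)),
    )


def expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))
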