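"""Outcome-risk prediction: LASSO risk model, discrimination, risk groups.

The risk model predicts the probability of the outcome within the
time-at-risk horizon.  It is fitted on the 1:1 propensity-matched subset of
the pooled treatment and comparator cohorts, so that neither arm dominates
the fit and no spurious treatment interactions are introduced.  Predicted
risks then partition the population into risk groups (fixed thresholds such
as 1% / 1.5%, or risk quantiles).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._lasso import lasso_logistic_cv, expit
from .cohort import StudyPopulation, ARM_TARGET, ARM_COMPARATOR
from .errors import DataError


@dataclass
class RiskModel:
    """Sparse penalized logistic model for outcome risk within the horizon."""

    intercept: float
    coefficients: pd.Series      # nonzero entries only, indexed by covariate id
    lambda_: float
    outcome_id: str
    horizon: int
    folds: int
    seed: int
    fit_population: str = "matched"
    cv_deviance: np.ndarray | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "coefficients": {k: float(v) for k, v in self.coefficients.items()},
                "lambda": self.lambda_,
                "outcome_id": self.outcome_id,
                "horizon": self.horizon,
                "folds": self.folds,
                "seed": self.seed,
                "fit_population": self.fit_population,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "RiskModel":
        d = json.loads(text)
        return cls(
            intercept=d["intercept"],
            coefficients=pd.Series(d["coefficients"], dtype=float),
            lambda_=d["lambda"],
            outcome_id=d["outcome_id"],
            horizon=d["horizon"],
            folds=d["folds"],
            seed=d["seed"],
            fit_population=d.get("fit_population", "matched"),
        )


def fit_risk_model(
    pop: StudyPopulation,
    outcome_id: str,
    subject_ids=None,
    folds: int = 3,
    seed: int = 0,
    n_lambdas: int = 50,
    lambda_min_ratio: float = 1e-4,
) -> RiskModel:
    """Fit the LASSO outcome-risk model on ``subject_ids`` (the matched set).

    The binary label is "event within the horizon"; subjects excluded for a
    prior outcome do not contribute.  Penalty selection by ``folds``-fold
    cross-validated deviance on a logarithmic grid; deterministic given
    ``seed``.
    """
    aset = pop.analysis_set(outcome_id, subject_ids=subject_ids)
    if aset["event"].sum() == 0:
        raise DataError("no_events", f"no events for outcome {outcome_id!r} in fit set")
    X = pop.covariates.loc[aset.index]
    fit = lasso_logistic_cv(
        X.to_numpy(), aset["event"].to_numpy(), folds=folds, seed=seed,
        n_lambdas=n_lambdas, lambda_min_ratio=lambda_min_ratio,
    )
    coefs = pd.Series(fit.coef, index=X.columns)
    return RiskModel(
        intercept=fit.intercept,
        coefficients=coefs[coefs != 0.0],
        lambda_=fit.lambda_,
        outcome_id=outcome_id,
        horizon=pop.spec.horizon,
        folds=folds,
        seed=seed,
        cv_deviance=fit.cv_deviance,
    )


def predict_risk(model: RiskModel, pop: "StudyPopulation | pd.DataFrame") -> pd.Series:
    """Per-subject predicted risk ``expit(intercept + coef . x)``.

    Covariates absent from the data are treated as 0 (absence semantics of
    sparse binary features).
    """
    cov = pop.covariates if isinstance(pop, StudyPopulation) else pop
    X = cov.reindex(columns=model.coefficients.index, fill_value=0.0)
    lp = model.intercept + X.to_numpy() @ model.coefficients.to_numpy()
    return pd.Series(expit(lp), index=cov.index, name="predicted_risk")


# ---------------------------------------------------------------------------
# Discrimination


def _midranks(x: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n, dtype=float)
    out[order] = ranks
    return out


@dataclass
class ConcordanceResult:
    c: float
    se: float
    ci95: tuple[float, float]
    n_events: int
    n_nonevents: int


def concordance(risks, labels) -> ConcordanceResult:
    """c-statistic (AUC with ties counted 1/2) and DeLong asymptotic 95% CI.

    The probability that a randomly chosen event subject is assigned higher
    risk than a randomly chosen non-event subject.
    """
    risks = np.asarray(risks, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = risks[labels == 1]
    neg = risks[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise DataError("undefined_c", "both classes must be present")
    all_r = np.concatenate([pos, neg])
    rk_all = _midranks(all_r)
    rk_pos = _midranks(pos)
    rk_neg = _midranks(neg)
    auc = (rk_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # DeLong structural components
    v10 = (rk_all[:m] - rk_pos) / n
    v01 = 1.0 - (rk_all[m:] - rk_neg) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    z = norm.ppf(0.975)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    return ConcordanceResult(float(auc), se, (float(lo), float(hi)), m, n)


def cv_concordance(
    pop: StudyPopulation,
    outcome_id: str,
    subject_ids=None,
    folds: int = 3,
    seed: int = 0,
    **fit_kw,
) -> ConcordanceResult:
    """Cross-validated c-statistic: out-of-fold predictions, pooled AUC."""
    from sklearn.model_selection import StratifiedKFold

    aset = pop.analysis_set(outcome_id, subject_ids=subject_ids)
    X = pop.covariates.loc[aset.index].to_numpy()
    y = aset["event"].to_numpy()
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.empty(len(y))
    for k, (train, test) in enumerate(skf.split(X, y)):
        fit = lasso_logistic_cv(X[train], y[train], folds=folds, seed=seed + k + 1, **fit_kw)
        oof[test] = expit(fit.intercept + X[test] @ fit.coef)
    return concordance(oof, y)


def evaluate_performance(
    model: RiskModel, pop: StudyPopulation, matched_ids=None
) -> pd.DataFrame:
    """c-statistic of the risk model in the four standard evaluation
    populations: matched (development), treatment, comparator, entire."""
    risks = predict_risk(model, pop)
    aset = pop.analysis_set(model.outcome_id)
    populations = {
        "treatment": aset.index[aset["arm"] == ARM_TARGET],
        "comparator": aset.index[aset["arm"] == ARM_COMPARATOR],
        "entire": aset.index,
    }
    if matched_ids is not None:
        populations = {"matched": aset.index.intersection(pd.Index(matched_ids)), **populations}
    rows = []
    for name, ids in populations.items():
        res = concordance(risks.loc[ids], aset.loc[ids, "event"])
        rows.append(
            {
                "population": name,
                "c_statistic": res.c,
                "ci_lo": res.ci95[0],
                "ci_hi": res.ci95[1],
                "n": len(ids),
                "events": int(aset.loc[ids, "event"].sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Risk groups


@dataclass
class RiskGroupAssignment:
    """Partition of subjects into risk groups RG-1..RG-k.

    Groups are half-open intervals ``[0, t1), [t1, t2), ..., [t_k, 1]`` of
    predicted risk: a risk exactly at a threshold belongs to the upper group.
    """

    predicted_risk: pd.Series
    group_index: pd.Series          # 1-based
    thresholds: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.labels:
            self.labels = [f"RG-{i + 1}" for i in range(len(self.thresholds) + 1)]

    @property
    def group(self) -> pd.Series:
        return self.group_index.map(lambda i: self.labels[i - 1])

    def members(self, label: str) -> pd.Index:
        i = self.labels.index(label) + 1
        return self.group_index.index[self.group_index == i]

    def counts(self) -> pd.Series:
        return self.group.value_counts().reindex(self.labels, fill_value=0)


def assign_risk_groups(
    risks: pd.Series,
    thresholds=None,
    n_quantile_groups: int | None = None,
) -> RiskGroupAssignment:
    """Assign risk groups by fixed ``thresholds`` or by risk quantiles."""
    risks = pd.Series(risks).astype(float)
    if (thresholds is None) == (n_quantile_groups is None):
        raise DataError("bad_thresholds", "give exactly one of thresholds / n_quantile_groups")
    if n_quantile_groups is not None:
        if n_quantile_groups < 2:
            raise DataError("bad_thresholds", "need at least 2 quantile groups")
        qs = np.arange(1, n_quantile_groups) / n_quantile_groups
        thresholds = np.unique(np.quantile(risks.to_numpy(), qs))
    thresholds = np.asarray(thresholds, dtype=float)
    if len(thresholds) == 0 or np.any(np.diff(thresholds) <= 0):
        raise DataError("bad_thresholds", "thresholds must be strictly increasing")
    if thresholds.min() <= 0.0 or thresholds.max() >= 1.0:
        raise DataError("bad_thresholds", "thresholds must lie strictly inside (0, 1)")
    idx = np.searchsorted(thresholds, risks.to_numpy(), side="right") + 1
    return RiskGroupAssignment(
        predicted_risk=risks,
        group_index=pd.Series(idx, index=risks.index, name="risk_group"),
        thresholds=thresholds,
    )
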