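"""Propensity machinery: score estimation, matching, stratification, overlap.

The propensity score ``S`` is the probability of receiving the target
treatment given baseline covariates, estimated by cross-validated LASSO
logistic regression (same machinery as the outcome-risk model).  The
preference score ``F`` removes the treatment-prevalence component:
``logit(F) = logit(S) - logit(phi)`` with ``phi`` the target-arm fraction,
so ``F = 0.5`` marks clinical equipoise.  The pipeline uses these scores
twice: a global 1:1 caliper match to form the risk-model development set,
and within-risk-group quintile stratification for effect estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._lasso import lasso_logistic_cv, expit
from .cohort import StudyPopulation, ARM_TARGET, ARM_COMPARATOR
from .errors import DataError

_EPS = 1e-12


@dataclass
class PropensityResult:
    """Per-subject propensity and preference scores plus the fitted model."""

    scores: pd.Series            # S in (0,1)
    preference: pd.Series        # F in (0,1)
    intercept: float
    coefficients: pd.Series      # nonzero entries, original scale
    phi: float                   # target-arm fraction
    lambda_: float
    arm: pd.Series


def _logit(p):
    p = np.clip(np.asarray(p, dtype=float), _EPS, 1 - _EPS)
    return np.log(p / (1 - p))


def preference_score(S, phi: float):
    """Preference score: ``logit(F) = logit(S) - logit(phi)``.

    Boundary scores are clipped to a machine-safe interval.
    """
    if not 0 < phi < 1:
        raise DataError("bad_prevalence", "phi must be in (0,1)")
    s = np.asarray(S, dtype=float)
    if np.any((s <= 0) | (s >= 1)):
        warnings.warn("propensity scores at {0,1} clipped for preference transform")
    f = expit(_logit(s) - _logit(phi))
    if isinstance(S, pd.Series):
        return pd.Series(f, index=S.index, name="preference")
    return f if np.ndim(S) else float(f)


def fit_propensity(
    pop: StudyPopulation,
    subject_ids=None,
    folds: int = 3,
    seed: int = 0,
    n_lambdas: int = 50,
    lambda_min_ratio: float = 1e-4,
) -> PropensityResult:
    """LASSO logistic regression of treatment arm on all candidate covariates."""
    sub = pop if subject_ids is None else pop.subset(subject_ids)
    arm = sub.arm
    y = (arm == ARM_TARGET).to_numpy(float)
    if y.min() == y.max():
        raise DataError("arm_missing", "both arms must be present to fit a propensity model")
    X = sub.covariates
    fit = lasso_logistic_cv(
        X.to_numpy(), y, folds=folds, seed=seed,
        n_lambdas=n_lambdas, lambda_min_ratio=lambda_min_ratio,
    )
    S = pd.Series(
        expit(fit.intercept + X.to_numpy() @ fit.coef), index=X.index, name="propensity"
    )
    phi = float(y.mean())
    coefs = pd.Series(fit.coef, index=X.columns)
    return PropensityResult(
        scores=S,
        preference=preference_score(S, phi),
        intercept=fit.intercept,
        coefficients=coefs[coefs != 0.0],
        phi=phi,
        lambda_=fit.lambda_,
        arm=arm,
    )


# ---------------------------------------------------------------------------
# Matching


@dataclass
class MatchResult:
    """1:1 match pairs with the absolute caliper used."""

    pairs: pd.DataFrame           # columns target_id, comparator_id, distance
    caliper: float                # requested (on the configured scale)
    caliper_abs: float            # absolute threshold on the matching scale
    scale: str
    n_unmatched_target: int
    n_unmatched_comparator: int

    @property
    def matched_ids(self) -> pd.Index:
        return pd.Index(
            np.concatenate([self.pairs["target_id"].to_numpy(), self.pairs["comparator_id"].to_numpy()])
        )


def match_1to1(
    ps: PropensityResult,
    caliper: float = 0.2,
    caliper_scale: str = "std_logit",
    seed: int = 0,
) -> MatchResult:
    """Greedy nearest-neighbour 1:1 matching without replacement.

    Matching is on the logit of the propensity score; with
    ``caliper_scale="std_logit"`` the caliper is ``caliper`` times the
    standard deviation of the logit scores in the pooled population (the
    prevailing convention for "a caliper of 0.2").  Target subjects are
    processed in a seeded random order; each is matched to the nearest
    still-available comparator within the caliper.
    """
    arm = ps.arm
    if caliper_scale == "std_logit":
        vals = pd.Series(_logit(ps.scores), index=ps.scores.index)
        cal_abs = float(caliper * vals.std(ddof=1))
    elif caliper_scale == "raw":
        vals = ps.scores.astype(float)
        cal_abs = float(caliper)
    else:
        raise DataError("bad_config", f"unknown caliper_scale {caliper_scale!r}")

    t_ids = arm.index[arm == ARM_TARGET]
    c_ids = arm.index[arm == ARM_COMPARATOR]
    if len(t_ids) == 0 or len(c_ids) == 0:
        raise DataError("arm_missing", "both arms required for matching")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(t_ids))

    c_vals = vals.loc[c_ids].to_numpy()
    c_sort = np.argsort(c_vals, kind="mergesort")
    sorted_vals = list(c_vals[c_sort])
    sorted_ids = list(np.asarray(c_ids)[c_sort])

    import bisect

    pairs = []
    t_vals = vals.loc[t_ids].to_numpy()
    t_arr = np.asarray(t_ids)
    for i in order:
        if not sorted_vals:
            break
        v = t_vals[i]
        j = bisect.bisect_left(sorted_vals, v)
        best, bd = None, np.inf
        if j < len(sorted_vals) and abs(sorted_vals[j] - v) < bd:
            best, bd = j, abs(sorted_vals[j] - v)
        if j > 0 and abs(sorted_vals[j - 1] - v) < bd:
            best, bd = j - 1, abs(sorted_vals[j - 1] - v)
        if best is not None and bd <= cal_abs:
            pairs.append((t_arr[i], sorted_ids[best], bd))
            del sorted_vals[best]
            del sorted_ids[best]

    if not pairs:
        raise DataError("no_overlap", "no match pairs within the caliper")
    pairs_df = pd.DataFrame(pairs, columns=["target_id", "comparator_id", "distance"])
    return MatchResult(
        pairs=pairs_df,
        caliper=caliper,
        caliper_abs=cal_abs,
        scale=caliper_scale,
        n_unmatched_target=len(t_ids) - len(pairs_df),
        n_unmatched_comparator=len(c_ids) - len(pairs_df),
    )


# ---------------------------------------------------------------------------
# Stratification


@dataclass
class StratumAssignment:
    stratum: pd.Series            # 1..k
    boundaries: np.ndarray        # inner quantile boundaries, length k-1
    k: int

    def counts(self) -> pd.Series:
        return self.stratum.value_counts().sort_index()


def stratify_by_ps(ps: "PropensityResult | pd.Series", k: int = 5) -> StratumAssignment:
    """Partition subjects into ``k`` strata by quantiles of the propensity
    score over the pooled population; scores equal to a boundary go to the
    lower stratum."""
    S = ps.scores if isinstance(ps, PropensityResult) else pd.Series(ps).astype(float)
    if len(S) < k:
        raise DataError("too_few_subjects", f"need at least {k} subjects for {k} strata")
    vals = S.to_numpy()
    if np.all(vals == vals[0]):
        warnings.warn("degenerate_ps: all propensity scores identical; single stratum")
        return StratumAssignment(
            stratum=pd.Series(1, index=S.index, name="ps_stratum"),
            boundaries=np.array([]),
            k=1,
        )
    qs = np.arange(1, k) / k
    bounds = np.quantile(vals, qs)
    idx = np.searchsorted(bounds, vals, side="left") + 1
    return StratumAssignment(
        stratum=pd.Series(idx, index=S.index, name="ps_stratum"),
        boundaries=bounds,
        k=k,
    )


# ---------------------------------------------------------------------------
# Overlap


def overlap_fraction(f_target, f_comparator, bins: int = 100) -> float:
    """Overlapping coefficient (%) of the two preference-score densities,
    computed on a fixed equal-width partition of [0, 1]."""
    ft = np.asarray(f_target, dtype=float)
    fc = np.asarray(f_comparator, dtype=float)
    if len(ft) == 0 or len(fc) == 0:
        raise DataError("arm_missing", "both arms required for overlap")
    edges = np.linspace(0.0, 1.0, bins + 1)
    ht, _ = np.histogram(ft, bins=edges, density=True)
    hc, _ = np.histogram(fc, bins=edges, density=True)
    width = 1.0 / bins
    return float(np.minimum(ht, hc).sum() * width * 100.0)


def preference_histograms(ps: PropensityResult, bins: int = 100) -> pd.DataFrame:
    """Preference-score histogram densities per arm (equipoise plot data)."""
    edges = np.linspace(0.0, 1.0, bins + 1)
    rows = []
    for arm_label in (ARM_TARGET, ARM_COMPARATOR):
        f = ps.preference[ps.arm == arm_label].to_numpy()
        h, _ = np.histogram(f, bins=edges, density=True) if len(f) else (np.zeros(bins), None)
        for b in range(bins):
            rows.append(
                {"arm": arm_label, "bin_lo": edges[b], "bin_hi": edges[b + 1], "density": h[b]}
            )
    return pd.DataFrame(rows)
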