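"""Effect estimation within risk groups: per-PS-stratum Cox hazard ratios
and Kaplan-Meier risk differences, pooled across strata.

Relative effects: each propensity-score stratum contributes a
single-covariate Cox proportional-hazards fit (treatment indicator, Breslow
tie handling, Newton maximization of the partial likelihood); stratum
log-HRs are pooled by inverse-variance weighting.  Absolute effects: each
stratum contributes the difference of Kaplan-Meier event probabilities at
the horizon (positive favouring the target arm), with Greenwood variances;
strata are pooled weighted by stratum size, approximating the average
treatment effect within the risk group.  The same procedure on the
ungrouped population yields the overall row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import StudyPopulation, ARM_TARGET, ARM_COMPARATOR
from .diagnostics import BalanceReport, evaluate_balance
from .errors import DataError, EstimationError
from .prediction import RiskGroupAssignment
from .propensity import (
    PropensityResult,
    StratumAssignment,
    fit_propensity,
    overlap_fraction,
    stratify_by_ps,
)

Z95 = 1.959963984540054

OVERALL = "overall"


# ---------------------------------------------------------------------------
# Cox partial likelihood (single binary covariate, Breslow ties)


def _breslow_terms(tte: np.ndarray, event: np.ndarray, z: np.ndarray):
    """Per-distinct-event-time terms: (d, d1, R0, R1).

    d = events at t, d1 = events with z=1 at t, R0/R1 = at-risk counts by arm.
    """
    order = np.argsort(tte, kind="mergesort")
    t, e, x = tte[order], event[order].astype(bool), z[order].astype(int)
    # at-risk counts just before each time: subjects with tte >= t
    et = t[e]
    ex = x[e]
    if len(et) == 0:
        raise EstimationError("inestimable", "no events in stratum")
    utimes, start = np.unique(et, return_index=True)
    d = np.diff(np.append(start, len(et)))
    d1 = np.add.reduceat(ex, start)
    # risk sets: count of tte >= utime, by arm
    n1_sorted = np.cumsum(x[::-1])[::-1]          # subjects at or after position i with z=1
    pos = np.searchsorted(t, utimes, side="left")
    R = len(t) - pos
    R1 = n1_sorted[pos]
    R0 = R - R1
    return d.astype(float), d1.astype(float), R0.astype(float), R1.astype(float)


def cox_loglik(gamma: float, d, d1, R0, R1) -> float:
    return float(np.sum(d1) * gamma - np.sum(d * np.log(R0 + R1 * np.exp(gamma))))


@dataclass
class CoxFit:
    log_hr: float
    se: float
    n_events: int
    n: int
    converged: bool


def cox_stratum_hr(tte, event, arm, tol: float = 1e-8, max_iter: int = 60) -> CoxFit:
    """Single-covariate Cox PH fit of the treatment indicator.

    Breslow tie handling; Newton-Raphson on the partial likelihood to
    gradient tolerance ``tol``; standard error from the observed
    information.  Raises ``EstimationError("inestimable")`` for strata with
    no events, a single arm, or a monotone likelihood (events confined to
    one arm).
    """
    tte = np.asarray(tte, dtype=float)
    event = np.asarray(event).astype(int)
    z = _arm_indicator(arm)
    if z.min() == z.max():
        raise EstimationError("inestimable", "single arm in stratum")
    d, d1, R0, R1 = _breslow_terms(tte, event, z)
    tot1 = d1.sum()
    if tot1 == 0 or tot1 == d.sum():
        raise EstimationError("inestimable", "all events in one arm (monotone likelihood)")

    gamma = 0.0
    ll = cox_loglik(gamma, d, d1, R0, R1)
    converged = False
    for _ in range(max_iter):
        eg = np.exp(gamma)
        frac = R1 * eg / (R0 + R1 * eg)
        grad = tot1 - np.sum(d * frac)
        info = np.sum(d * frac * (1 - frac))
        if info <= 0:
            raise EstimationError("inestimable", "non-positive information")
        step = grad / info
        # step-halving to guarantee ascent
        new = gamma + step
        ll_new = cox_loglik(new, d, d1, R0, R1)
        halvings = 0
        while ll_new < ll and halvings < 30:
            step *= 0.5
            new = gamma + step
            ll_new = cox_loglik(new, d, d1, R0, R1)
            halvings += 1
        gamma, ll = new, ll_new
        if abs(grad) <= tol:
            converged = True
            break
    eg = np.exp(gamma)
    frac = R1 * eg / (R0 + R1 * eg)
    info = np.sum(d * frac * (1 - frac))
    if not np.isfinite(gamma) or info <= 0 or abs(gamma) > 20:
        raise EstimationError("inestimable", "divergent Cox fit")
    return CoxFit(
        log_hr=float(gamma),
        se=float(1.0 / np.sqrt(info)),
        n_events=int(d.sum()),
        n=len(tte),
        converged=converged,
    )


def _arm_indicator(arm) -> np.ndarray:
    a = np.asarray(arm)
    if a.dtype.kind in "bif":
        return a.astype(int)
    return (a == ARM_TARGET).astype(int)


# ---------------------------------------------------------------------------
# Kaplan-Meier


def km_curve(tte, event):
    """Product-limit estimate with Greenwood variance.

    Returns (times, survival, variance) at the distinct event times.
    """
    tte = np.asarray(tte, dtype=float)
    event = np.asarray(event).astype(bool)
    order = np.argsort(tte, kind="mergesort")
    t, e = tte[order], event[order]
    et = t[e]
    if len(et) == 0:
        return np.array([]), np.array([]), np.array([])
    utimes, start = np.unique(et, return_index=True)
    d = np.diff(np.append(start, len(et))).astype(float)
    pos = np.searchsorted(t, utimes, side="left")
    n_at_risk = (len(t) - pos).astype(float)
    surv = np.cumprod(1.0 - d / n_at_risk)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.where(n_at_risk > d, d / (n_at_risk * (n_at_risk - d)), np.inf)
        var = surv**2 * np.cumsum(gw)
    var = np.where(np.isfinite(var), var, 0.0)  # S=0 after exhausted risk set
    return utimes, surv, var


def km_at(times, surv, var, t: float) -> tuple[float, float]:
    """Step-function lookup of (S(t), Var S(t)); S=1 before the first event."""
    if len(times) == 0:
        return 1.0, 0.0
    i = np.searchsorted(times, t, side="right") - 1
    if i < 0:
        return 1.0, 0.0
    return float(surv[i]), float(var[i])


@dataclass
class KMDifference:
    rd: float
    se: float
    surv_target: float
    surv_comparator: float
    n: int


def km_stratum_rd(tte, event, arm, horizon: float) -> KMDifference:
    """Kaplan-Meier risk difference at the horizon.

    ``rd = S_target(h) - S_comparator(h)``, i.e. comparator cumulative
    incidence minus target cumulative incidence: positive values favour the
    target arm.  Variance by Greenwood's formula, summed across arms.
    """
    tte = np.asarray(tte, dtype=float)
    event = np.asarray(event).astype(int)
    z = _arm_indicator(arm).astype(bool)
    if z.all() or (~z).all():
        raise EstimationError("inestimable", "single arm in stratum")
    out = {}
    for label, mask in (("t", z), ("c", ~z)):
        times, surv, var = km_curve(tte[mask], event[mask])
        if len(times) and horizon > tte[mask].max():
            warnings.warn("horizon beyond last observed time; survival carried forward")
        out[label] = km_at(times, surv, var, horizon)
    (st, vt), (sc, vc) = out["t"], out["c"]
    return KMDifference(
        rd=float(st - sc),
        se=float(np.sqrt(vt + vc)),
        surv_target=st,
        surv_comparator=sc,
        n=len(tte),
    )


# ---------------------------------------------------------------------------
# Pooling


@dataclass
class PooledEffect:
    estimate: float
    se: float
    ci95: tuple[float, float]
    n_components: int


def pool_relative(components, method: str = "ivw") -> PooledEffect:
    """Pool per-stratum (log_hr, se) estimates.

    ``ivw``: inverse-variance weighted mean, pooled se = sqrt(1/sum w).
    ``arithmetic_log``: plain mean of log-HRs, se = sqrt(sum se^2)/k.
    """
    comps = [(float(x), float(s)) for x, s in components if np.isfinite(x) and np.isfinite(s)]
    if not comps:
        raise EstimationError("suppressed", "no estimable components to pool")
    x = np.array([c[0] for c in comps])
    s = np.array([c[1] for c in comps])
    if method == "ivw":
        w = 1.0 / s**2
        est = float(np.sum(w * x) / np.sum(w))
        se = float(np.sqrt(1.0 / np.sum(w)))
    elif method == "arithmetic_log":
        est = float(x.mean())
        se = float(np.sqrt(np.sum(s**2)) / len(s))
    else:
        raise DataError("bad_config", f"unknown pooling method {method!r}")
    return PooledEffect(est, se, (est - Z95 * se, est + Z95 * se), len(comps))


def pool_absolute(components, weights=None) -> PooledEffect:
    """Pool per-stratum (rd, se) weighted by stratum size.

    ``se = sqrt(sum (w_i/sum w)^2 se_i^2)``; equal weights when ``weights``
    is None.
    """
    comps = [(float(x), float(s)) for x, s in components if np.isfinite(x) and np.isfinite(s)]
    if not comps:
        raise EstimationError("suppressed", "no estimable components to pool")
    x = np.array([c[0] for c in comps])
    s = np.array([c[1] for c in comps])
    w = np.ones(len(x)) if weights is None else np.asarray(list(weights), dtype=float)
    if len(w) != len(x):
        raise DataError("bad_config", "weights length mismatch")
    w = w / w.sum()
    est = float(np.sum(w * x))
    se = float(np.sqrt(np.sum(w**2 * s**2)))
    return PooledEffect(est, se, (est - Z95 * se, est + Z95 * se), len(comps))


# ---------------------------------------------------------------------------
# Scope-level estimation


@dataclass
class ScopeArtifacts:
    """Per-scope (overall or one risk group) propensity machinery."""

    scope: str
    subject_ids: pd.Index
    propensity: PropensityResult
    strata: StratumAssignment
    overlap: float
    balance: BalanceReport


@dataclass
class ResultSet:
    """Tidy grid of pooled effect estimates plus audit components."""

    table: pd.DataFrame
    components: dict = field(default_factory=dict)   # (scope, outcome) -> stratum records
    artifacts: dict = field(default_factory=dict)    # scope -> ScopeArtifacts
    metadata: dict = field(default_factory=dict)


def build_scope_artifacts(
    pop: StudyPopulation,
    risk_groups: "RiskGroupAssignment | None",
    k_strata: int = 5,
    folds: int = 3,
    seed: int = 0,
    balance_threshold: float = 0.1,
    ps_kw: dict | None = None,
    include_overall: bool = True,
) -> dict[str, ScopeArtifacts]:
    """Fit within-scope propensity models, strata and diagnostics.

    Scopes are the overall population plus each risk group (when
    ``risk_groups`` is given).  The propensity seed is offset per scope so
    fold draws are independent but reproducible.
    """
    ps_kw = ps_kw or {}
    scopes: list[tuple[str, pd.Index]] = [(OVERALL, pop.subject_ids)] if include_overall else []
    if risk_groups is not None:
        for label in risk_groups.labels:
            scopes.append((label, risk_groups.members(label)))
    out = {}
    for i, (scope, ids) in enumerate(scopes):
        ids = pop.subject_ids.intersection(ids)
        ps = fit_propensity(pop, subject_ids=ids, folds=folds, seed=seed + 1000 * i, **ps_kw)
        strata = stratify_by_ps(ps, k=k_strata)
        ov = overlap_fraction(
            ps.preference[ps.arm == ARM_TARGET], ps.preference[ps.arm == ARM_COMPARATOR]
        )
        bal = evaluate_balance(pop, strata.stratum, threshold=balance_threshold, subject_ids=ids)
        out[scope] = ScopeArtifacts(scope, ids, ps, strata, ov, bal)
    return out


def estimate_outcome_in_scope(
    pop: StudyPopulation,
    art: ScopeArtifacts,
    outcome_id: str,
    pool: str = "ivw",
) -> dict:
    """Pooled relative and absolute effect for one outcome in one scope."""
    aset = pop.analysis_set(outcome_id, subject_ids=art.subject_ids)
    strat = art.strata.stratum.reindex(aset.index)
    horizon = pop.spec.horizon
    hr_comps, rd_comps, sizes, records = [], [], [], []
    for s in range(1, art.strata.k + 1):
        m = (strat == s).to_numpy()
        sub = aset[m]
        rec = {"stratum": s, "n": len(sub), "events": int(sub["event"].sum())}
        try:
            cf = cox_stratum_hr(sub["tte"], sub["event"], sub["arm"])
            rec.update(log_hr=cf.log_hr, se_log_hr=cf.se)
            hr_comps.append((cf.log_hr, cf.se))
        except EstimationError as exc:
            rec.update(log_hr=np.nan, se_log_hr=np.nan, hr_flag=exc.code)
        try:
            kd = km_stratum_rd(sub["tte"], sub["event"], sub["arm"], horizon)
            rec.update(rd=kd.rd, se_rd=kd.se)
            rd_comps.append((kd.rd, kd.se))
            sizes.append(len(sub))
        except EstimationError as exc:
            rec.update(rd=np.nan, se_rd=np.nan, rd_flag=exc.code)
        records.append(rec)

    row = {
        "scope": art.scope,
        "outcome_id": outcome_id,
        "n_target": int((aset["arm"] == ARM_TARGET).sum()),
        "n_comparator": int((aset["arm"] == ARM_COMPARATOR).sum()),
        "events_target": int(aset.loc[aset["arm"] == ARM_TARGET, "event"].sum()),
        "events_comparator": int(aset.loc[aset["arm"] == ARM_COMPARATOR, "event"].sum()),
    }
    if hr_comps:
        pr = pool_relative(hr_comps, method=pool)
        row.update(
            log_hr=pr.estimate,
            se_log_hr=pr.se,
            hr=float(np.exp(pr.estimate)),
            hr_lo=float(np.exp(pr.ci95[0])),
            hr_hi=float(np.exp(pr.ci95[1])),
            n_strata_hr=pr.n_components,
        )
    else:
        row.update(log_hr=np.nan, se_log_hr=np.nan, hr=np.nan, hr_lo=np.nan, hr_hi=np.nan, n_strata_hr=0)
    if rd_comps:
        pa = pool_absolute(rd_comps, weights=sizes)
        row.update(
            rd=pa.estimate, se_rd=pa.se, rd_lo=pa.ci95[0], rd_hi=pa.ci95[1],
            n_strata_rd=pa.n_components,
        )
    else:
        row.update(rd=np.nan, se_rd=np.nan, rd_lo=np.nan, rd_hi=np.nan, n_strata_rd=0)
    row["_records"] = records
    return row


def estimate_effects(
    pop: StudyPopulation,
    risk_groups: "RiskGroupAssignment | None" = None,
    outcome_ids=None,
    k_strata: int = 5,
    folds: int = 3,
    seed: int = 0,
    pool: str = "ivw",
    balance_threshold: float = 0.1,
    overlap_floor: float = 20.0,
    suppress_on_diagnostics: bool = True,
    artifacts: dict | None = None,
) -> ResultSet:
    """Estimate pooled effects for every (outcome x scope) cell.

    Each scope (overall population and each risk group) gets its own LASSO
    propensity model and ``k_strata`` quantile strata; per-stratum Cox and
    Kaplan-Meier components are pooled.  A cell is flagged ``suppressed``
    (with a reason) when the scope's balance gate fails or its preference
    score overlap is below ``overlap_floor`` percent; estimates are still
    recorded for audit.
    """
    outcome_ids = list(outcome_ids) if outcome_ids is not None else list(pop.spec.outcome_ids)
    if artifacts is None:
        artifacts = build_scope_artifacts(
            pop, risk_groups, k_strata=k_strata, folds=folds, seed=seed,
            balance_threshold=balance_threshold,
        )
    rows, components = [], {}
    for scope, art in artifacts.items():
        reasons = []
        if suppress_on_diagnostics:
            if not art.balance.passed:
                reasons.append("balance_gate_failed")
            if art.overlap < overlap_floor:
                reasons.append("insufficient_overlap")
        for oid in outcome_ids:
            row = estimate_outcome_in_scope(pop, art, oid, pool=pool)
            components[(scope, oid)] = row.pop("_records")
            cell_reasons = list(reasons)
            if row["n_strata_hr"] == 0 and row["n_strata_rd"] == 0:
                cell_reasons.append("no_estimable_strata")
            row["suppressed"] = bool(cell_reasons)
            row["reason"] = ";".join(cell_reasons)
            rows.append(row)
    table = pd.DataFrame(rows)
    meta = {
        "k_strata": k_strata,
        "folds": folds,
        "seed": seed,
        "pool": pool,
        "balance_threshold": balance_threshold,
        "overlap_floor": overlap_floor,
        "horizon": pop.spec.horizon,
    }
    return ResultSet(table=table, components=components, artifacts=artifacts, metadata=meta)
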