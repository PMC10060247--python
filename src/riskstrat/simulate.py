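"""Synthetic observational studies with known ground truth.

The generator emulates the structure of a claims-database comparative
cohort: binary/continuous baseline covariates, confounded treatment
assignment through a logistic model, exponential (constant-hazard)
time-to-event outcomes with a log-linear covariate effect and a possibly
risk-dependent treatment effect, exponential censoring truncated
administratively, and negative-control outcomes whose hazards depend on
covariates but carry a treatment coefficient of exactly zero.

Randomness is a single seed fanned out into named substreams (covariates,
assignment, outcomes, censoring, negative controls, oracle), so e.g.
changing the number of negative controls does not perturb the cohort.
Exponential event times keep marginal quantities partially closed-form for
testing; event times and observation ends are rounded up to integer days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import ARM_TARGET, ARM_COMPARATOR
from .errors import ConfigError

_STREAMS = {
    "covariates": 0,
    "assignment": 1,
    "outcomes": 2,
    "censoring": 3,
    "negative_controls": 4,
    "oracle": 5,
    "latent": 6,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class OutcomeModel:
    """Log-linear exponential hazard for one outcome.

    hazard(x, z) = exp(log_rate + sum_j coefs[j] * x_j + z * gamma(x)) per
    day, with ``gamma(x) = gamma0 + gamma1 * (covariate linear predictor)``
    the (possibly risk-dependent) log hazard ratio of target vs comparator.
    """

    outcome_id: str
    log_rate: float                       # baseline log hazard per day
    coefs: tuple = ()                     # ((covariate, coef), ...)
    gamma0: float = 0.0
    gamma1: float = 0.0

    def coef_dict(self) -> dict:
        return dict(self.coefs)


@dataclass(frozen=True)
class SimulationScenario:
    """Full specification of a synthetic study."""

    n: int
    bin_prevalences: tuple = ()           # one binary covariate per entry
    n_continuous: int = 0                 # standard-normal covariates
    treat_intercept: float = 0.0
    treat_coefs: tuple = ()               # ((covariate, coef), ...)
    outcomes: tuple = ()                  # OutcomeModel instances
    censor_rate: float = 1.0 / 1825.0     # per day (mean ~5 years)
    admin_censor: int = 1095              # administrative truncation, days
    n_negative_controls: int = 0
    nc_log_rate: float = -10.3
    nc_intercept_sd: float = 0.3
    nc_coef_scale: float = 0.25
    unmeasured_treat_coef: float = 0.0    # latent confounder -> assignment
    nc_unmeasured_coef: float = 0.0       # latent confounder -> control hazards
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ConfigError("bad_scenario", "n must be >= 2")
        if self.censor_rate <= 0 or self.admin_censor <= 0:
            raise ConfigError("bad_scenario", "rates and admin_censor must be > 0")
        for p in self.bin_prevalences:
            if not 0 < p < 1:
                raise ConfigError("bad_scenario", f"binary prevalence {p} outside (0,1)")

    @property
    def covariate_names(self) -> list[str]:
        return [f"b{i + 1}" for i in range(len(self.bin_prevalences))] + [
            f"c{i + 1}" for i in range(self.n_continuous)
        ]


@dataclass
class SimulatedStudy:
    """Generated cohort/outcome tables plus generation internals."""

    cohorts: pd.DataFrame
    outcomes: pd.DataFrame
    scenario: SimulationScenario
    seed: int
    unmeasured: np.ndarray = field(repr=False, default=None)

    def with_negative_controls(self) -> pd.DataFrame:
        """Outcome table including negative-control events."""
        nc = simulate_negative_controls(self.scenario, self)
        if nc.empty:
            return self.outcomes
        return pd.concat([self.outcomes, nc], ignore_index=True)


def _lp(cov: pd.DataFrame, coefs) -> np.ndarray:
    out = np.zeros(len(cov))
    for name, c in dict(coefs).items():
        if name not in cov.columns:
            raise ConfigError("bad_scenario", f"coefficient on unknown covariate {name!r}")
        out += c * cov[name].to_numpy()
    return out


def _draw_covariates(scenario: SimulationScenario, rng: np.random.Generator, n: int) -> pd.DataFrame:
    cols = {}
    for i, p in enumerate(scenario.bin_prevalences):
        cols[f"b{i + 1}"] = (rng.random(n) < p).astype(float)
    for i in range(scenario.n_continuous):
        cols[f"c{i + 1}"] = rng.standard_normal(n)
    return pd.DataFrame(cols, index=pd.RangeIndex(1, n + 1, name="subject_id"))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohort(scenario: SimulationScenario, seed: int | None = None) -> SimulatedStudy:
    """Generate a synthetic cohort and outcome-event table.

    Bit-for-bit reproducible from ``(scenario, seed)``; ``seed`` defaults to
    ``scenario.seed``.
    """
    seed = scenario.seed if seed is None else int(seed)
    n = scenario.n
    cov = _draw_covariates(scenario, _rng(seed, "covariates"), n)
    u = _rng(seed, "latent").standard_normal(n)  # latent unmeasured confounder

    lp_treat = scenario.treat_intercept + _lp(cov, scenario.treat_coefs)
    lp_treat = lp_treat + scenario.unmeasured_treat_coef * u
    p_treat = _expit(lp_treat)
    z = (_rng(seed, "assignment").random(n) < p_treat).astype(int)
    if z.min() == z.max():
        warnings.warn("arm_degenerate: all subjects assigned to one arm")

    cens = _rng(seed, "censoring").exponential(1.0 / scenario.censor_rate, n)
    obs_end = np.minimum(np.ceil(cens), scenario.admin_censor).astype(int)
    obs_end = np.maximum(obs_end, 1)

    cohorts = pd.DataFrame(
        {
            "subject_id": cov.index,
            "arm": np.where(z == 1, ARM_TARGET, ARM_COMPARATOR),
            "obs_end": obs_end,
        }
    )
    cohorts = pd.concat([cohorts.set_index("subject_id"), cov], axis=1).reset_index()

    rng_out = _rng(seed, "outcomes")
    frames = []
    cap = float(scenario.admin_censor)
    for om in scenario.outcomes:
        lp_cov = _lp(cov, om.coefs)
        gamma = om.gamma0 + om.gamma1 * lp_cov
        rate = np.exp(om.log_rate + lp_cov + z * gamma)
        t = rng_out.exponential(1.0 / rate)
        t_days = np.ceil(t)
        keep = t_days <= cap
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": cov.index[keep],
                    "outcome_id": om.outcome_id,
                    "event_time": t_days[keep].astype(int),
                }
            )
        )
    outcomes = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["subject_id", "outcome_id", "event_time"])
    )
    return SimulatedStudy(cohorts=cohorts, outcomes=outcomes, scenario=scenario, seed=seed, unmeasured=u)


def simulate_negative_controls(
    scenario: SimulationScenario, study: SimulatedStudy, seed: int | None = None
) -> pd.DataFrame:
    """Generate event tables for ``n_negative_controls`` control outcomes.

    Each control gets its own covariate-dependent hazard (coefficients drawn
    once per control), optionally loading on the latent unmeasured
    confounder, and a treatment coefficient of exactly zero.  Outcome ids
    live in the reserved ``nc_*`` namespace.
    """
    k = scenario.n_negative_controls
    if k == 0:
        return pd.DataFrame(columns=["subject_id", "outcome_id", "event_time"])
    if k < 2:
        raise ConfigError("bad_scenario", "n_negative_controls must be 0 or >= 2")
    seed = study.seed if seed is None else int(seed)
    rng = _rng(seed, "negative_controls")
    cov = study.cohorts.set_index("subject_id")[scenario.covariate_names]
    X = cov.to_numpy()
    n, p = X.shape
    cap = float(scenario.admin_censor)
    frames = []
    width = max(3, len(str(k)))
    for j in range(k):
        b0 = scenario.nc_log_rate + rng.normal(0.0, scenario.nc_intercept_sd)
        beta = rng.normal(0.0, scenario.nc_coef_scale, p)
        lp = X @ beta + scenario.nc_unmeasured_coef * study.unmeasured
        rate = np.exp(b0 + lp)
        t_days = np.ceil(rng.exponential(1.0 / rate))
        keep = t_days <= cap
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": cov.index[keep],
                    "outcome_id": f"nc_{j + 1:0{width}d}",
                    "event_time": t_days[keep].astype(int),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def negative_control_ids(scenario: SimulationScenario) -> list[str]:
    width = max(3, len(str(scenario.n_negative_controls)))
    return [f"nc_{j + 1:0{width}d}" for j in range(scenario.n_negative_controls)]


# ---------------------------------------------------------------------------
# Ground-truth oracle


def true_marginal_effects(
    scenario: SimulationScenario,
    thresholds=None,
    n_quantile_groups: int | None = 3,
    horizon: int = 730,
    n_mc: int = 1_000_000,
    seed: int | None = None,
    outcome_ids=None,
) -> pd.DataFrame:
    """Large-sample Monte-Carlo ground truth per risk group.

    Draws ``n_mc`` covariate vectors (independent oracle stream) and
    computes, per outcome and per group of true baseline (comparator-arm)
    risk at the horizon: exact per-subject event probabilities under both
    arms (hence the true risk difference, Monte-Carlo error only from the
    covariate draw), the mean conditional hazard ratio, and the true
    marginal hazard ratio defined as the large-sample single-covariate Cox
    estimate on the randomized potential outcomes (both arms per subject,
    administratively censored at the horizon) -- the estimand a
    propensity-stratified analysis targets.
    """
    from .estimation import cox_stratum_hr

    seed = scenario.seed if seed is None else int(seed)
    rng = _rng(seed, "oracle")
    cov = _draw_covariates(scenario, rng, int(n_mc))
    rows = []
    want = set(outcome_ids) if outcome_ids is not None else None
    for om in scenario.outcomes:
        if want is not None and om.outcome_id not in want:
            continue
        lp_cov = _lp(cov, om.coefs)
        gamma = om.gamma0 + om.gamma1 * lp_cov
        rate0 = np.exp(om.log_rate + lp_cov)
        rate1 = rate0 * np.exp(gamma)
        p0 = 1.0 - np.exp(-horizon * rate0)
        p1 = 1.0 - np.exp(-horizon * rate1)
        if thresholds is not None:
            cuts = np.asarray(thresholds, dtype=float)
        else:
            qs = np.arange(1, n_quantile_groups) / n_quantile_groups
            cuts = np.quantile(p0, qs)
        gidx = np.searchsorted(cuts, p0, side="right")
        t0 = rng.exponential(1.0 / rate0)
        t1 = rng.exponential(1.0 / rate1)
        groups = {"overall": np.ones(len(p0), dtype=bool)}
        for g in range(len(cuts) + 1):
            groups[f"RG-{g + 1}"] = gidx == g
        for label, m in groups.items():
            nm = int(m.sum())
            if nm == 0:
                continue
            tt = np.concatenate([np.minimum(t1[m], horizon), np.minimum(t0[m], horizon)])
            ev = np.concatenate([(t1[m] <= horizon), (t0[m] <= horizon)]).astype(int)
            zz = np.concatenate([np.ones(nm, int), np.zeros(nm, int)])
            try:
                hr_marg = float(np.exp(cox_stratum_hr(tt, ev, zz).log_hr))
            except Exception:
                hr_marg = np.nan
            diff = p0[m] - p1[m]
            rows.append(
                {
                    "outcome_id": om.outcome_id,
                    "group": label,
                    "n_frac": nm / len(p0),
                    "p_target": float(p1[m].mean()),
                    "p_comparator": float(p0[m].mean()),
                    "rd": float(diff.mean()),
                    "mc_se_rd": float(diff.std(ddof=1) / np.sqrt(nm)),
                    "hr_marginal": hr_marg,
                    "hr_conditional_mean": float(np.exp(gamma[m]).mean()),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Canned scenarios (the package's reference study conditions)


def _calibrate_log_rate(
    scenario_covs: tuple, n_continuous: int, coefs: tuple, target_risk: float,
    horizon: int = 730, n: int = 200_000, seed: int = 12345,
) -> float:
    """Baseline log-rate giving a target mean comparator-arm risk at the
    horizon (deterministic internal draw)."""
    probe = SimulationScenario(
        n=2, bin_prevalences=scenario_covs, n_continuous=n_continuous, seed=seed
    )
    cov = _draw_covariates(probe, np.random.default_rng(seed), n)
    lp = _lp(cov, coefs)

    def mean_risk(b0):
        return float(np.mean(1.0 - np.exp(-horizon * np.exp(b0 + lp)))) - target_risk

    return float(brentq(mean_risk, -20.0, 0.0, xtol=1e-10))


def negative_control_scenario(n: int = 20_000, n_negative_controls: int = 50, seed: int = 0) -> SimulationScenario:
    """Unconfounded-after-adjustment study: 10 measured confounders drive
    both treatment assignment and outcome hazards; all negative-control
    hazard ratios are truly 1."""
    bins = (0.45, 0.35, 0.3, 0.25, 0.2)
    n_cont = 5
    treat = (
        ("b1", 0.4), ("b2", -0.3), ("b3", 0.3), ("b4", -0.25), ("b5", 0.25),
        ("c1", 0.3), ("c2", -0.25), ("c3", 0.2), ("c4", -0.2), ("c5", 0.15),
    )
    out_coefs = (
        ("b1", 0.35), ("b2", 0.3), ("b3", -0.25), ("b4", 0.2), ("b5", -0.2),
        ("c1", 0.4), ("c2", 0.3), ("c3", -0.25), ("c4", 0.2), ("c5", 0.15),
    )
    b0 = _calibrate_log_rate(bins, n_cont, out_coefs, target_risk=0.05)
    return SimulationScenario(
        n=n,
        bin_prevalences=bins,
        n_continuous=n_cont,
        treat_intercept=-0.3,
        treat_coefs=treat,
        outcomes=(OutcomeModel("o1", log_rate=b0, coefs=out_coefs),),
        n_negative_controls=n_negative_controls,
        nc_log_rate=_calibrate_log_rate(bins, n_cont, (), target_risk=0.025),
        nc_intercept_sd=0.3,
        nc_coef_scale=0.25,
        seed=seed,
    )


def balance_scenario(n: int = 20_000, seed: int = 0) -> SimulationScenario:
    """Strong measured confounding: 20 covariates with treatment
    assignment log-odds shifts up to 1.0."""
    bins = tuple([0.5, 0.4, 0.35, 0.3, 0.3, 0.25, 0.2, 0.2, 0.15, 0.1])
    n_cont = 10
    names = [f"b{i + 1}" for i in range(10)] + [f"c{i + 1}" for i in range(10)]
    mags = [1.0 * (0.85**i) for i in range(20)]
    signs = [1 if i % 2 == 0 else -1 for i in range(20)]
    treat = tuple((nm, s * m) for nm, m, s in zip(names, mags, signs))
    out_coefs = tuple((nm, 0.6 * s * m) for nm, m, s in zip(names, mags, signs))
    b0 = _calibrate_log_rate(bins, n_cont, out_coefs, target_risk=0.05)
    return SimulationScenario(
        n=n,
        bin_prevalences=bins,
        n_continuous=n_cont,
        treat_intercept=0.0,
        treat_coefs=treat,
        outcomes=(OutcomeModel("o1", log_rate=b0, coefs=out_coefs),),
        seed=seed,
    )


def constant_hr_scenario(n: int = 20_000, gamma0: float = float(np.log(0.8)), seed: int = 0) -> SimulationScenario:
    """Constant conditional hazard ratio (default 0.8) with a strongly
    risk-discriminating, high-incidence outcome so that risk groups are
    well separated (mean comparator-arm 2-year risk ~0.22, log-hazard
    linear predictor sd ~1.5)."""
    bins = (0.4, 0.3, 0.25)
    n_cont = 3
    out_coefs = (
        ("b1", 0.5), ("b2", 0.45), ("b3", 0.4),
        ("c1", 1.0), ("c2", 0.8), ("c3", 0.5),
    )
    treat = (
        ("b1", 0.3), ("b2", -0.25), ("c1", 0.3), ("c2", -0.2), ("c3", 0.15),
    )
    b0 = _calibrate_log_rate(bins, n_cont, out_coefs, target_risk=0.22)
    return SimulationScenario(
        n=n,
        bin_prevalences=bins,
        n_continuous=n_cont,
        treat_intercept=-0.2,
        treat_coefs=treat,
        outcomes=(OutcomeModel("o1", log_rate=b0, coefs=out_coefs, gamma0=gamma0),),
        seed=seed,
    )
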