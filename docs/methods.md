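# Methods

## The estimation problem

`riskstrat` targets risk-based heterogeneity of treatment effects (HTE) in
a new-user comparative cohort: subjects initiate either the target or the
comparator treatment at an index date, baseline covariates are measured in
a lookback window before index, and each outcome is analyzed as a
first-event time-to-event endpoint within a fixed time-at-risk horizon
(intention-to-treat; no censoring at treatment discontinuation). Effects
are reported on two scales because their heterogeneity patterns differ:
with a constant relative effect and a discriminating risk model, absolute
risk differences necessarily increase with baseline risk while hazard
ratios stay flat.

## Population construction

Time is integer days relative to index. For each outcome, subjects with an
event record at any time ≤ 0 are excluded from that outcome's analysis set
(the index day itself counts as prior — the conservative reading of "any
time prior to treatment initiation"; a `lookback` exclusion window is
available as a switch). Remaining subjects get
`tte = min(first post-index event, obs_end, horizon)` and an event
indicator for events at or before both truncations. Only the earliest
post-index event per (subject, outcome) is used.

## Risk model (step 3)

A LASSO logistic regression of "event within horizon" on all candidate
covariates, fitted on the 1:1 propensity-matched subset so neither arm
dominates the fit (which would otherwise induce spurious
treatment-interaction structure). Numerical choices:

- Penalty grid: 50 log-spaced values from `lambda_max` (the smallest
  penalty zeroing every coefficient) down by a factor 1e-4. Selection by
  minimum mean 3-fold cross-validated deviance, stratified folds, no 1-SE
  rule. Fold assignment is the only randomness and is seeded.
- Covariates are standardized to unit variance inside the fit; reported
  coefficients are on the original scale. The solver is liblinear via
  scikit-learn; the intercept is made effectively unpenalized by a large
  `intercept_scaling` (1000), which keeps the intercept-only limit at
  `logit(event rate)` to ~1e-5 on the probability scale.
- Missing covariates at prediction time are treated as zero (absence
  semantics of sparse binary features).

Discrimination is the c-statistic (ties 1/2) with a DeLong asymptotic 95%
CI, reported in the matched, treatment, comparator and entire populations;
a k-fold cross-validated c-statistic (out-of-fold predictions, pooled) is
also available because apparent and cross-validated discrimination can
differ.

Risk groups are half-open intervals of predicted risk: `[0,t1), [t1,t2),
…, [tk,1]` — a risk exactly at a threshold goes to the upper group
("below 1%" / "1–1.5%" / "above 1.5%" style thresholds, or k-quantile
groups; both are config options).

## Propensity machinery (step 4)

The propensity score `S` is fitted with exactly the same LASSO machinery,
regressing arm on all covariates — once globally (for the risk-model
development match) and once per risk group (for estimation). The
preference score removes prevalence: `logit F = logit S − logit φ`, with
`φ` the target-arm fraction; `F = 0.5` is clinical equipoise.

- Matching: greedy nearest-neighbour 1:1 without replacement on
  `logit S`, caliper 0.2 × SD of `logit S` in the pooled population (the
  prevailing convention behind "a caliper of 0.2"; a raw-scale caliper is
  a config switch). Target subjects are processed in a seeded random
  order; greedy rather than optimal matching keeps the result
  deterministic and is adequate at these scales.
- Stratification: k = 5 quantile strata of `S` over the pooled population
  (pooled rather than target-only boundaries — symmetric; switchable);
  scores equal to a boundary go to the lower stratum. All-identical scores
  degrade to a single stratum with a diagnostic.
- Overlap: the overlapping coefficient of the two preference-score
  densities on a fixed 100-bin partition of [0,1] (bin minima × width; a
  histogram rather than kernel estimate keeps it deterministic).

## Effect estimation

Per risk group (and for the overall row, computed identically on the
ungrouped population):

- Relative: per PS stratum, a single-covariate Cox proportional-hazards
  fit of the treatment indicator — Breslow tie handling (Efron left as an
  extension), Newton–Raphson on the partial likelihood to gradient
  tolerance 1e-8 with step-halving, SE from observed information. Strata
  with no events, a single arm, or a monotone likelihood are flagged
  inestimable and excluded from pooling with an audit record. Pooling is
  inverse-variance on the log scale ("averaging" of hazard ratios made
  estimable; plain log-scale averaging is a config switch).
- Absolute: per stratum, the difference of Kaplan–Meier event
  probabilities at the horizon, `rd = S_target(h) − S_comparator(h)`
  (positive favours the target arm), with per-arm Greenwood variances;
  pooled weighted by stratum size, approximating the average treatment
  effect in the risk group (matching would target the ATT instead and is
  supported via the match result).
- All CIs are Wald on the estimation scale (log for HR, identity for RD);
  bootstrap is deliberately omitted for determinism.

A cell is *suppressed* (reported but flagged, with machine-readable
reasons) when its scope fails a diagnostic gate: any post-stratification
weighted |SMD| above the threshold (default 0.1, a rule of thumb) or
preference-score overlap below a floor (default 20%).

## Diagnostics

- SMD: `(mean_t − mean_c) / sqrt((var_t + var_c)/2)` with population
  variances; the "after" version uses PS-stratum-size-weighted
  within-stratum means and variances.
- Negative-control calibration: observed control log-HRs `y_i` with
  sampling SEs `se_i` are modelled as `y_i ~ N(μ, σ² + se_i²)` — a
  Gaussian systematic-error distribution with closed-form marginal
  likelihood, the minimal standard model. The MLE profiles μ in closed
  form and optimizes σ ≥ 0 by bounded scalar minimization (boundary σ = 0
  checked explicitly). Calibrated CI:
  `(log HR − μ) ± 1.96·sqrt(se² + σ²)`; calibrated p from
  `N(μ, σ² + se²)`. Calibration models are fitted per risk group and
  overall (the per-group and shared variants answer different questions;
  both are computed).

## Synthetic studies

The simulator emulates the structure of a claims-database cohort without
any claims-data coding: binary covariates with set prevalences plus
standard-normal covariates; treatment assignment
`Z ~ Bernoulli(expit(a0 + a·x))`; exponential event times with
`hazard = exp(b0 + b·x + Z·γ(x))` per day, where
`γ(x) = γ0 + γ1·(b·x)` allows both constant and risk-dependent hazard
ratios; exponential censoring (mean ~5 years) truncated administratively
at 3 years; times rounded up to integer days (which produces realistic
ties for the Breslow handling). Negative controls draw per-control
covariate coefficients (sd 0.25) and carry a treatment coefficient of
exactly zero; an optional latent confounder loading on both assignment and
control hazards injects residual bias for calibration testing. A single
seed fans out into named substreams (covariates, assignment, outcomes,
censoring, negative controls, latent, oracle), so changing the number of
controls never perturbs the cohort.

Exponential hazards keep marginal quantities partially closed-form; what
the generator does **not** emulate — non-proportional hazards, informative
censoring, covariate measurement error, coded-vocabulary feature spaces
with thousands of sparse covariates, competing risks — bounds what passing
tests show about real data: they validate the estimation machinery, not
robustness to those violations.

The ground-truth oracle draws ≥ 10⁶ covariate vectors from an independent
substream and computes, per group of true baseline risk: exact per-subject
event probabilities under both arms (risk differences with MC error from
the covariate draw only), the mean conditional HR, and the **true marginal
HR**, defined as the large-sample single-covariate Cox estimate on the
randomized potential outcomes (both arms per subject, censored at the
horizon). This definition matches the estimand a propensity-stratified
analysis targets and absorbs the non-collapsibility of the hazard ratio,
which a naive "conditional γ" truth would not.

## Reference experiment design

The canned scenarios in `riskstrat.simulate` fix the operating conditions
for the validation experiments (`riskstrat.validation`):

- *Negative-control coverage*: n = 20,000 per replicate, 10 measured
  confounders with moderate effects (assignment log-odds ≤ 0.4), primary
  outcome ~5% two-year risk, 4 × 50 control outcomes (~2.5% risk each).
  Confounding is fully measured, so after within-risk-group quintile
  stratification the pooled control CIs should cover HR = 1 at ~95%.
- *Balance*: 20 covariates with assignment log-odds shifts decaying
  geometrically from 1.0, the largest on binary covariates — the
  claims-data regime, where features are predominantly binary flags.
  (A strong *continuous* confounder is the known hard case for
  5-stratum adjustment and can retain SMD > 0.1.)
- *Constant-HR recovery*: conditional HR 0.8 on a high-incidence,
  strongly risk-discriminating outcome (mean comparator-arm two-year risk
  ~22%, log-hazard linear-predictor sd ~1.5, risk-group tertiles). These
  values come from a design power calculation: detecting the increasing
  risk-difference pattern between *adjacent* tertiles needs
  (rd_{g+1} − rd_g)/SE ≳ 2, which at n = 20,000 requires both a large
  risk spread and a high event rate; at low incidence the ordering of two
  small, noisy risk differences is a coin flip. The experiment's problem
  sizes (50 replicates of n = 20,000; truth at n = 10⁶) are the
  package's reference settings.

## Known limitations

- Hazard-ratio "averaging" across strata assumes approximate
  within-group homogeneity; under strong HTE *within* a risk group the
  IVW pool is a precision-weighted summary, not a causal marginal HR.
- Competing risks are not modelled (sub-distribution hazards are a
  declared extension point), nor is inverse-probability weighting.
- The Gaussian systematic-error model is unimodal; multimodal residual
  confounding across controls would be summarized, not resolved.
- Rendered outputs contain no timestamps: reproducibility (byte-identical
  reruns under a fixed config hash and seed) is preferred over wall-clock
  provenance, which remains available in logs.
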