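# riskstrat

Risk-stratified assessment of treatment effect heterogeneity in
observational cohort data.

Average treatment effects from comparative cohort studies can hide large
differences between patients: on the absolute scale, a constant relative
effect produces much larger benefit in high-risk patients than in low-risk
ones. `riskstrat` implements a standardized five-step pipeline for
quantifying this risk-based heterogeneity in person-level observational
data, for epidemiologists and biostatisticians running comparative
effectiveness studies:

1. **Study definition** — target cohort `T`, comparator cohort `C`,
   outcomes `O_1..O_n`, a lookback window and a fixed time-at-risk horizon
   (default 2 years); subjects with the outcome at any time before
   treatment initiation are excluded from that outcome's analysis set.
2. **Per-database execution** — every database is an independent pipeline
   run over the same tabular schema (a cohort table and an outcome-event
   table); a simulator generates fully synthetic studies with known ground
   truth in the same schema.
3. **Risk prediction** — a LASSO logistic model for outcome risk within the
   horizon, developed on the 1:1 propensity-matched subset (caliper 0.2 on
   the standardized logit scale) so neither arm dominates the fit;
   discrimination (c-statistic with DeLong 95% CI) is reported in the
   matched, treatment, comparator and entire populations. Predicted risks
   partition patients into risk groups (fixed thresholds such as 1%/1.5%,
   or risk quantiles).
4. **Estimation** — within each risk group, a fresh LASSO propensity model
   `S(x) = P(Z=1|x)` and five propensity-score strata; per stratum a
   single-covariate Cox fit gives `log HR` (Breslow ties), and
   Kaplan–Meier curves give the risk difference at the horizon with
   Greenwood variances. Stratum log-HRs are pooled by inverse variance,
   risk differences by stratum size. Diagnostics gate every cell:
   standardized mean differences before/after stratification (rule of
   thumb |SMD| ≤ 0.1), preference-score overlap
   (`logit F = logit S − logit φ`), and empirical calibration from
   negative-control outcomes (true HR = 1), whose estimates fit a Gaussian
   systematic-error model `N(μ, σ²)` on the log-HR scale.
5. **Presentation** — tidy tables of relative (HR) and absolute (risk
   difference) effects per risk group and overall, plus all diagnostic
   data; cells failing diagnostics are reported but flagged suppressed.

## Worked example

```python
import numpy as np
from riskstrat import OutcomeModel, SimulationScenario, run_study
from riskstrat.io import scenario_to_dict

scenario = SimulationScenario(
    n=5000,
    bin_prevalences=(0.4, 0.25),
    n_continuous=2,
    treat_intercept=-0.2,
    treat_coefs=(("b1", 0.5), ("c1", 0.4)),        # confounded assignment
    outcomes=(
        OutcomeModel("o1", log_rate=-8.4, coefs=(("b1", 0.5), ("c1", 0.9)),
                     gamma0=float(np.log(0.8))),   # true conditional HR 0.8
    ),
    n_negative_controls=8,
    seed=21,
)
config = {
    "label": "SIM-A", "seed": 21,
    "simulation": scenario_to_dict(scenario),
    "study": {"outcomes": ["o1"], "risk_outcome": "o1"},
    "risk_groups": {"quantiles": 3},
}
report = run_study(config)
print(report.results.table[["scope", "outcome_id", "hr", "hr_lo", "hr_hi", "rd"]])
```

which prints (risk groups RG-1 → RG-3 are tertiles of predicted risk):

```
     scope outcome_id        hr     hr_lo     hr_hi        rd
0  overall         o1  0.818386  0.717268  0.933759  0.035962
1     RG-1         o1  0.824551  0.545595  1.246134  0.016543
2     RG-2         o1  0.728499  0.562374  0.943698  0.047120
3     RG-3         o1  0.818887  0.694151  0.966038  0.054658
```

The overall hazard ratio recovers the simulated protective effect
(HR ≈ 0.82 vs true conditional 0.8), and the absolute risk difference
(positive = fewer events under the target treatment) grows from 1.7% in
the lowest-risk tertile to 5.5% in the highest — the expected
scale-dependence of treatment effect heterogeneity under a constant
relative effect. `report.nc_estimates`, `report.calibration` and
`report.results.artifacts` hold the negative-control estimates, the fitted
systematic-error distribution and the per-scope balance/overlap
diagnostics. `render_tables(report, "out/")` writes everything as CSV.

The same pipeline runs from the shell:

```bash
riskstrat run --config study.yaml --out results/
riskstrat simulate --scenario scenario.yaml --out sim/
```

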