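# sprintcea

Eligibility screening and lifetime cost-effectiveness microsimulation of
intensive (SBP goal <120 mm Hg) versus standard (<140 mm Hg) systolic
blood-pressure treatment in a survey-style population of adults aged 45+.

The package provides:

- **`sprintcea.population`** — a synthetic survey-population generator
  (Gaussian copula over continuous risk factors with sex-stratified
  marginals, a logistic age/SBP treatment model, log-normal mean-1 survey
  weights), population CSV I/O with a column-mapping dialect, and
  survey-weighted proportion estimation with Wald CIs.
- **`sprintcea.eligibility`** — the multistep trial-eligibility screen
  (age ≥ 50; SBP 130–180 mm Hg; ≥1 high-CVD-risk condition among CHD
  history, eGFR 20–59 mL/min/1.73 m² via CKD-EPI 2009, 10-year
  general-CVD risk ≥ 15% via the sex-specific continuous Cox-form
  equation, age ≥ 75; no diabetes/stroke/HF/ESRD exclusion) and the
  weighted sequential-criterion funnel with national projections.
- **`sprintcea.risk_models`** — pluggable Cox-form risk equations,
  multi-year-to-annual risk conversion, rate-domain relative-risk
  application, life tables, and the `ModelParams` configuration (YAML
  round-trip, dotted-path access for sensitivity analyses). Shipped
  transition probabilities, costs and utilities are **plausible
  placeholders**, not the values of any specific published analysis.
- **`sprintcea.engine`** — a 9-state annual-cycle individual-level
  microsimulation (well, 3 acute, 3 post-event, 2 death states) with
  common random numbers across arms, bootstrap cohort construction, and
  life-table validation.
- **`sprintcea.economics`** — per-cycle cost/utility accrual, 3% annual
  discounting, PPP currency conversion (Int$1.00 = 3.54 yuan), and the
  1-week utility-0.5 serious-adverse-event rule.
- **`sprintcea.cea`** — ICER with full quadrant logic, national event
  scaling, one-way (tornado) sensitivity analysis, probabilistic
  sensitivity analysis, cost-effectiveness acceptability curves, and
  subgroup analyses.

## Command line

```bash
sprintcea synth-pop --n 50000 --seed 1 --out pop.csv
sprintcea screen --pop pop.csv --scale-millions 523 --out funnel.csv --eligible-out eligible.csv
sprintcea simulate --pop eligible.csv --params params.yaml --n 10000 --seed 42 --arm both --out results.json
sprintcea cea --pop eligible.csv --thresholds 16782,33564 --n-boot 2000 --psa 1000 --seed 7 --out report/
```

`screen` writes the weighted eligibility funnel (proportion, 95% CI,
represented millions per sequential criterion plus hypertension-status
subgroups). `cea` writes `summary.csv`, `tornado.csv`, `psa_scatter.csv`,
`ceac.csv`, and a plain-text report.

Model parameters live in a YAML file mirroring `ModelParams.to_yaml()`;
omitted blocks fall back to the shipped placeholder defaults.

## Notes on conventions

- Relative risks are applied in the hazard (rate) domain:
  `1 - (1 - p) ** rr`, so probabilities stay in [0, 1) for any RR.
- Costs/utilities accrue for the full cycle in which the individual is
  alive at cycle start; a death cycle contributes zero utility and zero
  life-years. Cycle 0 is undiscounted.
- Common random numbers: each individual's stream is keyed by
  (master seed, individual index) and replayed identically in both arms;
  with all RRs at 1 and equal arm costs, every per-individual delta is
  exactly zero.
- An event moves the individual into its acute state for the following
  cycle (the first, elevated-risk year after the event); absent further
  events the acute state hands over to the chronic post-event state.
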