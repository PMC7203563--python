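# akrisk

Competing-risks analysis of kidney failure after acute kidney injury (AKI)
in nephrology-clinic cohorts, built to run end to end on synthetic data:

- **`akrisk.synth`** — synthetic cohort generator: longitudinal creatinine
  series on a jittered protocolized test grid, injected AKI spike episodes,
  covariates drawn from configurable margins, and post-landmark competing
  event times (kidney failure vs death) from cause-specific exponential
  hazards with administrative censoring at 5 years.
- **`akrisk.renal`** — clinical definitions: CKD-EPI (2009) eGFR, a
  three-criterion creatinine-based AKI detector with KDIGO staging and
  recurrence, kidney-failure adjudication (long-term RRT or eGFR < 15
  sustained ≥ 90 days; 30%-decline sensitivity endpoint), and landmark
  cohort construction (follow-up starts at day 730 to avoid immortal time
  bias).
- **`akrisk.survival`** — a partial-likelihood engine fitting cause-specific
  Cox models (Efron ties) and Fine–Gray subdistribution models (Kaplan–Meier
  IPCW) by Newton–Raphson with step-halving, plus Kaplan–Meier,
  Aalen–Johansen cumulative incidence and −ln(−ln S) curves.
- **`akrisk.riskmodels`** — the published 5-year four-variable KFRE evaluated
  exactly as printed, and refitted 5-year risk equations (with/without the
  2-year AKI flag) of the form `risk = 1 − S0^exp(LP)` with the baseline
  anchored at the reference profile (age 70, female, eGFR 30, ACR 1 mg/g).
- **`akrisk.evaluation`** — Mann–Whitney AUC, paired DeLong AUC comparison,
  calibration by tenths of predicted risk with a Fine–Gray calibration
  slope, and decision-curve analysis (net benefit
  `TP/n − (FP/n)·p_t/(1−p_t)`).
- **`akrisk.pipeline` / `akrisk.cli`** — a reproducible
  generate → detect → landmark → fit → validate pipeline with report tables.

## CLI

```bash
akrisk all --config config.yaml --seed 1 --out out/           # full pipeline
akrisk generate --out out/data                                 # stages also run separately
akrisk landmark --data out/data --out out --endpoint kf15
akrisk fit      --cohort out/landmark_cohort.csv --out out
akrisk validate --cohort out/landmark_cohort.csv --out out --print-equation
```

Minimal `config.yaml`:

```yaml
scenario:
  n_patients: 5000
  seed: 1
  aki_rate_per_year: 0.12
  egfr_stage_mix: [0.36, 0.39, 0.15, 0.10]
  true_effects:
    kidney_failure: {baseline_rate: 0.045, loghr: {aki: 0.30, egfr_inv2: 1.0}}
    death:          {baseline_rate: 0.035, loghr: {aki: 0.64, age_per10: 0.55}}
analysis:
  aki_criteria: all        # all | i | ii | iii
  endpoint: kf15           # kf15 | decline30
```

A run writes `patients.csv` / `labs.csv` / `events.csv` (raw tables),
`landmark_cohort.csv` (one analysis-ready row per retained patient),
`table1_characteristics.csv`, `table2_outcomes.csv`,
`table3_stepwise_hr.csv` (AKI hazard ratios along the adjustment ladder,
per eGFR stratum), `table4_models.csv` (KFRE vs refitted models: equations,
calibration slope, AUC, DeLong p), `cif_curves.csv`, `loglog_survival.csv`,
`calibration_bins.csv` + `decision_curve.csv` (with PNG figures), and
`metrics.json` (byte-identical across reruns with the same config + seed).

Column codes in `landmark_cohort.csv`: `sex` 1 = male / 0 = female;
`proteinuria_cat` ∈ severe (ACR > 300 mg/g), moderate (30–300), none_mild
(< 30), not_tested; `event` ∈ kidney_failure, death, censored;
`time_years` ≤ 5 measured from the day-730 landmark.

## Notes and limitations

- The AKI episode-merging gap defaults to 30 days and is configurable
  (`AKIConfig.recurrence_gap_days`); staging follows standard KDIGO ratio
  bands with the ≥ 353.6 µmol/L absolute stage-3 rule.
- CKD-EPI is implemented without the race coefficient (no race variable in
  the data model).
- Fine–Gray standard errors are model-based (inverse observed information),
  not the robust sandwich form.
- Missing ACR is handled by complete-case restriction in risk-model fitting
  and validation (`acr_policy="impute_median"` optionally); the Table-3-style
  adjustment ladder instead keeps all rows via a "not tested" proteinuria
  category.
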