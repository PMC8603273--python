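# sbpcourse

Modelling of the systolic blood-pressure (SBP) course over the first 24
hours after endovascular stroke treatment, and prediction of 3-month
outcomes from each patient's deviation from a favourable-outcome
*reference course*.

The pipeline has three steps:

1. **Reference course** (`sbpcourse.course_model`) — a polynomial
   (linear/quadratic/cubic) mixed-effects model of SBP against hours since
   end of procedure, fitted by maximum likelihood on patients with the
   favourable value of an outcome. Every coefficient, including the
   intercept, carries a patient-level random effect with unstructured
   covariance G (Cholesky-parameterized, positive-definite by construction).
2. **Deviation projection** (`sbpcourse.eblup_projection`) — each patient's
   random-effects vector is predicted by the EBLUP shrinkage formula
   `G Z' (Z G Z' + σ²I)⁻¹ (q − Zα)` against the fitted course, for the full
   24-hour window and truncated 18/12/6-hour windows (with minimum
   measurement counts of 10/8/6/3 respectively).
3. **Outcome prediction** (`sbpcourse.outcome_prediction`) — logistic models
   of each binary outcome on the deviation components plus age, sex,
   baseline NIHSS, hypertension history and recanalisation success;
   percentile CIs from a bootstrap that reruns *all three steps* per
   patient resample; and an apparent-AUC stability grid across windows.

A synthetic cohort generator (`sbpcourse.synthetic_cohort`) reproduces the
monitoring protocol (21 scheduled measurements in 24 h plus 8 optional
odd-hour ones), polynomial courses with random effects, per-measurement
dropout and outcome labels from a configurable logistic model, so the whole
pipeline is testable without clinical data. Independent brute-force oracles
(dense multivariate-normal conditioning, per-patient density evaluation,
exhaustive pairwise AUC) live in `sbpcourse.validation_suite`.

## CLI

```sh
sbpcourse simulate --n-patients 300 --seed 1 --out-sbp sbp.csv --out-covariates cov.csv
sbpcourse fit      --sbp sbp.csv --covariates cov.csv --degree 1 --out course.json
sbpcourse project  --sbp sbp.csv --covariates cov.csv --course course.json --window 12 --out effects.csv
sbpcourse predict  --sbp sbp.csv --covariates cov.csv --degree 1 --out model.csv
sbpcourse bootstrap --sbp sbp.csv --covariates cov.csv --iterations 1000 --seed 1 --out model_ci.csv
sbpcourse evaluate --sbp sbp.csv --covariates cov.csv --out auc_grid.csv
sbpcourse run      --config run.yaml --seed 1      # end-to-end, writes a manifest
sbpcourse validate --seed 1 --out validation.csv   # brute-force oracle checks
```

Input format: a long SBP CSV (`patient_id, time_h, sbp_mmhg`) and a
covariate/outcome CSV (`patient_id, age, sex, nihss_baseline, hypertension,
mtici_success` plus one column per outcome; empty cell = missing label).
See `sbpcourse.io_cli.RunConfig.from_file` for the YAML run-configuration
schema (an example lives in the tests).

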