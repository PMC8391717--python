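# clical

Weighted categorical prognostic scoring for immunotherapy-treated melanoma
cohorts, with native survival statistics, a survival-random-forest validation
stage, and a calibrated synthetic-cohort generator.

## What it does

* **Scoring** (`clical.score`) — seven baseline clinical variables (age group,
  BRAF status, prior targeted therapy, LDH category, NLR category, eosinophil
  category, CNS involvement) each contribute an integer weight (1 =
  unfavorable, 2 = favorable, 3 = best LDH level). The score is the weight sum
  divided by 7, kept as an exact rational; adjacent score levels merge into
  five ordered prognostic signatures, I (worst) to V (best).
* **Cohort model** (`clical.cohort`) — patient data model, lab-value
  categorization (LDH vs. local reference, neutrophil/lymphocyte ratio, age
  dichotomization), CSV round-trip I/O with token normalization, and the
  complete-case filter the score requires.
* **Synthetic cohorts** (`clical.simulate`) — seeded generator matching the
  published category marginals, the prior-targeted-therapy ⊂ BRAF-mutated
  structural constraint, per-signature two-piece-exponential survival hitting
  the published 32-month cumulative hazards, a bisection-calibrated late
  plateau (cohort survival 20% at 70 months), uniform administrative
  censoring, signature-tilted response labels, and MCAR missingness.
* **Survival statistics** (`clical.estimators`) — native Kaplan–Meier
  (Greenwood variance, log-log CIs), Nelson–Aalen, multi-group Mantel–Cox
  log-rank, Cox proportional hazards with the Efron tie correction
  (Newton–Raphson with step-halving, Wald CIs, optional `x·log t`
  time-interaction diagnostic), and Harrell's concordance index.
* **SRF validation** (`clical.srf`) — survival random forest (delegating tree
  internals to scikit-survival) with out-of-bag tuning over a
  tree-count/mtry/node-size grid, survival-probability prediction at 12/24/36/60
  months, and probability-threshold risk grouping (three-group at 0.2/0.41, or
  five signature-sized quantile groups).
* **Evaluation** (`clical.evaluation`) — IPCW time-dependent ROC/AUC
  (cumulative cases / dynamic controls), IPCW Brier score with a
  Kaplan–Meier null reference, and the end-to-end pipeline driver.

## CLI

```sh
clical simulate --n 578 --seed 1 --out cohort.csv        # + JSON sidecar
clical score cohort.csv --out scores.csv                 # + scores_summary.csv
clical survival cohort.csv --scores scores.csv --group signature --outdir surv/
clical srf cohort.csv --seed 1 --outdir srf/
clical run --config pipeline.yaml --outdir run/
```

A pipeline config is a small YAML file:

```yaml
seed: 4
generator:
  n: 578
srf:
  ntree_grid: [50, 100, 200]
  mtry_grid: [2, 3]
  nodesize_grid: [6, 15]
```

`clical run` executes: simulate → complete-case filter → scoring →
KM/NA/log-rank by signature, agent and prior-treatment group → univariate and
multivariate Cox with a forest-plot table → 80/20 split with validation AUCs →
SRF tune/fit/predict → risk grouping → KM by SRF signature, and writes a
`manifest.json` recording the seed, calibrated plateau factor and stage
statuses. Identical config + seed reproduces every output byte-for-byte.

## Notes

* The tuning grid the forest stage uses by default in the pipeline is a
  desk-scale subset (the full published grid, up to 1000 trees, is available
  via config but takes much longer on one CPU).
* The generator calibrates the survival plateau against the *empirical*
  signature distribution of each generated cohort, so whole-cohort survival
  hits its target even though independent covariate marginals do not reproduce
  the published (correlated) score distribution.
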