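# brainagekit

A toolkit for sex-stratified brain-age modelling from ROI-level structural
MRI features, and for validating the resulting brain-age delta against
biomarkers of Alzheimer's disease and neurodegeneration. The package covers
the full analysis chain:

- **`synthetic_data`** — multi-cohort synthetic dataset generator with known
  ground truth: uniform age ranges, sex/site/TIV-structured ROI trajectories
  with sex × age interactions, a latent per-subject ageing acceleration
  (delta, in years), APOE-genotype and diagnosis shifts, a biomarker panel
  (CSF Aβ42, CSF p-tau, CSF/plasma NfL, WMH, Centiloids) with configurable
  standardized effects, and a follow-up visit advanced along each subject's
  own trajectory.
- **`harmonize`** — residualization of volumes on TIV + scanning site and of
  cortical thickness on site, followed by feature-wise z-scoring within each
  cohort (frozen models can be applied to new subjects).
- **`brainage`** — one gradient-boosted tree regressor per sex arm with an
  order-locked feature schema, repeated k-fold CV metrics (MAE, RMSE,
  Pearson R, R² as squared R), a sequential model-based hyperparameter tuner
  with a grid fallback (defaults return the published per-sex optima), and
  the model-comparison statistics (Fisher z, Williams' t, variance-ratio F).
- **`bias_delta`** — age-bias correction `corrected = predicted +
  (age − (α·age + β))` with α, β fit per evaluation cohort (or frozen from a
  reference sample), and the brain-age delta.
- **`importance`** — exact tree-Shapley attributions (hand-built
  path-dependent algorithm, numba-accelerated, verified against a
  brute-force coalition oracle), sex-specific importance maps with a
  female − male contrast, and a stability/permutation significance
  procedure (permutation-null by default, subsample-stability alternative)
  with Bonferroni correction.
- **`biomarkers`** — amyloid/tau staging with per-cohort cut-offs shipped as
  versioned YAML (CSF Aβ42 1098/880 pg/mL, p-tau 24 pg/mL, 17 Centiloids;
  strict-inequality boundary convention), A−T+ exclusion, the surface-area
  weighted ageing-signature thickness composite and its annualized change,
  NfL log + within-cohort z transforms, WMH log + TIV residualization.
- **`associations`** — the covariate-adjusted validation battery:
  standardized linear associations, ANCOVA-style categorical contrasts with
  Cohen's d, Cohen's f², sex/age interaction tests, Benjamini–Hochberg FDR
  over the whole family, and extreme-percentile subject selection.

## CLI

The console script `brainagekit` chains the pipeline on CSV tables:

```bash
brainagekit simulate --n 1000 --seed 7 --out data/
brainagekit harmonize --features data/features.csv --subjects data/subjects.csv \
    --out harmonized.csv --model harmonization.json
brainagekit train --features harmonized.csv --subjects data/subjects.csv \
    --cv 10x10 --seed 7 --out model/
brainagekit delta --predictions pred.csv --subjects data/subjects.csv \
    --per-cohort --out delta.csv
brainagekit importance --model model/model.joblib --features harmonized.csv \
    --subjects data/subjects.csv --arm female --replicates 1000 \
    --mode permutation-null --out importance.csv
brainagekit associate --delta delta.csv --biomarkers data/biomarkers.csv \
    --subjects data/subjects.csv --strata CU,MCI --out results.csv
```

## Acceptance

Acceptance is property-based (the study's real-data cohorts are
access-restricted): bias-correction orthogonality, recovery of the latent
ageing acceleration on synthetic cohorts, planted-effect and stage-ordering
recovery, oracle equivalences for every closed-form statistic, and
importance-significance calibration. These are enforced by
`tests/test_acceptance.py` (one test per criterion). The report script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs an end-to-end smoke of the pipeline and writes the (empty) numeric
target report — there are no published point values reproducible without
the restricted cohorts.
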