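# ssmmed

Statistical pipeline for ROI-level brain-aging cohorts: derivation of a
biomarker-related subcortical covariance pattern (Scaled Subprofile Model),
block-wise regression of lobar cortical volumes with Benjamini–Hochberg FDR
correction, and serial mediation (1–3 ordered mediators) with percentile
bootstrap confidence intervals and completely standardized effect sizes.
A synthetic-cohort generator with a planted causal chain and covariance
pattern makes every stage testable without external data.

## Modules

| module | contents |
|---|---|
| `ssmmed.cohort` | synthetic cohort + subcortical volume matrix generation (`CohortConfig`, `generate_cohort`, `plant_pattern`) |
| `ssmmed.ssm` | SSM workflow: log/TIV preprocessing, double-centering, PCA, AIC prefix selection, pattern combination, expression scoring, bootstrap weight reliability |
| `ssmmed.glm` | block-wise OLS with standardized coefficients, exact t inference, BH-FDR, residualization and log transforms |
| `ssmmed.mediation` | serial mediation engine: path estimation, indirect-path enumeration, percentile bootstrap, total/direct decomposition, reversed-order sensitivity |
| `ssmmed.pipeline` | end-to-end orchestration with FDR gating, covariate tiers, and a structured, reproducible report |

## CLI

```bash
ssmmed simulate --n 160 --seed 42 --out data/
ssmmed derive-pattern --volumes data/volumes.csv --pheno data/cohort.csv \
    --biomarker hcy --boot 10000 --seed 7 --out pattern/
ssmmed regress --pheno data/cohort.csv \
    --outcomes frontal,temporal,parietal,occipital --focal expression \
    --blocks "tiv|age,sex,education" --out table2.csv
ssmmed mediate --pheno data/cohort.csv --x age --m log_wmh,true_expression \
    --y tmta_log --cov tiv,sex,education,interval_days --boot 10000 \
    --seed 11 --out mediation/result
ssmmed run-all --config study.yaml --out results/
```

`study.yaml` accepts the `StudyConfig` fields (flat) plus a nested `cohort`
block of `CohortConfig` fields; see `ssmmed.pipeline.load_study_config`.
Release runs should set `n_boot: 10000`; the default of 500 is a scaled-down
test setting.

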