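# globinscreen

Quantification of haemoglobin chains from linear-mode MALDI-TOF blood
spectra, and machine-learning screening of thalassaemia built on the
resulting chain-imbalance features. Because no public spectra exist for this
assay, the package ships a first-class synthetic cohort generator that
emulates the acquisition (Gaussian globin and myoglobin internal-standard
peaks at 1+ and 2+, exponential baseline, additive noise, calibration
drift) with per-sample ground truth, so the entire pipeline is testable
offline.

## Modules

| module            | role |
|-------------------|------|
| `synthcohort`     | synthetic spectra + manifests with disease-dependent chain imbalance and linked clinical covariates (Hb, Hb F, Hb A2) |
| `spectra_io`      | two-column ASCII spectra, manifest/feature-table CSVs, JSON reports, `run.json` provenance |
| `specproc`        | smoothing, SNIP baseline removal, peak picking, one-point internal-standard m/z recalibration, 3000 ppm peak matching, internal-standard normalisation |
| `globin_features` | the 10 screening features per sample (α/β/γ intensities per charge, α/β ratio and α−β difference per charge) |
| `screenmodels`    | single-feature rank AUC selection, stratified 2:1 splitting, 8 classifier families, DeLong AUC CIs, sensitivity/specificity/accuracy/precision |
| `reportstats`     | Spearman feature–clinical matrix, PCA overview, β-vs-non-β / α-vs-non-α task groupings, end-to-end pipeline orchestration |

## CLI

```sh
globinscreen simulate --config config.yaml --out sim/ --seed 1
globinscreen process  --in sim/cohort1 --manifest sim/manifest_cohort1.csv --out features.csv
globinscreen train    --features features.csv --select top5 --methods all --seed 1 --out models/
globinscreen pipeline --config config.yaml --out run/
globinscreen report   --run run/
```

A pipeline configuration is YAML with `seed`, `cohorts` (per-cohort
`n_per_class`), optional `profiles` and `acquisition` overrides, `tasks`
(each with a `{top_k: N}` or `{auc_min: T}` selection rule), `methods`,
`threshold` (a probability or `youden`) and `split`. See
`reportstats.DEFAULT_CONFIG` for the full schema and defaults.

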