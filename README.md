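# somaclass

Tumor-only somatic vs germline variant classification with gradient-boosted
tabular models.

When a patient's matched-normal sample is unavailable, most putative somatic
calls in a tumor exome are actually rare germline variants, which inflates
tumor mutational burden (TMB) estimates — most severely for patients from
ancestry groups under-represented in population databases. `somaclass`
implements a complete, testable pipeline for this problem:

- **variant_io** — annotated VCF reading (pysam), SEG/BED parsing, a
  versioned lossless TSV interchange format, and `pop_max` aggregation over
  eight germline population databases.
- **pon** — leave-one-out variant-level panels of normals (keys recurrent in
  ≥2 of the other patients' normals), with a leakage guard.
- **prefilter** — the pre-classification filter: caller PASS, artifact-filter
  PASS, coding ontology whitelist, `pop_max < 0.01`.
- **features** — the model-ready matrix: scalar read/database features, a
  20-bin VAF histogram of informative SNPs sharing the variant's copy-number
  segment, and one-hot ontology / pyrimidine-centered substitution /
  flanking-context encodings (53 columns, schema-versioned and hashed).
- **labels** — somatic/germline truth labels from a matched-normal call set.
- **models** — two gradient-boosted tree backends behind one interface, per
  category (SNV/indel) F1-optimal threshold selection on a 500-quantile
  grid, ensemble averaging, permutation feature importance. An attentive
  deep tabular backend is an optional plugin (`pip install somaclass[tabnet]`).
- **evaluate** — confusion-count metrics (TPR/TNR/PPV/NPV/MCC/balanced
  accuracy), exact rank-based and quantile-grid ROC/PR AUC, TMB concordance
  regressions, Wilcoxon rank-sum ancestry-bias reports, TPR-vs-MVTSM and
  FP/TN contingency analyses.
- **tmb** — naive / model-corrected / truth TMB with per-kit footprint
  normalization or a pooled patient-weighted constant.
- **simulate** — a synthetic cohort generator (purity, copy-number segments,
  clonal/subclonal somatic VAFs with binomial read noise, rare and
  ancestry-dependent germline variants, informative SNPs, COSMIC and
  mutational-spectrum structure) so the full pipeline is exercisable without
  controlled-access data.

## CLI

```sh
# simulate a truth-labeled cohort
somaclass simulate --seed 1 --out scratch/cohort

# train models on a (freshly simulated) cohort
somaclass train --seed 1 --model lgbm --model xgb --out scratch/models

# evaluate on a held-out simulated cohort: metrics, TMB tables, bias report
somaclass evaluate --seed 2 --model-dir scratch/models/gbt_lgbm_like \
    --norm-mb 30 --out scratch/eval

# file-level building blocks
somaclass build-pon --cohort-dir scratch/cohort --leave-out P000 --out scratch/pon
somaclass filter --variants scratch/cohort/P000/P000.variants.tsv --out scratch/filtered
somaclass featurize --cohort-dir scratch/cohort --out scratch/feat
somaclass predict --matrix scratch/feat/matrix.tsv \
    --model-dir scratch/models/gbt_lgbm_like --out scratch/preds
somaclass tmb --matrix scratch/feat/matrix.tsv \
    --predictions scratch/preds/predictions.tsv --norm-mb 30 --out scratch/tmb
somaclass bias-report --cohort-dir scratch/cohort \
    --tmb-table scratch/tmb/tmb.tsv --out scratch/bias
```

Every run writes a `run_manifest.json` with the resolved seeds and feature
schema hash; identical config + seed reproduces identical artifacts.

## Notes

- The gradient-boosted backends are scikit-learn
  `HistGradientBoostingClassifier` instances configured with two distinct
  hyperparameter profiles (leaf-wise-style: 30 leaves / lr 0.1; depth-wise
  defaults: depth 6 / lr 0.3); the originally used boosting libraries are
  not required at runtime.
- All randomness is seeded; cohort simulation flows through per-patient
  child streams of a single root seed, so generation order cannot change
  results.
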