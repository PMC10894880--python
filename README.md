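# histofuse

Two-tier whole-slide-image (WSI) classification pipeline:

1. **Slide preparation** — tile pyramidal slides (or pre-tiled directories)
   into non-overlapping 512×512 tiles at 0.5 µm/pixel, drop background tiles
   (HSV-saturation rule), normalize color with the Macenko method and
   intensity with training-set Z-scores, with random flip augmentation for
   training.
2. **Patch model** — a convolutional patch classifier trained by transfer
   learning under two cosine-decay learning-rate schedules (the backbone is
   frozen for the first half of training, then fine-tuned), emitting per-tile
   class likelihoods, predicted labels, and Grad-CAM heatmaps.  The default
   backbone is a small from-scratch numpy CNN so everything runs on one CPU.
3. **Multi-instance fusion** — patch likelihoods are discretized (one decimal
   for the diagnostic setting, two for the prognostic setting) and aggregated
   per document (all slides of a case, or one designated slide) through two
   pipelines: a patch-likelihood histogram (`hist_-<token>` features) and a
   TF-IDF bag of words (`bow_<token>` features).  The binary prognostic
   configuration yields exactly 206 feature columns.
4. **Signature** — 7:3 case-level cohort split, Welch t-test feature filter,
   and grid-searched classifiers (RBF SVM, random forest, ExtraTrees, two
   gradient-boosting families, 128/64/32 MLP) selected by 5-fold CV AUC.
5. **Evaluation** — ROC-AUC with DeLong 95% CIs, one-vs-rest micro/macro AUC,
   confusion matrices with sensitivity/specificity, the DeLong paired-AUC
   test, decision-curve analysis, tile probability heatmaps, and t-SNE.
6. **Findings screen** — per-feature Welch t-test association with binary
   pathological findings, with raw and Benjamini–Hochberg adjusted p-values.

A synthetic-cohort module generates multi-slide cohorts (likelihood tables
and/or H&E-like tile images with planted stain vectors, textures, and
finding–feature associations) so the full pipeline is testable end to end
without clinical data.

## CLI

```sh
histofuse simulate --out sim --cases-per-class 30 --seed 4
histofuse fuse --likelihoods sim/likelihoods.csv --cohort sim/cohort.csv \
    --out fused --preset prognostic
histofuse fit-signature --features fused/features.csv --cohort fused/cohort.csv \
    --family SVM --out model
```

## Notes

- The tree-model hyperparameter grid enumerates n_estimators 10–50 step 5 ×
  max_depth {2,3,4,5} = 36 configurations (some descriptions of these same
  ranges quote 40 models; the stated ranges are implemented).
- XGBoost/LightGBM model families are backed by scikit-learn's gradient
  boosting implementations (`GradientBoostingClassifier`,
  `HistGradientBoostingClassifier`) so no extra native dependencies are
  required.
- Operating threshold for accuracy/sensitivity/specificity defaults to 0.5;
  AUC confidence intervals use the DeLong variance estimator.
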