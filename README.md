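# serumml

Serum peptidome diagnostics from MALDI-TOF mass spectrometry: an end-to-end,
testable implementation of the biomarker-screening workflow used in
case-control studies of cancer versus healthy sera — spectrum cleaning, peak
detection and cross-sample alignment, differential peptide screening,
multi-classifier benchmarking, attribution-consensus feature selection, and
clinical-utility validation (Youden-optimised ROC, decision-curve analysis,
clustering concordance).

Patient sera from such studies are typically not deposited, so the package
ships a first-class synthetic cohort generator with a known truth channel:
planted Gaussian peptide peaks, baseline drift, instrumental mass drift,
matrix-cluster artifacts, and a configurable set of up/down-regulated peaks
with controlled log2 fold changes. Every downstream stage can therefore be
scored against ground truth.

## The pipeline

1. **Preprocess** (`serumml.preprocess`) — Savitzky–Golay smoothing
   (window 21, polyorder 10), centered moving-median despiking (window 10),
   white top-hat baseline removal (flat element, 11 points).
2. **Peaks** (`serumml.peaks`) — `find_peaks`-style detection (height ≥ 3% of
   the spectrum maximum, width ≥ 5 grid points), flagging of the
   matrix-cluster region (m/z 1500–2000), iterative greedy alignment at a
   2500 ppm tolerance (absorbing ±1500 ppm instrumental drift), relative-area
   row normalisation, zero/linear imputation, replicate averaging.
3. **Screening** (`serumml.screening`) — per-feature two-sided Mann–Whitney U
   with log2FC = log2(mean_cancer / mean_healthy); volcano calls at
   p < 0.001 and |log2FC| > 1; top-k shortlists.
4. **Bench** (`serumml.bench`) — eight classifiers (KNN, SVM, Gaussian NB,
   decision tree, random forest, XGBoost, AdaBoost, LightGBM) under 80/20
   stratified splitting and 5-fold stratified CV; per-class and macro
   ROC/AUC, pooled confusion matrices, accuracy/precision/recall/F1.
5. **Interpret** (`serumml.interpret`) — Gini importances, kernel-method
   Shapley values (200 background samples; exact for ≤ 11 features), LIME
   local ridge surrogates; top-20 majority-vote consensus and the
   cross-model importance intersection.
6. **Clinical** (`serumml.clinical`) — oriented single-feature ROC,
   100-threshold Youden index optimisation, decision-curve analysis with
   net benefit NB(t) = TP/N − (FP/N)·t/(1−t), treat-all/treat-none
   references, fold-wise 95% CI bands and Simpson-integrated benefit area.
7. **Cluster** (`serumml.cluster`) — bisecting K-means and BIRCH
   (threshold 0.5, branching factor 50) scored by Rand index and AMI;
   PCA/KPCA/t-SNE/UMAP embeddings.

## Worked example

Run the numbered drivers in order (each reads the previous stage's tables
from `results/`):

```bash
python analysis/01_simulate_features.py     # cohort -> feature matrix
python analysis/02_screen_differential.py   # volcano screening
python analysis/03_benchmark_classifiers.py # 8-model CV benchmark
python analysis/04_feature_attribution.py   # Gini/SHAP/LIME consensus
python analysis/05_clinical_validation.py   # ROC / Youden / DCA
python analysis/06_clustering.py            # unsupervised concordance
```

Output of the first three stages on the default cohort (seed 17):

```
cohort: 240 cancer + 249 healthy, 3 replicates -> 1467 spectra
feature matrix: 489 samples x 144 aligned features (16.6% cells undetected before imputation)
planted: 19 up, 23 down within 1522-5863 Da

19 upregulated and 23 downregulated features (p < 0.001, |log2FC| > 1) out of 144

knn            macro AUC 1.00 +/- 0.00  acc 1.000  f1 1.000
svm            macro AUC 1.00 +/- 0.00  acc 0.998  f1 0.998
gaussian_nb    macro AUC 1.00 +/- 0.01  acc 0.996  f1 0.996
random_forest  macro AUC 1.00 +/- 0.00  acc 1.000  f1 1.000
...
```

The screening stage recovers exactly the planted differential structure
(19 up, 23 down), and with |log2FC| = 2.5 effects at 15% within-group CV the
classes are fully separable, so the strong classifier families reach a
cross-validated macro AUC of 1.00. Stage 5 then reports per-feature AUC,
the optimal Youden threshold and the decision-curve net-benefit area; stage
6 shows both clustering methods agreeing perfectly with the clinical labels
on the differential features (Rand = 1.0).

A single-command alternative is the orchestrated pipeline with a YAML
config (`serumml run --config cfg.yaml`), or per-stage subcommands
(`serumml preprocess|peaks|screen|bench|explain|clinical|cluster`).

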