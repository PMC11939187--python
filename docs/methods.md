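# Methods

## Scope and data model

The package reproduces a serum-peptidome diagnostic workflow: linear-mode
MALDI-TOF spectra of enriched serum peptides (m/z 1000–15,000 Da) from a
two-group case-control cohort, measured in triplicate, reduced to a
samples × aligned-peaks matrix of relative peak areas and pushed through
differential screening, supervised benchmarking, attribution-based feature
selection and clinical-utility validation. Because cohorts of this kind are
rarely deposited, all analyses run on a synthetic cohort whose generative
process and truth channel are part of the package.

## Synthetic cohort generator (`synth`)

Each spectrum is

    y(m) = Σ_i h_i · exp(−(m − c_i)² / 2σ²) + baseline(m) + ε(m)

on a shared 1 Da grid.

* **Peak placement.** 120 shared peptide peaks, log-spaced over
  1020–14,700 Da with small jitter (capped at 1% in log-m/z). Log spacing
  gives inter-peak gaps of ≈ 23,000 ppm, comfortably above the 2500 ppm
  alignment tolerance plus ±1500 ppm drift, so feature identity is
  well-defined and recovery is scoreable.
* **Peak shape.** Gaussian with a common σ = 2.5 Da: FWHM ≈ 5.9 grid points
  passes the 5-point width gate while staying narrow relative to the
  11-point top-hat element; a common shape also makes height and area fold
  changes identical, so truth fold changes are analytic.
* **Intensities.** Null-peak mean heights are log-uniform in 20–100
  (arbitrary units). Per sample, each peak's height is its group mean times
  a log-normal factor with unit mean and CV 0.15; replicates multiply in a
  further unit-mean log-normal with CV 0.05 (triplicates are near-copies of
  the sample, mirroring the high reproducibility of replicate spots).
  Because the multiplicative noise has unit mean, the expected group-mean
  ratio of a planted peak equals 2^log2FC exactly.
* **Differential structure.** The default cohort (240 cancer, 249 healthy)
  plants 19 upregulated and 23 downregulated peaks at |log2FC| = 2.5,
  placed in 1500–6000 Da. Up- and down-regulated base amplitudes are
  rescaled so the expected total ion signal is equal in the two groups.
  This matters: the feature matrix is row-normalised, so an unbalanced
  total would shift every null feature's relative area by the group total
  ratio and manufacture spurious calls. With balanced totals the null
  features stay null and the volcano counts measure the screening path,
  not a normalisation artifact.
* **Nuisance processes.** Baseline = amplitude 5 × (exponential decay,
  2000 Da scale, plus a broad parabolic hump), per-replicate scale jitter;
  additive Gaussian trace noise (SD 0.3); per-replicate global mass drift
  uniform in ±1500 ppm plus 100 ppm per-peak jitter; matrix-cluster
  artifact peaks appear in 1500–2000 Da with probability 0.05 per
  replicate.
* **Not emulated:** isotope envelopes, adducts, detector saturation,
  m/z-dependent peak width, heteroscedastic electronic noise, batch
  effects, or any biological covariance between peptides. Passing tests on
  this cohort therefore demonstrate the correctness and calibration of the
  pipeline's statistics, not clinical performance on real sera.

## Preprocessing (`preprocess`)

Savitzky–Golay (window 21, polyorder 10; polynomial-extension edges) →
centered moving median (window 10) → white top-hat (flat element, 11
points; reflected padding). The 21/10 filter order is unusually high but
kept as the workflow specifies; it is exposed in the config. The even
median window is centered with the extra point on the left and the lower
of the two middle order statistics taken, a frozen convention the tests
pin against a brute-force oracle. Negative residuals after the top-hat are
clipped to zero so areas stay non-negative. The m/z grid is never altered.

## Peaks and alignment (`peaks`)

Detection uses `scipy.signal.find_peaks` with height ≥ 3% of the spectrum
maximum and width ≥ 5 points at half prominence. Areas are trapezoid
integrals between peak bases; centroids are intensity-weighted means over
the half-prominence core only (full-base centroids are skewed by
neighbouring tails and baseline residue). Peaks in 1500–2000 Da are
flagged, not removed, by default: differential peptides are reported in
1500–6000 Da, so silent removal would destroy signal (removal is available
as an option).

Greedy alignment: repeatedly seed a consensus feature at the unassigned
peak with the largest ppm-window-aggregate intensity; gather each
replicate's nearest unassigned peak within 2500 ppm of the centroid;
re-centre once on the height-weighted member mean and re-gather; assign.
Tolerance is always measured against the current consensus centroid, which
absorbs drift. The result is a partition: every peak belongs to exactly one
feature, and a feature holds at most one peak per replicate. Matrix cells
are relative areas (row areas over the row's total detected area — peak-sum
normalisation, not raw TIC); undetected cells are imputed (zeros by
default, per-row linear interpolation in feature-m/z as an option) and
replicates are averaged last. Replicate spectra are aligned individually
and collapsed afterwards.

## Screening (`screening`)

Two-sided Mann–Whitney U per feature (exact-null enumeration when the
smaller group has ≤ 8 samples and no ties; tie-corrected normal
approximation otherwise — the cohort sizes here always use the latter).
log2FC = log2((mean_c + ε)/(mean_h + ε)) with ε = 1e-9 of the grand mean to
guard zero-imputed features. Volcano calls at p < 0.001 and |log2FC| > 1;
raw p-values by default (the thresholds are conventionally applied to raw
p in this workflow), Benjamini–Hochberg available as an option. Tie-breaks
in top-k shortlists are by ascending m/z, making shortlists deterministic.

## Benchmarking (`bench`)

All eight classifiers run at library-default hyperparameters, frozen —
the benchmark compares model families, not tunings. KNN and SVM sit behind
a fold-fitted standardiser (scale-sensitive); tree ensembles are left on
raw relative areas. ROC/AUC per class and per fold are computed one-vs-rest
from validation-fold probabilities; the macro AUC averages the per-class
values (identical per class in the binary case, reported per class anyway
for symmetry with multi-class extensions). The pooled out-of-fold confusion
matrix uses a 0.5 probability threshold; undefined metric ratios are
reported as 0 with a warning.

## Attribution (`interpret`)

* **Gini importances** come from the fitted tree model, normalised to sum
  to 1.
* **Kernel SHAP** is implemented directly: coalition value
  v(S) = E_b f(x_S, b_{\bar S}) over a 200-row background drawn from the
  training set; weighted least squares over coalitions with the Shapley
  kernel; the efficiency constraint is enforced by coefficient
  elimination, so local accuracy (base + Σφ = f(x)) holds to numerical
  precision by construction. With ≤ 11 features every non-trivial
  coalition is enumerated and the solution is the exact Shapley vector
  (verified against a direct subset-enumeration oracle); above that,
  coalition sizes are sampled from the kernel distribution with a budget
  of 2^min(d,11) capped at 2048.
* **LIME** fits a ridge surrogate per explained instance on 5000 Gaussian
  perturbations at the feature scale, weighted by an exponential proximity
  kernel of width 0.75·√d, keeping the top-10 surrogate weights per
  instance. Global signed scores are mean signed weights; ranks follow
  mean |weight|.
* **Consensus**: features in the top-20 of ≥ 2 of the 3 methods are
  selected first; remaining slots fill by ascending average rank, ties by
  ascending m/z.
* **Cross-model importance intersection**: the top-m (default 10)
  positive-importance features of decision tree, random forest, LightGBM
  and XGBoost are intersected. Zero-importance features never count: a
  feature a tree never splits on is not important, and including
  tie-broken zeros would make single-tree lists arbitrary. A caveat worth
  stating: on a perfectly separable cohort a single CART tree achieves
  purity with one split, so the intersection can legitimately be empty or
  a singleton — the statistic is informative only when each top feature is
  individually insufficient, which is also the regime the recovery test
  uses (three planted features at |log2FC| = 1, CV 0.4, 200 + 200
  samples, top-m 5).

## Clinical utility (`clinical`)

Single-feature ROC orients scores so that higher = more cancer-like when
the cancer mean exceeds the healthy mean and inverts otherwise; AUC is
computed on oriented scores (so the reported AUC ≥ 0.5 whenever means and
ranks agree). Youden optimisation scans 100 equally spaced thresholds over
the oriented score range, calling positive at score ≥ t, and returns the
lowest maximiser of J = sen + spec − 1.

Net benefit at probability threshold t is NB = TP/N − (FP/N)·t/(1−t).
Two treat-all references are provided: the **standard** prevalence form
π − (1−π)·t/(1−t), and an **as-printed** variant whose denominator is
TP + TN under the classify-everyone-positive rule (reducing to
1 − (n_neg/n_pos)·t/(1−t), since TN = 0). The as-printed variant is the
default for fidelity to the workflow being reproduced; it is almost
certainly a transcription slip for total N in the source material — the
standard form is the mathematically conventional reference and is one flag
away. Cross-validated DCA computes fold-wise curves from validation
probabilities, reports mean ± 1.96·SD/√k as the 95% band, and integrates
max(NB, 0) by Simpson's rule. Single-feature DCA maps grid point t to the
indicator's t-quantile ("high" direction) or (1−t)-quantile ("low"), which
makes the low direction on v exactly the high direction on −v.

## Clustering (`cluster`)

Bisecting K-means recursively 2-means-splits the cluster with the largest
within-cluster SSE (10 restarts, seeded). BIRCH builds a CF tree
(threshold 0.5, branching factor 50) and clusters leaf centroids
agglomeratively to k = 2. Both standardise features first (flag-controlled):
the CF-radius threshold of 0.5 is only meaningful on an O(1) scale, and raw
relative areas (~10⁻²) would collapse the entire cohort into a single CF
entry. Concordance against labels uses the Rand index and adjusted mutual
information. Embeddings (PCA/KPCA/t-SNE/UMAP) run on raw values, seeded.

## Orchestration and reproducibility

A single pydantic-validated YAML config drives the full pipeline
(synth → preprocess → peaks → screening → bench → interpret → clinical →
cluster); unknown keys are rejected, errors name the offending key. One
global seed fans out to per-stage seeds through a SHA-256 derivation, so
stages are individually reproducible and re-running a config reproduces
byte-identical tables.

## Problem sizes

The default cohort (489 samples × 3 replicates, 14,001-point spectra)
builds its feature matrix in ~15 s on one CPU; the five-model CV benchmark
adds ~5 s. The attribution stage explains 8 samples by default (kernel
SHAP at the 2048-coalition budget over a 200-row background). The recovery
and null-calibration test cohorts use single replicates at 100–200 samples
per group, chosen so the full suite completes in a few minutes.

## Known limitations

* Generator distributions are stand-ins; no distributional description of
  real sera informs them beyond the structural facts above.
* The Mann–Whitney choice for the per-feature screen is a documented
  convention; the source workflow does not name its test.
* Peak width is m/z-independent, so resolution effects on alignment are
  not exercised.
* The importance-intersection statistic degenerates on perfectly separable
  data (see above); interpret an empty intersection as "the ensemble needs
  fewer features than claimed", not as failure.
* The as-printed treat-all curve is not a calibrated clinical reference;
  use the standard variant for any real decision analysis.
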