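# Methods

`contraconn` implements an analysis pipeline for the question: *do
left-hemisphere gliomas leave a systematic, classifiable signature in the
right (contralesional) hemisphere's resting-state functional connectome?*
This note documents the models, estimators and numerical conventions the
package uses, the design choices made where the procedure is genuinely
open, and what the synthetic cohorts do and do not establish.

## Connectivity representation

Functional connectivity (FC) between two parcels is a Fisher-z-transformed
correlation, z = arctanh(r). For each subject the pipeline works on the
M = N(N−1)/2 edges among the N right-hemisphere parcels of a homotopically
paired atlas (M = 4950 at the 100-parcels-per-hemisphere scale), flattened
in row-major upper-triangle order (i < j, 1-based ROI ids in files,
0-based internally; file headers name each edge `e<i>_<j>`).

Each subject's edge vector is then z-scored to mean 0 and sample standard
deviation 1 (denominator n−1) — the **RRCz** representation. This removes
subject-level offsets and scale in overall connectivity (including
scanner-related magnitude differences), so all downstream models see only
the *pattern* of connectivity. The sample-sd convention is fixed for bit
reproducibility. A consequence worth keeping in mind: RRCz rows live on a
sphere (each row has identical norm), so any common additive component of
a group effect is removed and only pattern differences remain learnable.

## Classification protocol

All classifiers are linear SVMs (L2-regularized hinge loss, dual solver,
tolerance 1e−6, deterministic given the seed). Evaluation is nested
cross-validation:

* **outer loop**: leave-one-out (LOOCV); every subject is predicted by a
  model that never saw it. With 155 subjects the out-of-fold prediction
  vector has length 155.
* **inner loop**: stratified 5-fold CV (or inner LOOCV for the ROI-level
  models) on the training portion only, selecting the regularization
  parameter C from a grid — default {0.01, 0.1, 1, 10, 100}, selection by
  balanced accuracy, ties toward smaller C. With a single-value grid the
  inner loop is skipped.
* **class weights**: "dynamic" balanced weights n_total/(2·n_class),
  recomputed on each training set. At the 48/107 design this gives 1.6146
  (patients) and 0.7243 (controls).
* **feature selection** (where enabled): MRMR, refit inside every outer
  training fold.

Repeated evaluation re-runs the nested CV with re-shuffled inner-fold
assignments only (the SVM solver seed stays fixed), so configurations
with no inner randomness are exactly reproducible across repeats.

Metrics come from the out-of-fold confusion matrix: accuracy, precision
(positive predictive value), recall (sensitivity) and the Matthews
correlation coefficient (MCC). Precision/recall with a zero denominator
are reported as undefined (NaN + flag), distinct from zero; MCC with a
zero denominator factor is 0 by convention, flagged.

## MRMR feature selection

Minimum-redundancy-maximum-relevance ranks features greedily by the
mutual-information quotient: relevance MI(feature; label) divided by the
mean MI with already-selected features (the first feature scores its raw
relevance). MI is estimated on equal-frequency quartile bins computed on
the training data. Two estimator details matter at the sample sizes this
pipeline sees (n ≈ 50):

* the plug-in MI estimate is biased upward by roughly
  (k_a−1)(k_b−1)/(2n) under independence; the Miller–Madow correction is
  subtracted and the estimate clamped at 0, otherwise pure-noise features
  inherit the bias floor as apparent relevance;
* the quotient's denominator is floored at 0.1 nat; after bias correction
  most redundancies are ≈ 0, and an unfloored quotient would promote
  noise features purely for being unredundant.

Ranking stops when the best score falls below the threshold τ (τ = 0.05
for the tumor-characteristic models) or when `max_features` — default
min(n−1, 50), a guard against overfitting the selection itself — is
reached. If τ excludes everything, the single most relevant feature is
returned and flagged.

## Permutation inference

Significance of any out-of-fold metric is assessed by Monte-Carlo
permutation: labels are scrambled, the **full** pipeline (feature
selection, weights, C-tuning, all inside folds) is re-run against the
permuted labels, and the observed metric is compared with the null
distribution via the conservative empirical p-value **p = (r+1)/(n+1)**,
where r counts null samples ≥ the observed value. The floor is 1/(n+1)
(0.001 at n = 1000). Permutation seeds are base_seed + iteration index.
Null samples for which a metric is undefined (e.g. precision when a
permutation produces no positive predictions) are stored as NaN and
excluded from both the null mean and the r/n counts; this convention is
the package's own, as no standard exists.

The regional screen is two-stage: a 100-iteration permutation screen on
MCC selects candidate ROIs (p < 0.05), which then receive a
1000-iteration test on MCC, accuracy, precision and recall; an ROI is
reported significant only if all four pass. ROI-level models run once
(inner LOOCV) rather than 100 repeats.

## Lesion mapping

Lesion masks are binary volumes co-registered with the atlas label image
(no resampling is performed; grids must match). Per (patient, left ROI):
intersection fraction = |lesion ∩ ROI| / |ROI|; presence is called at an
inclusive 1% threshold; an ROI enters the regional analyses when at least
20% of patients are lesion-present (count cutoff = ceil, i.e. n ≥ 10 at
48 patients). Overlap maps are voxelwise sums of masks; cluster contrasts
divide each cluster's map by its own maximum before subtracting, bounding
the difference in [−1, 1] and controlling for cluster size.

Voxelwise cluster comparisons use Barnard's unconditional exact test on
the 2×2 table (lesion present/absent × cluster). The test statistic is
the pooled-variance (Wald) score for a difference of proportions; the
p-value maximizes the tail probability over a grid of the common success
probability (step 1e−3 by default, 1e−4 where oracle-grade precision is
wanted). Only voxels lesioned at least once are tested (others get
p = 1), and the significance map is uncorrected by design — it is an
exploratory contrast. Equal-statistic tables are included in the tail
within 1e−10 tolerance.

## Other statistics

* **Wilcoxon rank-sum**: mid-ranks, tie-corrected variance, continuity
  correction, z-statistic and two-tailed normal p — matching the
  approximate method of the major commercial statistics environments
  (needed to reproduce printed z/p values at two decimals). A toggle
  disables either correction.
* **Spearman**: mid-rank Pearson correlation with the two-tailed
  t-approximation on n−2 degrees of freedom; constant input is flagged
  undefined.

## Patient clustering

k-means on patient RRCz rows (Euclidean, k-means++ initialization, 20
restarts, best inertia); k chosen by mean silhouette over k = 2..10, ties
toward smaller k. None of these settings is canonical; they are declared
defaults.

## The synthetic cohort generator

The generator emulates the *structure* of the study data, not its
physiology. Controls' raw edges are Normal(μ_e, σ²) i.i.d. across edges
(μ_e ~ N(0.25, 0.15²), σ = `noise_sd`, default 1) plus a per-subject
intercept (sd 0.1) that RRCz removes by construction. Interhemispheric FC
is generated alongside: each left ROI's homotopic pair mean is drawn
uniformly from `pair_coupling_range` (default 0.3–1.2 Fisher-z) and
non-homotopic pairs sit at 0.15.

Patients additionally receive a spherical lesion (radius 2 to
min(grid)/3 voxels) centered on a left ROI drawn uniformly from a
"perisylvian" band (the middle half of left ROI ids), emulating the
selection bias of surgical cohorts. Every left ROI with ≥ 1% lesion
intersection contributes a shift of `delta` (Fisher-z units) to its
mapped right-hemisphere edges, multiplied by the ROI's homotopic coupling
when `homotopic_scaling` is on and by `idh_delta_ratio` for IDH-mutant
patients. Metadata (genotype 25/23, grade 32/16 at n = 48, scaled
proportionally otherwise; ages ~N(50, 16.7) patients / N(49, 15.9)
controls; sex ratios 31/48 and 44/107) mirrors the emulated design.

**Effect map.** The default map for a lesioned left ROI r targets
(i) the edges incident to r's homotopic partner (location-specific
signature) and (ii) the clique of edges among the homotopic partners of
the perisylvian band (a shared, coordinated reorganization of the
contralesional homologue network). The shared component is essential,
not cosmetic: because RRCz rows are norm-constrained, purely
site-specific shifts point in nearly orthogonal directions for different
lesion sites, and no linear classifier can separate such patients from
controls regardless of effect size (measured ceiling ≈ 0.70 accuracy).
A network-level shared component is also the scientifically expected
structure — lesions at different sites within one functional network
produce similar contralesional effects — and with it a delta of 1.5
(noise sd 1) yields nested-CV accuracy ≈ 0.95 at the 48/107 design.
Passing `network_rois=[]` to `default_effect_map` recovers the purely
site-specific model, which the construction-validity tests use when
ROI-specificity matters (homotopic-coupling recovery, single-ROI
screens).

What the generator does **not** model: BOLD time series and their
autocorrelation, spatial covariance among edges, scanner effects beyond
subject intercepts, lesion growth or mass effect, any relation between
genotype/grade and lesion location. Passing tests therefore demonstrate
that the *pipeline* recovers known injected structure under the stated
noise model — not that real cohorts behave this way.

## Problem sizes used in the shipped runs

The test suite and the acceptance script run on reduced problem sizes,
chosen as the package's own trade-off between statistical resolution and
run time: 10–20 ROIs per hemisphere (45–190 edges) on 16³–24³ grids,
single-value C grids where the inner loop is not itself under test, and
60–200 permutation iterations. The two null-precision targets are
distribution-level quantities whose expectation is the positive-class
prevalence (48/155 ≈ 0.31 and 25/48 ≈ 0.52) independent of the edge
count, so the reduced feature space changes only Monte-Carlo error. The
full 100-ROI, 1000-iteration configuration is a parameter choice away
(`generate_atlas(100, (40, 40, 40))`, `n_iter=1000`); the uniformity
check of null rank-sum p-values across all 4950 edges runs at full scale
in the test suite.

## Known limitations

* Barnard's test uses a grid maximization; p-values are exact up to the
  grid resolution (error < ~1e−6 at step 1e−4 on small tables).
* The MRMR importance scale depends on the binning and bias-correction
  choices above; thresholds (τ = 0.05) are conventions on that scale,
  not probabilities.
* The empirical-p convention for undefined null metrics (exclude NaN)
  slightly reduces n for those metrics.
* Voxelwise Barnard maps are uncorrected by default; a minP/maxT
  permutation correction is available (`max_t_permutations`) but off,
  matching the exploratory intent of the map.
* No registration or resampling: all volumes must share a voxel grid.
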