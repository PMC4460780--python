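# Methods

## Problem and model

`brainpath` classifies two groups of subjects (e.g. patients vs controls)
from resting-state functional connectivity, using *pathway activity*
features instead of single-region features. The inputs are region-averaged
signal time courses over a parcellation (the bundled default is the 116-region
AAL atlas, giving 116 × 115 / 2 = 6670 region pairs).

**Functional connectivity.** For each subject, the connectivity between
regions a and b is the Pearson correlation r_ab of their time courses over
the full series. No temporal filtering, nuisance regression or global-signal
handling is applied: inputs are assumed preprocessed.

**Pathways.** A brain pathway is an ordered sequence of regions whose
consecutive pairs (plus the closing pair for circular pathways such as the
orbitofrontal cortico-basal ganglia loop) are its edges. The catalog stores
hemisphere-neutral definitions; expansion realizes bilateral rows as a left
and a right instance (`_L`/`_R` suffixes, AAL naming), unilateral rows as
one instance, and the default mode network as two variants seeded at the
posterior cingulate and ventromedial prefrontal cortex. The bundled catalog
has 33 definitions expanding to 59 instances, 7 of them unilateral. Only the
orbitofrontal loop's region sequence is documented anatomy; the other rows
are plausible reconstructions (flagged in the catalog file) and the TSV
catalog format is the supported way to substitute curated definitions.

**Activity inference.** For a pathway with edges e_1..e_n, the cohort's
Fisher-z-transformed edge correlations form the samples × edges matrix F
(entries R_ij, z = arctanh(r)). For a nonempty edge subset B_k the activity
of sample i is the mean a_i = (1/k) Σ_{s∈B_k} R_is. Every one of the
2^n − 1 subsets is scored by the absolute two-group Welch t statistic of its
activity vector; the maximizing subset is the *discriminative connectivity
set* and its activity vector is the pathway's feature. Welch's unequal-
variance t is used unconditionally; per-group Kolmogorov–Smirnov normality
p-values (against a normal with the group's own moments) and Levene's
equal-variance p are reported as diagnostics and never gate selection.

**Region baseline (RFCS).** The comparison arm is the regional functional
correlation strength CS(a) = (1/(N−1)) Σ_{b≠a} |r_ab|, computed on r (not
z). Regions are ranked by a per-region Welch t on CS between groups and the
top K kept, with K equal to the pathway feature count so both arms feed the
classifiers the same number of inputs.

**Evaluation.** Stratified 10-fold cross-validation (each sample tested
once, fold sizes differing by at most one) over four classifier families:
Gaussian naive Bayes, logistic regression, RBF-kernel SVM, and a
500-tree random forest. Scaling for the margin/regression models is fit on
training folds only. Accuracy, sensitivity and specificity (patients =
positive class) are averaged over folds; AUC is reported both pooled over
concatenated held-out decision scores and fold-averaged, since the two
conventions differ and either may be wanted. SVM tuning scans C and gamma
over the nine powers of ten from 1e−4 to 1e4 (81 pairs) by cross-validated
pooled AUC.

**Pathway discovery.** Feature importance is the classical out-of-bag mean
decrease in accuracy: for each tree, the drop in its out-of-bag accuracy
when one feature column is permuted among the out-of-bag samples, averaged
over trees. Out-of-bag evaluation is essential — importance measured on
training samples collapses to exactly zero once the forest memorizes the
cohort, regardless of signal. The discriminatory feature count K comes from
an elbow rule on the descending importance curve: the changing point is the
position of maximum vertical distance below the chord joining the first and
last scores (the standard knee criterion), and features before it are kept.
A first-large-drop rule (drop > α × median drop) was considered and
rejected: with a handful of strong features over many near-zero ones the
median drop is a noise–noise gap, so any gap inside the informative block
triggers it and K degenerates to 1. The knee criterion reproduces the
intended behavior on both a (10, 9, 8, 2, 1) curve (K = 3) and planted
5-signal/54-noise tables (K ≈ 5). Curves with no bend fall back to the
largest single drop; all-equal scores give K = 1 with a warning.

## Information leakage

Subset selection and region ranking are label-aware. The default
("full-cohort") workflow selects on the full cohort before
cross-validation, replicating the original study design; absolute AUCs in
this mode are optimistic. `workflow.nested_cv_scores` re-runs the subset
search inside each training fold and applies the selected subset to the
held-out fold, for honest estimates. The two arms are compared under the
same protocol and fold assignments, so the *comparison* is paired and fair
either way.

## Synthetic cohorts

The generator draws what the analysis assumes and nothing more: stationary
Gaussian AR(1) series in time with a group-specific spatial correlation
matrix, no hemodynamics, motion or atlas geometry. Defaults emulate a
realistic study: 116 regions, 94 retained volumes, group sizes 22 vs 37
(with 61 available for the late-stage contrasts), AR coefficient 0.3 (mild
smoothness at a 3 s sampling interval). The base correlation matrix is a
random rank-10-plus-diagonal factor model (diagonal noise 5.0, giving
off-diagonal correlations mostly within ±0.5, typical of region-averaged
resting data), normalized to unit diagonal and hence positive
semi-definite. Disruption is planted as correlation attenuation: planted
edges are set to r = 0.6 in controls and 0.6 − δ in patients (default
δ = 0.4), followed by an eigenvalue-clipping nearest-PSD repair that
preserves unplanted entries to within 0.02. A direct z-space generator
plants a mean shift on F-matrix columns (unit noise SD, so δ is in
within-group SD units) to calibrate the subset search in isolation.

Passing tests on these cohorts show that the algorithms recover what they
are designed to recover under their own assumptions (Gaussian signals,
edge-localized effects, exchangeable nuisance edges); they do not show
robustness to hemodynamic confounds, motion, non-stationarity, or
misspecified pathway anatomy.

## Numerical choices

- |r| is clipped to 1 − 1e−7 before arctanh so degenerate perfect
  correlations stay finite; zero-variance regions are an error naming the
  region, never a silent NaN.
- Search ties (identical |t|) resolve to the smaller subset, then the
  lexicographically smallest index set, making results deterministic.
- Pathways are capped at 20 edges (~10^6 subsets) with a clear error above;
  bundled pathways have at most 5.
- The vectorized search computes Welch t for subsets in blocks of 2^15 via a
  subset-indicator matrix product; tests verify exact subset agreement and
  1e−9-relative t agreement against per-subset scipy enumeration.
- All randomness flows through `numpy.random.default_rng` seeds carried in
  specs and reports; classifier fold assignment is seeded and shared between
  arms for paired comparisons.

## Problem sizes in the validation suite

Statistical checks run at deliberately modest sizes chosen to make their
expected outcomes near-certain under the stated effect sizes: search/oracle
agreement on 100 random F matrices (≤ 8 edges); planted-edge recovery over
100 replicates (δ = 1.0 z-shift, 30 vs 30); the pathway-vs-region ordering
over 20 full-pipeline replicates at the default 116-region, 22 vs 37 cohort
with four disrupted pathways; null calibration over 50 seeds. The
permutation-null calibration of the search uses 60 replicates × 199 label
permutations.

## Known limitations

- Catalog anatomy beyond the orbitofrontal loop is reconstruction, not
  ground truth; scientific use requires a curated catalog.
- Exhaustive search is exponential by design; long pathways need the nested
  catalog edit rather than a heuristic search (none is provided).
- No multiple-testing correction is applied across pathways, matching the
  original procedure; the selection-inflated null is quantified by the
  permutation calibration test instead.
- OOB index reconstruction for MDA mirrors scikit-learn's bootstrap
  sampling; a future scikit-learn changing its sampling scheme would shift
  MDA values (not the interface).
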