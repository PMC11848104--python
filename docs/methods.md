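# Methods

This note documents the model, the numerical choices, and the synthetic
data underlying `gradiomics`, in the spirit of a package methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Region construction

A lesion is a single connected binary mask on a 3D grid with physical
voxel spacing (mm); multi-lesion instance splitting is out of scope (one
mask = one lesion). Morphological expansion and contraction are defined by
Euclidean distance thresholds computed with a spacing-aware distance
transform, not by voxel-count structuring elements: a voxel belongs to the
dilated mask iff its physical distance to the mask is ≤ *d*, and to the
contracted mask iff its distance to the complement is > *d*. This is the
only reading that keeps a "3 mm margin" meaning 3 mm on anisotropic
clinical grids (e.g. 0.5 × 0.5 × 2 mm voxels). Distance comparisons carry
a 1e-9 slack so voxels at exactly the threshold are included regardless of
floating-point square-root rounding.

Parameters, with defaults:

| parameter | default | meaning |
|---|---|---|
| `dilate_mm` | 3 (large) / 1 (small) | outward margin distance; keyed to GTV ≥ 4000 mm³ |
| `contract_mm` | = `dilate_mm` | core retraction distance |
| `size_threshold_mm3` | 4000 | large/small cutoff |

The contraction distance is not pinned down by any clinical convention we
could adopt, so the default mirrors the dilation (a symmetric shell about
the original boundary); it is an explicit knob. The margin is *expanded −
contracted*, which deliberately includes the rind of the original GTV
between the contracted core and the boundary as well as the expansion
outside it. A margin that exits the field of view is clipped with a
warning rather than an error; a contraction that empties the core is a
hard error naming the lesion as degenerate.

The center of mass is the unweighted centroid of the binary mask in
physical coordinates (it is a mask property, not an intensity property).
Octants are assigned by the sign of each coordinate relative to the
centroid under a fixed axis convention (array axis 0 → R, 1 → A, 2 → S
when headers are ambiguous); a coordinate exactly equal to the centroid
resolves to the positive direction so the partition is exact and
deterministic. The canonical octant order is RAS, LAS, RPS, LPS, RAI,
LAI, RPI, LPI; reproducible feature names require fixing this order once.

## Gradient features

Gradients use the separable 3D Sobel family (derivative [−1, 0, 1] along
the axis, smoothing [1, 2, 1] ⊗ [1, 2, 1] across it). The raw response is
divided by the total smoothing weight (16) and by twice the axis spacing,
making the output consistent with a central difference in intensity/mm: a
ramp of slope *k* per mm yields exactly *k* on interior voxels, regardless
of spacing anisotropy. Borders are replicate-padded to avoid spurious
edge gradients inside margins near the volume boundary. Gradients are
computed once on the full volume and then sampled per region, so region
boundaries never alter the convolution support.

The radial vector **D** points from the voxel toward the lesion centroid,
so a decreasing radial intensity profile (bright core fading outward) has
gradient aligned with **D**: positive RG, RD near 0. RD is undefined where
the gradient vanishes or at the exact centroid voxel (|**D**| = 0); such
voxels are excluded from the statistics rather than imputed — an angle of
a zero vector has no meaning — and per-region exclusion counts are kept as
provenance. RG is taken signed, as the inner product dictates; its sign
carries the inward/outward information that an absolute value would
destroy.

Region statistics are the mean, the *population* standard deviation
(ddof = 0 — these are descriptive summaries of a fixed voxel set, and a
single-voxel region must yield σ = 0, not NaN), and the coefficient of
variation σ/μ. A mean within 1e-12 of zero makes CV a NaN sentinel with a
flag; NaNs propagate through delta features and are median-imputed inside
training folds during modeling. Intensity is not normalized by default:
gradients already discard offsets (features are shift-invariant by
construction), and GM scales linearly under intensity scaling while its CV
is scale-free. A per-volume z-score switch exists for cross-scanner
harmonization experiments but is off.

Delta features subtract the first scan's vector from the second's,
with each timepoint using its own mask and region set — tumors change
shape mid-treatment, and freezing the first mask would misplace the margin
on the second scan.

## Modeling

Labels: responder iff follow-up volume < 0.8 × initial volume; the exact
80% boundary is a non-responder. Non-responder — the clinically critical
minority — is the positive class; SVM coefficients are reported so that
positive values push toward non-response.

All classifiers are linear-kernel SVMs with C = 1 (config-exposed; no
value is dictated by the problem) and balanced class weights, the latter
because the target cohort is ~4:1 imbalanced and both error rates matter.
Features are median-imputed and z-scored *inside training folds only*;
scaling is also what makes SVM coefficients comparable across features.
Recursive feature elimination removes one feature per round (the finest,
fully reproducible granularity). Within each of 50 iterations the 5
stratified folds are reshuffled; RFE on each training fold nominates a
top-9 set, the iteration's set is the most frequent over its folds, and
the final selection is the 9 features present in the most iteration sets.
Frequency ties break by better (lower) mean RFE rank, then lexicographic
name, and tie-break events are logged. Metrics (sensitivity, specificity,
accuracy, precision, F1, AUC from decision values) are averaged per fold
across the 5 × 50 = 250 fold fits, with 95% percentile intervals over the
fold scores — no distributional assumption. Precision with no predicted
positives is reported as 0 and flagged.

The EFS model re-runs the same frequency-based selection on the union of
the top-9 sets of the three full-pool models (≤ 27 mode-tagged names)
rather than hand-picking from them; re-running the identical procedure is
the only choice that needs no extra convention. The final 9 features are
cross-validated and refit on the full cohort for the coefficient report.
Group-difference reports use Shapiro-Wilk (α = 0.05) on both groups to
choose between a two-sample t-test and Mann-Whitney U, report two-sided
p-values unadjusted, and add a Benjamini-Hochberg column for reference
only.

Selection and evaluation share folds drawn from the same seed policy, so
the default procedure is *not* nested: performance estimates carry the
optimism of selecting on data that later scores the model. This mirrors
the frequency-RFE procedure as specified; the effect is visible in the
examples, where region series without planted signal can exceed chance.
Every modeling operation is a pure function of (data, config, seed).

## Synthetic phantoms

The phantom module emulates what the method needs to be exercised — not
MR physics. Lesions are spheres, ellipsoids, or lobulated unions of 2-4
offset ellipsoids (the irregular-shape/high-RD case), with radial
intensity profiles (decreasing Gaussian with σ = radius/1.5, increasing
linear, or flat), per-octant amplitude multipliers whose field is smoothed
over ~2 voxels so octant seams carry no artificial edges, anisotropic
spacing, and additive Gaussian noise. Image cohorts link class to
geometry: responders shrink to 85% radius between scans and draw follow-up
volume ratios from N(0.50, 0.10) clipped below 0.8; non-responders from
N(1.10, 0.15) clipped above 0.8. Table-level cohorts draw standard-normal
features with planted class-mean shifts at stated effect sizes; the
default cohort size is 69 lesions at a 55:14 responder:non-responder
split, the scale and imbalance of the adaptive-therapy cohort this
pipeline targets.

What passing tests on phantoms do **not** show: robustness to Rician
noise, bias fields, registration error, contouring variability, or real
biological heterogeneity; and no phantom can validate the clinical
performance figures, which require patient data.

## Problem sizes and tolerances

Unit geometry tests compare against a brute-force all-pairs distance
oracle on grids up to 32³ with distances {0, 1, 2, 3} mm and spacings
{(1,1,1), (0.5,0.5,2)} — exact set equality. Gradient ramps are checked to
1e-6; radial-regime RD bounds at 0.2 rad. Modeling calibration uses the
spec-scale simulations: permutation-null AUC within 0.5 ± 0.05 over 50
iterations, and recovery of 3 planted d = 2 features from the 90-feature
pool at n = 100 in ≥ 90% of 10 seeds. The acceptance script runs the full
15-model enumeration at 5 folds × 50 iterations on the 69-lesion default
cohort. Structural feature extraction on a 64³ phantom completes in
seconds.

## Known limitations

- Single-lesion masks only; no RTSTRUCT parsing, registration, or bias
  correction (binary co-registered masks are the contract).
- Non-nested selection by default (see above); a nested evaluation is the
  obvious extension when cohort sizes allow.
- CV features are unstable for regions whose parameter mean crosses zero
  (RG in symmetric lesions); the NaN sentinel plus fold-wise imputation
  contains but does not eliminate this.
- The contraction distance default is a convention, not a measurement;
  results for thin lesions are sensitive to it.
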