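# Methods

## Model and procedure

The package estimates a disease-related spatial covariance pattern from a
two-group cohort of volumetric PET scans and scores its expression in
arbitrary scans.

**Preprocessing (scaled subprofile model).** Voxels are kept if their
intensity exceeds a fraction (default 0.2) of each image's own maximum in
*every* derivation image; the per-image maximum makes masking invariant to
global scaling. Masked intensities must be strictly positive; they are
log-transformed (natural log — the base only rescales raw scores and
cancels in the Z-transform) and doubly centred: the subject mean (the SSM
proxy for global metabolic activity) is removed first, then the group mean
profile (GMP), defined as the voxel-wise mean of the *row-centred* matrix.
This ordering matters: the stored GMP is reused verbatim when scoring scans
outside the derivation cohort, so scoring and derivation are numerically
identical for derivation subjects. Masked vectors are always serialized in
lexicographic voxel order with x fastest, recorded in the bundle sidecar.

**Derivation.** PCA is computed through the subjects × subjects covariance
`S Sᵀ` (subjects ≪ voxels; deterministic and cheap), eigenvalues below
1e-10 of the leading one are treated as null space, and voxel loadings are
unit-normalised with sign fixed by the largest-magnitude entry. Components
with VAF ≥ `vaf_min` (default 0.05, "at least" inclusive) enter logistic
group-discrimination models; candidate subsets default to nested prefixes
of the screened list ({PC1}, {PC1,PC2}, …) with an all-subsets option. Each
model carries a ridge penalty 1e-4 on the slopes (scikit-learn lbfgs,
intercept unpenalised) so complete separation — likely at n = 20+20 —
converges; AIC = 2(k+1) − 2·loglik is computed from the *unpenalised*
log-likelihood at the converged coefficients. Ties break toward the
smaller, then lexicographically first, subset. The selected loadings are
combined with the fitted coefficients, renormalised to unit norm, and
oriented so the mean patient raw score exceeds the mean control raw score.

**Scoring.** Topographic profile rating: log, subtract own mean, subtract
the derivation GMP, project onto the weights. Z-transform uses the
derivation control group's raw-score mean and *sample* SD (ddof = 1; small
reference groups make the conventional unbiased denominator the safer
choice). Nothing is re-estimated from the scored cohort.

**Validation.**
- *Bootstrap ICV*: subjects are resampled with replacement within each
  group (sizes preserved — the two-group design is part of the estimand);
  each replicate reruns the derivation on a mask fixed from the full
  cohort, including the VAF screen and AIC selection (an option freezes the
  subset for speed), and is sign-aligned to the original pattern. ICV =
  voxel mean / SD (ddof 1) over replicates; zero-SD voxels get ±infinity
  with the mean's sign; |ICV| ≥ 1.96 is read as two-sided p < 0.05.
  Replicates with fewer than two distinct subjects in a group are redrawn
  and counted.
- *k-fold topography*: group-stratified folds; one pattern per training
  portion. All folds share the full-cohort mask so their weight maps live
  on one voxel support and are directly correlatable (per-fold masks would
  differ at the rim and make voxel-wise correlation ill-defined); signs are
  aligned to the first fold.
- *Fisher–Pitman test*: difference of group means; full enumeration when
  C(n, n_a) ≤ 200 000 (two-tailed proportion with the observed labeling
  included, so p > 0 always), otherwise Monte-Carlo with 100 000 draws and
  the add-one correction (1 + count)/(1 + n_mc), which preserves validity.
- *ROC/Youden*: AUC is the tie-corrected Mann–Whitney probability;
  candidate cut-points are midpoints between consecutive distinct scores
  plus sentinels beyond both extremes, positivity is score ≥ threshold, and
  Youden ties break toward higher specificity (matching the usual clinical
  preference for specific biomarkers) and then the higher threshold.
- *Correlations*: Pearson (t-transform p, n − 2 df) or Spearman via scipy;
  callers drop incomplete pairs and n is reported per analysis.

## The phantom generator

Inside an ellipsoidal "brain" mask, subject *i*'s pre-smoothing intensity is

    I_i(v) = g_i · b(v) · exp(e_i · P(v) + ε_i(v)),

with `b` a positive baseline (level 100 with a ±10% low-frequency cosine
ripple so intensity masking is non-trivial), `g_i = exp(N(0, global_sd))` a
multiplicative global factor, `P` the planted pattern (truncated Gaussian
blobs of either sign, centred and unit-normalised over the mask) and
`ε_i` iid voxel log-noise. Expression `e_i` is Gaussian: control mean 0,
patient mean `effect_delta`, common SD. The volume is then smoothed with an
isotropic Gaussian kernel of `smooth_fwhm_mm` FWHM applied as a
*mask-normalised convolution* (numerator and indicator smoothed separately
with zero padding, ratio taken inside the mask). Plain convolution of a
brain-against-empty-background phantom would bleed activity across the
sharp boundary and place a distorted rim inside the analysis mask — an
artefact of the phantom's hard edge, not of real pre-smoothed scans, which
the normalised form avoids. An MMSE-like score is
`clip(round(intercept − slope·e_i + noise), 0, 30)`.

Defaults define the reference conditions used throughout the tests: a
32×40×32 grid of 2 mm voxels, 20 subjects per group, `effect_delta` 2.0,
expression SD 0.5, voxel noise SD 0.1, global-factor log-SD 0.15, 10 mm
FWHM smoothing, and clinical intercept 28.7 / slope 5.35 / noise SD 1.1 so
the group score means land near 28.7 (controls) and 18 (patients). Blob
geometry mimics the bilateral temporoparietal / posterior midline /
thalamic hypometabolic topography co-varying with a hypermetabolic
cerebellar focus.

Randomness follows a documented hierarchy: one `SeedSequence` substream per
(group, subject), so enlarging a cohort never reshuffles existing subjects
and identical configs are bit-reproducible.

**What the phantom does not emulate:** PET physics (attenuation, scatter,
reconstruction), partial-volume effects, anatomical variability and
registration error, multi-scanner harmonisation, and non-Gaussian
population structure. Passing recovery tests therefore demonstrates the
estimator's correctness under the stated generative model, not clinical
performance on real scans.

## Numerical choices and degenerate inputs

- Double centering is exactly idempotent; row/column means are asserted to
  < 1e-8 in the container invariants.
- Rank-deficient SRPs (e.g. noise-free cohorts are rank one) are handled by
  the eigenvalue cutoff; a rank-0 matrix is an error.
- Non-positive masked intensities, empty masks, single-class labels, empty
  candidate sets and zero combined patterns all raise informative errors
  rather than propagating NaNs.
- Exact permutation comparisons use an epsilon of 1e-12 scaled by the data
  magnitude to avoid float misses on the |stat| ≥ |observed| boundary.
- With no voxel noise and no smoothing, every bootstrap replicate recovers
  the same weight map and the whole mask is reliably suprathreshold — the
  degenerate check of the ICV machinery. With noise present, note that the
  centring constraint makes even off-blob weights systematically non-zero
  and stably estimated, so at the phantom's benign noise level a large part
  of the mask (not only the blobs) can be suprathreshold; blob centres are
  always the strongest.

## Problem sizes in the shipped checks

The test-suite and `scripts/acceptance.py` run at sizes chosen to keep a
full run fast on one CPU while leaving every conclusion stable across
seeds: 10 seeds for pattern recovery and threefold cross-validation at the
full 32×40×32 / 20+20 reference settings, 200 bootstrap replicates for the
ICV map (50 for the degenerate case), 1000 null simulations with 2000
Monte-Carlo relabelings each for permutation-test calibration, and smaller
16×20×16 cohorts for per-module unit tests.

## Known limitations

- The candidate-model family for AIC selection (nested prefixes by VAF
  rank) is one conventional choice; all-subsets search is available but
  grows combinatorially.
- Pattern weights are unit-norm by convention; any eigenvalue-weighted
  display scaling would cancel in the Z-transform and is not implemented.
- The ICV map treats replicate weights voxel-wise; spatial correlation of
  the bootstrap field is not modelled.
- Scoring requires the scored scan to cover the pattern's mask on the same
  grid; no resampling/registration is performed.
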