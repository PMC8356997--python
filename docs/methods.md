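# Methods

`lesionorm` implements lesion-aware spatial normalization of brain images:
symmetric diffeomorphic registration with constrained cost-function masking
(CCFM), iterative construction of a cohort-specific template (CST), and an
evaluation harness based on label overlap and normalized mutual
information.  This note documents the models, the defaults and why they
are what they are, and what the synthetic study design does and does not
emulate.

## Registration model

Registration proceeds in two stages.

**Affine pre-alignment.**  A rigid then full-affine transform is estimated
by maximizing the globally normalized correlation between the fixed image
and the resampled moving image, evaluated over the fixed image's
foreground support (smoothed magnitude above 10% of its maximum, dilated
by 4 voxels).  The optimizer is Powell's method on a subsampled grid,
initialized from the intensity-centroid difference, run coarse-to-fine
over Gaussian-smoothed copies (sigma 2, then 1 voxel).  The search is
bounded around the initialization (about ±6 voxels of translation, ±17
degrees, ±0.12 on linear coefficients): the pre-alignment stage is meant
to capture pose, and an unbounded search can absorb deformable shape
change into a spurious affine.  The returned matrix is a pull-back
(fixed world → moving world).

**Symmetric diffeomorphic stage.**  The deformable solver follows the
greedy symmetric-normalization scheme: two half displacement fields pull
the fixed and moving images toward a common midpoint.  Each iteration

1. resamples both images to the midpoint fresh from the originals (no
   accumulation of interpolation error),
2. computes the windowed local cross-correlation `A²/(B·C)` and its
   analytic gradient with respect to the moving half-field, symmetrized
   over both image gradients,
3. smooths the update (Gaussian, `update_smoothing_sigma`), normalizes its
   99th-percentile magnitude to `step_size` voxels and caps outliers at
   the same step (edge spikes would otherwise starve bulk motion),
4. composes the update into each half-field with opposite signs, then
   lightly smooths the total fields (`total_smoothing_sigma`), and
5. rejects any update that would make a half-field's interior
   finite-difference Jacobian non-positive (halving the step up to five
   times before skipping the iteration).

Similarity is evaluated only over the joint foreground support of the two
images; in pure-background regions the variance-normalized CC gradient is
amplified noise and destabilizes the updates.  Per level the solver keeps
the best-scoring fields and stops after 8 iterations without a tolerance-
sized improvement.  The full forward map is assembled by composing the
inverse of the fixed half-field with the moving half-field; if numerical
inversion error leaves the composed field's interior Jacobian non-positive
(possible for near-singular warps, although the analytic composition of
two diffeomorphisms cannot fold), the field is smoothed with escalating
sigma until positivity holds, and the inverse field is then recomputed by
damped fixed-point inversion of the repaired forward field.  As a final
safeguard the full-resolution similarity of the deformable result is
compared with the affine-only alignment and the deformable stage is
dropped if it scores worse, so the metric trace never ends below its
starting value.

Which image is source and which is target is *exactly* immaterial: both
the affine stage and (for unmasked pairs) the full solve run in a
canonical image order determined by a deterministic content key, and the
result is inverted exactly when the caller's order differs.  A lesion
mask pins the orientation instead, since CCFM is defined on the lesioned
(moving) image.

### Defaults

| parameter | default | rationale |
| --- | --- | --- |
| `step_size` | 0.25 voxel | gradient-descent step of the reference protocol |
| `outer_iterations` | 3 | sweeps over the multiresolution schedule (the reference protocol's iteration count); converged sweeps exit immediately |
| `levels` | (×4, 100), (×2, 70), (×1, 80) | coarse levels carry bulk motion; the long finest level exploits fine texture for sub-voxel refinement |
| `cc_radius` | 3 | window radius of the local CC; radius 3 outperformed the common radius-4 default on 128² phantoms whose texture scale is finer than clinical voxel grids |
| `update_smoothing_sigma` | 4 mm | fluid-like regularization; the value that maximized known-warp recovery on the phantom suite |
| `total_smoothing_sigma` | 0.5 mm | near-free total field (elastic component kept minimal) |
| `convergence_tol` | 1e-5 | improvement granularity for best-field tracking |

All sigmas are in mm and divided by the level's voxel spacing, so
smoothing is constant in physical units across the pyramid.

### Constrained cost-function masking

The lesion mask (1 = lesion, given in the moving image's space) acts in
three places: lesion voxels are excluded from the affine similarity; the
moving image is *nearest-outside filled* inside the lesion before any
smoothing or pyramid construction, so no derived quantity can see
intra-lesion intensities; and the windowed CC uses weighted window sums in
which masked voxels contribute to neither the score nor the gradient,
with the mask tracked through the moving half-warp at every iteration.
The deformation inside the lesion is therefore produced purely by the
smoothing of the surrounding flow — the "interpolation" of the missing
values.  A consequence the tests verify: replacing intensities strictly
inside the mask changes nothing in the estimated transform.

## Cohort-specific template

The builder starts from the voxelwise mean of the (bias-corrected) cohort
and iterates, four times by default: register every image to the current
template; average the warped images (in sorted subject order, for bitwise
reproducibility); sharpen the average with a mild unsharp pass (strength
0.3, scale 1 voxel) — the appearance-optimization step of the reference
protocol, without which repeated interpolation progressively blurs the
template below the naive mean's sharpness on noisy images; average the
subject transforms (fields voxelwise, affines in the matrix-log domain);
and warp the template by the averaged forward field scaled by
`-step_size`, moving it against the residual mean displacement so it
drifts toward the cohort's mean shape.  Applying the raw average verbatim
would move the template *away* from centrality; the sign convention is
covered by the centrality test (the mean final subject→CST displacement
stays below half a voxel).  No cost-function masking is used during
construction by default: lesions at varied locations enter the average
with weight 1/n and are strongly diluted.

Template "sharpness" is the mean gradient magnitude of the template image,
reported per iteration together with the mean residual displacement.

### Bias-field correction

A simplified N4-style loop, used on template inputs: work in the
log-intensity domain over the positive foreground; sharpen the intensity
histogram by Wiener deconvolution with a Gaussian kernel (width 0.10 log
units, 200 bins); form the voxelwise residual between observed intensity
and its sharpened-histogram expectation; smooth it with a 25 mm Gaussian
(standing in for full N4's B-spline fit); accumulate over 10 iterations.
The recovered field is multiplicative, smooth, 1 on the background and
mean-normalized over the foreground, and `corrected × field` reconstructs
the input exactly by construction.  On a phantom corrupted with a smooth
field in [0.84, 1.20] the correction removes ~85% of the bias-induced
excess within-tissue coefficient of variation and recovers a field whose
log correlates at r > 0.9 with the true one.  This is not byte-compatible
with N4 — it captures the mechanism at desk scale.

## Synthetic study design

The generator stands in for the study's real cohorts with 2-D 128²
labeled head phantoms (a 3-D 64³ mode exists; nothing in the method is
dimension-specific).  A phantom is an ellipsoidal head with a cortical
ribbon of angularly varying thickness, white-matter interior, paired
unequal ventricle lobes, and an off-centre deep-grey nucleus — the
asymmetries are deliberate, since a rotationally near-symmetric head
leaves rigid registration ill-posed.  Tissue means (CSF 30, GM 60, WM
100, deep GM 75) with additive Gaussian noise (sigma 2) approximate
T1-like contrast.  Each subject is a random smooth warp (mean amplitude 3
voxels, smoothness 10) of the common base, applied consistently to the
image and to its 12-parcel wedge parcellation, which stands in for a full
anatomical labeling protocol; the evaluation averages over whatever labels
exist.

Ground-truth deformations are exponentials of Gaussian-filtered white
noise velocity fields (scaling and squaring, 7 squarings; inverse from
the negated velocity).  `amplitude` is the *mean* speed in voxels; peaks
are soft-capped at twice the amplitude and the field is shrunk until
numerically diffeomorphic in both directions, so the generator's
invertibility guarantee takes precedence over the exact requested
amplitude.

Lesion masks are connected, rough-edged blobs confined to the brain, with
the radius of a noise-roughened distance ball solved by bisection to hit
the requested volume fraction within ±10%.  Donor images paint the lesion
interior at 30% of the white-matter mean with 10% noise, mimicking
chronic-stroke T1 hypointensity.  Virtual lesions follow the masked-mean
construction: the donor lesion is rescaled by
`mean(healthy | brain \ lesion) / mean(donor | brain \ lesion)` and copied
into the healthy image, touching nothing outside the mask.  "Inside the
brain" is the Otsu foreground of the healthy image (the original
construction assumes a brain mask without defining one).  A 6-control ×
6-lesion cohort yields exactly 36 virtual-lesion images.

What the phantoms do **not** emulate: MRI physics (no Rician noise,
k-space artifacts or partial voluming), perilesional mass effect (lesions
replace intensity only, as in the virtual-lesion construction),
inter-subject intensity variation, and 3-D cortical folding.  Passing
tests therefore demonstrate the correctness and internal consistency of
the algorithms and the direction of the methodological comparisons at
desk scale — not clinical-grade accuracy on real scans.

## Evaluation harness

Pairwise accuracy mirrors group-analysis practice: each subject is
registered once to the common space and the transform reused across
pairs; source labels are warped to the space (nearest neighbour) and then
into the target's native space through the inverse of the target's
transform; the per-label Jaccard against the target's own labels is
averaged unweighted over labels.  Labels present in only one volume score
0 and are flagged.  Pairs that share a control use the clean image's
round trip through the space as their ground truth.  Lesion-induced error
is the absolute difference between a lesioned pair's mean Jaccard and its
matched clean pair's.

NMI uses 64-bin joint histograms over the space image's Otsu brain
voxels; entropy is in bits (NMI is base-invariant).  The dependence of
per-subject NMI on lesion size is summarized by Pearson's r with a fitted
line, and the two arms' correlations are compared with Steiger's test for
dependent correlations sharing one variable (Fisher transforms with the
shared-variable covariance correction; two-sided by default).  Its type-I
error calibrates to 0.03–0.07 at alpha 0.05 in the null simulation the
tests run.

### The two-arm benchmark

`run_benchmark` executes the full comparison on one seeded cohort: both
arms register all 6 clean and 36 lesioned images (CCFM for the latter) to
a common space — an unrelated healthy phantom standing in for a
population template in one arm, the CST in the other — and report mean
absolute Jaccard accuracy difference, the NMI-vs-size correlation, and
the lesioned-vs-clean NMI gap.  The CST is built from one lesioned image
per control taking the *diagonal* of the controls × lesions cross, so
each lesion location enters the template average with weight 1/6, as in a
template built from a real lesioned cohort.  The benchmark uses a
lighter solver schedule ((×4, 30), (×2, 20), (×1, 8), one sweep, no bias
correction on the noise-free-bias phantoms) so the 86-registration study
completes in about two minutes per seed on one CPU; the comparisons are
between arms run under identical settings, so the schedule does not favor
either arm.

On seeded 6×6 benchmarks the expected orderings reproduce in at least
four of five seeds per comparison: the cohort template shows a smaller
mean accuracy difference, a weaker lesion-size dependence, and a smaller
lesioned-vs-clean NMI gap than the fixed external reference.

## Numerical conventions and degenerate inputs

- Displacement fields are pull-back maps in mm, stored on the reference
  grid; a zero field is the identity; composition and inversion are
  numeric (linear interpolation; damped fixed-point inversion, 40
  iterations or mean update < 0.01 voxel).
- Out-of-bounds resampling fills with 0; nearest-neighbour interpolation
  breaks exact half-voxel ties toward the lower index on every axis.
- Geometry comparisons use an absolute tolerance of 1e-5 mm; averaging
  orders are fixed by sorted subject identifier for reproducibility.
- Constant images abort registration with a diagnostic rather than
  returning a silent identity; masks are binarized at 0.5 after any
  resampling; empty lesion masks return the input with a warning.
- Jacobian checks are finite-difference determinants on interior voxels
  (one-sided boundary differences are not meaningful).

## Known limitations

- The greedy solver recovers ~70–88% of the displacement of smooth
  ground-truth warps on the phantom suite, but degrades (to ~30–55%) for
  warps whose Jacobian approaches zero — near-singular deformations are
  at the edge of what any smoothness-regularized method can recover.
- The affine search bounds assume the initial centroid alignment is
  within ~6 voxels and ~17 degrees of the truth; grossly misaligned
  acquisitions would need a wider bound via configuration.
- Bias correction is a Gaussian-smoothing analogue of N4, adequate for
  smooth synthetic fields; real multi-coil inhomogeneity may need the
  full B-spline machinery.
- 2-D phantoms are the default study scale; 3-D runs are supported but
  slower, and the solver's per-level schedules were tuned on 2-D grids.
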