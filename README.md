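# lesionorm

Lesion-aware spatial normalization of brain images: symmetric
diffeomorphic registration with constrained cost-function masking (CCFM),
iterative cohort-specific template construction, virtual-lesion
simulation, and an overlap/mutual-information evaluation harness.

## The problem

Group analysis of patients with focal brain lesions (e.g. chronic stroke)
requires warping every subject into a shared coordinate space.  Two
things go wrong with the standard recipe: the lesion's abnormal
intensities drag the registration's similarity metric, distorting the
deformation around (and beyond) the lesion; and the usual target — a
population template built from healthy brains such as MNI-152 — assumes
an anatomy the patient cohort does not have, biasing normalization
against exactly the subjects under study.

`lesionorm` addresses both.  Registration is a symmetric diffeomorphic
(SyN-style) method: the deformation splits into two halves meeting at a
midpoint, so which image is "source" and which is "target" is immaterial,
and the estimated map is smooth and invertible with an everywhere-positive
Jacobian.  With a lesion mask, CCFM removes lesion voxels from the
similarity and its gradient, and the deformation inside the lesion is
interpolated from the healthy surrounding flow.  Instead of a fixed
external template, a cohort-specific template (CST) can be built from the
study's own images by iterating: register all images to the current
template, average the warped images, average the transforms, and move the
template against the residual mean displacement so it converges to the
cohort's mean shape and appearance.

Evaluation follows the virtual-lesion paradigm: lesions are transplanted
from donor images into healthy images with a masked-mean intensity
rescaling, so registration accuracy on the lesioned image can be compared
with the unlesioned ground truth it came from.  Accuracy between a source
and target subject is the mean Jaccard overlap of anatomical labels pushed
through the common space,

    J = |L_src→tgt ∩ L_tgt| / |L_src→tgt ∪ L_tgt|,

averaged over regions, and the lesion-induced error is
|J_lesioned − J_clean| per pair.  Cohorts without labels are scored by
normalized mutual information, NMI(I₁, I₂) = (H(I₁) + H(I₂)) / H(I₁, I₂),
between each warped image and the space image within brain voxels; the
dependence of NMI on lesion size is summarized by Pearson's r, and
correlations are compared across arms with Steiger's test for dependent
correlations.

## Worked example

Deform a labeled phantom by a known smooth warp, register it back, and
measure how much of the deformation the solver recovers:

```python
import numpy as np
from lesionorm.lesion_sim import PhantomSpec, make_phantom, make_synthetic_deformation
from lesionorm.registration import syn_register
from lesionorm.volumes import resample
from lesionorm.evaluation import jaccard

image, labels = make_phantom(PhantomSpec(seed=3))
truth = make_synthetic_deformation(image.geometry, amplitude=4, smoothness=8, seed=5)
moving = resample(image, truth)
moving_labels = resample(labels, truth, interpolation="nearest")

result = syn_register(fixed=image, moving=moving)
recovered = resample(moving_labels, result.transform, interpolation="nearest")

def overlap(a, b):
    return np.mean([jaccard(a.data == i, b.data == i) for i in sorted(b.label_ids)])

pts = image.geometry.grid_world()
err0 = np.linalg.norm(truth.map_points_inverse(pts) - pts, axis=-1)
err1 = np.linalg.norm(result.transform.map_points(pts) - truth.map_points_inverse(pts), axis=-1)
fg = labels.data > 0
print(f"mean misalignment: {err0[fg].mean():.2f} -> {err1[fg].mean():.2f} voxels")
print(f"mean label Jaccard: {overlap(moving_labels, labels):.3f} -> {overlap(recovered, labels):.3f}")
print(f"final similarity: {result.metric_trace[-1]:.3f}")
```

```
mean misalignment: 3.39 -> 0.95 voxels
mean label Jaccard: 0.671 -> 0.924
final similarity: 0.867
```

The warp displaced the anatomy by 3.4 voxels on average inside the head;
registration recovers 72% of it, raising the mean label overlap from 0.67
to 0.92.  The similarity is the windowed local cross-correlation of the
aligned pair (1.0 would be a perfect local match).  The estimated
transform is guaranteed diffeomorphic: its Jacobian determinant is
positive at every interior voxel and composing it with its inverse
deviates from the identity by well under half a voxel.

The same pipeline is scriptable from the shell:

```sh
lesionorm simulate --out sim --n-controls 6 --n-lesions 6 --seed 17
lesionorm register --fixed sim/ctl00_t1.nii.gz --moving sim/ctl01_les02_t1.nii.gz \
    --lesion-mask sim/ctl01_les02_mask.nii.gz --out-prefix out/reg
lesionorm benchmark --out bench --seed 17
```

`benchmark` runs the full two-arm study (fixed external reference vs.
cohort-specific template) and prints the headline comparison: the mean
absolute Jaccard accuracy difference, the NMI-vs-lesion-size correlation,
and the lesioned-vs-clean NMI gap, per arm.  Across seeded cohorts the
cohort-template arm consistently shows the smaller accuracy difference
and the weaker size dependence, and a smaller NMI gap for most seeds.

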