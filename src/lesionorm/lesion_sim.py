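"""Synthetic study data: labeled brain-like phantoms, lesion masks, virtual
lesions, and ground-truth diffeomorphic deformations.

The generator emulates the study design used to evaluate lesion-aware
normalization: a small cohort of healthy labeled "subjects" (each a random
smooth shape perturbation of a common head phantom), a set of lesion donors
with hypointense chronic-stroke-like blobs, and the full controls x lesions
cross of virtual-lesion images produced by masked-mean intensity rescaling.

Phantoms default to 2-D 128x128 slices so full pipelines run at desk scale;
nothing in the methods is dimension-specific and every operation also works
on 3-D grids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volumes import (
    AffineTransform,
    DiffeomorphicTransform,
    DisplacementField,
    Geometry,
    ImageVolume,
    LabelVolume,
    LesionMask,
    ValidationError,
    compose_displacements,
)

__all__ = [
    "PhantomSpec",
    "LesionSpec",
    "SpecError",
    "make_phantom",
    "make_lesion_mask",
    "insert_virtual_lesion",
    "make_synthetic_deformation",
    "make_virtual_cohort",
    "VirtualCohort",
    "otsu_brain_mask",
]


class SpecError(ValueError):
    """Synthetic-data specification that cannot be realized."""


# tissue class codes used internally
_BG, _CSF, _GM, _WM, _DGM = 0, 1, 2, 3, 4


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one labeled head phantom.

    ``n_labels`` wedge-shaped parcels stand in for a full anatomical
    protocol (e.g. the 56 LPBA structures) at desk scale; the evaluation
    averages over whatever labels exist.  ``perturbation_amplitude`` /
    ``perturbation_smoothness`` control the per-subject random smooth
    shape change (voxels) that makes subjects anatomically distinct.
    """

    shape: tuple = (128, 128)
    n_labels: int = 12
    tissue_means: tuple = (30.0, 60.0, 100.0, 75.0)  # CSF, GM, WM, deep GM
    noise_sigma: float = 2.0
    smoothness: float = 1.0
    perturbation_amplitude: float = 3.0
    perturbation_smoothness: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_labels < 1:
            raise SpecError("n_labels must be >= 1")
        if self.noise_sigma < 0:
            raise SpecError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class LesionSpec:
    """Size, placement and boundary roughness of a synthetic lesion."""

    volume_fraction: float = 0.05
    center: tuple | int | None = None  # voxel coords, region label, or random
    irregularity: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.volume_fraction < 0.5):
            raise SpecError("volume_fraction must be in (0, 0.5)")
        if self.irregularity < 0:
            raise SpecError("irregularity must be >= 0")


# ---------------------------------------------------------------------------
# deformations
# ---------------------------------------------------------------------------


def make_synthetic_deformation(
    geometry: Geometry,
    amplitude: float,
    smoothness: float,
    seed: int = 0,
    squarings: int = 7,
) -> DiffeomorphicTransform:
    """Random smooth diffeomorphism from a stationary velocity field.

    Draws Gaussian-filtered white noise per component, rescales it so the
    mean speed over the grid equals ``amplitude`` voxels, and exponentiates
    it by scaling-and-squaring; the inverse comes from the negated
    velocity, so both directions are diffeomorphic by construction.
    ``amplitude`` must stay below ``smoothness`` (folding risk otherwise).
    """
    if amplitude < 0:
        raise SpecError("amplitude must be >= 0")
    d = geometry.ndim
    if amplitude == 0:
        return DiffeomorphicTransform.identity(geometry)
    if amplitude >= smoothness:
        raise SpecError(
            f"amplitude ({amplitude}) must be < smoothness ({smoothness}) "
            "to stay in the diffeomorphic regime"
        )
    rng = np.random.default_rng(seed)
    vel = rng.standard_normal(geometry.shape + (d,))
    for c in range(d):
        vel[..., c] = ndimage.gaussian_filter(vel[..., c], sigma=smoothness)
    speed = np.sqrt((vel**2).sum(axis=-1))
    mean_speed = float(speed.mean())
    if mean_speed > 0:
        vel *= amplitude / mean_speed
    # soft-cap velocity peaks: Gaussian-filtered noise has heavy spatial
    # maxima whose gradients would exceed the folding limit; renormalize
    # the mean speed after capping so ``amplitude`` keeps its meaning
    cap = 2.0 * amplitude
    for _ in range(3):
        speed = np.sqrt((vel**2).sum(axis=-1))
        over = speed > 1e-12
        factor = np.ones_like(speed)
        factor[over] = cap * np.tanh(speed[over] / cap) / speed[over]
        vel *= factor[..., None]
        m = float(np.sqrt((vel**2).sum(axis=-1)).mean())
        if m > 0:
            vel *= amplitude / m

    lin = geometry.affine[:d, :d]  # voxel -> mm

    def _exp(v_mm: np.ndarray) -> DisplacementField:
        u = DisplacementField(v_mm / (2**squarings), geometry)
        for _ in range(squarings):
            u = compose_displacements(u, u)
        return u

    def _interior_jac_min(field: DisplacementField) -> float:
        from .volumes import jacobian_determinant

        det = jacobian_determinant(field)
        core = det[tuple(slice(1, -1) for _ in range(d))]
        return float(core.min())

    # construction check: shrink the velocity until both directions are
    # numerically diffeomorphic (guarantee trumps the requested amplitude)
    scale = 1.0
    for _ in range(8):
        fwd = _exp(scale * vel @ lin.T)
        inv = _exp(-scale * vel @ lin.T)
        if _interior_jac_min(fwd) > 0 and _interior_jac_min(inv) > 0:
            return DiffeomorphicTransform(AffineTransform.identity(d), fwd, inv)
        scale *= 0.9
    raise SpecError(
        "could not realize a diffeomorphic field at the requested amplitude"
    )


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------


def _base_maps(spec: PhantomSpec):
    """Unperturbed tissue-class map and wedge parcellation on the requested grid."""
    shape = np.array(spec.shape, dtype=float)
    d = len(spec.shape)
    center = (shape - 1) / 2.0
    semi = shape * 0.40
    idx = np.stack(
        np.meshgrid(*[np.arange(s) for s in spec.shape], indexing="ij"), axis=-1
    ).astype(float)
    rel = (idx - center) / semi
    r2 = (rel**2).sum(axis=-1)
    head = r2 <= 1.0

    theta = np.arctan2(rel[..., 1], rel[..., 0])

    # paired, unequal ventricle lobes and an off-centre deep-grey nucleus:
    # the asymmetries define a unique orientation (a near-symmetric head
    # would leave rigid rotation ill-posed)
    off1 = np.zeros(d); off1[0] = -0.02 * shape[0]; off1[1] = 0.10 * shape[1]
    off2 = np.zeros(d); off2[0] = -0.02 * shape[0]; off2[1] = -0.12 * shape[1]
    relv1 = (idx - (center + off1)) / (shape * 0.085)
    relv2 = (idx - (center + off2)) / (shape * 0.065)
    vent = ((relv1**2).sum(axis=-1) <= 1.0) | ((relv2**2).sum(axis=-1) <= 1.0)
    offd = np.zeros(d); offd[0] = 0.16 * shape[0]; offd[1] = 0.10 * shape[1]
    reld = (idx - (center + offd)) / (shape * 0.07)
    deep = (reld**2).sum(axis=-1) <= 1.0

    tissue = np.zeros(spec.shape, dtype=np.int8)
    tissue[head] = _WM
    # cortical ribbon: outer shell with angularly varying thickness
    ribbon = head & (r2 >= 0.62 - 0.10 * np.cos(theta - 0.7))
    tissue[ribbon] = _GM
    tissue[deep & head] = _DGM
    tissue[vent & head] = _CSF

    # wedge parcellation around the head centre (first two axes)
    sector = np.floor((theta + np.pi) / (2 * np.pi) * spec.n_labels).astype(np.int32)
    sector = np.clip(sector, 0, spec.n_labels - 1)
    labels = np.where(head, sector + 1, 0).astype(np.int32)
    if len(np.unique(labels[labels > 0])) != spec.n_labels:
        raise SpecError(
            f"cannot carve {spec.n_labels} non-empty parcels on grid {spec.shape}"
        )
    return tissue, labels


def make_phantom(spec: PhantomSpec) -> tuple:
    """Labeled head phantom: (ImageVolume, LabelVolume), deterministic in seed.

    The head is an ellipse with a cortical-ribbon shell, white-matter
    interior and a ventricle analogue; a random smooth per-subject warp is
    applied to both the tissue map and the parcellation so every seed is a
    distinct "subject" with consistent image/label anatomy.
    """
    geometry = Geometry.unit(spec.shape)
    tissue, labels = _base_maps(spec)
    rng = np.random.default_rng(spec.seed)

    if spec.perturbation_amplitude > 0:
        warp = make_synthetic_deformation(
            geometry,
            spec.perturbation_amplitude,
            spec.perturbation_smoothness,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        from .volumes import resample  # local import to keep module load light

        tissue = resample(
            LabelVolume(tissue.astype(np.int32), geometry), warp,
            interpolation="nearest",
        ).data.astype(np.int8)
        labels = resample(
            LabelVolume(labels, geometry), warp, interpolation="nearest"
        ).data
        # keep image and parcels coherent: parcels only on foreground
        labels = np.where(tissue > 0, labels, 0)

    means = np.array([0.0, *spec.tissue_means])
    img = means[tissue]
    if spec.smoothness > 0:
        img = ndimage.gaussian_filter(img, sigma=spec.smoothness)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, None)
    return ImageVolume(img, geometry), LabelVolume(labels, geometry)


# ---------------------------------------------------------------------------
# lesions
# ---------------------------------------------------------------------------


def make_lesion_mask(labels: LabelVolume, spec: LesionSpec) -> LesionMask:
    """Connected, rough-edged binary lesion confined to the brain foreground.

    The mask is the connected component around the chosen centre of a
    roughened distance ball, with its radius solved by bisection so the
    voxel count hits ``volume_fraction`` of the brain within +-10%.
    """
    rng = np.random.default_rng(spec.seed)
    fg = labels.data > 0
    n_brain = int(fg.sum())
    target = spec.volume_fraction * n_brain
    if target < 1:
        raise SpecError("requested lesion volume below one voxel")

    # centre selection: explicit coords, a labeled region, or random interior
    interior = ndimage.binary_erosion(fg, iterations=3)
    if not interior.any():
        interior = fg
    if isinstance(spec.center, tuple):
        center = np.array(spec.center, dtype=float)
        cidx = tuple(int(round(c)) for c in center)
        if not fg[cidx]:
            raise SpecError(f"lesion centre {spec.center} is outside the brain")
    elif isinstance(spec.center, int) and spec.center is not None:
        region = interior & (labels.data == spec.center)
        if not region.any():
            region = labels.data == spec.center
        if not region.any():
            raise SpecError(f"no voxels with label {spec.center} for lesion placement")
        cands = np.argwhere(region)
        center = cands[rng.integers(len(cands))].astype(float)
    else:
        cands = np.argwhere(interior)
        center = cands[rng.integers(len(cands))].astype(float)

    idx = np.stack(
        np.meshgrid(*[np.arange(s) for s in labels.shape], indexing="ij"), axis=-1
    ).astype(float)
    dist = np.linalg.norm(idx - center, axis=-1)
    rough = rng.standard_normal(labels.shape)
    rough = ndimage.gaussian_filter(rough, sigma=3.0)
    rms = float(np.sqrt(np.mean(rough**2)))
    if rms > 0:
        rough /= rms
    d_rough = dist * (1.0 + spec.irregularity * np.tanh(rough))

    struct = ndimage.generate_binary_structure(labels.ndim, 1)

    def blob(radius: float) -> np.ndarray:
        cand = (d_rough <= radius) & fg
        lab, n = ndimage.label(cand, structure=struct)
        if n == 0:
            return cand
        comp = lab[tuple(int(round(c)) for c in center)]
        if comp == 0:  # centre fell off: take the largest component
            comp = int(np.argmax(np.bincount(lab.ravel())[1:])) + 1
        return lab == comp

    lo, hi = 0.0, float(np.max(d_rough[fg])) * 1.01
    if blob(hi).sum() < 0.9 * target:
        raise SpecError("requested lesion volume infeasible at this location")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if blob(mid).sum() < target:
            lo = mid
        else:
            hi = mid
    mask = blob(hi)
    if not (0.9 * target <= mask.sum() <= 1.1 * target):
        raise SpecError(
            f"could not match lesion volume: wanted ~{target:.0f}, got {mask.sum()}"
        )
    return LesionMask(mask.astype(np.uint8), labels.geometry)


def otsu_brain_mask(image: ImageVolume) -> np.ndarray:
    """Foreground ("inside the brain") as intensities above the Otsu threshold."""
    thr = threshold_otsu(image.data)
    return image.data > thr


def insert_virtual_lesion(
    healthy: ImageVolume,
    donor: ImageVolume,
    donor_mask: LesionMask,
    pre_aligned: bool = True,
    brain_mask: np.ndarray | None = None,
) -> ImageVolume:
    """Transplant a donor lesion into a healthy image with intensity rescaling.

    The scale factor is the masked mean of the healthy image divided by the
    masked mean of the donor, where "masked mean" averages voxels inside
    the brain but outside the lesion; donor lesion intensities are
    multiplied by that factor and copied into the healthy image.  Voxels
    outside the mask are bit-identical to the input.
    """
    if not pre_aligned:
        # bring the healthy image onto the donor grid first
        from .registration import affine_register
        from .volumes import resample

        aff = affine_register(moving=healthy, fixed=donor)
        healthy = resample(healthy, aff, donor.geometry, interpolation="linear")
    if not healthy.geometry.matches(donor.geometry) or not healthy.geometry.matches(
        donor_mask.geometry
    ):
        raise ValidationError("healthy/donor/mask must share one grid")
    m = donor_mask.data.astype(bool)
    if not m.any():
        warnings.warn("empty lesion mask: returning the healthy image unchanged")
        return healthy.copy()
    if brain_mask is None:
        brain_mask = otsu_brain_mask(healthy)
    sel = brain_mask & ~m
    mm_healthy = float(healthy.data[sel].mean())
    mm_donor = float(donor.data[sel].mean())
    if abs(mm_donor) < 1e-12:
        raise ZeroDivisionError("donor masked mean is zero; cannot compute scale factor")
    s = mm_healthy / mm_donor
    out = healthy.data.copy()
    out[m] = s * donor.data[m]
    return ImageVolume(out, healthy.geometry)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class VirtualCohort:
    """Full cross of controls x lesion donors, mirroring the 6x6=36 design."""

    controls: list  # (control_id, ImageVolume, LabelVolume)
    donors: list  # (lesion_id, ImageVolume donor, LesionMask)
    cases: list  # (control_id, lesion_id, ImageVolume lesioned, LesionMask)
    manifest: pd.DataFrame


def _paint_donor_lesion(
    donor_img: ImageVolume, mask: LesionMask, wm_mean: float, rng
) -> ImageVolume:
    """Hypointense chronic-stroke-like appearance: 30% of WM mean, 10% noise."""
    data = donor_img.data.copy()
    m = mask.data.astype(bool)
    level = 0.3 * wm_mean
    data[m] = level * (1.0 + 0.1 * rng.standard_normal(int(m.sum())))
    return ImageVolume(np.clip(data, 0.0, None), donor_img.geometry)


def make_virtual_cohort(
    n_controls: int,
    n_lesions: int,
    seed: int = 0,
    spec: PhantomSpec | None = None,
    lesion_fractions: Sequence[float] | None = None,
) -> VirtualCohort:
    """Generate the controls, lesion donors and all controls x lesions cases.

    Lesion donors are phantoms of their own with painted hypointense blobs;
    each case is produced by :func:`insert_virtual_lesion` on a shared grid,
    so a 6x6 run yields exactly 36 lesioned images plus the 6 clean ones.
    Lesion sizes span ``lesion_fractions`` (default log-spaced 1%-12% of the
    brain) so size-dependence statistics have support.
    """
    if n_controls < 1 or n_lesions < 1:
        raise SpecError("n_controls and n_lesions must be >= 1")
    if spec is None:
        spec = PhantomSpec()
    if lesion_fractions is None:
        lesion_fractions = np.geomspace(0.01, 0.12, n_lesions)
    elif len(lesion_fractions) != n_lesions:
        raise SpecError("lesion_fractions must have n_lesions entries")

    children = np.random.SeedSequence(seed).spawn(4)
    ctrl_seeds = children[0].generate_state(n_controls) % (2**31 - 1)
    donor_seeds = children[1].generate_state(n_lesions) % (2**31 - 1)
    mask_seeds = children[2].generate_state(n_lesions) % (2**31 - 1)
    paint_seed = int(children[3].generate_state(1)[0] % (2**31 - 1))
    paint_rng = np.random.default_rng(paint_seed)
    wm_mean = spec.tissue_means[2]

    controls = []
    for i in range(n_controls):
        img, lab = make_phantom(replace(spec, seed=int(ctrl_seeds[i])))
        controls.append((f"ctl{i:02d}", img, lab))

    donors = []
    for j in range(n_lesions):
        dimg, dlab = make_phantom(replace(spec, seed=int(donor_seeds[j])))
        lspec = LesionSpec(
            volume_fraction=float(lesion_fractions[j]), seed=int(mask_seeds[j])
        )
        mask = make_lesion_mask(dlab, lspec)
        dimg = _paint_donor_lesion(dimg, mask, wm_mean, paint_rng)
        donors.append((f"les{j:02d}", dimg, mask))

    cases = []
    rows = []
    for cid, cimg, clab in controls:
        for lid, dimg, mask in donors:
            lesioned = insert_virtual_lesion(cimg, dimg, mask, pre_aligned=True)
            cases.append((cid, lid, lesioned, mask))
            rows.append(
                {
                    "control_id": cid,
                    "lesion_id": lid,
                    "lesion_size_voxels": int(mask.count()),
                }
            )
    manifest = pd.DataFrame(rows)
    return VirtualCohort(controls, donors, cases, manifest)
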