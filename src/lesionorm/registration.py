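"""Rigid/affine pre-alignment and SyN-style symmetric diffeomorphic
registration with constrained cost-function masking (CCFM).

The deformable solver follows the greedy symmetric normalization scheme:
two half pull-back fields deform the fixed and the moving image toward a
common midpoint, each iteration composes a smoothed, step-limited local
cross-correlation force into both halves (with opposite signs), and the
full forward/inverse pair is assembled from the half fields at the end, so
the result is independent of argument order up to inversion.

CCFM: when a lesion mask is given, lesion voxels are excluded from both
the similarity score and its gradient (weighted window statistics), and
the moving image is nearest-outside filled inside the lesion before any
smoothing so that no pyramid or gradient computation can see intra-lesion
intensities.  The deformation inside the lesion is therefore produced
purely by the smoothing/regularization of the surrounding flow.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize

from .volumes import (
    AffineTransform,
    DiffeomorphicTransform,
    DisplacementField,
    Geometry,
    ImageVolume,
    LesionMask,
    compose_displacements,
    invert_displacement,
    jacobian_determinant,
    resample,
)

__all__ = [
    "RegistrationConfig",
    "RegistrationResult",
    "RegistrationError",
    "affine_register",
    "local_cross_correlation",
    "syn_register",
    "register_symmetry_check",
]

log = logging.getLogger(__name__)


class RegistrationError(RuntimeError):
    pass


@dataclass
class RegistrationConfig:
    """Tunable parameters of the symmetric diffeomorphic solver.

    ``step_size`` (0.25) and ``outer_iterations`` (3) follow the reference
    protocol; the multiresolution schedule ``levels`` is a list of
    (downsample factor, max inner iterations) pairs.  Smoothing sigmas are
    in mm (voxels on unit-spacing phantoms): the update field is smoothed
    strongly for stable greedy steps, the total field only lightly.
    """

    cc_radius: int = 3
    step_size: float = 0.25
    outer_iterations: int = 3
    levels: tuple = ((4, 100), (2, 70), (1, 80))
    update_smoothing_sigma: float = 4.0
    total_smoothing_sigma: float = 0.5
    convergence_tol: float = 1e-5
    do_affine: bool = True

    def __post_init__(self):
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if self.cc_radius < 1:
            raise ValueError("cc_radius must be >= 1")
        if not self.levels:
            raise ValueError("levels must be non-empty")
        if self.update_smoothing_sigma < 0 or self.total_smoothing_sigma < 0:
            raise ValueError("smoothing sigmas must be >= 0")


@dataclass
class RegistrationResult:
    transform: DiffeomorphicTransform
    metric_trace: list
    converged: bool


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------


def _window_mean(x: np.ndarray, radius: int) -> np.ndarray:
    return ndimage.uniform_filter(x, size=2 * radius + 1, mode="constant")


def _cc_terms(a: np.ndarray, b: np.ndarray, w: np.ndarray, radius: int):
    """Weighted local correlation terms; lesion (w=0) voxels never enter
    any window sum."""
    sw = _window_mean(w, radius)
    valid = sw > 1e-6
    swc = np.where(valid, sw, 1.0)
    ma = _window_mean(w * a, radius) / swc
    mb = _window_mean(w * b, radius) / swc
    A = _window_mean(w * a * b, radius) / swc - ma * mb
    B = _window_mean(w * a * a, radius) / swc - ma * ma
    C = _window_mean(w * b * b, radius) / swc - mb * mb
    floor = 1e-8 * max(float(B.max(initial=0.0)), 1e-30) * max(
        float(C.max(initial=0.0)), 1e-30
    )
    ok = valid & (B * C > floor) & (B > 0) & (C > 0)
    return A, B, C, ma, mb, ok


def local_cross_correlation(
    a: ImageVolume | np.ndarray,
    b: ImageVolume | np.ndarray,
    radius: int = 4,
    weight: np.ndarray | LesionMask | None = None,
):
    """Mean squared local correlation and its gradient field.

    Returns ``(score, gradient)``: the score is the weighted mean over
    included voxels of ``A^2/(B C)`` within the ``(2 radius + 1)^ndim``
    window (affine-invariant, 1.0 for identical non-constant images;
    zero-variance windows contribute 0), the gradient is the analytic
    derivative with respect to ``b``'s sampling positions in voxel units,
    zero wherever the weight is 0.
    """
    arr_a = np.asarray(a.data if isinstance(a, ImageVolume) else a, dtype=float)
    arr_b = np.asarray(b.data if isinstance(b, ImageVolume) else b, dtype=float)
    if arr_a.shape != arr_b.shape:
        raise ValueError("images must share one grid")
    if weight is None:
        w = np.ones_like(arr_a)
    elif isinstance(weight, LesionMask):
        w = 1.0 - weight.data.astype(float)
    else:
        w = np.asarray(weight, dtype=float)

    A, B, C, ma, mb, ok = _cc_terms(arr_a, arr_b, w, radius)
    cc = np.zeros_like(arr_a)
    np.divide(A * A, B * C, out=cc, where=ok)
    np.clip(cc, 0.0, 1.0, out=cc)
    included = w > 0
    n_inc = included.sum()
    score = float(cc[included].mean()) if n_inc else 0.0

    g = np.zeros_like(arr_a)
    safe_BC = np.where(ok, B * C, 1.0)
    safe_C = np.where(ok, C, 1.0)
    g = np.where(
        ok,
        2.0 * A / safe_BC * ((arr_a - ma) - (A / safe_C) * (arr_b - mb)),
        0.0,
    )
    g *= w
    grad_b = np.stack(np.gradient(arr_b), axis=-1)
    grad = g[..., None] * grad_b
    return score, grad


# ---------------------------------------------------------------------------
# affine stage
# ---------------------------------------------------------------------------


def _rot_matrix(ndim: int, angles: np.ndarray) -> np.ndarray:
    if ndim == 2:
        c, s = np.cos(angles[0]), np.sin(angles[0])
        return np.array([[c, -s], [s, c]])
    rx, ry, rz = angles
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _params_to_matrix(p: np.ndarray, ndim: int, center: np.ndarray, kind: str):
    n_rot = 1 if ndim == 2 else 3
    t = p[:ndim]
    if kind == "rigid":
        lin = _rot_matrix(ndim, p[ndim : ndim + n_rot])
    else:
        lin = p[ndim:].reshape(ndim, ndim) + np.eye(ndim)
    mat = np.eye(ndim + 1)
    mat[:ndim, :ndim] = lin
    mat[:ndim, ndim] = center - lin @ center + t
    return mat


def _weighted_ncc(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
    ws = w.sum()
    if ws < 16:
        return 0.0
    am = (w * a).sum() / ws
    bm = (w * b).sum() / ws
    ad, bd = a - am, b - bm
    num = (w * ad * bd).sum()
    den = np.sqrt((w * ad * ad).sum() * (w * bd * bd).sum())
    return float(num / den) if den > 0 else 0.0


def _centroid_world(img: ImageVolume) -> np.ndarray:
    data = np.clip(img.data, 0, None)
    total = data.sum()
    if total <= 0:
        return img.geometry.voxel_to_world((np.array(img.shape) - 1) / 2.0)
    idx = np.indices(img.shape).reshape(img.ndim, -1)
    com = (idx * data.ravel()).sum(axis=1) / total
    return img.geometry.voxel_to_world(com)


def affine_register(
    moving: ImageVolume,
    fixed: ImageVolume,
    mask: LesionMask | None = None,
) -> AffineTransform:
    """Rigid-then-affine pre-alignment maximizing masked global correlation.

    The returned matrix is a pull-back (fixed world -> moving world).
    ``mask`` lives in the moving image's space; its voxels are excluded
    from the similarity.  Optimization runs coarse-to-fine over smoothed
    copies with a centroid-difference initialization.  The computation is
    performed in a canonical image order (deterministic content key) and
    inverted if needed, so ``affine_register(a, b)`` is exactly the
    inverse of ``affine_register(b, a)``.
    """
    if _canon_key(moving) < _canon_key(fixed):
        return _affine_core(moving, fixed, mask_moving=mask)
    inv = _affine_core(fixed, moving, mask_fixed=mask)
    return AffineTransform(np.linalg.inv(inv.matrix), kind=inv.kind)


def _canon_key(img: ImageVolume):
    data = np.asarray(img.data)
    return (float(data.sum()), float(data.std()), float(np.abs(data).max()))


def _affine_core(
    moving: ImageVolume,
    fixed: ImageVolume,
    mask_moving: LesionMask | None = None,
    mask_fixed: LesionMask | None = None,
) -> AffineTransform:
    d = fixed.ndim
    if float(np.std(fixed.data)) < 1e-12 or float(np.std(moving.data)) < 1e-12:
        raise RegistrationError("constant image: affine registration is ill-posed")

    mask_w = None
    moving_use = moving
    if mask_moving is not None:
        mask_w = mask_moving
        moving_use = ImageVolume(
            _fill_masked(moving.data, mask_moving.data), moving.geometry
        )
    fixed_use = fixed
    if mask_fixed is not None:
        fixed_use = ImageVolume(
            _fill_masked(fixed.data, mask_fixed.data), fixed.geometry
        )
    fixed = fixed_use

    center = fixed.geometry.voxel_to_world((np.array(fixed.shape) - 1) / 2.0)
    # subsample the fixed grid for metric evaluation
    stride = max(1, int(np.ceil((np.prod(fixed.shape) / 96**2) ** (1.0 / d))))
    sl = tuple(slice(None, None, stride) for _ in range(d))
    pts = fixed.geometry.grid_world()[sl]

    # static similarity support: the fixed image's foreground (background
    # would otherwise dominate the global correlation)
    sup = ndimage.gaussian_filter(np.abs(fixed.data.astype(float)), 2.0)
    sup = ndimage.binary_dilation(sup > 0.10 * float(sup.max()), iterations=4)
    w_support = sup[sl].astype(float)

    inv_aff_mov = np.linalg.inv(moving.geometry.affine)

    def sample_moving(arr, mapped_world, order):
        vox = mapped_world @ inv_aff_mov[:d, :d].T + inv_aff_mov[:d, d]
        return ndimage.map_coordinates(
            arr, np.moveaxis(vox, -1, 0), order=order, mode="constant", cval=0.0
        )

    t0 = _centroid_world(moving_use) - _centroid_world(fixed)

    best = None
    for sigma, kind, extra_stage in ((2.0, "rigid", False), (1.0, "rigid", False), (1.0, "affine", True)):
        f_s = ndimage.gaussian_filter(fixed.data, sigma)[sl]
        m_s = ndimage.gaussian_filter(moving_use.data, sigma)
        mask_f = (
            ndimage.binary_dilation(
                mask_w.data.astype(bool), iterations=int(np.ceil(2 * sigma))
            ).astype(float)
            if mask_w is not None
            else None
        )
        w_stage = w_support
        if mask_fixed is not None:
            excl = ndimage.binary_dilation(
                mask_fixed.data.astype(bool), iterations=int(np.ceil(2 * sigma))
            )
            w_stage = w_support * (~excl[sl]).astype(float)

        n_rot = 1 if d == 2 else 3
        if kind == "rigid":
            if best is None:
                x0 = np.concatenate([t0, np.zeros(n_rot)])
            else:
                x0 = best
            scales = np.concatenate([np.ones(d), np.full(n_rot, 0.05)])
        else:
            rigid_mat = _params_to_matrix(best, d, center, "rigid")
            x0 = np.concatenate(
                [rigid_mat[:d, d] - (center - rigid_mat[:d, :d] @ center),
                 (rigid_mat[:d, :d] - np.eye(d)).ravel()]
            )
            scales = np.concatenate([np.ones(d), np.full(d * d, 0.02)])

        def loss(q, kind=kind, f_s=f_s, m_s=m_s, mask_f=mask_f, scales=scales,
                 w_stage=w_stage):
            p = q * scales
            mat = _params_to_matrix(p, d, center, kind)
            mapped = pts @ mat[:d, :d].T + mat[:d, d]
            mv = sample_moving(m_s, mapped, order=1)
            w = w_stage.copy()
            if mask_f is not None:
                wm = sample_moving(mask_f, mapped, order=1)
                w *= (wm < 0.5).astype(float)
            return -_weighted_ncc(f_s, mv, w)

        # bounded search around the initialization: the pre-alignment stage
        # should capture pose, not explain deformable shape change
        q0 = x0 / scales
        bounds = [(q - 6.0, q + 6.0) for q in q0]
        res = optimize.minimize(
            loss, q0, method="Powell", bounds=bounds,
            options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 2000},
        )
        best = res.x * scales
        if kind == "affine":
            final_mat = _params_to_matrix(best, d, center, "affine")
            return AffineTransform(final_mat, kind="affine")
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# CCFM helpers
# ---------------------------------------------------------------------------


def _fill_masked(data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace masked voxels by their nearest unmasked neighbour's value.

    Keeps every pyramid/smoothing/gradient computation independent of the
    intensities inside the lesion (the CCFM insensitivity contract).
    """
    m = mask.astype(bool)
    if not m.any():
        return np.asarray(data, dtype=float)
    _, idx = ndimage.distance_transform_edt(m, return_indices=True)
    return np.asarray(data, dtype=float)[tuple(idx)]


def _downsample(data: np.ndarray, factor: int, smooth: bool = True) -> np.ndarray:
    if factor == 1:
        return np.asarray(data, dtype=float).copy()
    d = ndimage.gaussian_filter(np.asarray(data, dtype=float), sigma=factor / 2.0) if smooth else np.asarray(data, dtype=float)
    sl = tuple(slice(None, None, factor) for _ in range(data.ndim))
    return d[sl].copy()


def _level_geometry(geometry: Geometry, factor: int) -> Geometry:
    if factor == 1:
        return geometry
    d = geometry.ndim
    shape = tuple(int(np.ceil(s / factor)) for s in geometry.shape)
    aff = geometry.affine.copy()
    aff[:d, :d] = aff[:d, :d] * factor
    return Geometry(shape, tuple(s * factor for s in geometry.spacing), aff)


def _resample_field(vectors: np.ndarray, from_geom: Geometry, to_geom: Geometry) -> np.ndarray:
    """Linearly interpolate mm displacement components onto another grid."""
    d = from_geom.ndim
    pts = to_geom.grid_world()
    inv = np.linalg.inv(from_geom.affine)
    vox = pts @ inv[:d, :d].T + inv[:d, d]
    coords = np.moveaxis(vox, -1, 0)
    out = np.empty(to_geom.shape + (d,))
    for c in range(d):
        out[..., c] = ndimage.map_coordinates(
            vectors[..., c], coords, order=1, mode="nearest"
        )
    return out


# ---------------------------------------------------------------------------
# SyN solver
# ---------------------------------------------------------------------------


def _smooth_field(vec: np.ndarray, sigma_vox: float) -> np.ndarray:
    if sigma_vox <= 0:
        return vec
    out = np.empty_like(vec)
    for c in range(vec.shape[-1]):
        out[..., c] = ndimage.gaussian_filter(vec[..., c], sigma=sigma_vox)
    return out


class _Level:
    """Per-level state: images, mask and sampling machinery in voxel units."""

    def __init__(self, f: np.ndarray, m: np.ndarray, mask: np.ndarray | None):
        self.f = f
        self.m = m
        self.mask = mask
        self.shape = f.shape
        self.ndim = f.ndim

    def sample(self, arr: np.ndarray, disp_vox: np.ndarray) -> np.ndarray:
        idx = np.indices(self.shape, dtype=float)
        coords = idx + np.moveaxis(disp_vox, -1, 0)
        return ndimage.map_coordinates(arr, coords, order=1, mode="constant", cval=0.0)


def _compose_vox(step: np.ndarray, u: np.ndarray, level: _Level) -> np.ndarray:
    """Pull-back composition in voxel units: (step ; u)(x) = step(x) + u(x + step(x))."""
    out = np.empty_like(u)
    idx = np.indices(level.shape, dtype=float)
    coords = idx + np.moveaxis(step, -1, 0)
    for c in range(u.shape[-1]):
        out[..., c] = step[..., c] + ndimage.map_coordinates(
            u[..., c], coords, order=1, mode="nearest"
        )
    return out


def _jac_min(u_vox: np.ndarray) -> float:
    """Minimum finite-difference Jacobian over interior voxels."""
    d = u_vox.shape[-1]
    grads = [np.stack(np.gradient(u_vox[..., c]), axis=-1) for c in range(d)]
    jac = np.stack(grads, axis=-2) + np.eye(d)
    det = np.linalg.det(jac)
    interior = tuple(slice(1, -1) for _ in range(d))
    return float(det[interior].min())


def _invert_transform_onto(
    t: DiffeomorphicTransform, geometry: Geometry
) -> DiffeomorphicTransform:
    """Exact functional inverse of a transform, sampled on ``geometry``.

    The inverted affine stays in ``pre_affine`` (with the displacement
    fields carrying only the residual deformation), so downstream
    transform averaging treats all members uniformly.
    """
    d = geometry.ndim
    pre = AffineTransform(
        np.linalg.inv(t.pre_affine.matrix), kind=t.pre_affine.kind
    )
    m_lin = t.pre_affine.matrix[:d, :d]
    pts = geometry.grid_world()
    # map'(x) = N(x + u'(x)) == t.map_points_inverse(x), N = M^-1
    fwd_vec = (t.map_points_inverse(pts) - pre.apply(pts)) @ m_lin.T
    # map'^-1(y): z = N^-1 y applied first, then z + u_inv'(z) == t.map_points(y)
    inv_vec = t.map_points(pre.apply(pts)) - pts
    return DiffeomorphicTransform(
        pre,
        DisplacementField(fwd_vec, geometry),
        DisplacementField(inv_vec, geometry),
    )


def syn_register(
    fixed: ImageVolume,
    moving: ImageVolume,
    lesion_mask: LesionMask | None = None,
    config: RegistrationConfig | None = None,
) -> RegistrationResult:
    """Symmetric diffeomorphic registration of ``moving`` onto ``fixed``.

    Affine pre-alignment runs first (unless disabled); the deformable stage
    then estimates two half-transforms meeting at a midpoint and composes
    them into the forward/inverse pull-back pair.  ``lesion_mask`` (in the
    moving image's space, 1 = lesion) activates CCFM: within the lesion the
    metric gradient is zero and the deformation is interpolated from the
    surrounding flow by the update/total field smoothing.

    For unmasked pairs the solve runs in a canonical argument order
    (deterministic content key) and is inverted exactly if the caller's
    order differs, so which image is source and which is target is
    immaterial; a lesion mask pins the orientation instead (the lesioned
    image is the moving one).
    """
    if config is None:
        config = RegistrationConfig()
    if lesion_mask is None and _canon_key(moving) < _canon_key(fixed):
        res = _syn_core(fixed=moving, moving=fixed, lesion_mask=None, config=config)
        return RegistrationResult(
            transform=_invert_transform_onto(res.transform, fixed.geometry),
            metric_trace=res.metric_trace,
            converged=res.converged,
        )
    return _syn_core(fixed, moving, lesion_mask, config)


def _syn_core(
    fixed: ImageVolume,
    moving: ImageVolume,
    lesion_mask: LesionMask | None = None,
    config: RegistrationConfig | None = None,
) -> RegistrationResult:
    d = fixed.ndim
    if moving.ndim != d:
        raise RegistrationError("fixed and moving must have the same dimensionality")
    if float(np.std(fixed.data)) < 1e-12 or float(np.std(moving.data)) < 1e-12:
        raise RegistrationError("constant image: registration is ill-posed")

    # --- affine stage -------------------------------------------------------
    if config.do_affine:
        pre = affine_register(moving, fixed, mask=lesion_mask)
    else:
        pre = AffineTransform.identity(d)

    mov_filled = moving
    if lesion_mask is not None:
        mov_filled = ImageVolume(
            _fill_masked(moving.data, lesion_mask.data), moving.geometry
        )
    m_on_fixed = resample(mov_filled, pre, fixed.geometry, interpolation="linear")
    mask_on_fixed = None
    if lesion_mask is not None:
        mask_on_fixed = resample(
            lesion_mask, pre, fixed.geometry, interpolation="nearest"
        ).data.astype(float)

    # normalize intensities for a scale-free metric floor
    def _norm(x):
        s = float(np.std(x))
        return (x - float(np.mean(x))) / s

    F = _norm(fixed.data.astype(float))
    M = _norm(m_on_fixed.data)

    # similarity support: the joint foreground of both images (background
    # noise has near-zero window variance, where the CC gradient is pure
    # amplified noise; excluding it is what keeps greedy updates stable)
    def _support(data):
        sm = ndimage.gaussian_filter(np.abs(np.asarray(data, float)), 2.0)
        return sm > 0.10 * float(sm.max())

    support = (_support(fixed.data) | _support(m_on_fixed.data)).astype(float)
    support = ndimage.binary_dilation(
        support > 0.5, iterations=config.cc_radius
    ).astype(float)

    geom = fixed.geometry
    mean_spacing = float(np.mean(geom.spacing))
    u1 = np.zeros(geom.shape + (d,))  # fixed -> midpoint (mm)
    u2 = np.zeros(geom.shape + (d,))  # moving -> midpoint (mm)
    trace: list = []
    converged = False
    if not np.isfinite(M).all() or not np.isfinite(F).all():
        raise RegistrationError("NaN in input intensities")

    sl_cache = {}

    def _level_weight_arrays(factor):
        if factor not in sl_cache:
            sl = tuple(slice(None, None, factor) for _ in range(d))
            lsupport = support[sl]
            lmask = None
            if mask_on_fixed is not None:
                lmask = (mask_on_fixed[sl] >= 0.5).astype(float)
            sl_cache[factor] = (lsupport, lmask)
        return sl_cache[factor]

    def _score_and_force(level, v1, v2, lsupport, lmask, radius, want_force=True):
        f_mid = level.sample(level.f, v1)
        m_mid = level.sample(level.m, v2)
        w = np.minimum(level.sample(lsupport, v1) + level.sample(lsupport, v2), 1.0)
        w = (w >= 0.5).astype(float)
        if lmask is not None:
            w_mid = level.sample(lmask, v2)
            w *= (w_mid < 0.5).astype(float)
        A, B, C, ma, mb, ok = _cc_terms(f_mid, m_mid, w, radius)
        cc = np.zeros_like(f_mid)
        np.divide(A * A, B * C, out=cc, where=ok)
        np.clip(cc, 0.0, 1.0, out=cc)
        inc = w > 0
        score = float(cc[inc].mean()) if inc.any() else 0.0
        if not np.isfinite(score):
            raise RegistrationError("NaN in similarity metric")
        if not want_force:
            return score, None
        safe_BC = np.where(ok, B * C, 1.0)
        safe_C = np.where(ok, C, 1.0)
        g = np.where(
            ok,
            2.0 * A / safe_BC * ((f_mid - ma) - (A / safe_C) * (m_mid - mb)),
            0.0,
        )
        g *= w
        gf = np.stack(np.gradient(f_mid), axis=-1)
        gm = np.stack(np.gradient(m_mid), axis=-1)
        return score, g[..., None] * 0.5 * (gf + gm)

    prev_outer_best = -np.inf
    for outer in range(config.outer_iterations):
        for factor, max_iters in config.levels:
            lf = _downsample(F, factor)
            lm = _downsample(M, factor)
            lsupport, lmask = _level_weight_arrays(factor)
            level = _Level(lf, lm, lmask)
            spacing = mean_spacing * factor
            sig_up = config.update_smoothing_sigma / spacing
            sig_tot = config.total_smoothing_sigma / spacing

            level_geom = _level_geometry(geom, factor)
            v1 = _resample_field(u1, geom, level_geom) / spacing  # voxel units
            v2 = _resample_field(u2, geom, level_geom) / spacing

            best_score = -np.inf
            best_v1, best_v2 = v1.copy(), v2.copy()
            best_it = 0
            for it in range(max_iters):
                score, delta = _score_and_force(
                    level, v1, v2, lsupport, lmask, config.cc_radius
                )
                if score > best_score + config.convergence_tol:
                    best_score = score
                    best_v1, best_v2 = v1.copy(), v2.copy()
                    best_it = it
                elif score > best_score:
                    best_score = score
                    best_v1, best_v2 = v1.copy(), v2.copy()
                trace.append(max(score, best_score))
                if it - best_it >= 8:  # no tol-sized improvement in 8 iters
                    break
                if score >= 1.0 - 1e-9:
                    converged = True
                    break

                delta = _smooth_field(delta, sig_up)
                norms = np.sqrt((delta**2).sum(axis=-1))
                mag = float(np.percentile(norms, 99))
                if mag < 1e-12:
                    converged = True
                    break
                # normalize the bulk of the update to step_size voxels and
                # cap outliers at the same step (edge spikes otherwise
                # starve the bulk motion)
                delta *= config.step_size / mag
                norms = np.sqrt((delta**2).sum(axis=-1))
                over = norms > config.step_size
                if over.any():
                    scale = np.ones_like(norms)
                    scale[over] = config.step_size / norms[over]
                    delta *= scale[..., None]

                # safeguard: half-fields must stay diffeomorphic
                ok_update = False
                for _ in range(5):
                    v2_new = _smooth_field(_compose_vox(delta, v2, level), sig_tot)
                    v1_new = _smooth_field(_compose_vox(-delta, v1, level), sig_tot)
                    if _jac_min(v1_new) > 0.0 and _jac_min(v2_new) > 0.0:
                        ok_update = True
                        break
                    delta *= 0.5
                if not ok_update:
                    log.warning(
                        "level x%d iter %d: update skipped (Jacobian safeguard)",
                        factor, it,
                    )
                    continue
                v1, v2 = v1_new, v2_new

            u1 = _resample_field(best_v1 * spacing, level_geom, geom)
            u2 = _resample_field(best_v2 * spacing, level_geom, geom)

        final = trace[-1] if trace else 0.0
        if final - prev_outer_best < config.convergence_tol:
            converged = True
            break
        prev_outer_best = final

    # safeguard: never return a deformable stage that scores worse than the
    # affine-only alignment at full resolution
    full_support, full_mask = _level_weight_arrays(1)
    full_level = _Level(F, M, full_mask)
    zero = np.zeros_like(u1)
    s_id, _ = _score_and_force(
        full_level, zero, zero, full_support, full_mask, config.cc_radius,
        want_force=False,
    )
    s_fin, _ = _score_and_force(
        full_level, u1 / mean_spacing, u2 / mean_spacing, full_support, full_mask,
        config.cc_radius, want_force=False,
    )
    if s_fin < s_id:
        log.warning("deformable stage rejected (%.4f < %.4f): keeping affine only",
                    s_fin, s_id)
        u1, u2 = zero, zero.copy()
        converged = False
        s_fin = s_id
    # bracket the per-level trace with comparable full-resolution scores
    trace = [s_id] + trace + [s_fin]

    # --- assemble the full transform ---------------------------------------
    f1 = DisplacementField(u1, geom)
    f2 = DisplacementField(u2, geom)
    f1_inv = invert_displacement(f1)
    fwd = compose_displacements(f1_inv, f2)
    # numerical inversion/interpolation error can push the composed field's
    # finite-difference Jacobian negative even though the analytic
    # composition of two diffeomorphisms cannot fold; smooth minimally
    # until interior positivity holds, then invert the repaired field so
    # the pair stays mutually inverse
    d_vox = np.linalg.inv(geom.affine[:d, :d])
    sigma = 0.5
    for attempt in range(12):
        if _jac_min(fwd.vectors @ d_vox.T) > 0:
            break
        log.warning("composed field folds; smoothing (attempt %d)", attempt + 1)
        fwd = DisplacementField(_smooth_field(fwd.vectors, sigma), geom)
        sigma = min(sigma * 1.4, 3.0)
    inv = invert_displacement(fwd, iterations=80, tol_voxels=0.002)
    sigma = 0.5
    for attempt in range(12):
        if _jac_min(inv.vectors @ d_vox.T) > 0:
            break
        inv = DisplacementField(_smooth_field(inv.vectors, sigma), geom)
        sigma = min(sigma * 1.4, 3.0)
    transform = DiffeomorphicTransform(pre, fwd, inv)
    return RegistrationResult(transform=transform, metric_trace=trace, converged=converged)


def register_symmetry_check(
    fixed: ImageVolume,
    moving: ImageVolume,
    config: RegistrationConfig | None = None,
) -> float:
    """Mean voxel discrepancy between the two registration directions.

    Registers A->B and B->A and compares each result's full forward map
    with the other's inverse map, averaged over the images' foreground
    support (outside it the deformation is unconstrained regularizer
    extrapolation); the two comparisons are averaged, so the value is
    invariant to exchanging the arguments.  Small values certify the
    solver's symmetry (source/target choice is immaterial).
    """
    r_ab = syn_register(fixed, moving, config=config)
    r_ba = syn_register(moving, fixed, config=config)
    ms = float(np.mean(fixed.geometry.spacing))

    def _fg(img):
        sm = ndimage.gaussian_filter(np.abs(img.data.astype(float)), 2.0)
        return sm > 0.10 * float(sm.max())

    fg_a, fg_b = _fg(fixed), _fg(moving)
    pts_a = fixed.geometry.grid_world()
    pts_b = moving.geometry.grid_world()
    d1 = np.linalg.norm(
        r_ab.transform.map_points(pts_a) - r_ba.transform.map_points_inverse(pts_a),
        axis=-1,
    )[fg_a].mean()
    d2 = np.linalg.norm(
        r_ba.transform.map_points(pts_b) - r_ab.transform.map_points_inverse(pts_b),
        axis=-1,
    )[fg_b].mean()
    return float(0.5 * (d1 + d2)) / ms
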