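"""Volumetric data model, NIfTI I/O, resampling, and transform algebra.

Conventions used throughout the package:

* Voxel indices are 0-based; world coordinates (mm) are obtained through
  the NIfTI-style homogeneous affine.  Grids may be 2-D or 3-D; every
  operation is dimension-generic.
* Displacement fields are *pull-back* maps stored in mm world units on
  the grid of the transform's reference (fixed/template) space: for each
  reference voxel they say where to sample the other image.  A field of
  zeros is the identity.
* A :class:`DiffeomorphicTransform` maps a reference-space world point
  ``x`` to the moving-space point ``M (x + u_fwd(x))`` where ``M`` is the
  affine pre-alignment; its inverse maps ``y`` to
  ``M^-1 y + u_inv(M^-1 y)``.
* Out-of-bounds samples fill with 0 (background is air in all phantoms
  and brain volumes).  Nearest-neighbour interpolation breaks exact
  half-voxel ties toward the lower index on every axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.linalg import expm, logm

__all__ = [
    "Geometry",
    "ImageVolume",
    "LabelVolume",
    "LesionMask",
    "AffineTransform",
    "DisplacementField",
    "DiffeomorphicTransform",
    "GeometryError",
    "ValidationError",
    "read_nifti",
    "write_nifti",
    "read_displacement_field",
    "read_affine_text",
    "write_affine_text",
    "resample",
    "compose",
    "average_transforms",
    "invert_displacement",
    "jacobian_determinant",
    "inverse_consistency_voxels",
    "compose_displacements",
]

GEOM_ATOL = 1e-5  # mm tolerance for geometry comparisons


class GeometryError(ValueError):
    """Grids or affines that are incompatible for the requested operation."""


class ValidationError(ValueError):
    """Data that violates a type invariant."""


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Geometry:
    """Shape, voxel spacing (mm) and voxel->world affine of a grid."""

    shape: tuple
    spacing: tuple
    affine: np.ndarray  # (ndim+1, ndim+1) homogeneous

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        aff = np.asarray(self.affine, dtype=float)
        d = len(self.shape)
        if aff.shape != (d + 1, d + 1):
            raise GeometryError(
                f"affine shape {aff.shape} does not match {d}-D grid"
            )
        if abs(np.linalg.det(aff)) < 1e-12:
            raise GeometryError("affine is singular")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("voxel spacing must be strictly positive")
        if any(s < 1 for s in self.shape):
            raise ValidationError("all grid dimensions must be >= 1")
        object.__setattr__(self, "affine", aff)

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @classmethod
    def unit(cls, shape: Sequence[int]) -> "Geometry":
        """Unit-spacing, identity-affine geometry (world == voxel)."""
        d = len(shape)
        return cls(tuple(shape), (1.0,) * d, np.eye(d + 1))

    def voxel_to_world(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        d = self.ndim
        return pts @ self.affine[:d, :d].T + self.affine[:d, d]

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        d = self.ndim
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:d, :d].T + inv[:d, d]

    def grid_world(self) -> np.ndarray:
        """World coordinates of every voxel, shape ``shape + (ndim,)``."""
        idx = np.stack(
            np.meshgrid(*[np.arange(s, dtype=float) for s in self.shape], indexing="ij"),
            axis=-1,
        )
        return self.voxel_to_world(idx)

    def matches(self, other: "Geometry", atol: float = GEOM_ATOL) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.affine, other.affine, atol=atol)
        )


def _require_same_geometry(a, b, what: str = "operands"):
    if not a.geometry.matches(b.geometry):
        raise GeometryError(f"{what} are on different grids")


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------


class _BaseVolume:
    def __init__(self, data: np.ndarray, geometry: Geometry):
        data = np.asarray(data)
        if data.ndim != geometry.ndim or data.shape != geometry.shape:
            raise GeometryError(
                f"data shape {data.shape} does not match geometry {geometry.shape}"
            )
        self.data = data
        self.geometry = geometry

    @property
    def shape(self):
        return self.geometry.shape

    @property
    def ndim(self):
        return self.geometry.ndim

    @property
    def spacing(self):
        return self.geometry.spacing

    @property
    def affine(self):
        return self.geometry.affine

    def copy(self):
        return type(self)(self.data.copy(), self.geometry)


class ImageVolume(_BaseVolume):
    """3-D (or 2-D) scalar intensity grid with voxel spacing and affine."""

    def __init__(self, data, geometry: Geometry):
        data = np.asarray(data, dtype=np.float64)
        if not np.all(np.isfinite(data)):
            raise ValidationError("image intensities must be finite")
        super().__init__(data, geometry)


class LabelVolume(_BaseVolume):
    """Non-negative integer label grid sharing ImageVolume geometry."""

    def __init__(self, data, geometry: Geometry):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("label data must be integer-valued")
            arr = np.round(arr).astype(np.int32)
        if arr.min() < 0:
            raise ValidationError("labels must be non-negative")
        super().__init__(arr.astype(np.int32), geometry)

    @property
    def label_ids(self) -> set:
        ids = np.unique(self.data)
        return set(int(i) for i in ids if i != 0)


class LesionMask(_BaseVolume):
    """Binary grid, 1 inside the lesion and 0 elsewhere."""

    def __init__(self, data, geometry: Geometry):
        arr = np.asarray(data)
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValidationError(f"lesion mask values must be 0/1, got {vals}")
        super().__init__(arr.astype(np.uint8), geometry)

    def invert(self) -> "LesionMask":
        """Complement mask (0 inside lesion, 1 elsewhere) used for CCFM."""
        return LesionMask(1 - self.data, self.geometry)

    def count(self) -> int:
        return int(self.data.sum())


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


@dataclass
class AffineTransform:
    """Homogeneous world->world matrix; pull-back (fixed world -> moving world)."""

    matrix: np.ndarray
    kind: str = "affine"  # "rigid" | "affine"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValidationError("affine matrix must be square homogeneous")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValidationError("affine matrix must be invertible")
        if self.kind == "rigid":
            rot = self.matrix[:-1, :-1]
            if not np.allclose(rot @ rot.T, np.eye(n - 1), atol=1e-6) or np.linalg.det(rot) < 0:
                raise ValidationError("rigid transform requires a proper rotation block")

    @property
    def ndim(self) -> int:
        return self.matrix.shape[0] - 1

    @classmethod
    def identity(cls, ndim: int) -> "AffineTransform":
        return cls(np.eye(ndim + 1), kind="rigid")

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        d = self.ndim
        return pts @ self.matrix[:d, :d].T + self.matrix[:d, d]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix), kind=self.kind)

    def is_identity(self, atol: float = 1e-9) -> bool:
        return np.allclose(self.matrix, np.eye(self.ndim + 1), atol=atol)


@dataclass
class DisplacementField:
    """Per-voxel pull-back displacements in mm on a reference grid."""

    vectors: np.ndarray  # shape + (ndim,)
    geometry: Geometry

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        d = self.geometry.ndim
        if self.vectors.shape != self.geometry.shape + (d,):
            raise GeometryError(
                f"field shape {self.vectors.shape} does not match grid "
                f"{self.geometry.shape} + ({d},)"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValidationError("displacement components must be finite")

    @classmethod
    def zeros(cls, geometry: Geometry) -> "DisplacementField":
        return cls(np.zeros(geometry.shape + (geometry.ndim,)), geometry)

    def sample_world(self, pts_world: np.ndarray) -> np.ndarray:
        """Linearly interpolate the field at world points (zero outside)."""
        vox = self.geometry.world_to_voxel(pts_world)
        coords = np.moveaxis(vox, -1, 0)
        out = np.empty_like(pts_world, dtype=float)
        for c in range(self.geometry.ndim):
            out[..., c] = ndimage.map_coordinates(
                self.vectors[..., c], coords, order=1, mode="constant", cval=0.0
            )
        return out

    def magnitude_voxels(self) -> np.ndarray:
        """Per-voxel displacement magnitude expressed in voxel units."""
        d = self.geometry.ndim
        lin_inv = np.linalg.inv(self.geometry.affine[:d, :d])
        vox = self.vectors @ lin_inv.T
        return np.sqrt((vox**2).sum(axis=-1))


@dataclass
class DiffeomorphicTransform:
    """Affine pre-alignment plus mutually inverse dense displacement fields.

    ``forward`` and ``inverse`` both live on the reference (fixed) grid.
    The forward map pulls the reference space into the moving space:
    ``phi(x) = M (x + u_fwd(x))``; the inverse pulls back:
    ``phi^-1(y) = z + u_inv(z)`` with ``z = M^-1 y``.
    """

    pre_affine: AffineTransform
    forward: DisplacementField
    inverse: DisplacementField

    def __post_init__(self):
        if not self.forward.geometry.matches(self.inverse.geometry):
            raise GeometryError("forward/inverse fields must share one grid")

    @property
    def geometry(self) -> Geometry:
        return self.forward.geometry

    @classmethod
    def identity(cls, geometry: Geometry) -> "DiffeomorphicTransform":
        return cls(
            AffineTransform.identity(geometry.ndim),
            DisplacementField.zeros(geometry),
            DisplacementField.zeros(geometry),
        )

    @classmethod
    def from_affine(
        cls, affine: AffineTransform, geometry: Geometry
    ) -> "DiffeomorphicTransform":
        return cls(
            affine, DisplacementField.zeros(geometry), DisplacementField.zeros(geometry)
        )

    def map_points(self, pts_world: np.ndarray) -> np.ndarray:
        return self.pre_affine.apply(pts_world + self.forward.sample_world(pts_world))

    def map_points_inverse(self, pts_world: np.ndarray) -> np.ndarray:
        z = self.pre_affine.inverse().apply(pts_world)
        return z + self.inverse.sample_world(z)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def _nearest_sample(data: np.ndarray, vox: np.ndarray, fill=0):
    """Nearest-neighbour sampling; half-voxel ties round to the lower index."""
    idx = np.ceil(vox - 0.5).astype(np.int64)  # 2.5 -> 2, 2.51 -> 3
    inside = np.ones(idx.shape[:-1], dtype=bool)
    for ax, n in enumerate(data.shape):
        inside &= (idx[..., ax] >= 0) & (idx[..., ax] < n)
    idx_c = np.where(inside[..., None], idx, 0)
    out = data[tuple(idx_c[..., ax] for ax in range(data.ndim))]
    return np.where(inside, out, np.asarray(fill, dtype=data.dtype))


def _transform_target_to_source_vox(transform, target_geometry, source_geometry, invert):
    pts = target_geometry.grid_world()
    if isinstance(transform, AffineTransform):
        mapped = transform.inverse().apply(pts) if invert else transform.apply(pts)
    elif isinstance(transform, DiffeomorphicTransform):
        mapped = transform.map_points_inverse(pts) if invert else transform.map_points(pts)
    else:
        raise TypeError(f"unsupported transform type {type(transform)!r}")
    return source_geometry.world_to_voxel(mapped)


def resample(
    image,
    transform,
    target_geometry: Geometry | None = None,
    interpolation: str = "linear",
    invert: bool = False,
):
    """Warp a volume onto ``target_geometry`` through a pull-back transform.

    ``transform`` maps target-space world points into source-space world
    points (pass ``invert=True`` to use its inverse direction).  Labels and
    masks must use nearest interpolation; out-of-bounds samples fill with 0.
    """
    if target_geometry is None:
        target_geometry = (
            transform.geometry
            if isinstance(transform, DiffeomorphicTransform)
            else image.geometry
        )
    is_discrete = isinstance(image, (LabelVolume, LesionMask))
    if is_discrete and interpolation != "nearest":
        raise ValidationError("labels and masks must be resampled with nearest interpolation")
    if interpolation not in ("linear", "nearest"):
        raise ValidationError(f"unknown interpolation {interpolation!r}")

    vox = _transform_target_to_source_vox(transform, target_geometry, image.geometry, invert)
    if interpolation == "nearest":
        out = _nearest_sample(image.data, vox, fill=0)
    else:
        coords = np.moveaxis(vox, -1, 0)
        out = ndimage.map_coordinates(
            np.asarray(image.data, dtype=float), coords, order=1,
            mode="constant", cval=0.0,
        )
    return type(image)(out, target_geometry)


# ---------------------------------------------------------------------------
# field algebra
# ---------------------------------------------------------------------------


def compose_displacements(
    a: DisplacementField, b: DisplacementField
) -> DisplacementField:
    """Pull-back composition ``w(x) = a(x) + b(x + a(x))`` on ``a``'s grid."""
    pts = a.geometry.grid_world()
    ax = a.vectors
    w = ax + b.sample_world(pts + ax)
    return DisplacementField(w, a.geometry)


def invert_displacement(
    u: DisplacementField, iterations: int = 40, tol_voxels: float = 0.01
) -> DisplacementField:
    """Fixed-point inverse ``v(x) = -u(x + v(x))`` with under-relaxation.

    Runs until the mean update drops below ``tol_voxels`` or the iteration
    budget is spent; the 0.5 damping keeps the iteration contractive for
    fields whose gradients approach the folding limit.
    """
    geom = u.geometry
    pts = geom.grid_world()
    mean_spacing = float(np.mean(geom.spacing))
    v = np.zeros_like(u.vectors)
    relax = 1.0
    prev_delta = np.inf
    for _ in range(iterations):
        target = -u.sample_world(pts + v)
        new = v + relax * (target - v)
        delta = float(np.mean(np.linalg.norm(new - v, axis=-1))) / mean_spacing
        if delta > prev_delta:  # not contracting: damp
            relax = max(0.25, relax * 0.5)
        prev_delta = delta
        v = new
        if delta < tol_voxels:
            break
    return DisplacementField(v, geom)


def compose(
    outer: DiffeomorphicTransform, inner: DiffeomorphicTransform
) -> DiffeomorphicTransform:
    """Chain two pull-back transforms: resampling with the result equals
    resampling with ``inner`` first, then ``outer``.

    The composed map is ``x -> inner(outer(x))`` with the inverse
    ``y -> outer^-1(inner^-1(y))``; both are sampled onto ``outer``'s grid
    (one interpolation step).
    """
    geom = outer.geometry
    pts = geom.grid_world()
    fwd = inner.map_points(outer.map_points(pts)) - pts
    inv = outer.map_points_inverse(inner.map_points_inverse(pts)) - pts
    return DiffeomorphicTransform(
        AffineTransform.identity(geom.ndim),
        DisplacementField(fwd, geom),
        DisplacementField(inv, geom),
    )


def average_transforms(
    transforms: Sequence[DiffeomorphicTransform],
) -> DiffeomorphicTransform:
    """Voxelwise mean of the forward fields with log-domain affine averaging.

    The inverse field is recomputed numerically from the averaged forward
    field.  Used by the template builder's shape-update step, where the mean
    subject->template transform estimates the residual drift of the template
    from the true mean shape.
    """
    transforms = list(transforms)
    if not transforms:
        raise ValidationError("cannot average an empty list of transforms")
    geom = transforms[0].geometry
    for t in transforms[1:]:
        if not t.geometry.matches(geom):
            raise GeometryError("transforms to average must share one grid")
    fwd = np.mean([t.forward.vectors for t in transforms], axis=0)
    logs = [logm(t.pre_affine.matrix) for t in transforms]
    avg_mat = expm(np.real(np.mean(logs, axis=0)))
    fwd_field = DisplacementField(fwd, geom)
    inv_field = invert_displacement(fwd_field)
    return DiffeomorphicTransform(AffineTransform(avg_mat), fwd_field, inv_field)


def jacobian_determinant(field: DisplacementField) -> np.ndarray:
    """Finite-difference Jacobian determinant of ``x + u(x)`` in voxel units."""
    geom = field.geometry
    d = geom.ndim
    lin_inv = np.linalg.inv(geom.affine[:d, :d])
    u_vox = field.vectors @ lin_inv.T
    grads = []
    for c in range(d):
        grads.append(np.stack(np.gradient(u_vox[..., c]), axis=-1))
    jac = np.stack(grads, axis=-2)  # shape + (d, d) of du_c/dx_ax
    jac = jac + np.eye(d)
    return np.linalg.det(jac)


def inverse_consistency_voxels(t: DiffeomorphicTransform) -> float:
    """Mean |phi^-1(phi(x)) - x| in voxel units over the reference grid."""
    geom = t.geometry
    pts = geom.grid_world()
    back = t.map_points_inverse(t.map_points(pts))
    return float(np.mean(np.linalg.norm(back - pts, axis=-1))) / float(
        np.mean(geom.spacing)
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FIELD_DESCRIP = b"lesionorm displacement field: pull-back, mm, components last axis"


def _to_nifti_affine(geometry: Geometry) -> np.ndarray:
    """Embed a 2-D or 3-D grid affine into the 4x4 NIfTI affine."""
    aff4 = np.eye(4)
    d = geometry.ndim
    aff4[:d, :d] = geometry.affine[:d, :d]
    aff4[:d, 3] = geometry.affine[:d, d]
    return aff4


def _geometry_from_nifti(img, ndim: int) -> Geometry:
    aff4 = img.affine
    aff = np.eye(ndim + 1)
    aff[:ndim, :ndim] = aff4[:ndim, :ndim]
    aff[:ndim, ndim] = aff4[:ndim, 3]
    spacing = tuple(float(s) for s in np.sqrt((aff4[:3, :ndim] ** 2).sum(axis=0)))
    return Geometry(img.shape[:ndim], spacing, aff)


def write_nifti(volume, path) -> None:
    """Serialize a volume or displacement field as NIfTI-1.

    Displacement fields are written with the vector components in the last
    axis (a 4-D file for 3-D grids) and a dialect note in the header
    description field.
    """
    path = Path(path)
    if isinstance(volume, DisplacementField):
        img = nib.Nifti1Image(
            volume.vectors.astype(np.float64), _to_nifti_affine(volume.geometry)
        )
        img.header["descrip"] = _FIELD_DESCRIP
    elif isinstance(volume, LesionMask):
        img = nib.Nifti1Image(volume.data.astype(np.uint8), _to_nifti_affine(volume.geometry))
    elif isinstance(volume, LabelVolume):
        img = nib.Nifti1Image(volume.data.astype(np.int32), _to_nifti_affine(volume.geometry))
    elif isinstance(volume, ImageVolume):
        img = nib.Nifti1Image(volume.data.astype(np.float64), _to_nifti_affine(volume.geometry))
    else:
        raise TypeError(f"cannot serialize object of type {type(volume)!r}")
    nib.save(img, str(path))


def read_nifti(path, kind: str = "image"):
    """Load a NIfTI volume as an :class:`ImageVolume`, :class:`LabelVolume`
    or :class:`LesionMask` (``kind`` in ``image|labels|mask``)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # nibabel raises assorted types for bad files
        raise IOError(f"could not read NIfTI file {path}: {exc}") from exc
    data = np.squeeze(data)
    if data.ndim not in (2, 3):
        raise GeometryError(
            f"{path}: expected a single 2-D/3-D volume, got shape {data.shape}"
        )
    geom = _geometry_from_nifti(img, data.ndim)
    if kind == "image":
        return ImageVolume(data, geom)
    if kind == "labels":
        return LabelVolume(data, geom)
    if kind == "mask":
        return LesionMask(data, geom)
    raise ValidationError(f"unknown volume kind {kind!r}")


def read_displacement_field(path) -> DisplacementField:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    data = np.squeeze(data)
    ndim = data.shape[-1]
    if data.ndim != ndim + 1:
        raise GeometryError(f"{path}: not a displacement field (shape {data.shape})")
    geom = _geometry_from_nifti(img, ndim)
    return DisplacementField(data, geom)


def write_affine_text(transform: AffineTransform, path) -> None:
    """Write the homogeneous matrix as whitespace-delimited rows (4x4 for 3-D)."""
    np.savetxt(str(path), transform.matrix, fmt="%.12g")


def read_affine_text(path, kind: str = "affine") -> AffineTransform:
    mat = np.loadtxt(str(path))
    return AffineTransform(mat, kind=kind)
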