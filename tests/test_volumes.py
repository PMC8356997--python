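"""Core data model: NIfTI round trips, resampling, transform algebra."""

import numpy as np
import pytest

from lesionorm.lesion_sim import make_synthetic_deformation
from lesionorm.volumes import (
    AffineTransform,
    DiffeomorphicTransform,
    DisplacementField,
    Geometry,
    GeometryError,
    ImageVolume,
    LabelVolume,
    LesionMask,
    ValidationError,
    average_transforms,
    compose,
    inverse_consistency_voxels,
    invert_displacement,
    jacobian_determinant,
    read_displacement_field,
    read_nifti,
    resample,
    write_nifti,
)


def _translation(t):
    d = len(t)
    mat = np.eye(d + 1)
    mat[:d, d] = t
    return AffineTransform(mat)


class TestIO:
    @pytest.mark.parametrize("kind", ["image", "labels", "mask"])
    def test_round_trip_preserves_data_and_affine(self, tmp_path, kind):
        rng = np.random.default_rng(0)
        geom = Geometry((8, 9, 7), (1.0, 1.2, 2.0), np.diag([1.0, 1.2, 2.0, 1.0]))
        if kind == "image":
            vol = ImageVolume(rng.random(geom.shape) * 50, geom)
        elif kind == "labels":
            vol = LabelVolume(rng.integers(0, 6, geom.shape), geom)
        else:
            vol = LesionMask(rng.integers(0, 2, geom.shape), geom)
        path = tmp_path / f"{kind}.nii.gz"
        write_nifti(vol, path)
        back = read_nifti(path, kind=kind)
        np.testing.assert_array_equal(back.data, vol.data)
        np.testing.assert_allclose(back.affine, vol.affine, atol=1e-6)
        if kind == "labels":
            assert back.label_ids == vol.label_ids

    def test_displacement_field_round_trip_and_layout(self, tmp_path):
        geom = Geometry.unit((16, 16, 16))
        field = DisplacementField(
            np.random.default_rng(1).normal(size=geom.shape + (3,)), geom
        )
        path = tmp_path / "field.nii.gz"
        write_nifti(field, path)
        import nibabel as nib

        assert nib.load(str(path)).shape[-1] == 3  # vector components last
        back = read_displacement_field(path)
        np.testing.assert_allclose(back.vectors, field.vectors, atol=1e-12)

    def test_mask_with_value_two_rejected(self):
        geom = Geometry.unit((4, 4))
        with pytest.raises(ValidationError):
            LesionMask(np.full((4, 4), 2), geom)

    def test_garbage_file_raises_io_error(self, tmp_path):
        bad = tmp_path / "bad.nii"
        bad.write_bytes(b"xx")
        with pytest.raises(IOError):
            read_nifti(bad)

    def test_missing_file_raises_io_error(self, tmp_path):
        with pytest.raises(IOError):
            read_nifti(tmp_path / "nope.nii.gz")

    def test_nonfinite_image_rejected(self):
        geom = Geometry.unit((4, 4))
        data = np.zeros((4, 4))
        data[0, 0] = np.nan
        with pytest.raises(ValidationError):
            ImageVolume(data, geom)


class TestMask:
    def test_invert_is_complement(self):
        geom = Geometry.unit((5, 5))
        m = LesionMask(np.eye(5, dtype=int), geom)
        np.testing.assert_array_equal(m.invert().data, 1 - np.eye(5, dtype=int))
        np.testing.assert_array_equal(m.invert().invert().data, m.data)


class TestResample:
    def test_identity_transform_is_identity(self, phantom64):
        img, lab = phantom64
        ident = DiffeomorphicTransform.identity(img.geometry)
        np.testing.assert_allclose(
            resample(img, ident, interpolation="linear").data, img.data, atol=1e-9
        )
        np.testing.assert_array_equal(
            resample(lab, ident, interpolation="nearest").data, lab.data
        )

    def test_pure_translation_matches_integer_shift(self):
        rng = np.random.default_rng(4)
        geom = Geometry.unit((8, 8))
        img = LabelVolume(rng.integers(1, 9, (8, 8)), geom)
        # pull-back translation (3, -2): output(x) = input(x + (3, -2))
        out = resample(img, _translation((3.0, -2.0)), interpolation="nearest")
        expected = np.zeros((8, 8), dtype=int)
        expected[:5, 2:] = img.data[3:, :6]
        np.testing.assert_array_equal(out.data, expected)

    def test_labels_never_gain_new_values(self, phantom64):
        img, lab = phantom64
        data = np.where(lab.data == 1, 1, np.where(lab.data == 5, 5, 0))
        sparse = LabelVolume(data, lab.geometry)
        warp = make_synthetic_deformation(lab.geometry, 3, 8, seed=2)
        out = resample(sparse, warp, interpolation="nearest")
        assert out.label_ids <= {1, 5}

    def test_linear_interpolation_on_labels_rejected(self, phantom64):
        _, lab = phantom64
        ident = DiffeomorphicTransform.identity(lab.geometry)
        with pytest.raises(ValidationError):
            resample(lab, ident, interpolation="linear")

    def test_half_voxel_ties_round_to_lower_index(self):
        geom = Geometry.unit((4, 4))
        img = LabelVolume(np.arange(16).reshape(4, 4), geom)
        out = resample(img, _translation((0.5, 0.0)), interpolation="nearest")
        # sampling at x + 0.5 exactly: ties resolve toward the lower index
        np.testing.assert_array_equal(out.data[:3], img.data[:3])


class TestCompose:
    def test_identity_is_neutral_element(self, phantom64):
        img, _ = phantom64
        geom = img.geometry
        phi = make_synthetic_deformation(geom, 3, 8, seed=1)
        ident = DiffeomorphicTransform.identity(geom)
        pts = geom.grid_world()[8:-8:4, 8:-8:4]
        np.testing.assert_allclose(
            compose(phi, ident).map_points(pts), phi.map_points(pts), atol=1e-6
        )

    def test_translations_add(self):
        geom = Geometry.unit((16, 16))
        t1 = DiffeomorphicTransform.from_affine(_translation((2.0, 0.0)), geom)
        t2 = DiffeomorphicTransform.from_affine(_translation((0.0, 3.0)), geom)
        c = compose(t1, t2)
        pt = np.array([[5.0, 5.0]])
        np.testing.assert_allclose(c.map_points(pt) - pt, [[2.0, 3.0]], atol=1e-9)

    def test_phi_with_its_inverse_is_near_identity(self):
        geom = Geometry.unit((64, 64))
        phi = make_synthetic_deformation(geom, 4, 8, seed=6)
        phi_inv = DiffeomorphicTransform(phi.pre_affine, phi.inverse, phi.forward)
        c = compose(phi, phi_inv)
        mean_disp = c.forward.magnitude_voxels().mean()
        assert mean_disp < 0.5

    def test_resampling_equivalence(self, phantom64):
        """Resampling with the composition equals sequential resampling."""
        img, _ = phantom64
        geom = img.geometry
        a = make_synthetic_deformation(geom, 2, 10, seed=3)
        b = make_synthetic_deformation(geom, 2, 10, seed=4)
        two_step = resample(resample(img, a), b)
        one_step = resample(img, compose(b, a))
        core = (slice(8, -8), slice(8, -8))
        assert np.abs(two_step.data[core] - one_step.data[core]).mean() < 1.0


class TestAverageTransforms:
    def test_average_of_copies_is_that_transform(self):
        geom = Geometry.unit((32, 32))
        phi = make_synthetic_deformation(geom, 2, 8, seed=5)
        avg = average_transforms([phi, phi, phi])
        np.testing.assert_allclose(avg.forward.vectors, phi.forward.vectors, atol=1e-12)

    def test_field_and_negation_average_to_identity(self):
        geom = Geometry.unit((32, 32))
        u = np.random.default_rng(7).normal(size=(32, 32, 2))
        t1 = DiffeomorphicTransform(
            AffineTransform.identity(2),
            DisplacementField(u, geom),
            DisplacementField(-u, geom),
        )
        t2 = DiffeomorphicTransform(
            AffineTransform.identity(2),
            DisplacementField(-u, geom),
            DisplacementField(u, geom),
        )
        avg = average_transforms([t1, t2])
        np.testing.assert_allclose(avg.forward.vectors, 0.0, atol=1e-12)

    def test_translations_average_to_midpoint(self):
        geom = Geometry.unit((16, 16))
        t1 = DiffeomorphicTransform.from_affine(_translation((4.0, 0.0)), geom)
        t2 = DiffeomorphicTransform.from_affine(_translation((0.0, 2.0)), geom)
        avg = average_transforms([t1, t2])
        pt = np.array([[8.0, 8.0]])
        np.testing.assert_allclose(avg.map_points(pt) - pt, [[2.0, 1.0]], atol=1e-9)

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            average_transforms([])

    def test_mixed_geometries_rejected(self):
        a = DiffeomorphicTransform.identity(Geometry.unit((16, 16)))
        b = DiffeomorphicTransform.identity(Geometry.unit((8, 8)))
        with pytest.raises(GeometryError):
            average_transforms([a, b])


class TestTransformContracts:
    @pytest.mark.parametrize("seed", [1, 5, 9])
    def test_synthetic_warp_contracts(self, seed):
        """Positive Jacobian and inverse consistency for generated warps."""
        geom = Geometry.unit((64, 64))
        phi = make_synthetic_deformation(geom, 3, 8, seed=seed)
        det = jacobian_determinant(phi.forward)[1:-1, 1:-1]
        assert det.min() > 0
        assert inverse_consistency_voxels(phi) < 0.5

    def test_invert_displacement_round_trip(self):
        geom = Geometry.unit((48, 48))
        phi = make_synthetic_deformation(geom, 2, 8, seed=11)
        v = invert_displacement(phi.forward)
        # u then v should cancel
        from lesionorm.volumes import compose_displacements

        w = compose_displacements(phi.forward, v)
        assert DisplacementField(w.vectors, geom).magnitude_voxels().mean() < 0.1

    def test_zero_field_is_identity(self):
        geom = Geometry.unit((8, 8))
        t = DiffeomorphicTransform.identity(geom)
        pts = geom.grid_world()
        np.testing.assert_allclose(t.map_points(pts), pts, atol=1e-12)
        assert jacobian_determinant(t.forward).min() == pytest.approx(1.0)

    def test_rigid_kind_requires_rotation_block(self):
        mat = np.eye(3)
        mat[0, 0] = 2.0
        with pytest.raises(ValidationError):
            AffineTransform(mat, kind="rigid")
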