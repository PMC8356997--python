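"""Overlap metrics, information metrics, and the statistics layer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lesionorm.evaluation import (
    accuracy_difference,
    compare_dependent_correlations,
    entropy,
    jaccard,
    lesion_size,
    nmi,
    pairwise_overlap,
    size_dependence,
)
from lesionorm.lesion_sim import make_synthetic_deformation
from lesionorm.volumes import (
    DiffeomorphicTransform,
    Geometry,
    LabelVolume,
    LesionMask,
    ValidationError,
    resample,
)


class TestJaccard:
    def test_hand_counted_values(self):
        a = np.zeros(200, dtype=bool)
        b = np.zeros(200, dtype=bool)
        a[:60] = True
        b[30:90] = True  # |a|=|b|=60, overlap 30, union 90
        assert jaccard(a, b) == pytest.approx(30 / 90)
        assert jaccard(a, a) == 1.0
        assert jaccard(a[:50], ~a[:50]) == 0.0

    def test_both_empty_defined_as_one_with_warning(self):
        z = np.zeros(10, dtype=bool)
        with pytest.warns(UserWarning):
            assert jaccard(z, z) == 1.0

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**20 - 1), st.integers(0, 2**20 - 1))
    def test_symmetry_and_bounds(self, xa, xb):
        a = np.array([(xa >> i) & 1 for i in range(20)], dtype=bool)
        b = np.array([(xb >> i) & 1 for i in range(20)], dtype=bool)
        if not (a.any() or b.any()):
            return
        j1 = jaccard(a, b)
        assert j1 == jaccard(b, a)
        assert 0.0 <= j1 <= 1.0
        assert (j1 == 1.0) == bool((a == b).all())


class TestPairwiseOverlap:
    def test_identity_transforms_identical_labels(self, phantom64):
        _, lab = phantom64
        ident = DiffeomorphicTransform.identity(lab.geometry)
        rec = pairwise_overlap((lab, ident), (lab, ident))
        assert rec.mean_jaccard == pytest.approx(1.0)
        assert len(rec.per_label_jaccard) == 12

    def test_matches_single_interpolation_oracle(self, phantom64):
        """Two-step warp through the space agrees with composing the
        ground-truth maps directly (one interpolation)."""
        _, lab = phantom64
        geom = lab.geometry
        t_src = make_synthetic_deformation(geom, 2, 10, seed=31)
        t_tgt = make_synthetic_deformation(geom, 2, 10, seed=32)
        tgt_lab = resample(lab, t_tgt, interpolation="nearest", invert=True)

        rec = pairwise_overlap((lab, t_src), (tgt_lab, t_tgt))

        # oracle: map each target voxel through tgt, then src, sample once
        pts = geom.grid_world()
        mapped = t_src.map_points(t_tgt.map_points_inverse(pts))
        vox = geom.world_to_voxel(mapped)
        from lesionorm.volumes import _nearest_sample

        direct = _nearest_sample(lab.data, vox)
        ids = sorted(set(np.unique(direct)) | tgt_lab.label_ids)
        scores = [
            jaccard(direct == i, tgt_lab.data == i) for i in ids if i != 0
        ]
        assert rec.mean_jaccard == pytest.approx(float(np.mean(scores)), abs=0.02)

    def test_relabeling_invariance(self, phantom64):
        _, lab = phantom64
        ident = DiffeomorphicTransform.identity(lab.geometry)
        perm = np.zeros(13, dtype=int)
        perm[1:] = np.roll(np.arange(1, 13), 5)
        relabeled = LabelVolume(perm[lab.data], lab.geometry)
        r1 = pairwise_overlap((lab, ident), (lab, ident))
        r2 = pairwise_overlap((relabeled, ident), (relabeled, ident))
        assert r1.mean_jaccard == pytest.approx(r2.mean_jaccard)


class TestAccuracyDifference:
    def _rec(self, src, tgt, mj):
        from lesionorm.evaluation import OverlapRecord

        return OverlapRecord(src, tgt, {1: mj}, mj)

    def test_hand_difference(self):
        les = [self._rec("c0+l0", "c1+l0", 0.55)]
        gnd = [self._rec("c0", "c1", 0.60)]
        table = accuracy_difference(les, gnd).table
        assert table.abs_difference.iloc[0] == pytest.approx(0.05)

    def test_zero_when_scores_match(self):
        les = [self._rec("c0+l0", "c1+l0", 0.6)]
        gnd = [self._rec("c0", "c1", 0.6)]
        assert accuracy_difference(les, gnd).mean_abs_difference == 0.0

    def test_symmetric_in_score_order(self):
        a = accuracy_difference(
            [self._rec("c0+l0", "c1+l0", 0.7)], [self._rec("c0", "c1", 0.5)]
        ).mean_abs_difference
        b = accuracy_difference(
            [self._rec("c0+l0", "c1+l0", 0.5)], [self._rec("c0", "c1", 0.7)]
        ).mean_abs_difference
        assert a == b

    def test_unmatched_pair_rejected(self):
        with pytest.raises(ValidationError):
            accuracy_difference(
                [self._rec("c0+l0", "c9+l0", 0.5)], [self._rec("c0", "c1", 0.6)]
            )


class TestInformationMetrics:
    def test_entropy_uniform_bins(self):
        assert entropy(np.array([0.0, 0.0, 1.0, 1.0]), bins=2) == pytest.approx(1.0)
        assert entropy(np.array([0.0, 1.0, 2.0, 3.0]), bins=4) == pytest.approx(2.0)

    def test_entropy_constant_is_zero(self):
        assert entropy(np.full(100, 7.0), bins=8) == 0.0

    def test_nmi_identity_and_independence(self):
        rng = np.random.default_rng(1)
        a = rng.random((32, 32))
        assert nmi(a, a, bins=16) == pytest.approx(2.0)
        i1 = np.array([0.0, 0.0, 1.0, 1.0])
        i2 = np.array([0.0, 1.0, 0.0, 1.0])
        assert nmi(i1, i2, bins=2) == pytest.approx(1.0)

    def test_nmi_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.random((16, 16)), rng.random((16, 16))
        assert nmi(a, b, bins=8) == pytest.approx(nmi(b, a, bins=8))

    def test_nmi_degenerate_marginal_rejected(self):
        with pytest.raises(ValidationError):
            nmi(np.zeros((8, 8)), np.random.default_rng(0).random((8, 8)))

    def test_lesion_size_counts_voxels(self):
        g3 = Geometry.unit((10, 10, 10))
        assert lesion_size(LesionMask(np.ones((10, 10, 10), int), g3)) == 1000
        assert lesion_size(LesionMask(np.zeros((10, 10, 10), int), g3)) == 0


class TestSizeDependence:
    def test_exact_linear_relations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert size_dependence(x, x)["r"] == pytest.approx(1.0)
        assert size_dependence(-x + 10, x)["r"] == pytest.approx(-1.0)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(5)
        sizes = rng.uniform(100, 5000, 24)
        acc = 2.0 - 1e-4 * sizes + rng.normal(0, 0.05, 24)
        out = size_dependence(acc, sizes)
        n = len(sizes)
        sx, sy = sizes.sum(), acc.sum()
        sxx, syy, sxy = (sizes**2).sum(), (acc**2).sum(), (sizes * acc).sum()
        r_direct = (n * sxy - sx * sy) / np.sqrt(
            (n * sxx - sx**2) * (n * syy - sy**2)
        )
        assert out["r"] == pytest.approx(r_direct, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            size_dependence([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSteiger:
    def test_equal_correlations_give_zero(self):
        for r_kh in (0.0, 0.3, 0.8):
            assert compare_dependent_correlations(0.5, 0.5, r_kh, 50)["z"] == 0.0

    def test_sign_antisymmetry(self):
        z1 = compare_dependent_correlations(0.6, 0.3, 0.4, 50)["z"]
        z2 = compare_dependent_correlations(0.3, 0.6, 0.4, 50)["z"]
        assert z1 == pytest.approx(-z2)

    def test_one_sided_p_halves_two_sided_at_positive_z(self):
        two = compare_dependent_correlations(0.6, 0.3, 0.4, 50)
        one = compare_dependent_correlations(0.6, 0.3, 0.4, 50, one_sided=True)
        assert one["p"] == pytest.approx(two["p"] / 2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            compare_dependent_correlations(1.0, 0.5, 0.3, 50)
        with pytest.raises(ValidationError):
            compare_dependent_correlations(0.5, 0.4, 0.3, 3)
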