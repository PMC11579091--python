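"""Registration core: losses, transforms, warps, and both stages."""

import numpy as np
import pytest
import skimage.transform

from brainslide.core import PointSet
from brainslide.landmarks import LandmarkPairs
from brainslide.phantom import make_elastic_warp
from brainslide.register import (
    DisplacementField,
    RegistrationConfig,
    SimilarityTransform,
    affine_register,
    diffusion,
    elastic_register,
    invert_field,
    jacobian_map,
    landmark_term,
    ncc_loss,
    total_loss,
    warp_image,
    warp_points,
)


# ---------------------------------------------------------------------------
# similarity transform
# ---------------------------------------------------------------------------


class TestSimilarityTransform:
    def test_matches_skimage_similarity(self):
        """Point mapping agrees with an independent implementation."""
        t = SimilarityTransform(rotation=0.3, scale=1.2, translation=(4.0, -2.0))
        ref = skimage.transform.SimilarityTransform(
            rotation=0.3, scale=1.2, translation=(4.0, -2.0)
        )
        pts = np.array([[1.0, 2.0], [-3.0, 5.0], [0.0, 0.0]])
        np.testing.assert_allclose(t.apply(pts), ref(pts), atol=1e-12)

    def test_inverse_round_trip(self):
        t = SimilarityTransform(
            rotation=0.4, scale=0.8, reflection=True, translation=(3, -7), center=(10, 20)
        )
        pts = np.random.default_rng(0).uniform(-50, 50, (20, 2))
        back = t.inverse().apply(t.apply(pts))
        np.testing.assert_allclose(back, pts, atol=1e-10)

    def test_reflection_flips_orientation(self):
        t = SimilarityTransform(reflection=True)
        assert np.linalg.det(t.matrix) < 0

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            SimilarityTransform(scale=-1.0)


# ---------------------------------------------------------------------------
# loss terms
# ---------------------------------------------------------------------------


class TestNccLoss:
    def test_self_correlation_is_zero(self, textured):
        assert ncc_loss(textured, textured) == pytest.approx(0.0, abs=1e-12)

    def test_affine_intensity_invariance(self, textured):
        assert ncc_loss(textured, 0.3 * textured + 0.2) == pytest.approx(0.0, abs=1e-10)

    def test_contrast_inversion_gives_two(self, textured):
        assert ncc_loss(textured, -textured) == pytest.approx(2.0, abs=1e-10)

    def test_zero_variance_rejected(self, textured):
        with pytest.raises(ValueError, match="variance"):
            ncc_loss(textured, np.zeros_like(textured))

    def test_mask_restricts_support(self, textured):
        corrupted = textured.copy()
        corrupted[:20] = 0.5  # damage outside the mask
        mask = np.ones_like(textured, bool)
        mask[:20] = False
        assert ncc_loss(textured, corrupted, mask) == pytest.approx(0.0, abs=1e-12)


class TestDiffusion:
    def test_zero_field(self):
        assert diffusion(np.zeros((8, 8, 2))) == 0.0

    def test_constant_translation_free(self):
        u = np.broadcast_to(np.array([3.0, -2.0]), (8, 8, 2)).copy()
        assert diffusion(u) == 0.0

    def test_linear_field_matches_hand_computed_mean(self):
        """u = (x, 0) on a 4x4 grid against an explicit finite-difference sum."""
        ys, xs = np.mgrid[0:4, 0:4].astype(float)
        u = np.stack([xs, np.zeros_like(xs)], axis=2)
        # oracle: loop over every forward difference that exists
        sq = []
        for k in range(2):
            for y in range(4):
                for x in range(3):
                    sq.append((u[y, x + 1, k] - u[y, x, k]) ** 2)
            for y in range(3):
                for x in range(4):
                    sq.append((u[y + 1, x, k] - u[y, x, k]) ** 2)
        assert diffusion(u) == pytest.approx(sum(sq) / len(sq))


class TestLandmarkTerm:
    def test_aligned_pairs_zero(self):
        p = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert landmark_term(p, p) == 0.0

    def test_three_four_five(self):
        assert landmark_term([[0.0, 0.0]], [[3.0, 4.0]]) == pytest.approx(25.0)

    def test_two_pair_sum(self):
        assert landmark_term([[0, 0], [1, 1]], [[1, 0], [1, 3]]) == pytest.approx(5.0)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            landmark_term([[0, 0]], [[1, 1], [2, 2]])


class TestTotalLoss:
    def test_identity_on_identical_images(self, textured):
        t = SimilarityTransform.identity(textured.shape)
        lb = total_loss(textured, textured, t)
        assert lb.total == pytest.approx(0.0, abs=1e-9)

    def test_lambda2_zero_ignores_pairs(self, textured):
        t = SimilarityTransform.identity(textured.shape)
        pairs = LandmarkPairs(PointSet([[10.0, 10.0]]), PointSet([[40.0, 60.0]]))
        cfg0 = RegistrationConfig(lambda2=0.0)
        with_pairs = total_loss(textured, textured, t, pairs, cfg0)
        without = total_loss(textured, textured, t, None, cfg0)
        assert with_pairs.total == pytest.approx(without.total)

    def test_recomposition_identity(self, textured):
        """total always equals ncc + lambda1*df + lambda2*lrt recomputed."""
        cfg = RegistrationConfig()
        fld = make_elastic_warp(textured.shape, 5.0, seed=3)
        pairs = LandmarkPairs(
            PointSet([[30.0, 40.0], [60.0, 70.0]]), PointSet([[33.0, 41.0], [58.0, 69.0]])
        )
        lb = total_loss(textured, np.roll(textured, 3, axis=1), [fld], pairs, cfg)
        assert lb.total == pytest.approx(
            lb.ncc_term + cfg.lambda1 * lb.df_term + cfg.lambda2 * lb.lrt_term, abs=1e-12
        )
        assert lb.lrt_term == pytest.approx(lb.lrt_raw / 2)


# ---------------------------------------------------------------------------
# warps
# ---------------------------------------------------------------------------


class TestWarps:
    def test_identity_leaves_image_unchanged(self, textured):
        t = SimilarityTransform.identity(textured.shape)
        np.testing.assert_allclose(warp_image(textured, t), textured, atol=1e-12)

    def test_integer_translation_shifts_exactly(self, textured):
        t = SimilarityTransform(translation=(3.0, 0.0))
        w = warp_image(textured, t)
        np.testing.assert_allclose(w[:, 3:], textured[:, :-3], atol=1e-12)
        assert np.all(w[:, :3] == 0.0)  # zero fill

    def test_point_translation(self):
        t = SimilarityTransform(translation=(5.0, -3.0))
        np.testing.assert_allclose(warp_points([[0.0, 0.0]], t), [[5.0, -3.0]])

    def test_point_round_trip_similarity(self):
        t = SimilarityTransform(rotation=0.2, scale=1.1, translation=(5, -3), center=(50, 50))
        pts = np.random.default_rng(1).uniform(0, 100, (30, 2))
        back = warp_points(warp_points(pts, t), t.inverse())
        assert np.abs(back - pts).max() <= 0.1

    def test_field_inverse_consistency(self, textured):
        """Warping by a smooth field then by its exact inverse recovers the
        image to within interpolation error."""
        fld = make_elastic_warp(textured.shape, 6.0, seed=5)
        inv = DisplacementField(
            -fld.control_points, fld.spacing, fld.shape, True, fld.squaring_steps
        )
        twice = warp_image(warp_image(textured, fld), inv)
        assert np.abs(twice - textured).mean() <= 0.02

    def test_points_follow_field_forward_map(self, textured):
        fld = make_elastic_warp(textured.shape, 6.0, seed=5)
        pts = np.array([[40.0, 50.0], [70.0, 60.0]])
        moved = warp_points(pts, fld)
        back = warp_points(
            moved,
            DisplacementField(-fld.control_points, fld.spacing, fld.shape, True),
        )
        assert np.abs(back - pts).max() <= 0.15


class TestJacobian:
    def test_zero_field_unit_determinant(self):
        np.testing.assert_allclose(jacobian_map(np.zeros((16, 16, 2))), 1.0)

    def test_uniform_scaling_field(self):
        ys, xs = np.mgrid[0:32, 0:32].astype(float)
        u = 0.1 * np.stack([xs - 15.5, ys - 15.5], axis=2)
        j = jacobian_map(u)
        np.testing.assert_allclose(j[1:-1, 1:-1], 1.21, atol=1e-9)

    def test_generated_fields_positive(self):
        for seed in range(5):
            fld = make_elastic_warp((96, 96), 8.0, seed=seed)
            assert jacobian_map(fld).min() > 0

    def test_invert_field_fixed_point(self):
        fld = make_elastic_warp((96, 96), 5.0, seed=2)
        u = fld.dense()
        w = invert_field(u)
        np.testing.assert_allclose(
            np.abs(u + w).max(), 0.0, atol=1.5
        )  # coarse check: inverse roughly cancels
        resid = u + w
        assert np.abs(resid).mean() < 0.2


# ---------------------------------------------------------------------------
# affine stage
# ---------------------------------------------------------------------------


FAST = RegistrationConfig(iters=250, try_reflection=False)


class TestAffineRegister:
    def test_identity_recovery(self, textured):
        res = affine_register(textured, textured, FAST)
        assert res.final_loss <= 1e-3
        t = res.transform
        assert abs(np.rad2deg(t.rotation)) <= 0.5
        assert abs(t.scale - 1) <= 0.01
        assert np.hypot(*t.translation) <= 0.5

    def test_known_similarity_recovered(self, textured):
        truth = SimilarityTransform(
            rotation=np.deg2rad(10), scale=1.05, translation=(5, -3),
            center=((textured.shape[1] - 1) / 2, (textured.shape[0] - 1) / 2),
        )
        fixed = warp_image(textured, truth)
        res = affine_register(fixed, textured, RegistrationConfig(try_reflection=False))
        h, w = textured.shape
        corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], float)
        rms = np.sqrt(
            np.mean(
                np.sum(
                    (warp_points(corners, truth) - warp_points(corners, res.transform)) ** 2,
                    axis=1,
                )
            )
        )
        assert rms <= 1.0

    def test_mirrored_image_triggers_reflection(self, textured):
        mirrored = textured[:, ::-1].copy()
        res = affine_register(textured, mirrored, RegistrationConfig(iters=250))
        assert res.transform.reflection
        assert res.final_loss <= 0.05

    def test_loss_trace_decreases(self, textured):
        truth = SimilarityTransform(
            rotation=np.deg2rad(8), scale=1.02, translation=(4, 2),
            center=((textured.shape[1] - 1) / 2, (textured.shape[0] - 1) / 2),
        )
        fixed = warp_image(textured, truth)
        res = affine_register(fixed, textured, RegistrationConfig(try_reflection=False))
        trace = np.array(res.trace)
        assert np.median(trace[-100:]) <= np.median(trace[:100])


# ---------------------------------------------------------------------------
# elastic stage
# ---------------------------------------------------------------------------


class TestElasticRegister:
    def test_identical_images_near_zero_field(self, textured):
        res = elastic_register(textured, textured, cfg=FAST)
        assert np.abs(res.field.dense()).max() <= 0.5

    def test_jacobian_positive_contract(self, textured):
        fld = make_elastic_warp(textured.shape, 6.0, seed=9)
        fixed = warp_image(textured, fld)
        res = elastic_register(fixed, textured, cfg=RegistrationConfig(iters=400))
        assert jacobian_map(res.field).min() > 0

    def test_recovers_known_smooth_warp(self, textured):
        fld = make_elastic_warp(textured.shape, 6.0, seed=9)
        fixed = warp_image(textured, fld)
        res = elastic_register(fixed, textured, cfg=RegistrationConfig(iters=400))
        fg = textured > 0.2
        err = res.field.dense() - fld.dense()
        assert np.abs(err[fg]).mean() <= 1.0

    def test_trace_recomposition_and_decrease(self, textured):
        cfg = RegistrationConfig(iters=300, try_reflection=False)
        fld = make_elastic_warp(textured.shape, 5.0, seed=4)
        fixed = warp_image(textured, fld)
        pts = np.array([[40.0, 40.0], [80.0, 70.0], [60.0, 90.0]])
        pairs = LandmarkPairs(PointSet(pts), PointSet(warp_points(pts, fld)))
        res = elastic_register(fixed, textured, pairs=pairs, cfg=cfg)
        for lb in res.trace:
            assert lb.total == pytest.approx(
                lb.ncc_term + cfg.lambda1 * lb.df_term + cfg.lambda2 * lb.lrt_term, abs=1e-9
            )
        totals = [lb.total for lb in res.trace]
        assert np.median(totals[-100:]) <= np.median(totals[:100])

    def test_landmark_pull_moves_points_toward_targets(self, textured):
        """With identical images, a strong landmark term drags the field so
        the warped landmarks close most of the gap to their targets."""
        pts = np.array([[40.0, 40.0], [80.0, 80.0]])
        q = pts + np.array([5.0, 3.0])
        pairs = LandmarkPairs(PointSet(pts), PointSet(q))
        cfg = RegistrationConfig(iters=300, lambda1=0.0, lambda2=5.0)
        res = elastic_register(textured, textured, pairs=pairs, cfg=cfg)
        wp = warp_points(pts, res.field)
        assert np.all(np.linalg.norm(wp - q, axis=1) < np.linalg.norm(pts - q, axis=1) / 2)

    def test_landmark_term_improves_on_initial_value(self, textured):
        fld = make_elastic_warp(textured.shape, 6.0, seed=13)
        fixed = warp_image(textured, fld)
        pts = np.array([[40.0, 40.0], [80.0, 70.0], [60.0, 90.0]])
        pairs = LandmarkPairs(PointSet(pts), PointSet(warp_points(pts, fld)))
        init_lrt = landmark_term(pts, pairs.q.xy)
        res = elastic_register(fixed, textured, pairs=pairs, cfg=RegistrationConfig(iters=300))
        final_lrt = landmark_term(warp_points(pts, res.field), pairs.q.xy)
        assert final_lrt < init_lrt
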