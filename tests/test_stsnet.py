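"""Similarity network, block-NCC loss and the registration loop."""

import numpy as np
import pytest

from ablamark.imaging_core import GeometryError, ValidationError, Volume
from ablamark.stsnet_registration import (
    ConvFeaturePyramid,
    DegenerateFeatureError,
    FeatureBlocks,
    LandmarkSet,
    RegistrationConfig,
    block_ncc_loss,
    extract_features,
    landmark_error,
    register_pair,
    siamese_localize,
)

SMALL_CFG = dict(mode="3d", feature_levels=2, base_channels=4, block_partition=(2, 2, 2), seed=0)


def _fb(vectors):
    return FeatureBlocks([np.asarray(v, dtype=float) for v in vectors], {})


def eq2_oracle(Fw, Fa):
    """Direct per-block evaluation of the loss: -sum dot/sqrt(dot_w * dot_a)."""
    total = 0.0
    for w, a in zip(Fw, Fa):
        total += np.dot(w, a) / np.sqrt(np.dot(w, w) * np.dot(a, a))
    return -total


class TestBlockNCCLoss:
    def test_identical_blocks_give_minus_n(self):
        blocks = [np.array([1.0, 2.0, 3.0])] * 4
        assert block_ncc_loss(_fb(blocks), _fb(blocks)) == pytest.approx(-4.0)

    def test_orthogonal_blocks_give_zero(self):
        fw = _fb([[1.0, 0.0], [1.0, 0.0]])
        fa = _fb([[0.0, 1.0], [0.0, 1.0]])
        assert block_ncc_loss(fw, fa) == pytest.approx(0.0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            Fw = [rng.normal(size=6) for _ in range(8)]
            Fa = [rng.normal(size=6) for _ in range(8)]
            assert block_ncc_loss(_fb(Fw), _fb(Fa)) == pytest.approx(eq2_oracle(Fw, Fa), rel=1e-12)

    def test_lower_bound_minus_n(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(1, 6))
            Fw = [rng.normal(size=4) for _ in range(n)]
            Fa = [rng.normal(size=4) for _ in range(n)]
            assert block_ncc_loss(_fb(Fw), _fb(Fa)) >= -n - 1e-12

    def test_equality_iff_positively_proportional(self):
        Fw = [np.array([1.0, 2.0]), np.array([0.5, -1.0])]
        Fa = [3.0 * Fw[0], 0.25 * Fw[1]]
        assert block_ncc_loss(_fb(Fw), _fb(Fa)) == pytest.approx(-2.0)

    def test_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(2)
        Fw = [rng.normal(size=5) for _ in range(3)]
        Fa = [rng.normal(size=5) for _ in range(3)]
        base = block_ncc_loss(_fb(Fw), _fb(Fa))
        scaled = block_ncc_loss(_fb([7.3 * w for w in Fw]), _fb([0.01 * a for a in Fa]))
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_zero_norm_block_raises(self):
        fw = _fb([[0.0, 0.0], [1.0, 1.0]])
        fa = _fb([[1.0, 0.0], [1.0, 1.0]])
        with pytest.raises(DegenerateFeatureError):
            block_ncc_loss(fw, fa)

    def test_zero_norm_block_dropped_on_request(self):
        fw = _fb([[0.0, 0.0], [1.0, 1.0]])
        fa = _fb([[1.0, 0.0], [1.0, 1.0]])
        assert block_ncc_loss(fw, fa, drop_zero_blocks=True) == pytest.approx(-1.0)

    def test_mismatched_counts_rejected(self):
        with pytest.raises(ValidationError):
            block_ncc_loss(_fb([[1.0, 0.0]]), _fb([[1.0, 0.0], [0.0, 1.0]]))


class TestFeatureExtraction:
    def test_identical_images_identical_blocks(self, small_phantom):
        _, pair = small_phantom
        cfg = RegistrationConfig(**SMALL_CFG)
        fb1 = extract_features(pair.moving, cfg)
        fb2 = extract_features(Volume(pair.moving.data.copy(), pair.moving.spacing), cfg)
        for a, b in zip(fb1.blocks, fb2.blocks):
            np.testing.assert_array_equal(a, b)

    def test_single_block_partition(self, small_phantom):
        _, pair = small_phantom
        cfg = RegistrationConfig(**{**SMALL_CFG, "block_partition": (1, 1, 1)})
        assert extract_features(pair.moving, cfg).n_blocks == 1

    def test_image_too_small_for_pooling_depth(self):
        cfg = RegistrationConfig(mode="3d", feature_levels=5, seed=0)
        tiny = Volume(np.random.default_rng(0).random((8, 8, 8)))
        from ablamark.imaging_core import ConfigurationError

        with pytest.raises(ConfigurationError):
            extract_features(tiny, cfg)

    def test_translation_changes_features_less_than_noise(self, small_phantom):
        spec, pair = small_phantom
        cfg = RegistrationConfig(**SMALL_CFG)
        base = extract_features(pair.moving, cfg)
        shifted = extract_features(
            Volume(np.roll(pair.moving.data, 1, axis=2), spec.spacing), cfg
        )
        noise = extract_features(
            Volume(np.random.default_rng(0).random(pair.moving.shape), spec.spacing), cfg
        )
        d_shift = sum(np.linalg.norm(a - b) for a, b in zip(base.blocks, shifted.blocks))
        d_noise = sum(np.linalg.norm(a - b) for a, b in zip(base.blocks, noise.blocks))
        assert d_shift < d_noise

    def test_2d_mode_blocks_per_slice(self, small_phantom):
        _, pair = small_phantom
        cfg = RegistrationConfig(mode="2d", feature_levels=2, base_channels=4,
                                 block_partition=(2, 2), seed=0)
        fb = extract_features(pair.moving, cfg)
        assert fb.n_blocks == pair.moving.shape[0] * 4


class TestSiameseLocalize:
    def test_identical_inputs_fresh_head_gives_identity_field(self, small_phantom):
        _, pair = small_phantom
        cfg = RegistrationConfig(**SMALL_CFG)
        field = siamese_localize(pair.moving, pair.moving, cfg)
        assert np.all(field.control_grid == 0.0)

    def test_deterministic_given_seed(self, small_phantom):
        _, pair = small_phantom
        cfg = RegistrationConfig(**SMALL_CFG)
        f1 = siamese_localize(pair.moving, pair.fixed, cfg)
        f2 = siamese_localize(pair.moving, pair.fixed, cfg)
        np.testing.assert_array_equal(f1.control_grid, f2.control_grid)

    def test_swapped_inputs_run_and_stay_finite(self, small_phantom):
        _, pair = small_phantom
        cfg = RegistrationConfig(**SMALL_CFG)
        fwd = siamese_localize(pair.moving, pair.fixed, cfg)
        rev = siamese_localize(pair.fixed, pair.moving, cfg)
        assert np.all(np.isfinite(fwd.control_grid)) and np.all(np.isfinite(rev.control_grid))

    def test_geometry_mismatch_rejected(self, small_phantom):
        _, pair = small_phantom
        other = Volume(np.zeros((8, 8, 8)))
        with pytest.raises(GeometryError):
            siamese_localize(pair.moving, other, RegistrationConfig(**SMALL_CFG))


class TestRegisterPair:
    def test_already_aligned_pair_keeps_near_identity_field(self, small_phantom):
        _, pair = small_phantom
        cfg = RegistrationConfig(**SMALL_CFG, max_iters=10)
        res = register_pair(pair.moving, pair.moving, cfg)
        dense = res.field.materialize(pair.moving.shape)
        assert np.linalg.norm(dense, axis=-1).mean() < 0.1
        assert res.best_loss <= res.initial_loss + 1e-12

    def test_max_iters_one_gives_single_loss_evaluation(self, small_phantom):
        _, pair = small_phantom
        cfg = RegistrationConfig(**SMALL_CFG, max_iters=1)
        res = register_pair(pair.moving, pair.fixed, cfg)
        assert res.iterations_run == 1 and len(res.loss_trace) == 1

    def test_deterministic_loss_trace(self, small_phantom):
        _, pair = small_phantom
        cfg = RegistrationConfig(**SMALL_CFG, max_iters=6)
        t1 = register_pair(pair.moving, pair.fixed, cfg).loss_trace
        t2 = register_pair(pair.moving, pair.fixed, cfg).loss_trace
        assert t1 == t2

    def test_best_loss_never_exceeds_identity_loss(self, small_phantom):
        _, pair = small_phantom
        cfg = RegistrationConfig(**SMALL_CFG, max_iters=15)
        res = register_pair(pair.moving, pair.fixed, cfg)
        assert res.best_loss <= res.loss_trace[0]

    def test_phantom_recovery_reduces_landmark_error(self, small_phantom):
        spec, pair = small_phantom
        init = np.linalg.norm(pair.landmarks.fixed_mm - pair.landmarks.moving_mm, axis=1).mean()
        cfg = RegistrationConfig(**SMALL_CFG, max_iters=60, learning_rate=0.2)
        res = register_pair(pair.moving, pair.fixed, cfg)
        err = landmark_error(res.field, pair.landmarks, spec.spacing, shape=spec.shape)
        assert err.mean_mm < init

    def test_geometry_mismatch_rejected(self, small_phantom):
        _, pair = small_phantom
        with pytest.raises(GeometryError):
            register_pair(pair.moving, Volume(np.zeros((8, 8, 8))), RegistrationConfig(**SMALL_CFG))

    def test_joint_feature_adaptation_runs_and_descends(self, small_phantom):
        _, pair = small_phantom
        cfg = RegistrationConfig(**SMALL_CFG, max_iters=8, train_features=True)
        res = register_pair(pair.moving, pair.fixed, cfg)
        assert np.all(np.isfinite(res.loss_trace))
        assert res.best_loss <= res.loss_trace[0]

    def test_exclusion_mask_keeps_loss_descending(self, small_phantom):
        """Blanking the no-correspondence ablation zone still optimizes."""
        _, pair = small_phantom
        cfg = RegistrationConfig(**SMALL_CFG, max_iters=10)
        res = register_pair(pair.moving, pair.fixed, cfg, exclude=pair.ablation)
        assert np.all(np.isfinite(res.loss_trace))
        assert res.best_loss <= res.loss_trace[0]
        assert np.all(np.isfinite(res.field.materialize(pair.moving.shape)))

    def test_exclusion_mask_geometry_checked(self, small_phantom):
        from ablamark.imaging_core import Mask

        _, pair = small_phantom
        bad = Mask(np.zeros((4, 4, 4), dtype=np.uint8))
        with pytest.raises(GeometryError):
            register_pair(pair.moving, pair.fixed, RegistrationConfig(**SMALL_CFG), exclude=bad)

    def test_warped_has_fixed_geometry(self, small_phantom):
        _, pair = small_phantom
        cfg = RegistrationConfig(**SMALL_CFG, max_iters=2)
        res = register_pair(pair.moving, pair.fixed, cfg)
        assert res.warped.same_geometry(pair.fixed)


class TestFullGradient:
    def test_lattice_gradient_matches_finite_differences(self):
        """End-to-end analytic gradient (sampler -> conv stack -> NCC -> lattice)."""
        from ablamark.imaging_core import (
            dense_grad_to_lattice,
            interp_matrix,
            lattice_to_dense,
            n_control_points,
            sample_trilinear,
        )
        import ablamark.stsnet_registration as S

        rng = np.random.default_rng(0)
        shape = (8, 12, 12)
        mv, fx = rng.random(shape), rng.random(shape)
        cs = (4.0, 6.0, 6.0)
        nc = tuple(n_control_points(shape[a], cs[a]) for a in range(3))
        mats = tuple(
            interp_matrix(np.arange(shape[a], dtype=float), cs[a], nc[a]) for a in range(3)
        )
        net = ConvFeaturePyramid(3, 2, 4, 0)
        part = (2, 2, 2)
        featf, _ = net.forward(fx)
        fb = S._gather_blocks(featf, part, "flat")
        idz, idy, idx = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")

        def loss(theta):
            dense = lattice_to_dense(theta, mats)
            V = sample_trilinear(mv, idx + dense[..., 2], idy + dense[..., 1], idz + dense[..., 0])
            feats, _ = net.forward(V)
            sims, _, _, _ = S._ncc_terms(S._gather_blocks(feats, part, "flat"), fb, False)
            return -float(np.sum(sims))

        def grad(theta):
            dense = lattice_to_dense(theta, mats)
            V, gx, gy, gz = sample_trilinear(
                mv, idx + dense[..., 2], idy + dense[..., 1], idz + dense[..., 0], with_grad=True
            )
            feats, cache = net.forward(V)
            wb = S._gather_blocks(feats, part, "flat")
            _, gw, _, _ = S._ncc_terms(wb, fb, False)
            dimg = net.backward(S._scatter_block_grads([-g for g in gw], feats, part, "flat"), cache)
            dd = np.zeros(shape + (3,))
            dd[..., 2], dd[..., 1], dd[..., 0] = dimg * gx, dimg * gy, dimg * gz
            return dense_grad_to_lattice(dd, mats)

        theta = rng.normal(0, 0.3, nc + (3,))
        g = grad(theta)
        eps = 1e-5
        for _ in range(10):
            i = tuple(rng.integers(0, s) for s in g.shape)
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            fd = (loss(tp) - loss(tm)) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestLandmarkError:
    def test_identity_field_coincident_landmarks(self):
        f = np.zeros((4, 4, 4, 3))
        from ablamark.imaging_core import DisplacementField

        field = DisplacementField(None, spacing=(1, 1, 1), dense=f)
        lms = LandmarkSet(moving_mm=[[1, 1, 1]], fixed_mm=[[1, 1, 1]])
        err = landmark_error(field, lms, (1, 1, 1), shape=(4, 4, 4))
        assert err.mean_mm == 0.0

    def test_constant_offset_gives_analytic_mean_and_sd(self):
        from ablamark.imaging_core import DisplacementField

        field = DisplacementField(None, spacing=(1, 1, 1), dense=np.zeros((8, 8, 8, 3)))
        fixed = np.array([[2.0, 2.0, 2.0], [5.0, 5.0, 5.0]])
        moving = fixed + np.array([0.0, 3.0, 0.0])  # 3 mm offset along y
        err = landmark_error(field, LandmarkSet(moving, fixed), (1, 1, 1), shape=(8, 8, 8))
        assert err.mean_mm == pytest.approx(3.0)
        assert err.sd_mm == pytest.approx(0.0)

    def test_empty_landmark_set_rejected(self):
        with pytest.raises(ValidationError):
            LandmarkSet(moving_mm=np.zeros((0, 3)), fixed_mm=np.zeros((0, 3)))

    def test_truth_field_self_consistency(self, small_phantom):
        spec, pair = small_phantom
        err = landmark_error(pair.truth_field, pair.landmarks, spec.spacing, shape=spec.shape)
        half_diag = 0.5 * np.linalg.norm(spec.spacing)
        assert err.mean_mm < 0.5 * 2 * half_diag  # < half the voxel diagonal
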