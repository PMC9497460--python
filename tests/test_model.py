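"""Classifier construction, weighted loss, augmentation, LR schedule."""

import numpy as np
import pytest

import psmaseg as ps
from psmaseg import _nn
from psmaseg import model_train as mt


class TestBuildModel:
    def test_dense_prediction_shape_and_prob_sums(self, small_model):
        x = np.random.default_rng(0).random((2, 6, 8, 8, 8), dtype=np.float32)
        probs = small_model.predict_proba(x)
        assert probs.shape == (2, 4, 8, 8, 8)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_gives_identical_weights(self):
        cfg = ps.ModelConfig(base_filters=4)
        a = ps.build_model(cfg, seed=3)
        b = ps.build_model(cfg, seed=3)
        for (pa, _, _), (pb, _, _) in zip(a.param_grads(), b.param_grads()):
            np.testing.assert_array_equal(pa, pb)

    def test_incompatible_patch_size_rejected(self, small_model):
        x = np.zeros((1, 6, 10, 8, 8), dtype=np.float32)  # 10 not divisible by 4
        with pytest.raises(ps.ConfigurationError):
            small_model.predict_proba(x)

    def test_two_dropout_sites_active_only_in_training(self, small_model):
        x = np.random.default_rng(1).random((1, 6, 8, 8, 8), dtype=np.float32)
        assert small_model.n_dropout_sites == 2
        eval_a = small_model.predict_proba(x)
        eval_b = small_model.predict_proba(x)
        np.testing.assert_array_equal(eval_a, eval_b)
        rng = np.random.default_rng(2)
        train_logits = small_model._forward_impl(x, train=True, rng=rng)
        assert not np.array_equal(train_logits,
                                  small_model._forward_impl(x, False, None))

    def test_invalid_config_rejected(self):
        with pytest.raises(ps.ConfigurationError):
            ps.ModelConfig(n_classes=3)
        with pytest.raises(ps.ConfigurationError):
            ps.ModelConfig(dropout_rate=1.0)


class TestWeightedCce:
    def test_foreground_background_ratio_is_exactly_2_5(self):
        probs = np.full((4, 1, 1, 1), 0.5, dtype=np.float64)
        fg_loss, _ = ps.weighted_cce(probs, np.full((1, 1, 1), 3), 2.5)
        bg_loss, _ = ps.weighted_cce(probs, np.zeros((1, 1, 1), dtype=int), 2.5)
        assert fg_loss / bg_loss == pytest.approx(2.5, abs=1e-12)

    def test_perfect_prediction_gives_zero_loss(self):
        probs = np.zeros((4, 2, 2, 2))
        probs[1] = 1.0
        loss, per_voxel = ps.weighted_cce(probs, np.ones((2, 2, 2), dtype=int))
        assert loss == 0.0
        assert (per_voxel == 0.0).all()

    def test_hand_computed_two_voxel_example(self):
        # background voxel p_true=0.5, node voxel p_true=0.25
        probs = np.zeros((4, 2, 1, 1))
        probs[0, 0] = 0.5
        probs[2, 1] = 0.25
        probs[3] = 1.0 - probs[:3].sum(axis=0)
        targets = np.array([0, 2]).reshape(2, 1, 1)
        loss, _ = ps.weighted_cce(probs, targets, 2.5)
        expected = (1.0 * np.log(2) + 2.5 * np.log(4)) / 2
        assert loss == pytest.approx(expected, rel=1e-12)

    def test_fg_weight_one_matches_plain_cross_entropy(self):
        rng = np.random.default_rng(4)
        logits = rng.normal(size=(2, 4, 3, 3, 3))
        probs = _nn.softmax(logits, axis=1)
        targets = rng.integers(0, 4, size=(2, 3, 3, 3))
        loss, _ = ps.weighted_cce(probs, targets, fg_weight=1.0)
        p_true = np.take_along_axis(probs, targets[:, None], axis=1)[:, 0]
        plain = float(-np.log(p_true).mean())
        assert loss == pytest.approx(plain, abs=1e-10)

    def test_zero_probability_clamped_not_infinite(self):
        probs = np.zeros((4, 1, 1, 1))
        probs[0] = 1.0  # true class 2 has probability 0
        loss, _ = ps.weighted_cce(probs, np.full((1, 1, 1), 2))
        assert np.isfinite(loss)
        assert loss == pytest.approx(2.5 * -np.log(1e-7))

    def test_loss_map_feeds_sampler_grid(self, prep_study):
        probs = np.full((4, *prep_study.grid_shape), 0.25)
        _, per_voxel = ps.weighted_cce(probs, prep_study.labels.data)
        mask = ps.update_sample_mask(
            ps.init_sample_mask(prep_study.labels),
            ps.LossMap(per_voxel),
        )
        assert mask.weights.shape == prep_study.grid_shape


class TestBackprop:
    def test_gradients_match_finite_differences(self):
        cfg = ps.ModelConfig(n_input_channels=2, base_filters=2,
                             encoder_depth=1, dropout_rate=0.0)
        model = ps.build_model(cfg, seed=1).astype(np.float64)
        rng = np.random.default_rng(2)
        x = rng.random((1, 2, 4, 4, 4))
        y = rng.integers(0, 4, (1, 4, 4, 4))

        def loss_of():
            probs = _nn.softmax(model._forward_impl(x, False, None), axis=1)
            return ps.weighted_cce(probs, y)[0]

        probs = _nn.softmax(model._forward_impl(x, False, None), axis=1)
        model.backward(mt.weighted_cce_grad(probs, y))
        worst = 0.0
        for p, g, _ in model.param_grads():
            flat, gflat = p.ravel(), g.ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                eps, old = 1e-6, flat[i]
                flat[i] = old + eps
                up = loss_of()
                flat[i] = old - eps
                down = loss_of()
                flat[i] = old
                numeric = (up - down) / (2 * eps)
                scale = max(abs(numeric), abs(gflat[i]), 1e-8)
                worst = max(worst, abs(numeric - gflat[i]) / scale)
        assert worst < 1e-5


class TestAugmentation:
    def _patch(self, fill=0.5, size=(8, 8, 8)):
        channels = np.full((6, *size), fill, dtype=np.float32)
        target = np.zeros(size, dtype=np.int16)
        target[3:5, 3:5, 3:5] = 2
        return ps.Patch(channels, target, tuple(s // 2 for s in size), size)

    def test_collapsed_ranges_are_identity(self):
        spec = ps.AugmentationSpec((0, 0), (0, 0), (0, 0), (0, 0))
        patch = self._patch()
        out = ps.augment_patch(patch, spec, seed=9)
        np.testing.assert_array_equal(out.channels, patch.channels)
        np.testing.assert_array_equal(out.target, patch.target)

    def test_ct_shift_maps_through_normalisation_window(self):
        # geometric ranges collapsed; only the CT shift is active
        spec = ps.AugmentationSpec((0, 0), (0, 0), (0, 0), (-100, 100))
        seed = 13
        rng = np.random.default_rng(seed)
        rng.uniform(0, 0)  # scale draw
        rng.uniform(0, 0)  # rotation draw
        rng.uniform(0, 0)  # pet draw
        hu = rng.uniform(-100, 100)
        patch = self._patch(fill=0.5)
        out = ps.augment_patch(patch, spec, seed=seed)
        expected = np.clip(0.5 + hu / 1600.0, 0.0, 1.0)
        np.testing.assert_allclose(out.channels[0], expected, rtol=1e-6)
        # a +100 HU shift on a pre-normalisation 0 HU voxel gives 0.5625
        assert (0.0 + 800.0 + 100.0) / 1600.0 == pytest.approx(0.5625)

    def test_rotation_introduces_no_new_label_codes(self):
        spec = ps.AugmentationSpec((-0.1, 0.1), (-0.15, 0.15), (0, 0), (0, 0))
        patch = self._patch()
        out = ps.augment_patch(patch, spec, seed=3)
        assert set(np.unique(out.target)) <= set(np.unique(patch.target))
        # organ channels stay binary under nearest-neighbour transform
        patch.channels[2:] = (patch.channels[2:] > 0.4).astype(np.float32)
        out2 = ps.augment_patch(patch, spec, seed=4)
        assert set(np.unique(out2.channels[2:])) <= {0.0, 1.0}

    def test_deterministic_given_seed(self):
        spec = ps.AugmentationSpec()
        patch = self._patch()
        a = ps.augment_patch(patch, spec, seed=5)
        b = ps.augment_patch(patch, spec, seed=5)
        np.testing.assert_array_equal(a.channels, b.channels)

    def test_asymmetric_range_rejected(self):
        with pytest.raises(ps.ValidationError):
            ps.AugmentationSpec(scale_range=(-0.1, 0.2))


class TestLrSchedule:
    def test_strictly_decreasing_loss_keeps_lr_constant(self):
        sched = ps.ValLossHalver(0.001, patience=5)
        lrs = [sched.step(loss) for loss in np.linspace(1.0, 0.1, 12)]
        assert all(lr == 0.001 for lr in lrs)

    def test_five_flat_epochs_halve_lr(self):
        sched = ps.ValLossHalver(0.001, patience=5)
        sched.step(1.0)  # first epoch sets the best
        lrs = [sched.step(1.0) for _ in range(5)]
        assert lrs[:4] == [0.001] * 4
        assert lrs[4] == pytest.approx(0.0005)

    def test_improvement_resets_patience(self):
        sched = ps.ValLossHalver(0.001, patience=3)
        for loss in (1.0, 1.0, 1.0, 0.9, 1.0, 1.0):
            lr = sched.step(loss)
        assert lr == 0.001  # never 3 consecutive bad epochs
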