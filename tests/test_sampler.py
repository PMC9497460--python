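"""Sample-mask initialisation, patch drawing/extraction, adaptive update."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import psmaseg as ps
from psmaseg.sampler import _extract_window

from _oracles import mirror_window


def labelmap_1d(values) -> ps.LabelMap:
    return ps.LabelMap(np.asarray(values, dtype=np.int16).reshape(-1, 1, 1),
                       (1.0, 1.0, 1.0))


class TestInitSampleMask:
    def test_half_background_split_among_present_classes(self):
        # 100 background, 10 prostate, 5 bone, no node
        data = [0] * 100 + [1] * 10 + [3] * 5
        mask = ps.init_sample_mask(labelmap_1d(data))
        w = mask.weights.ravel()
        np.testing.assert_allclose(w[:100], 0.005)
        np.testing.assert_allclose(w[100:110], 0.025)
        np.testing.assert_allclose(w[110:], 0.05)
        assert w.sum() == pytest.approx(1.0)

    def test_all_background_falls_back_to_uniform(self):
        mask = ps.init_sample_mask(labelmap_1d([0] * 50))
        np.testing.assert_allclose(mask.weights, 1.0 / 50)

    def test_three_classes_each_sum_to_one_sixth(self):
        data = [0] * 40 + [1] * 4 + [2] * 8 + [3] * 2
        lm = labelmap_1d(data)
        mask = ps.init_sample_mask(lm)
        for c in (1, 2, 3):
            class_sum = mask.weights.ravel()[np.asarray(data) == c].sum()
            assert class_sum == pytest.approx(1.0 / 6)

    def test_empty_grid_rejected(self):
        with pytest.raises(Exception):
            ps.init_sample_mask(
                ps.LabelMap(np.zeros((0, 1, 1), dtype=np.int16), (1, 1, 1))
            )


class TestDrawPatchCentres:
    def test_degenerate_mask_always_hits_its_voxel(self):
        w = np.zeros((4, 4, 4))
        w[1, 2, 3] = 1.0
        centres = ps.draw_patch_centres(ps.SampleMask(w), 50, seed=0)
        assert (centres == [1, 2, 3]).all()

    def test_uniform_two_voxel_frequencies(self):
        w = np.zeros((2, 1, 1))
        w[:] = 0.5
        centres = ps.draw_patch_centres(ps.SampleMask(w), 10_000, seed=1)
        freq = (centres[:, 0] == 0).mean()
        assert 0.48 <= freq <= 0.52

    def test_background_centre_fraction_near_half(self, tiny_study):
        mask = ps.init_sample_mask(tiny_study.labels)
        centres = ps.draw_patch_centres(mask, 10_000, seed=2)
        labels_at = tiny_study.labels.data[tuple(centres.T)]
        bg_fraction = (labels_at == 0).mean()
        assert abs(bg_fraction - 0.5) <= 0.0129  # 99% binomial interval

    def test_empirical_frequencies_match_weights_chisquare(self):
        rng = np.random.default_rng(3)
        w = rng.random((100, 1, 1)) + 0.05
        mask = ps.SampleMask(w)
        centres = ps.draw_patch_centres(mask, 50_000, seed=4)
        observed = np.bincount(centres[:, 0], minlength=100)
        expected = mask.weights.ravel() * 50_000
        _, p = stats.chisquare(observed, expected)
        assert p > 0.01

    def test_n_below_one_rejected(self):
        mask = ps.SampleMask(np.ones((2, 2, 2)))
        with pytest.raises(ValueError):
            ps.draw_patch_centres(mask, 0)


class TestExtractPatch:
    def test_interior_patch_equals_direct_slice(self, prep_study):
        patch = ps.extract_patch(prep_study, (16, 16, 16), (8, 8, 8))
        stacked = ps.stack_input_channels(prep_study)
        np.testing.assert_array_equal(
            patch.channels, stacked[:, 12:20, 12:20, 12:20]
        )
        np.testing.assert_array_equal(
            patch.target, prep_study.labels.data[12:20, 12:20, 12:20]
        )

    def test_corner_patch_matches_mirror_oracle(self, prep_study):
        size = (6, 6, 6)
        patch = ps.extract_patch(prep_study, (0, 0, 0), size)
        pet = prep_study.pet.data
        starts = (-3, -3, -3)
        expected = mirror_window(pet, starts, size)
        np.testing.assert_allclose(patch.channels[1], expected)

    def test_full_volume_patch_equals_volume(self, prep_study):
        shape = prep_study.grid_shape
        centre = tuple(s // 2 for s in shape)
        patch = ps.extract_patch(prep_study, centre, shape)
        np.testing.assert_array_equal(
            patch.channels, ps.stack_input_channels(prep_study)
        )

    def test_oversized_patch_rejected(self, prep_study):
        with pytest.raises(ValueError):
            ps.extract_patch(prep_study, (0, 0, 0), (100, 8, 8))

    def test_window_helper_matches_oracle_on_random_offsets(self):
        rng = np.random.default_rng(5)
        arr = rng.random((7, 6, 5))
        for _ in range(10):
            starts = [int(rng.integers(-3, 4)) for _ in range(3)]
            size = (5, 4, 3)
            centre = [st + sz // 2 for st, sz in zip(starts, size)]
            got = _extract_window(arr, centre, size)
            np.testing.assert_allclose(got, mirror_window(arr, starts, size))


class TestMaskUpdate:
    def test_scalar_example(self):
        w = np.array([1.0, 1.0, 1.0])
        l = np.array([1.0, 2.0, 4.0])
        np.testing.assert_allclose(ps.eq1_update(w, l), [0.625, 0.75, 1.0])

    def test_uniform_mask_fixed_point_under_constant_loss(self):
        w = np.full((4, 4, 4), 1.0 / 64)
        loss = ps.LossMap(np.full((4, 4, 4), 3.7))
        updated = ps.update_sample_mask(ps.SampleMask(w), loss)
        np.testing.assert_allclose(updated.weights, w)

    def test_vectorised_equals_scalar_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            w = rng.random((8, 8, 8))
            l = rng.random((8, 8, 8))
            expected = np.empty_like(w)
            wmax, lmax = w.max(), l.max()
            for idx in np.ndindex(w.shape):
                expected[idx] = 0.5 * w[idx] + 0.5 * (wmax / lmax) * l[idx]
            np.testing.assert_allclose(ps.eq1_update(w, l), expected,
                                       atol=1e-12, rtol=0)

    def test_order_preserving_in_loss(self):
        w = np.full(5, 0.2)
        l = np.array([0.1, 0.5, 0.2, 0.9, 0.3])
        w2 = ps.eq1_update(w, l)
        assert (np.argsort(w2) == np.argsort(l)).all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0.1, 100.0))
    def test_covariant_under_uniform_weight_scaling(self, c):
        rng = np.random.default_rng(7)
        w = rng.random((3, 3, 3)) + 0.01
        l = rng.random((3, 3, 3))
        np.testing.assert_allclose(ps.eq1_update(c * w, l), c * ps.eq1_update(w, l),
                                   rtol=1e-10)

    def test_zero_loss_leaves_mask_unchanged(self):
        mask = ps.SampleMask(np.ones((3, 3, 3)))
        out = ps.update_sample_mask(mask, ps.LossMap(np.zeros((3, 3, 3))))
        np.testing.assert_array_equal(out.weights, mask.weights)

    def test_grid_mismatch_rejected(self):
        mask = ps.SampleMask(np.ones((3, 3, 3)))
        with pytest.raises(ps.AlignmentError):
            ps.update_sample_mask(mask, ps.LossMap(np.ones((4, 3, 3))))

    def test_mask_normalised_after_update(self):
        rng = np.random.default_rng(8)
        mask = ps.SampleMask(rng.random((5, 5, 5)))
        out = ps.update_sample_mask(mask, ps.LossMap(rng.random((5, 5, 5))))
        assert out.weights.sum() == pytest.approx(1.0)
        assert (out.weights >= 0).all()


@pytest.fixture(scope="module")
def flat_cohort():
    studies = [
        ps.preprocess_study(ps.generate_study(
            ps.PhantomSpec(grid_shape=(16, 16, 16),
                           lesions_per_class=(0, 0, 0),
                           n_unspecific_bone_foci=0, seed=21 + i),
            study_id=f"s{i}"))
        for i in range(10)
    ]
    cfg = ps.ModelConfig(n_input_channels=6, encoder_depth=1, base_filters=2)
    model = ps.build_model(cfg, seed=0)
    return studies, model


class TestRefreshMasks:
    def _masks(self, studies):
        return {s.study_id: ps.init_sample_mask(s.labels, s.study_id)
                for s in studies}

    def test_fraction_zero_changes_nothing(self, flat_cohort):
        studies, model = flat_cohort
        masks = self._masks(studies)
        before = {k: m.weights.copy() for k, m in masks.items()}
        ps.refresh_masks(studies, masks, model, fraction=0.0, seed=0)
        for k in masks:
            np.testing.assert_array_equal(masks[k].weights, before[k])

    def test_fraction_one_updates_all(self, flat_cohort):
        studies, model = flat_cohort
        masks = self._masks(studies[:4])
        before = {k: m.weights.copy() for k, m in masks.items()}
        ps.refresh_masks(studies[:4], masks, model, fraction=1.0, seed=0)
        changed = [not np.array_equal(masks[k].weights, before[k]) for k in masks]
        assert all(changed)

    def test_half_fraction_selects_exactly_half_reproducibly(self, flat_cohort):
        studies, model = flat_cohort
        masks_a = self._masks(studies)
        before = {k: m.weights.copy() for k, m in masks_a.items()}
        ps.refresh_masks(studies, masks_a, model, fraction=0.5, seed=42)
        changed_a = {k for k in masks_a
                     if not np.array_equal(masks_a[k].weights, before[k])}
        assert len(changed_a) == 5
        masks_b = self._masks(studies)
        ps.refresh_masks(studies, masks_b, model, fraction=0.5, seed=42)
        changed_b = {k for k in masks_b
                     if not np.array_equal(masks_b[k].weights, before[k])}
        assert changed_a == changed_b

    def test_empty_study_list_rejected(self, flat_cohort):
        _, model = flat_cohort
        with pytest.raises(ValueError):
            ps.refresh_masks([], {}, model)
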