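"""Affine matrix closed forms, resampling contracts, preprocessing."""

import math

import numpy as np
import pytest

from acnedx import augment as aug
from acnedx import synthetic as syn


def _apply_point(m, point):
    x = m @ np.array([point[0], point[1], 1.0])
    return x[:2]


CENTER = np.array([25.5, 25.5])  # (h+1)/2 for h = w = 50


class TestMatrices:
    def test_all_matrices_reduce_to_identity_at_neutral_parameters(self):
        eye = np.eye(3)
        assert np.allclose(aug.rotation_matrix(0.0, 50, 50), eye)
        assert np.allclose(aug.shift_matrix(0.0, 0.0), eye)
        assert np.allclose(aug.shear_matrix(0.0, 50, 50), eye)
        assert np.allclose(aug.zoom_matrix(1.0, 1.0, 50, 50), eye)

    def test_half_turn_rotation_matrix_closed_form(self):
        m = aug.rotation_matrix(math.pi, 50, 50)
        expected = np.array([[-1.0, 0.0, 51.0],
                             [0.0, -1.0, 51.0],
                             [0.0, 0.0, 1.0]])
        assert np.allclose(m, expected, atol=1e-9)

    def test_center_is_fixed_point_of_rotation_shear_zoom(self):
        rng = np.random.default_rng(100)
        for _ in range(100):
            theta = rng.uniform(-math.pi, math.pi)
            shear = rng.uniform(-1.2, 1.2)
            zx, zy = rng.uniform(0.2, 3.0, 2)
            for m in (aug.rotation_matrix(theta, 50, 50),
                      aug.shear_matrix(shear, 50, 50),
                      aug.zoom_matrix(zx, zy, 50, 50)):
                assert np.abs(_apply_point(m, CENTER) - CENTER).max() < 1e-9

    def test_shift_matrix_translates_and_composes_additively(self):
        assert np.allclose(_apply_point(aug.shift_matrix(3, -2), (10, 10)),
                           (13, 8))
        ab = aug.shift_matrix(1.5, -4) @ aug.shift_matrix(2.5, 7)
        assert np.allclose(ab, aug.shift_matrix(4.0, 3.0))

    def test_shear_acts_as_linear_map_on_centered_coordinates(self):
        s = 0.2
        m = aug.shear_matrix(s, 50, 50)
        lin = np.array([[1.0, -math.sin(s)], [0.0, math.cos(s)]])
        rng = np.random.default_rng(0)
        for _ in range(20):
            d = rng.uniform(-20, 20, 2)
            expected = CENTER + lin @ d
            assert np.allclose(_apply_point(m, CENTER + d), expected,
                               atol=1e-12)

    def test_zoom_doubles_centered_offsets(self):
        m = aug.zoom_matrix(2.0, 2.0, 50, 50)
        got = _apply_point(m, CENTER + np.array([3.0, -4.0]))
        assert np.allclose(got, CENTER + np.array([6.0, -8.0]))

    @pytest.mark.parametrize("call", [
        lambda: aug.rotation_matrix(math.nan, 50, 50),
        lambda: aug.shear_matrix(math.pi / 2, 50, 50),
        lambda: aug.zoom_matrix(0.0, 1.0, 50, 50),
        lambda: aug.shift_matrix(math.inf, 0.0),
    ])
    def test_invalid_parameters_rejected(self, call):
        with pytest.raises(ValueError):
            call()


class TestResampling:
    def test_identity_matrix_preserves_image_exactly(self):
        img = syn.gen_patch("c0", np.random.default_rng(1)).pixels
        out = aug.apply_transform(img, np.eye(3))
        assert np.array_equal(out, img)

    def test_constant_image_is_invariant_under_centered_transform(self):
        img = np.full((50, 50, 3), 77, dtype=np.uint8)
        m = aug.rotation_matrix(0.7, 50, 50)
        assert np.array_equal(aug.apply_transform(img, m), img)

    def test_horizontal_flip_is_an_involution(self):
        img = syn.gen_patch("c2", np.random.default_rng(4)).pixels
        assert np.array_equal(aug.hflip(aug.hflip(img)), img)

    def test_singular_matrix_rejected(self):
        m = np.eye(3)
        m[0, 0] = 0.0
        with pytest.raises(ValueError):
            aug.apply_transform(np.zeros((50, 50, 3), np.uint8), m)

    def test_inverse_roundtrip_on_smooth_image_loses_little(self):
        # low-frequency sinusoid: bilinear interpolation loss must stay
        # below 2 intensity units in mean absolute error
        yy, xx = np.mgrid[0:50, 0:50]
        field = 128 + 60 * np.sin(2 * np.pi * yy / 50) * np.cos(
            2 * np.pi * xx / 50)
        img = np.repeat(field[:, :, None], 3, axis=2).astype(np.uint8)
        m = aug.rotation_matrix(0.3, 50, 50)
        back = aug.apply_transform(aug.apply_transform(img, m),
                                   np.linalg.inv(m))
        mae = np.abs(back.astype(float) - img.astype(float)).mean()
        assert mae <= 2.0


class TestRandomAugment:
    def test_degenerate_config_is_identity(self):
        cfg = aug.AugmentConfig(theta_range=(0, 0), shift_range=(0, 0),
                                shear_range=(0, 0), zoom_range=(1, 1),
                                flip_prob=0.0)
        img = syn.gen_patch("c4", np.random.default_rng(2)).pixels
        out = aug.random_augment(img, cfg, np.random.default_rng(0))
        assert np.array_equal(out, img)

    def test_same_rng_state_gives_identical_output(self):
        img = syn.gen_patch("c1", np.random.default_rng(5)).pixels
        cfg = aug.AugmentConfig()
        a = aug.random_augment(img, cfg, np.random.default_rng(9))
        b = aug.random_augment(img, cfg, np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_output_shape_matches_input_over_many_draws(self):
        img = syn.gen_patch("c3", np.random.default_rng(6)).pixels
        cfg = aug.AugmentConfig()
        rng = np.random.default_rng(1)
        for _ in range(100):
            assert aug.random_augment(img, cfg, rng).shape == img.shape


class TestAugmentToTarget:
    def test_pads_classes_and_keeps_originals_first(self):
        pset = syn.gen_patchset(10, ("skin", "non_skin"), 3)
        out = aug.augment_to_target(pset, 30, aug.AugmentConfig(), seed=0)
        assert len(out) == 60
        assert (out.class_counts() == 30).all()
        # originals of class 0 are retained, unchanged, at the front
        assert np.array_equal(out.pixels[:10], pset.pixels[:10])

    def test_target_below_count_is_a_noop(self):
        pset = syn.gen_patchset(10, ("skin", "non_skin"), 3)
        out = aug.augment_to_target(pset, 5, aug.AugmentConfig(), seed=0)
        assert len(out) == len(pset)
        assert np.array_equal(out.pixels, pset.pixels)

    def test_empty_class_rejected(self):
        pset = syn.gen_patchset(2, ("skin", "non_skin"), 3)
        bad = syn.PatchSet(pset.pixels[:2], pset.labels[:2],
                           pset.class_names)
        with pytest.raises(ValueError):
            aug.augment_to_target(bad, 4, aug.AugmentConfig(), seed=0)


class TestPreprocess:
    def test_rescale_endpoints(self):
        img = np.array([[[0, 255, 128]]], dtype=np.uint8)
        out = aug.preprocess(img, aug.PreprocSpec(mode="rescale_01"))
        assert out[0, 0, 0] == 0.0 and out[0, 0, 1] == 1.0

    def test_standardize_maps_mean_to_zero(self):
        spec = aug.PreprocSpec(mode="standardize", mean=183.643, std=38.210)
        out = aug.preprocess(np.array([[[183.643]]]), spec)
        assert abs(out[0, 0, 0]) < 1e-5

    def test_self_standardized_set_has_zero_mean_unit_sd(self):
        pixels = syn.gen_patchset(20, ("skin", "non_skin"), 8).pixels
        spec = aug.fit_standardizer(pixels)
        out = aug.preprocess(pixels, spec).astype(np.float64)
        assert abs(out.mean()) < 1e-6
        assert abs(out.std() - 1.0) < 1e-6

    def test_invalid_std_rejected(self):
        with pytest.raises(ValueError):
            aug.PreprocSpec(mode="standardize", mean=0.0, std=0.0)
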