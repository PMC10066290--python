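import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from fangmark import preprocess as pp


def _uniform_image(value, shape=(8, 8, 3)):
    return np.full(shape, value, dtype=np.float64)


class TestBrightnessTransform:
    def test_identity_at_ratio_one(self, cobra_image):
        out = pp.brightness_transform(cobra_image.pixels, 1.0)
        np.testing.assert_allclose(out, cobra_image.pixels, atol=1e-12)

    def test_black_fixed_point(self):
        out = pp.brightness_transform(_uniform_image(0.0), 3.0)
        np.testing.assert_array_equal(out, 0.0)

    def test_uniform_half_at_ratio_two(self):
        # hand evaluation of the camera-model transform at a single pixel
        a, b = pp.BTF_A, pp.BTF_B
        expected = np.exp(b * (1 - 2 ** a)) * 0.5 ** (2 ** a)
        out = pp.brightness_transform(_uniform_image(0.5), 2.0)
        np.testing.assert_allclose(out, min(expected, 1.0), rtol=1e-12)

    def test_rejects_nonpositive_ratio(self):
        with pytest.raises(pp.PreprocessError, match="exposure ratio"):
            pp.brightness_transform(_uniform_image(0.5), 0.0)

    def test_monotone_in_input(self):
        lo = pp.brightness_transform(_uniform_image(0.2), 4.0)
        hi = pp.brightness_transform(_uniform_image(0.6), 4.0)
        assert np.all(hi >= lo)

    @given(k=st.floats(min_value=0.1, max_value=10.0),
           v=st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=50, deadline=None)
    def test_range_preserved(self, k, v):
        out = pp.brightness_transform(_uniform_image(v), k)
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestEstimateWeightMap:
    def test_white_gives_ones(self):
        w = pp.estimate_weight_map(_uniform_image(1.0), mu=0.5)
        np.testing.assert_array_equal(w, 1.0)

    def test_black_gives_zeros(self):
        w = pp.estimate_weight_map(_uniform_image(0.0), mu=0.5)
        np.testing.assert_array_equal(w, 0.0)

    def test_single_pixel_hand_value(self):
        img = np.array([[[0.25, 0.16, 0.04]]])
        w = pp.estimate_weight_map(img, mu=0.5)
        np.testing.assert_allclose(w, [[0.5]])  # max=0.25, sqrt -> 0.5

    def test_invalid_mu(self):
        with pytest.raises(pp.PreprocessError):
            pp.estimate_weight_map(_uniform_image(0.5), mu=0.0)


class TestFindExposureRatio:
    def test_well_exposed_returns_smallest(self):
        ratio = pp.find_exposure_ratio(_uniform_image(0.9), grid=(1.5, 3.0, 6.0))
        assert ratio == 1.5

    def test_single_candidate_forced(self):
        ratio = pp.find_exposure_ratio(_uniform_image(0.1), grid=(4.0,))
        assert ratio == 4.0

    def test_empty_grid(self):
        with pytest.raises(pp.PreprocessError, match="empty"):
            pp.find_exposure_ratio(_uniform_image(0.1), grid=())

    def test_matches_exhaustive_grid_search(self):
        # independent brute force over the candidates on a half-black /
        # half-gray fixture
        rng = np.random.default_rng(3)
        img = np.concatenate([
            np.full((4, 8, 3), 0.02) + rng.uniform(0, 0.02, (4, 8, 3)),
            np.full((4, 8, 3), 0.35) + rng.uniform(0, 0.05, (4, 8, 3))])
        grid = (1.5, 3.0, 6.0)

        illum = img.max(axis=2)
        dark = np.sqrt(illum) < 0.5
        best, best_h = None, -np.inf
        for k in sorted(grid):
            t = pp.brightness_transform(illum[dark], k)
            hist, _ = np.histogram(t, bins=128, range=(0, 1))
            p = hist[hist > 0] / hist.sum()
            h = -(p * np.log2(p)).sum()
            if h > best_h + 1e-12:
                best, best_h = k, h
        assert pp.find_exposure_ratio(img, grid) == best


class TestFuseExposures:
    def test_single_image_identity(self, cobra_image):
        es = pp.ExposureSet(images=[cobra_image.pixels],
                            weights=[np.ones(cobra_image.pixels.shape[:2])],
                            ratios=[1.0])
        np.testing.assert_allclose(pp.fuse_exposures(es), cobra_image.pixels)

    def test_equal_images_any_weights(self, cobra_image):
        px = cobra_image.pixels
        half = np.full(px.shape[:2], 0.5)
        es = pp.ExposureSet(images=[px, px.copy()], weights=[half, half],
                            ratios=[1.0, 2.0])
        np.testing.assert_allclose(pp.fuse_exposures(es), px, atol=1e-12)

    def test_hand_weighted_sum(self):
        # 0.25 * 0.2 + 0.75 * 0.6 = 0.5 at every pixel
        p1, p2 = _uniform_image(0.2, (2, 2, 3)), _uniform_image(0.6, (2, 2, 3))
        w1, w2 = np.full((2, 2), 0.25), np.full((2, 2), 0.75)
        es = pp.ExposureSet(images=[p1, p2], weights=[w1, w2],
                            ratios=[1.0, 2.0])
        np.testing.assert_allclose(pp.fuse_exposures(es), 0.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(pp.PreprocessError):
            pp.ExposureSet(images=[np.zeros((4, 4, 3)), np.zeros((5, 5, 3))],
                           weights=[np.ones((4, 4)), np.zeros((5, 5))],
                           ratios=[1.0, 2.0])

    def test_weights_must_sum_to_one(self):
        with pytest.raises(pp.PreprocessError, match="sum to 1"):
            pp.ExposureSet(images=[np.zeros((4, 4, 3))] * 2,
                           weights=[np.full((4, 4), 0.3)] * 2,
                           ratios=[1.0, 2.0])

    def test_linear_in_images_for_fixed_weights(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0, 1, (6, 6))
        weights = [w, 1.0 - w]
        p = [rng.uniform(0, 0.5, (6, 6, 3)) for _ in range(2)]
        q = [rng.uniform(0, 0.5, (6, 6, 3)) for _ in range(2)]
        a, b = 0.4, 0.6
        mixed = pp.fuse_exposures(pp.ExposureSet(
            images=[a * pi + b * qi for pi, qi in zip(p, q)],
            weights=weights, ratios=[1.0, 2.0]))
        parts = (a * pp.fuse_exposures(pp.ExposureSet(images=p, weights=weights,
                                                      ratios=[1.0, 2.0]))
                 + b * pp.fuse_exposures(pp.ExposureSet(images=q, weights=weights,
                                                        ratios=[1.0, 2.0])))
        np.testing.assert_allclose(mixed, parts, atol=1e-6)


class TestEnhance:
    def test_well_exposed_nearly_unchanged(self):
        rng = np.random.default_rng(1)
        img = np.clip(rng.uniform(0.85, 0.98, (16, 16, 3)), 0, 1)
        out = pp.enhance(img)
        assert np.abs(out - img).max() < 0.02

    def test_darkened_fixture_brightens(self, darkened_fixture):
        out = pp.enhance(darkened_fixture)
        assert out.mean() > darkened_fixture.mean()

    def test_all_zero_fixed_point(self):
        out = pp.enhance(_uniform_image(0.0, (16, 16, 3)))
        np.testing.assert_array_equal(out, 0.0)

    def test_underexposed_mean_does_not_decrease(self, darkened_fixture):
        w = pp.estimate_weight_map(darkened_fixture)
        dark = w < 0.5
        out = pp.enhance(darkened_fixture)
        assert out[dark].mean() >= darkened_fixture[dark].mean() - 1e-12

    def test_near_idempotent_on_darkened_fixture(self, darkened_fixture):
        once = pp.enhance(darkened_fixture)
        twice = pp.enhance(once)
        assert np.abs(twice - once).mean() < 0.05

    def test_range_preserved(self, darkened_fixture):
        out = pp.enhance(darkened_fixture)
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestResize:
    def test_upscale_to_canonical(self):
        out = pp.resize_to_canonical(np.zeros((64, 48, 3)), side=100)
        assert out.shape == (100, 100, 3)

    def test_identity_shape(self, cobra_image):
        out = pp.resize_to_canonical(cobra_image.pixels, side=64)
        assert out.shape == (64, 64, 3)
        np.testing.assert_allclose(out, cobra_image.pixels)

    def test_grayscale_replicated(self):
        out = pp.resize_to_canonical(np.full((32, 32), 0.5), side=32)
        assert out.shape == (32, 32, 3)
        np.testing.assert_allclose(out[:, :, 0], out[:, :, 2])

    def test_paper_canonical_side(self):
        out = pp.resize_to_canonical(np.zeros((64, 48, 3)), side=1000)
        assert out.shape == (1000, 1000, 3)

    def test_empty_rejected(self):
        with pytest.raises(pp.PreprocessError):
            pp.resize_to_canonical(np.zeros((0, 0, 3)), side=64)

    def test_small_side_rejected(self):
        with pytest.raises(pp.PreprocessError):
            pp.resize_to_canonical(np.zeros((16, 16, 3)), side=4)


class TestAugment:
    def test_variant_count_default(self, cobra_image):
        out = pp.augment(cobra_image.pixels)
        assert len(out) == 3  # original + rotation + zoom

    def test_variant_count_scales_with_flags(self, cobra_image):
        cfg = pp.AugmentConfig(rotate90=True, zoom=True, mirror=True)
        assert len(pp.augment(cobra_image.pixels, cfg)) == 4
        cfg = pp.AugmentConfig(rotate90=False, zoom=False, mirror=False)
        assert len(pp.augment(cobra_image.pixels, cfg)) == 1

    def test_rotation_order_four(self, cobra_image):
        img = cobra_image.pixels
        for _ in range(4):
            img = pp.augment(img, pp.AugmentConfig(zoom=False))[1]
        np.testing.assert_array_equal(img, cobra_image.pixels)

    def test_zoom_factor_one_is_identity(self, cobra_image):
        cfg = pp.AugmentConfig(zoom_range=(1.0, 1.0), rotate90=False)
        out = pp.augment(cobra_image.pixels, cfg)
        np.testing.assert_allclose(out[1], cobra_image.pixels)

    def test_dataset_expansion(self, tiny_dataset):
        images = tiny_dataset[:10]
        total = sum(len(pp.augment(im.pixels, pp.AugmentConfig(seed=i)))
                    for i, im in enumerate(images))
        assert total == 30

    def test_deterministic_under_seed(self, cobra_image):
        a = pp.augment(cobra_image.pixels, pp.AugmentConfig(seed=5))
        b = pp.augment(cobra_image.pixels, pp.AugmentConfig(seed=5))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_invalid_zoom_range(self):
        with pytest.raises(pp.PreprocessError):
            pp.AugmentConfig(zoom_range=(0.0, 1.0))


@given(hnp.arrays(np.float64, (5, 5, 3),
                  elements=st.floats(min_value=0, max_value=1)))
@settings(max_examples=25, deadline=None)
def test_ops_preserve_unit_range(img):
    for out in (pp.brightness_transform(img, 3.0), pp.enhance(img),
                pp.resize_to_canonical(img, 8), *pp.augment(img)):
        assert out.min() >= 0.0 and out.max() <= 1.0
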