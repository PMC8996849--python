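import numpy as np
import pytest

from salrad.saliency import (SaliencyMap, SaliencyParams, compute_saliency_slice,
                             compute_saliency_volume, derive_products, foci_weighting,
                             fuse_images, mean_saliency, normalize_slice,
                             patch_dissimilarity, single_scale_saliency,
                             single_scale_saliency_bruteforce)
from salrad.synthetic import PhantomSpec, make_phantom
from salrad.volume_io import Modality, TumorMask, VolumeImage, crop_to_bbox

SMALL_PARAMS = SaliencyParams(patch_sizes=(3, 3, 3, 3), K=4)


class TestNormalizeSlice:
    def test_min_max(self):
        np.testing.assert_allclose(normalize_slice(np.array([0.0, 50.0, 100.0])),
                                   [0.0, 0.5, 1.0])

    def test_constant_maps_to_zero(self):
        assert normalize_slice(np.full((4, 4), 7.0)).max() == 0.0

    def test_ct_window_endpoints(self):
        sl = np.array([[-200.0, 300.0], [50.0, 50.0]])
        out = normalize_slice(sl)
        assert out[0, 0] == 0.0 and out[0, 1] == 1.0


class TestPatchDissimilarity:
    def test_identical_patches_zero(self):
        p = np.arange(9.0)
        assert patch_dissimilarity(p, p, (0.1, 0.1), (0.9, 0.9)) == 0.0

    def test_position_discounts_intensity(self):
        pi, pj = np.zeros(4), np.array([1.0, 0, 0, 0])  # d_intensity = 1
        assert patch_dissimilarity(pi, pj, (0, 0), (0, 0), c=3.0) == 1.0
        d = patch_dissimilarity(pi, pj, (0, 0), (0.6, 0.8), c=3.0)  # d_pos = 1
        assert d == pytest.approx(0.25)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            patch_dissimilarity(np.zeros(4), np.zeros(9), (0, 0), (0, 0))


class TestSingleScaleSaliency:
    def test_constant_slice_exactly_zero(self):
        out = single_scale_saliency(np.zeros((9, 9)), 1.0, SMALL_PARAMS, 3)
        assert out.max() == 0.0

    def test_matches_bruteforce_on_bright_block(self):
        sl = np.zeros((9, 9))
        sl[3:6, 3:6] = 1.0
        fast = single_scale_saliency(sl, 1.0, SMALL_PARAMS, 3)
        slow = single_scale_saliency_bruteforce(sl, 1.0, SMALL_PARAMS, 3)
        np.testing.assert_allclose(fast, slow, atol=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_on_random_slices(self, seed):
        rng = np.random.default_rng(seed)
        shape = rng.integers(8, 17, size=2)
        sl = rng.uniform(size=tuple(shape))
        for r in (1.0, 0.8):
            fast = single_scale_saliency(sl, r, SMALL_PARAMS, 3)
            slow = single_scale_saliency_bruteforce(sl, r, SMALL_PARAMS, 3)
            np.testing.assert_allclose(fast, slow, atol=1e-10)

    def test_patch_too_large_skips_scale(self):
        with pytest.warns(UserWarning):
            out = single_scale_saliency(np.zeros((4, 4)), 0.3, SMALL_PARAMS, 3)
        assert out is None

    def test_values_below_one(self, rng):
        sl = rng.uniform(size=(14, 14))
        out = single_scale_saliency(sl, 1.0, SMALL_PARAMS, 3)
        assert out.min() >= 0.0 and out.max() < 1.0


class TestMeanAndFoci:
    def test_mean_of_identical_maps(self, rng):
        m = rng.uniform(size=(6, 6))
        np.testing.assert_array_equal(mean_saliency([m, m, m, m]), m)

    def test_pixelwise_mean(self):
        maps = [np.full((2, 2), v) for v in (0.0, 0.0, 1.0, 1.0)]
        np.testing.assert_allclose(mean_saliency(maps), 0.5)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            mean_saliency([])

    def test_focus_pixel_keeps_its_value(self):
        m = np.full((5, 5), 0.1)
        m[2, 2] = 0.9
        out = foci_weighting(m, 0.8)
        assert out[2, 2] == pytest.approx(0.9)

    def test_distance_attenuation_matches_bruteforce(self):
        # single focus in a corner: compare against explicit distances
        m = np.full((5, 5), 0.6)
        m[0, 0] = 0.9
        out = foci_weighting(m, 0.8)
        diag = np.hypot(5, 5)
        for i in range(5):
            for j in range(5):
                d = np.hypot(i, j) / diag
                assert out[i, j] == pytest.approx(m[i, j] * (1 - d), abs=1e-12)

    def test_empty_foci_falls_back_to_argmax(self):
        m = np.full((4, 4), 0.3)
        m[1, 2] = 0.5
        out = foci_weighting(m, 0.8)
        assert out[1, 2] == pytest.approx(0.5)  # argmax is its own focus
        assert out[3, 0] < 0.3


class TestSaliencyVolume:
    def test_constant_phantom_zero_map(self):
        img = VolumeImage(np.full((10, 10, 4), 2.0), (1, 1, 1))
        mask = TumorMask(np.ones((10, 10, 4), bool), (1, 1, 1))
        sal = compute_saliency_volume(img, mask, SMALL_PARAMS)
        assert sal.values.max() == 0.0

    def test_single_slice_volume_equals_2d_pipeline(self, rng):
        sl = rng.uniform(size=(12, 12))
        img = VolumeImage(sl[:, :, None], (1, 1, 1))
        mask = TumorMask(np.ones((12, 12, 1), bool), (1, 1, 1))
        vol = compute_saliency_volume(img, mask, SMALL_PARAMS)
        np.testing.assert_array_equal(vol.values[:, :, 0],
                                      compute_saliency_slice(sl, SMALL_PARAMS))

    def test_maskless_slices_zero(self, rng):
        img = VolumeImage(rng.uniform(size=(10, 10, 3)), (1, 1, 1))
        m = np.zeros((10, 10, 3), bool)
        m[3:7, 3:7, 1] = True
        sal = compute_saliency_volume(img, TumorMask(m, (1, 1, 1)), SMALL_PARAMS)
        assert sal.values[:, :, 0].max() == 0.0
        assert sal.values[:, :, 2].max() == 0.0

    def test_blob_saliency_exceeds_background(self, rng):
        img_arr = rng.normal(0.2, 0.02, (14, 14, 2))
        img_arr[5:9, 5:9, :] = rng.normal(1.0, 0.02, (4, 4, 2))
        img = VolumeImage(np.clip(img_arr, 0, None), (1, 1, 1))
        mask = TumorMask(np.ones((14, 14, 2), bool), (1, 1, 1))
        sal = compute_saliency_volume(img, mask, SMALL_PARAMS)
        blob = sal.values[5:9, 5:9, :].mean()
        bg = sal.values[:4, :4, :].mean()
        assert blob > bg

    def test_contrast_monotonicity(self, rng):
        """Raising blob contrast must not lower the blob's mean saliency."""
        base = rng.normal(0.2, 0.01, (14, 14, 1)).clip(0, None)
        means = []
        for contrast in (0.5, 1.0, 2.0):
            arr = base.copy()
            arr[5:9, 5:9, 0] += contrast
            img = VolumeImage(arr, (1, 1, 1))
            mask = TumorMask(np.ones(arr.shape, bool), (1, 1, 1))
            sal = compute_saliency_volume(img, mask, SMALL_PARAMS)
            means.append(sal.values[5:9, 5:9, 0].mean())
        assert means[0] <= means[1] + 1e-12 <= means[2] + 2e-12

    def test_determinism(self, rng):
        arr = rng.uniform(size=(12, 12, 3))
        img = VolumeImage(arr, (1, 1, 1))
        mask = TumorMask(np.ones(arr.shape, bool), (1, 1, 1))
        a = compute_saliency_volume(img, mask, SMALL_PARAMS)
        b = compute_saliency_volume(img, mask, SMALL_PARAMS)
        np.testing.assert_array_equal(a.values, b.values)


class TestDeriveProducts:
    def _setup(self, sal_value, rng):
        arr = rng.uniform(1, 5, (8, 8, 2))
        img = VolumeImage(arr, (1, 1, 1), Modality.PET)
        mask = TumorMask(np.ones(arr.shape, bool), (1, 1, 1))
        sal = SaliencyMap(np.full(arr.shape, sal_value), SMALL_PARAMS)
        return img, mask, sal

    def test_all_high_when_saliency_above_threshold(self, rng):
        img, mask, sal = self._setup(0.6, rng)
        prod = derive_products(img, sal, mask, SMALL_PARAMS)
        assert prod.high_mask.n_voxels == mask.n_voxels
        assert prod.low_mask is None and not prod.low_usable

    def test_partition_is_exact(self, rng):
        img, mask, _ = self._setup(0.0, rng)
        vals = rng.uniform(size=img.shape)
        prod = derive_products(img, SaliencyMap(vals, SMALL_PARAMS), mask, SMALL_PARAMS)
        high = prod.high_mask.voxels if prod.high_mask is not None else 0
        low = prod.low_mask.voxels if prod.low_mask is not None else 0
        np.testing.assert_array_equal(high | low, mask.voxels)
        assert not (high & low).any()

    def test_zero_saliency_zero_products(self, rng):
        img, mask, sal = self._setup(0.0, rng)
        prod = derive_products(img, sal, mask, SMALL_PARAMS)
        assert prod.sal_x_img.voxels.max() == 0.0
        ct = VolumeImage(img.voxels, img.spacing, Modality.CT)
        prod_ct = derive_products(ct, sal, mask, SMALL_PARAMS)
        assert fuse_images(prod, prod_ct).voxels.max() == 0.0


def test_phantom_blob_beats_background_each_slice():
    pet, ct, mask, sub = make_phantom(PhantomSpec(), seed=5)
    pet_c, mask_c = crop_to_bbox(pet, mask)
    sub_img = VolumeImage(sub.voxels.astype(float), sub.spacing)
    sub_c, _ = crop_to_bbox(sub_img, mask)
    sal = compute_saliency_volume(pet_c, mask_c)
    subm = sub_c.voxels > 0.5
    shell = mask_c.voxels & ~subm
    assert sal.values[subm].mean() > sal.values[shell].mean()
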