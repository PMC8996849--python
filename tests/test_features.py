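import numpy as np
import pytest

from salrad import texture
from salrad.features import (FeatureConfig, FeatureVector, discretize_fbn,
                             extract_features, feature_names)
from salrad.volume_io import TumorMask, VolumeImage


def volume_of(arr, spacing=(1.0, 1.0, 1.0)):
    return VolumeImage(np.asarray(arr, dtype=float), spacing)


def full_mask(shape, spacing=(1.0, 1.0, 1.0)):
    return TumorMask(np.ones(shape, bool), spacing)


class TestDiscretize:
    def test_levels_span_bins(self):
        arr = np.arange(64, dtype=float).reshape(4, 4, 4)
        roi = discretize_fbn(volume_of(arr), full_mask((4, 4, 4)), 64)
        assert roi.levels.min() == 1 and roi.levels.max() == 64
        assert sorted(np.unique(roi.levels)) == list(range(1, 65))

    def test_constant_roi_level_one(self):
        roi = discretize_fbn(volume_of(np.full((3, 3, 3), 9.0)), full_mask((3, 3, 3)), 64)
        assert (roi.levels == 1).all()

    def test_max_clamps_to_n_bins(self):
        arr = np.zeros((2, 2, 2))
        arr[1, 1, 1] = 10.0
        roi = discretize_fbn(volume_of(arr), full_mask((2, 2, 2)), 8)
        assert roi.levels.max() == 8  # not n_bins + 1

    def test_out_of_mask_is_zero(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = m[0, 0, 0] = True
        roi = discretize_fbn(volume_of(np.arange(27.0).reshape(3, 3, 3)),
                             TumorMask(m, (1, 1, 1)), 4)
        assert roi.level_volume[2, 2, 2] == 0


class TestFirstOrder:
    def test_hand_computed_mean_variance(self):
        # single-slice 3x3 ROI with values 1..9
        arr = np.arange(1.0, 10.0).reshape(3, 3, 1)
        fv = extract_features(volume_of(arr), full_mask((3, 3, 1)),
                              FeatureConfig(families=("stat",))).as_dict()
        assert fv["stat.mean"] == pytest.approx(5.0)
        assert fv["stat.variance"] == pytest.approx(6.666666667)
        assert fv["stat.median"] == pytest.approx(5.0)
        assert fv["stat.energy"] == pytest.approx(sum(v * v for v in range(1, 10)))

    def test_uniform_roi_degenerate_features(self):
        fv = extract_features(volume_of(np.full((4, 4, 4), 3.0)),
                              full_mask((4, 4, 4))).as_dict()
        assert fv["stat.variance"] == 0.0
        assert fv["glcm.contrast"] == 0.0
        assert fv["ih.minimum"] == fv["ih.maximum"] == 1.0
        assert fv["ih.uniformity"] == 1.0

    def test_all_values_finite_on_random_roi(self, rng, small_volume, ellipsoid_mask):
        fv = extract_features(small_volume, ellipsoid_mask)
        assert np.isfinite(fv.values).all()

    def test_submininal_mask_flagged_missing(self, small_volume):
        m = np.zeros(small_volume.shape, bool)
        m[0, 0, 0] = True
        fv = extract_features(small_volume, TumorMask(m, (1, 1, 1)))
        assert fv.missing and np.isnan(fv.values).all()


class TestInvariances:
    def test_translation_invariance(self, rng):
        arr = rng.uniform(0, 5, (6, 5, 4))
        m = np.zeros((6, 5, 4), bool)
        m[1:4, 1:4, 1:3] = True
        base_img = np.zeros((12, 12, 10))
        base_msk = np.zeros((12, 12, 10), bool)
        vecs = []
        for off in ((0, 0, 0), (4, 5, 3)):
            img = base_img.copy()
            msk = base_msk.copy()
            img[off[0]:off[0] + 6, off[1]:off[1] + 5, off[2]:off[2] + 4] = arr
            msk[off[0]:off[0] + 6, off[1]:off[1] + 5, off[2]:off[2] + 4] = m
            vecs.append(extract_features(volume_of(img), TumorMask(msk, (1, 1, 1))))
        np.testing.assert_allclose(vecs[0].values, vecs[1].values, rtol=1e-12)

    def test_deterministic(self, small_volume, ellipsoid_mask):
        a = extract_features(small_volume, ellipsoid_mask)
        b = extract_features(small_volume, ellipsoid_mask)
        np.testing.assert_array_equal(a.values, b.values)

    def test_name_order_fixed(self):
        names = feature_names()
        assert len(names) == len(set(names))
        assert names == feature_names()


class TestGlcm:
    def test_contrast_zero_iff_single_level(self, rng):
        uni = extract_features(volume_of(np.full((4, 4, 4), 2.0)),
                               full_mask((4, 4, 4))).as_dict()
        assert uni["glcm.contrast"] == 0.0
        tex = extract_features(VolumeImage(rng.uniform(0, 9, (5, 5, 5)), (1, 1, 1)),
                               full_mask((5, 5, 5))).as_dict()
        assert tex["glcm.contrast"] > 0.0

    def test_matrix_symmetric_and_normalizable(self, rng, small_volume, ellipsoid_mask):
        from salrad.features import discretize_fbn
        roi = discretize_fbn(small_volume, ellipsoid_mask, 16)
        mat = texture.glcm_matrix(roi)
        np.testing.assert_array_equal(mat, mat.T)
        assert mat.sum() > 0


class TestZoneFamilies:
    def test_glszm_zone_count_matches_floodfill_oracle(self, rng):
        """Zone counts equal an independent BFS flood-fill enumeration."""
        from collections import deque
        arr = rng.integers(0, 3, (10, 10, 10)).astype(float)
        img = volume_of(arr)
        mask = full_mask((10, 10, 10))
        roi = discretize_fbn(img, mask, 3)
        mat = texture.glszm_matrix(roi)

        # oracle: BFS over 26-neighborhoods of equal discretized level
        lev = roi.level_volume
        seen = np.zeros(lev.shape, bool)
        zones = []
        offs = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
                if (a, b, c) != (0, 0, 0)]
        for start in np.argwhere(mask.voxels):
            s = tuple(start)
            if seen[s]:
                continue
            g = lev[s]
            q = deque([s])
            seen[s] = True
            size = 0
            while q:
                v = q.popleft()
                size += 1
                for o in offs:
                    w = tuple(np.add(v, o))
                    if all(0 <= w[i] < lev.shape[i] for i in range(3)) \
                            and not seen[w] and lev[w] == g:
                        seen[w] = True
                        q.append(w)
            zones.append((int(g), size))
        assert mat.sum() == len(zones)
        for g, size in zones:
            assert mat[g - 1, size - 1] >= 1

    def test_single_blob_one_zone(self):
        arr = np.zeros((10, 10, 10))
        arr[3:7, 3:7, 3:7] = 5.0
        roi = discretize_fbn(volume_of(arr), full_mask((10, 10, 10)), 2)
        mat = texture.glszm_matrix(roi)
        assert mat[1, 63] == 1.0  # one 64-voxel zone at the top level
        assert mat[1].sum() == 1.0

    def test_gldzm_edge_zone_distance_one(self):
        arr = np.zeros((6, 6, 6))
        arr[0, 0, 0] = 1.0  # bright corner voxel touches the ROI edge
        roi = discretize_fbn(volume_of(arr), full_mask((6, 6, 6)), 2)
        mat = texture.gldzm_matrix(roi)
        assert mat[1, 0] == 1.0


class TestRunLength:
    def test_uniform_volume_single_runs(self):
        """In a constant cube every direction yields one full-length run per line."""
        n = 4
        roi = discretize_fbn(volume_of(np.full((n, n, n), 1.0)), full_mask((n, n, n)), 8)
        mat = texture.glrlm_matrix(roi)
        # axis-aligned directions contribute n*n runs of length n
        assert mat[0, n - 1] >= 3 * n * n

    def test_matches_line_walk_oracle(self, rng):
        """Merged run-length counts equal an explicit per-line walking oracle."""
        arr = rng.integers(0, 4, (6, 5, 4)).astype(float)
        m = rng.uniform(size=(6, 5, 4)) < 0.8
        m[2, 2, 2] = True
        img = volume_of(arr)
        mask = TumorMask(m, (1, 1, 1))
        roi = discretize_fbn(img, mask, 4)
        mat = texture.glrlm_matrix(roi)

        lev = np.where(roi.mask, roi.level_volume, 0)
        shape = lev.shape
        counts = {}
        for off in texture.DIRECTIONS_13:
            starts = [tuple(v) for v in np.argwhere(np.ones(shape, bool))
                      if not all(0 <= v[i] - off[i] < shape[i] for i in range(3))]
            for s in starts:
                line = []
                v = s
                while all(0 <= v[i] < shape[i] for i in range(3)):
                    line.append(lev[v])
                    v = tuple(np.add(v, off))
                run_level, run_len = 0, 0
                for g in line + [0]:
                    if g == run_level:
                        run_len += 1
                    else:
                        if run_level > 0:
                            counts[(run_level, run_len)] = counts.get(
                                (run_level, run_len), 0) + 1
                        run_level, run_len = g, 1
        oracle = np.zeros_like(mat)
        for (g, l), c in counts.items():
            oracle[g - 1, l - 1] = c
        np.testing.assert_array_equal(mat, oracle)


class TestNeighborhoodFamilies:
    def test_ngtdm_uniform_volume(self):
        roi = discretize_fbn(volume_of(np.full((5, 5, 5), 2.0)), full_mask((5, 5, 5)), 4)
        feats = texture.ngtdm_features(roi)
        assert feats["contrast"] == 0.0
        assert feats["coarseness"] > 0

    def test_ngldm_uniform_volume_max_dependence(self):
        n = 5
        roi = discretize_fbn(volume_of(np.full((n, n, n), 1.0)), full_mask((n, n, n)), 4)
        mat = texture.ngldm_matrix(roi)
        # interior voxels have all 26 neighbors equal -> dependence 26
        assert mat[0, 26] == (n - 2) ** 3
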