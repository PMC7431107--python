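"""Texture-matrix construction and features against hand-enumerated and
brute-force oracles on tiny phantoms."""

import numpy as np
import pytest

from conftest import strip_volume
from radpipe.fixtures import PhantomSpec, make_phantom
from radpipe.texture import (
    ALL_DIRECTIONS_3D,
    glcm,
    glcm_features,
    glrlm,
    glrlm_features,
    glszm,
    glszm_features,
    roi_directions,
)
from radpipe.volume import CaseVolume, EmptyRoiError, quantize


class TestQuantize:
    def test_constant_roi_collapses_to_one_level(self):
        v = strip_volume([5, 5, 5, 5])
        q = quantize(v, 8)
        assert q.n_levels == 1
        assert set(q.levels[q.mask]) == {1}

    def test_equal_width_binning(self):
        v = strip_volume([1, 2, 3, 4, 5, 6, 7, 8])
        q = quantize(v, 4)
        assert list(q.levels[q.mask]) == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_extremes_map_to_first_and_last_bin(self):
        v = strip_volume([0, 10])
        q = quantize(v, 2)
        assert list(q.levels[q.mask]) == [1, 2]

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyRoiError, match="empty ROI"):
            CaseVolume("x", np.ones((2, 2, 2)), np.zeros((2, 2, 2)))

    def test_bad_bin_count(self):
        with pytest.raises(ValueError):
            quantize(strip_volume([1, 2]), 0)


class TestGlcm:
    def test_hand_enumerated_strip(self):
        # two adjacent pairs (1,1) and (1,2), counted in both orders
        q = quantize(strip_volume([1, 1, 2]), 2)
        m = glcm(q, directions=((1, 0, 0),))
        assert m.counts.tolist() == [[2, 1], [1, 0]]
        p = m.normalized
        assert p[0, 0] == 0.5 and p[0, 1] == 0.25 and p[1, 0] == 0.25

    def test_constant_roi_single_cell(self):
        q = quantize(strip_volume([7, 7, 7]), 4)
        m = glcm(q)
        assert m.normalized.tolist() == [[1.0]]

    def test_normalization_and_symmetry(self, random_volume):
        q = quantize(random_volume, 8)
        m = glcm(q)
        assert m.normalized.sum() == pytest.approx(1.0)
        assert (m.counts >= 0).all()
        assert np.array_equal(m.counts, m.counts.T)

    def test_distance_validated(self):
        q = quantize(strip_volume([1, 2]), 2)
        with pytest.raises(ValueError):
            glcm(q, distance=0)


class TestGlcmFeatures:
    @pytest.mark.parametrize(
        "p, expected_ac",
        [
            ([[1.0]], 1.0),
            ([[0.5, 0.25], [0.25, 0.0]], 1.5),
            ([[0.5, 0.0], [0.0, 0.5]], 2.5),
        ],
    )
    def test_autocorrelation(self, p, expected_ac):
        from radpipe.texture import TextureMatrix

        counts = (np.array(p) * 4).astype(int)
        feats = glcm_features(TextureMatrix("GLCM", counts))
        assert feats["autocorrelation"] == pytest.approx(expected_ac)

    def test_rejects_wrong_family(self):
        from radpipe.texture import TextureMatrix

        with pytest.raises(ValueError):
            glcm_features(TextureMatrix("GLRLM", np.ones((2, 2), int)))


class TestGlrlm:
    def test_single_run_percentage(self):
        q = quantize(strip_volume([3, 3, 3]), 4)
        feats = glrlm_features(q, directions=((1, 0, 0),))
        assert feats["run_percentage"] == pytest.approx(1 / 3)
        # one run of length 3 => LRE = 9
        assert feats["long_run_emphasis"] == pytest.approx(9.0)

    def test_all_short_runs(self):
        q = quantize(strip_volume([1, 10, 1]), 2)
        feats = glrlm_features(q, directions=((1, 0, 0),))
        assert feats["short_run_emphasis"] == pytest.approx(1.0)

    def test_run_decomposition_covers_roi_per_direction(self, random_volume):
        # along any single direction, runs partition the ROI voxels
        q = quantize(random_volume, 4)
        n_roi = int(q.mask.sum())
        for d in ((1, 0, 0), (0, 1, 1), (1, -1, 1)):
            m = glrlm(q, directions=(d,))
            lengths = np.arange(1, m.counts.shape[1] + 1)
            assert int((m.counts * lengths).sum()) == n_roi


class TestGlszm:
    def test_constant_roi_zero_variance(self):
        vol = make_phantom(PhantomSpec(texture="constant"))
        feats = glszm_features(quantize(vol, 8))
        assert feats["gray_level_variance"] == 0.0
        assert feats["zone_percentage"] == pytest.approx(1 / vol.mask.sum())

    def test_two_disjoint_zones_hand_matrix(self):
        # two equal-size zones at levels 1 and 3 of a 3-level quantization
        img = np.zeros((1, 1, 7))
        img[0, 0, :3] = 0.0
        img[0, 0, 3] = 50.0  # separator, its own level
        img[0, 0, 4:] = 100.0
        mask = np.ones((1, 1, 7), bool)
        mask[0, 0, 3] = False
        v = CaseVolume("zones", img, mask)
        q = quantize(v, 3)
        feats = glszm_features(q)
        # mu = 0.5*1 + 0.5*3 = 2; GLV = 0.5*1 + 0.5*1 = 1
        assert feats["gray_level_variance"] == pytest.approx(1.0)

    def test_zone_count_matches_flood_fill_oracle(self, rng):
        # independent BFS flood fill with 26-connectivity
        def flood_zones(levels, mask):
            seen = np.zeros_like(mask, bool)
            zones = []
            offsets = [
                (a, b, c)
                for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
                if (a, b, c) != (0, 0, 0)
            ]
            for start in zip(*np.nonzero(mask)):
                if seen[start]:
                    continue
                level = levels[start]
                stack, size = [start], 0
                seen[start] = True
                while stack:
                    cur = stack.pop()
                    size += 1
                    for o in offsets:
                        nb = tuple(np.array(cur) + o)
                        if all(0 <= nb[i] < mask.shape[i] for i in range(3)):
                            if mask[nb] and not seen[nb] and levels[nb] == level:
                                seen[nb] = True
                                stack.append(nb)
                zones.append(size)
            return sorted(zones)

        for _ in range(5):
            img = rng.integers(0, 3, size=(4, 4, 4)).astype(float)
            mask = rng.random((4, 4, 4)) > 0.4
            mask[1, 1, 1] = True
            q = quantize(CaseVolume("r", img, mask), 3)
            m = glszm(q)
            sizes = []
            for lvl in range(m.counts.shape[0]):
                for s in range(m.counts.shape[1]):
                    sizes.extend([s + 1] * int(m.counts[lvl, s]))
            assert sorted(sizes) == flood_zones(q.levels, q.mask)

    def test_zone_sizes_partition_roi(self, random_volume):
        q = quantize(random_volume, 4)
        m = glszm(q)
        sizes = np.arange(1, m.counts.shape[1] + 1)
        assert int((m.counts * sizes).sum()) == int(q.mask.sum())


class TestInvariances:
    def test_intensity_shift_invariance(self, random_volume):
        q1 = quantize(random_volume, 8)
        shifted = CaseVolume(
            "shift", random_volume.image + 500.0, random_volume.mask,
            random_volume.spacing,
        )
        q2 = quantize(shifted, 8)
        f1 = glcm_features(glcm(q1))
        f2 = glcm_features(glcm(q2))
        for k in f1:
            assert f1[k] == pytest.approx(f2[k]), k
        g1, g2 = glszm_features(q1), glszm_features(q2)
        for k in g1:
            assert g1[k] == pytest.approx(g2[k]), k

    def test_rotation_invariance_90_degrees(self, rng):
        img = rng.normal(size=(5, 5, 5))
        mask = np.zeros((5, 5, 5), bool)
        mask[1:4, 1:4, 1:4] = True
        v = CaseVolume("v", img, mask)
        vr = CaseVolume("vr", np.rot90(img, axes=(0, 1)).copy(),
                        np.rot90(mask, axes=(0, 1)).copy())
        q, qr = quantize(v, 6), quantize(vr, 6)
        f = glcm_features(glcm(q, directions=ALL_DIRECTIONS_3D))
        fr = glcm_features(glcm(qr, directions=ALL_DIRECTIONS_3D))
        for key in f:
            assert f[key] == pytest.approx(fr[key]), key
        r = glrlm_features(q, directions=ALL_DIRECTIONS_3D)
        rr = glrlm_features(qr, directions=ALL_DIRECTIONS_3D)
        for key in r:
            assert r[key] == pytest.approx(rr[key]), key

    def test_single_slice_roi_uses_in_plane_directions(self):
        mask = np.zeros((1, 4, 4), bool)
        mask[0] = True
        assert len(roi_directions(mask)) == 4
        assert all(d[0] == 0 for d in roi_directions(mask))

    def test_constant_phantom_variance_features_zero_and_finite(self):
        vol = make_phantom(PhantomSpec(texture="constant"))
        q = quantize(vol, 16)
        all_feats = {}
        all_feats.update(glcm_features(glcm(q)))
        all_feats.update(glrlm_features(q))
        all_feats.update(glszm_features(q))
        assert all(np.isfinite(v) for v in all_feats.values())
        for key in ("contrast", "gray_level_variance", "gray_level_variance_glrlm"):
            assert all_feats[key] == pytest.approx(0.0, abs=1e-12)
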