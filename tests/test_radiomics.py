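"""Feature extraction: hand-computed values, brute-force oracles, invariances."""
import numpy as np
import pandas as pd
import pytest

from mammodiff.images import BreastMask, GrayImage
from mammodiff.radiomics import (FEATURE_NAMES, GLCM, RadiomicsConfig,
                                 case_features, compute_glcm, compute_ngtdm,
                                 extract_image_features, fos_range,
                                 haralick_features, ngtdm_features, quantize,
                                 zscore_table)


def brute_force_glcm(q, levels, distance=1):
    """Directly enumerate symmetric co-occurring pairs in 4 directions."""
    offsets = [(0, distance), (distance, distance), (distance, 0), (distance, -distance)]
    counts = np.zeros((levels, levels))
    h, w = q.shape
    for dr, dc in offsets:
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    counts[q[r, c] - 1, q[r2, c2] - 1] += 1
                    counts[q[r2, c2] - 1, q[r, c] - 1] += 1
    return counts / counts.sum()


def brute_force_ngtdm(q, levels):
    """Per-pixel double loop over interior pixels."""
    h, w = q.shape
    s = np.zeros(levels)
    n = np.zeros(levels, dtype=int)
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            nbhd = q[r - 1:r + 2, c - 1:c + 2].astype(float)
            mean = (nbhd.sum() - q[r, c]) / 8.0
            lvl = int(q[r, c])
            s[lvl - 1] += abs(q[r, c] - mean)
            n[lvl - 1] += 1
    return s, n


class TestQuantize:
    def test_constant_region_maps_to_level_one(self):
        assert (quantize(np.full((4, 4), 7), 64) == 1).all()

    def test_endpoints_two_levels(self):
        q = quantize(np.array([[0, 255]]), 2)
        assert q.tolist() == [[1, 2]]

    def test_ramp_bin_width(self):
        ramp = np.arange(256).reshape(16, 16)
        q = quantize(ramp, 64)
        assert q.min() == 1 and q.max() == 64
        assert q.ravel()[100] == 26  # 4 intensity units per level
        assert (np.bincount(q.ravel())[1:] == 4).all()

    def test_rejects_single_level(self):
        with pytest.raises(ValueError):
            quantize(np.ones((3, 3)), 1)


class TestGLCM:
    def test_constant_raster_single_entry(self):
        g = compute_glcm(np.ones((4, 4), dtype=int), levels=4)
        assert g.matrix[0, 0] == pytest.approx(1.0)
        assert g.matrix.sum() == pytest.approx(1.0)

    def test_two_by_two_horizontal_pairs(self):
        # [[1,2],[1,2]]: two horizontal (1,2) pairs; symmetrised
        q = np.array([[1, 2], [1, 2]])
        counts = brute_force_glcm(q, 2)
        g = compute_glcm(q, levels=2)
        np.testing.assert_allclose(g.matrix, counts, atol=1e-12)

    def test_matches_brute_force_on_random_rasters(self, rng):
        for _ in range(50):
            q = rng.integers(1, 9, size=(10, 10))
            g = compute_glcm(q, levels=8)
            np.testing.assert_allclose(g.matrix, brute_force_glcm(q, 8), atol=1e-12)
            assert g.matrix.sum() == pytest.approx(1.0, abs=1e-12)


class TestHaralick:
    def test_constant_image_limits(self):
        g = compute_glcm(np.full((6, 6), 3, dtype=int), levels=8)
        f = haralick_features(g)
        assert f["Contrast"] == 0
        assert f["Cluster_prominence"] == 0
        assert f["Cluster_shade"] == 0
        assert f["Entropy"] == 0
        assert f["Energy"] == pytest.approx(1.0)

    def test_two_point_glcm_by_hand(self):
        m = np.zeros((2, 2))
        m[0, 1] = m[1, 0] = 0.5
        f = haralick_features(GLCM(matrix=m, levels=2))
        assert f["Contrast"] == pytest.approx(1.0)   # |1-2|^2 * 1
        assert f["Entropy"] == pytest.approx(1.0)    # two equal cells, 1 bit

    def test_doubly_symmetric_glcm_has_zero_cluster_shade(self, rng):
        # transpose symmetry alone does not kill the third co-moment; the
        # invariant holds when the GLCM is also centrally symmetric
        # (p(i,j) = p(L+1-i, L+1-j)), making i+j symmetric about 2*mu
        for _ in range(20):
            a = rng.random((5, 5))
            m = a + a.T
            m = m + m[::-1, ::-1]
            m /= m.sum()
            f = haralick_features(GLCM(matrix=m, levels=5))
            assert f["Cluster_shade"] == pytest.approx(0.0, abs=1e-9)

    def test_rejects_unnormalised(self):
        with pytest.raises(ValueError):
            haralick_features(GLCM(matrix=np.ones((3, 3)), levels=3))

    def test_shift_invariance_of_glcm_features(self, rng):
        raw = rng.integers(0, 200, size=(20, 20))
        cfg = RadiomicsConfig(levels=16)
        f1 = haralick_features(compute_glcm(quantize(raw, 16), 16))
        f2 = haralick_features(compute_glcm(quantize(raw + 37, 16), 16))
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], abs=1e-10), k


class TestNGTDM:
    def test_constant_raster_coarseness_is_inverse_epsilon(self):
        f = ngtdm_features(np.ones((5, 5), dtype=int), levels=4)
        assert f["Coarseness"] == pytest.approx(1e6)

    def test_single_interior_pixel_by_hand(self):
        q = np.ones((3, 3), dtype=int)
        q[1, 1] = 2
        m = compute_ngtdm(q, levels=2)
        assert m.n.tolist() == [0, 1]
        assert m.s[1] == pytest.approx(1.0)  # |2 - mean(eight 1s)|

    def test_matches_double_loop_on_random_rasters(self, rng):
        for _ in range(50):
            q = rng.integers(1, 7, size=(12, 12))
            m = compute_ngtdm(q, levels=6)
            s, n = brute_force_ngtdm(q, 6)
            np.testing.assert_allclose(m.s, s, atol=1e-9)
            assert m.n.tolist() == n.tolist()


class TestFOSRange:
    @pytest.mark.parametrize(
        "values,expected",
        [(np.zeros((3, 3)), 0.0), (np.array([[0, 255]]), 255.0),
         (np.array([12, 47, 200]), 188.0)],
    )
    def test_examples(self, values, expected):
        assert fos_range(values) == expected

    def test_shift_invariant_not_scale_invariant(self, rng):
        v = rng.integers(0, 100, size=(8, 8))
        assert fos_range(v + 11) == fos_range(v)
        assert fos_range(v * 2) == 2 * fos_range(v)


class TestImageFeatures:
    CFG = RadiomicsConfig(levels=16, block_size=30, min_coverage=0.5)

    def test_emits_exactly_34_named_finite_features(self, small_breast_image, rng):
        img, mask = small_breast_image
        noisy = img.with_pixels(
            np.where(mask.pixels, rng.integers(120, 250, img.shape), 0).astype(np.uint8)
        )
        vec = extract_image_features(noisy, mask, self.CFG)
        assert list(vec.index) == list(FEATURE_NAMES)
        assert len(vec) == 34
        assert np.isfinite(vec.to_numpy()).all()

    def test_feature_roster_composition(self):
        glcm = [n for n in FEATURE_NAMES if not any(
            q in n for q in ("Coarseness", "Range"))]
        ngtdm = [n for n in FEATURE_NAMES if "Coarseness" in n]
        fos = [n for n in FEATURE_NAMES if "Range" in n]
        assert (len(glcm), len(ngtdm), len(fos)) == (30, 2, 2)

    def test_constant_image_all_variation_features_zero(self):
        # a constant full-frame image: every block is identical, so all
        # spread features vanish (boundary blocks of a breast-on-background
        # image still mix in background zeros, so the limit is stated for
        # the full-frame case)
        img = GrayImage(pixels=np.full((90, 90), 180, dtype=np.uint8))
        mask = BreastMask(pixels=np.ones((90, 90), dtype=bool))
        vec = extract_image_features(img, mask, self.CFG)
        assert vec["SQ_Contrast"] == 0
        assert vec["SQ_Cluster_prominence"] == 0
        assert vec["SQ_Range"] == 0
        assert (vec.filter(like="ROI_Std_") == 0).all()

    def test_determinism(self, small_breast_image, rng):
        img, mask = small_breast_image
        noisy = img.with_pixels(
            np.where(mask.pixels, rng.integers(120, 250, img.shape), 0).astype(np.uint8)
        )
        v1 = extract_image_features(noisy, mask, self.CFG)
        v2 = extract_image_features(noisy, mask, self.CFG)
        pd.testing.assert_series_equal(v1, v2)


class TestCaseFeatures:
    def test_mean_of_four_views(self):
        vecs = [pd.Series({"a": v, "b": 2.0}) for v in (1.0, 2.0, 3.0, 4.0)]
        out = case_features(vecs, "case0")
        assert out["a"] == 2.5
        assert out["b"] == 2.0

    def test_permutation_invariant(self, rng):
        vecs = [pd.Series(rng.random(3), index=list("abc")) for _ in range(4)]
        a = case_features(vecs)
        b = case_features(vecs[::-1])
        pd.testing.assert_series_equal(a, b)

    def test_wrong_count_or_names_rejected(self):
        v = pd.Series({"a": 1.0})
        with pytest.raises(ValueError):
            case_features([v, v, v])
        with pytest.raises(ValueError):
            case_features([v, v, v, pd.Series({"b": 1.0})])


class TestZScore:
    def test_columns_standardised(self, rng):
        t = pd.DataFrame(rng.random((20, 5)), columns=list("abcde"))
        z, params = zscore_table(t)
        assert np.allclose(z.mean(), 0.0, atol=1e-10)
        assert np.allclose(z.std(ddof=1), 1.0, atol=1e-10)

    def test_constant_column_zeroed(self):
        t = pd.DataFrame({"x": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        z, params = zscore_table(t)
        assert (z["c"] == 0).all()
        np.testing.assert_allclose(z["x"], [-1, 0, 1])

    def test_transform_projects_held_out(self):
        t = pd.DataFrame({"x": [0.0, 2.0, 4.0]})
        _, params = zscore_table(t)
        held = params.transform(pd.DataFrame({"x": [6.0]}))
        assert held["x"].iloc[0] == pytest.approx(2.0)
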