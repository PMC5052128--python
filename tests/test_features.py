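import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from slicseg import (FEATURE_NAMES, LOW_LEVEL_FEATURE_NAMES, extract_features,
                     glcm_stats, haar_stats)
from slicseg.features import GLCM_LEVELS, GLCM_OFFSETS


def reference_haar2d(x):
    """Textbook orthonormal 2D Haar step: averaging/differencing by hand."""
    x = np.asarray(x, dtype=float)
    a = (x[0::2, 0::2] + x[0::2, 1::2] + x[1::2, 0::2] + x[1::2, 1::2]) / 2.0
    h = (x[0::2, 0::2] + x[1::2, 0::2] - x[0::2, 1::2] - x[1::2, 1::2]) / 2.0
    v = (x[0::2, 0::2] + x[0::2, 1::2] - x[1::2, 0::2] - x[1::2, 1::2]) / 2.0
    d = (x[0::2, 0::2] + x[1::2, 1::2] - x[0::2, 1::2] - x[1::2, 0::2]) / 2.0
    return a, h, v, d


def reference_glcm(q, offset):
    """Co-occurrence counts accumulated pair by pair."""
    L = GLCM_LEVELS
    P = np.zeros((L, L))
    dr, dc = offset
    H, W = q.shape
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W:
                P[q[r, c], q[r2, c2]] += 1
                P[q[r2, c2], q[r, c]] += 1
    return P / P.sum()


class TestConstantRoi:
    def test_intensity_glcm_haar_identities(self):
        roi = np.full((9, 9), 7.0)
        fm = extract_features(roi, [(4, 4)])
        row = dict(zip(FEATURE_NAMES, fm.values[0]))
        assert row["intensity_mean"] == pytest.approx(7.0)
        assert row["intensity_sd"] == pytest.approx(0.0)
        assert row["glcm_energy"] == pytest.approx(1.0)
        assert row["glcm_contrast"] == pytest.approx(0.0)
        assert row["glcm_homogeneity"] == pytest.approx(1.0)
        for name in ("haar_lh1", "haar_hl1", "haar_hh1",
                     "haar_lh2", "haar_hl2", "haar_hh2"):
            assert row[name] == pytest.approx(0.0, abs=1e-12)
        # orthonormal scaling: two levels multiply a constant by 4
        assert row["haar_approx2"] == pytest.approx(28.0)


class TestIntensityStats:
    def test_known_values_match_direct_formula(self):
        rng = np.random.default_rng(1)
        img = rng.permutation(np.arange(81.0)).reshape(9, 9)
        fm = extract_features(img, [(4, 4)])
        assert fm.values[0, 0] == pytest.approx(np.mean(np.arange(81.0)))
        assert fm.values[0, 1] == pytest.approx(np.std(np.arange(81.0)))


class TestGlcm:
    def test_checkerboard_contrast_matches_hand_counts(self):
        roi = np.indices((9, 9)).sum(axis=0) % 2 * 7.0  # two extreme levels
        q = (roi > 0).astype(int) * (GLCM_LEVELS - 1)
        stats = glcm_stats(roi)
        expected = []
        for off in GLCM_OFFSETS:
            P = reference_glcm(q, off)
            i, j = np.meshgrid(range(GLCM_LEVELS), range(GLCM_LEVELS),
                               indexing="ij")
            expected.append(np.sum(P * (i - j) ** 2))
        assert stats[0] == pytest.approx(np.mean(expected))

    def test_column_stripes_have_unit_contrast_horizontally(self):
        # alternating columns at two quantized levels: every horizontal pair
        # differs by (L-1), every vertical pair by 0
        roi = np.tile(np.arange(9) % 2, (9, 1)).astype(float)
        q = roi.astype(int) * (GLCM_LEVELS - 1)
        P = reference_glcm(q, (0, 1))
        i, j = np.meshgrid(range(GLCM_LEVELS), range(GLCM_LEVELS), indexing="ij")
        assert np.sum(P * (i - j) ** 2) == pytest.approx((GLCM_LEVELS - 1) ** 2)

    def test_matches_skimage_on_random_rois(self):
        from skimage.feature import graycomatrix, graycoprops
        rng = np.random.default_rng(4)
        for _ in range(10):
            roi = rng.uniform(0, 100, size=(9, 9))
            mn, mx = roi.min(), roi.max()
            q = np.clip(((roi - mn) / (mx - mn) * GLCM_LEVELS).astype(int),
                        0, GLCM_LEVELS - 1).astype(np.uint8)
            g = graycomatrix(q, [1], [0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
                             levels=GLCM_LEVELS, symmetric=True, normed=True)
            ours = glcm_stats(roi)
            for k, prop in enumerate(["contrast", "correlation", "energy",
                                      "homogeneity"]):
                ref = graycoprops(g, prop)[0].mean()
                assert ours[k] == pytest.approx(ref, abs=1e-10), prop

    def test_ranges(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            s = glcm_stats(rng.normal(size=(9, 9)))
            assert np.all(np.isfinite(s))
            assert 0 < s[2] <= 1  # energy
            assert 0 < s[3] <= 1  # homogeneity


class TestHaar:
    def test_vertical_step_edge_excites_only_one_orientation(self):
        roi = np.zeros((9, 9))
        roi[:, 5:] = 10.0  # vertical edge: horizontal intensity change
        stats = haar_stats(roi)
        named = dict(zip(("lh1", "hl1", "hh1", "lh2", "hl2", "hh2", "a2"),
                         stats))
        assert named["hh1"] == pytest.approx(0.0, abs=1e-12)
        # one of the two oriented detail bands is silent, the other is not
        assert min(named["lh1"], named["hl1"]) == pytest.approx(0.0, abs=1e-12)
        assert max(named["lh1"], named["hl1"]) > 0

    def test_matches_textbook_two_level_transform(self):
        rng = np.random.default_rng(2)
        img = np.zeros((9, 9))
        img[:8, :8] = rng.normal(size=(8, 8))
        a1, h1, v1, d1 = reference_haar2d(img[:8, :8])
        a2, h2, v2, d2 = reference_haar2d(a1)
        expected = [np.abs(h1).mean(), np.abs(v1).mean(), np.abs(d1).mean(),
                    np.abs(h2).mean(), np.abs(v2).mean(), np.abs(d2).mean(),
                    a2.mean()]
        got = haar_stats(img)
        # detail features are orientation summaries: compare as sets of the
        # two level-1 oriented bands since H/V naming conventions differ
        assert sorted(got[:2]) == pytest.approx(sorted(expected[:2]))
        assert got[2] == pytest.approx(expected[2])
        assert sorted(got[3:5]) == pytest.approx(sorted(expected[3:5]))
        assert got[5] == pytest.approx(expected[5])
        assert got[6] == pytest.approx(expected[6])


class TestExtractFeatures:
    def test_empty_pixel_list_gives_empty_matrix(self):
        fm = extract_features(np.zeros((9, 9)), [])
        assert fm.values.shape == (0, len(FEATURE_NAMES))

    def test_out_of_bounds_pixel_rejected(self):
        with pytest.raises(ValueError):
            extract_features(np.zeros((9, 9)), [(9, 0)])

    def test_feature_vector_layout_fixed(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(20, 20))
        fm = extract_features(img, [(3, 3), (10, 10)])
        assert fm.values.shape == (2, 13)
        assert fm.feature_names == FEATURE_NAMES
        low = extract_features(img, [(3, 3)], feature_set="lowlevel")
        assert low.feature_names == LOW_LEVEL_FEATURE_NAMES
        np.testing.assert_allclose(low.values[0], fm.values[0, :2])

    @given(st.integers(0, 2 ** 31 - 1))
    def test_translation_consistency(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.normal(size=(24, 24))
        shifted = np.roll(img, (2, 3), axis=(0, 1))
        a = extract_features(img, [(10, 10)]).values
        b = extract_features(shifted, [(12, 13)]).values
        np.testing.assert_allclose(a, b, atol=1e-10)
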