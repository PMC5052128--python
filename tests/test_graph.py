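

import numpy as np
import pytest

import slicseg
from slicseg import (CorrespondenceSet, CosegParams, CrfParams, Volume,
                     build_correspondences, coseg_refine, crf_segment_slice,
                     intensity_pairwise, prob_pairwise_interimage,
                     prob_pairwise_slice, unary_cost)
from slicseg.graph import (_coseg_terms, _slice_edges, coseg_energy,
                           crf_energy)


def all_labelings(n):
    """(2**n, n) array of all binary labelings."""
    codes = np.arange(2 ** n, dtype=np.uint32)
    return ((codes[:, None] >> np.arange(n)[None, :]) & 1).astype(np.int8)


def enumerate_min(u0, u1, ei, ej, ew):
    """Exhaustive minimum energy via vectorised evaluation of all labelings."""
    n = len(u0)
    L = all_labelings(n)
    e = L @ u1 + (1 - L) @ u0
    if len(ei):
        e = e + (L[:, ei] != L[:, ej]) @ ew
    return float(e.min())


def crf_terms(p, img, spacing, params):
    u1 = np.asarray(unary_cost(p.ravel(), 1))
    u0 = np.asarray(unary_cost(p.ravel(), 0))
    ei, ej, ew = _slice_edges(p.shape, img, spacing, params.lambda1,
                              params.sigma1)
    return u0, u1, ei, ej, ew


class TestClosedForms:
    def test_unary_cost(self):
        assert unary_cost(0.5, 1) == pytest.approx(np.log(2), rel=1e-12)
        assert unary_cost(0.5, 0) == pytest.approx(np.log(2), rel=1e-12)
        assert unary_cost(1.0, 1) == pytest.approx(-np.log(1 - 1e-6), rel=1e-9)
        # clamped certainty: -log of the clamped complement, large but finite
        assert unary_cost(1.0, 0) == pytest.approx(
            -np.log(1.0 - (1.0 - 1e-6)), rel=1e-12)
        with pytest.raises(ValueError):
            unary_cost(1.5, 1)

    def test_intensity_pairwise(self):
        assert intensity_pairwise(5.0, 5.0, 1.0, 2.5) == pytest.approx(1.0)
        assert intensity_pairwise(0.0, 2.5, 1.0, 2.5) == pytest.approx(
            np.exp(-0.5), rel=1e-12)
        assert intensity_pairwise(0.0, 2.5, 2.0, 2.5) == pytest.approx(
            np.exp(-0.5) / 2, rel=1e-12)
        with pytest.raises(ValueError):
            intensity_pairwise(0.0, 1.0, 0.0, 2.5)

    def test_prob_pairwise_slice(self):
        assert prob_pairwise_slice(0.4, 0.4, 1.0, 0.005) == pytest.approx(1.0)
        assert prob_pairwise_slice(0.0, 0.005, 1.0, 0.005) == pytest.approx(
            np.exp(-0.5), rel=1e-12)
        assert prob_pairwise_slice(0.0, 0.015, 1.0, 0.005) == pytest.approx(
            np.exp(-4.5), rel=1e-12)

    def test_prob_pairwise_interimage_no_distance_factor(self):
        assert prob_pairwise_interimage(0.3, 0.3, 0.08) == pytest.approx(1.0)
        assert prob_pairwise_interimage(0.0, 0.08, 0.08) == pytest.approx(
            np.exp(-0.5), rel=1e-12)
        # extreme disagreement underflows gracefully to ~0, no error
        v = prob_pairwise_interimage(0.0, 1.0, 0.08)
        assert v == pytest.approx(np.exp(-78.125), abs=1e-30)


class TestCrfSlice:
    def test_unary_only_limit_is_thresholding(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, (6, 7))
        labels = crf_segment_slice(p, rng.normal(size=(6, 7)), (1, 1),
                                   CrfParams(lambda1=0.0))
        np.testing.assert_array_equal(labels, (p >= 0.5).astype(np.uint8))

    def test_uniformly_confident_slice_goes_all_foreground(self):
        p = np.full((5, 5), 0.9)
        labels = crf_segment_slice(p, np.zeros((5, 5)), (1, 1), CrfParams())
        assert labels.all()

    def test_matches_brute_force_on_3x3(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            p = rng.uniform(0, 1, (3, 3))
            img = rng.uniform(0, 10, (3, 3))
            params = CrfParams(lambda1=float(rng.uniform(0, 5)),
                               sigma1=float(rng.uniform(0.5, 4)))
            labels = crf_segment_slice(p, img, (1.0, 1.0), params)
            e = crf_energy(labels, p, img, (1.0, 1.0), params)
            best = enumerate_min(*crf_terms(p, img, (1.0, 1.0), params))
            assert e == pytest.approx(best, abs=1e-6)

    def test_hard_constraints_enforced(self):
        p = np.full((5, 5), 0.9)
        labels = crf_segment_slice(p, np.zeros((5, 5)), (1, 1),
                                   CrfParams(lambda1=0.0),
                                   hard_bg=[(2, 2)], hard_fg=[(0, 0)])
        assert labels[2, 2] == 0 and labels[0, 0] == 1

    def test_overlapping_hard_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            crf_segment_slice(np.full((3, 3), 0.5), np.zeros((3, 3)), (1, 1),
                              CrfParams(), hard_fg=[(1, 1)], hard_bg=[(1, 1)])

    def test_potts_symmetry_complement(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.02, 0.98, (4, 4))
        img = rng.uniform(0, 5, (4, 4))
        params = CrfParams(lambda1=2.0, sigma1=2.0)
        a = crf_segment_slice(p, img, (1, 1), params)
        b = crf_segment_slice(1.0 - p, img, (1, 1), params)
        np.testing.assert_array_equal(a, 1 - b)

    def test_energy_no_worse_than_trivial_labelings(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, (8, 8))
        img = rng.normal(size=(8, 8)) * 3
        params = CrfParams()
        labels = crf_segment_slice(p, img, (1, 0.8), params)
        e = crf_energy(labels, p, img, (1, 0.8), params)
        for trivial in (np.zeros((8, 8)), np.ones((8, 8)),
                        (p >= 0.5).astype(int)):
            assert e <= crf_energy(trivial, p, img, (1, 0.8), params) + 1e-6


def tiny_volume(data, spacing):
    return Volume(np.asarray(data, dtype=float), spacing)


class TestCorrespondences:
    def test_identical_grids_pair_same_index(self):
        vols = [tiny_volume(np.zeros((2, 3, 3)), (2, 1, 1)) for _ in range(2)]
        eye = np.eye(4)
        corr = build_correspondences(vols, [eye, eye])
        assert len(corr) == 18  # each voxel pairs with its counterpart, deduped
        np.testing.assert_array_equal(corr.pairs[:, 1], corr.pairs[:, 3])

    def test_subvoxel_shift_rounds_to_same_index(self):
        vols = [tiny_volume(np.zeros((2, 4, 4)), (2, 1, 1)) for _ in range(2)]
        shifted = np.eye(4)
        shifted[1, 3] = 0.4  # 0.4 of the in-plane pitch
        corr = build_correspondences(vols, [np.eye(4), shifted])
        np.testing.assert_array_equal(corr.pairs[:, 1], corr.pairs[:, 3])

    def test_pair_count_bound(self):
        rng = np.random.default_rng(0)
        vols = [tiny_volume(rng.normal(size=(2, 3, 4)), (2, 1, 1)),
                tiny_volume(rng.normal(size=(3, 3, 3)), (2, 1, 1))]
        t2 = np.eye(4)
        t2[0, 3] = 0.7
        corr = build_correspondences(vols, [np.eye(4), t2])
        assert len(corr) <= 24 + 27

    def test_single_volume_rejected(self):
        with pytest.raises(ValueError):
            build_correspondences([tiny_volume(np.zeros((2, 2, 2)), (2, 1, 1))],
                                  [np.eye(4)])

    def test_self_pairs_rejected(self):
        with pytest.raises(ValueError, match="self"):
            CorrespondenceSet(np.array([[0, 1, 0, 2]]), (8,))


class TestCosegRefine:
    def _random_instance(self, rng):
        vols = [tiny_volume(rng.uniform(0, 10, (2, 2, 2)), (2, 1, 1))
                for _ in range(2)]
        probs = [rng.uniform(0, 1, (2, 2, 2)) for _ in range(2)]
        corr = build_correspondences(vols, [np.eye(4), np.eye(4)])
        return vols, probs, corr

    def test_matches_brute_force_on_two_2x2x2_volumes(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            vols, probs, corr = self._random_instance(rng)
            params = CosegParams(lambda1=float(rng.uniform(0, 2)),
                                 lambda2=float(rng.uniform(0, 2)),
                                 lambda3=float(rng.uniform(0, 2)),
                                 sigma1=2.5, sigma2=0.3, sigma3=0.3)
            refined = coseg_refine(vols, probs, None, corr, params)
            labs = [r.data for r in refined]
            e = coseg_energy(labs, vols, probs, corr, params)
            u0, u1, ei, ej, ew, _ = _coseg_terms(vols, probs, corr, params)
            assert e == pytest.approx(enumerate_min(u0, u1, ei, ej, ew),
                                      abs=1e-6)

    def test_decoupling_limit_equals_per_slice_crf(self):
        rng = np.random.default_rng(11)
        vol = tiny_volume(rng.uniform(0, 10, (3, 5, 5)), (4, 1, 1))
        probs = rng.uniform(0, 1, (3, 5, 5))
        params = CosegParams(lambda2=0.0, lambda3=0.0)
        refined = coseg_refine([vol], [probs], None, None, params)[0]
        for s in range(3):
            expected = crf_segment_slice(probs[s], vol.data[s], (1, 1),
                                         params.crf)
            np.testing.assert_array_equal(refined.data[s], expected)

    def test_cross_view_coupling_repairs_degraded_probabilities(self):
        """A view with mid-confidence probabilities on alternate slices is
        pulled toward the clean view when the inter-volume term is on."""
        wins = 0
        for seed in range(10):
            spec = slicseg.PhantomSpec(grid_shape=(40, 40, 10),
                                       spacing=((1, 1, 4), (1, 1, 4)),
                                       noise_sd=0.0, slice_gain_sd=0.0,
                                       motion_shift_sd=0.0, seed=seed)
            study = slicseg.generate_study(spec, 2)
            truths = study.truths
            probs = []
            rng = np.random.default_rng(seed)
            for k in range(2):
                t = truths[k].data.astype(float)
                p = 0.98 * t + 0.02
                probs.append(p)
            # degrade view 1 on alternate slices: posterior shrunk toward 0.5
            for s in range(0, 10, 2):
                noise = rng.uniform(-0.08, 0.08, probs[1][s].shape)
                probs[1][s] = 0.5 + 0.12 * (probs[1][s] - 0.5) + noise
            corr = build_correspondences(study.volumes, study.view_transforms)
            base = CosegParams(sigma3=0.3)
            with_n3 = coseg_refine(study.volumes, probs, None, corr, base)
            no_n3 = coseg_refine(study.volumes, probs, None, corr,
                                 CosegParams(lambda3=0.0, sigma3=0.3))
            d_with = slicseg.dice(with_n3[1], truths[1])
            d_without = slicseg.dice(no_n3[1], truths[1])
            wins += d_with > d_without
        assert wins > 5

    def test_inconsistent_shapes_rejected(self):
        vol = tiny_volume(np.zeros((2, 2, 2)), (2, 1, 1))
        with pytest.raises(ValueError):
            coseg_refine([vol], [np.zeros((3, 2, 2))], None, None,
                         CosegParams())
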