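"""Weir-Cockerham F_ST and PCoA against independent oracles."""

import numpy as np
import pytest

import clonecross as cc
from clonecross.matrix import MISSING
from clonecross.structure import impute_centred_dosages, wc_components

from conftest import make_gm

M = MISSING


def hw_matrix(p, n, rng):
    return ((rng.random((n, p.size)) < p).astype(np.int8) + (rng.random((n, p.size)) < p).astype(np.int8))


@pytest.fixture
def toy_two_pop():
    # A: (0,1), (0,0); B: (1,2), (2,2) over two loci
    return make_gm([[0, 1], [0, 0], [1, 2], [2, 2]], sample_ids=["a1", "a2", "b1", "b2"])


class TestFstWc:
    def test_worked_toy_matches_symbolic_evaluation(self, toy_two_pop):
        # independent sympy evaluation of the WC84 components gives exactly 2/3
        theta = cc.fst_wc(toy_two_pop, ["a1", "a2"], ["b1", "b2"])
        assert theta == pytest.approx(2 / 3, abs=1e-12)

    def test_complete_fixation_is_one(self):
        calls = np.vstack([np.zeros((3, 50), np.int8), np.full((3, 50), 2, np.int8)])
        gm = make_gm(calls)
        ids = gm.sample_ids
        assert cc.fst_wc(gm, ids[:3], ids[3:]) == pytest.approx(1.0)

    def test_copied_group_theta_near_zero(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.1, 0.9, 500)
        block = hw_matrix(p, 50, rng)
        gm = make_gm(np.vstack([block, block]))
        ids = gm.sample_ids
        assert abs(cc.fst_wc(gm, ids[:50], ids[50:])) < 0.02

    def test_symmetry_and_allele_swap_invariance(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, size=(10, 40)).astype(np.int8)
        gm = make_gm(calls)
        a, b = gm.sample_ids[:5], gm.sample_ids[5:]
        theta = cc.fst_wc(gm, a, b)
        assert cc.fst_wc(gm, b, a) == pytest.approx(theta, abs=1e-12)
        swapped = calls.copy()
        swap_cols = rng.random(40) < 0.5
        swapped[:, swap_cols] = 2 - swapped[:, swap_cols]
        gm2 = make_gm(swapped)
        assert cc.fst_wc(gm2, a, b) == pytest.approx(theta, abs=1e-12)

    def test_identically_monomorphic_groups_undefined(self):
        gm = make_gm(np.zeros((6, 20), np.int8))
        assert np.isnan(cc.fst_wc(gm, gm.sample_ids[:3], gm.sample_ids[3:]))

    def test_recovers_divergence_ordering(self):
        # theta grows with the Balding-Nichols divergence of the second pop
        rng = np.random.default_rng(11)
        base = cc.generate_base_frequencies(2000, 0.2, 0.5, rng)
        thetas = []
        for F in (0.05, 0.2, 0.5):
            drifted = cc.generate_congener_frequencies(base, F, rng)
            calls = np.vstack([hw_matrix(base, 100, rng), hw_matrix(drifted, 100, rng)])
            gm = make_gm(calls)
            thetas.append(cc.fst_wc(gm, gm.sample_ids[:100], gm.sample_ids[100:]))
        assert thetas[0] < thetas[1] < thetas[2]


class TestFstSubsampled:
    def test_full_size_subsample_equals_point_estimate(self, toy_two_pop):
        res = cc.fst_subsampled(
            toy_two_pop, {"A": ["a1", "a2"], "B": ["b1", "b2"]}, n_sub=2, iterations=20, seed=0
        )[("A", "B")]
        assert np.allclose(res.iteration_values, res.point_fst)
        assert res.mean_fst == pytest.approx(res.point_fst)

    def test_disjoint_fixed_groups_mean_one(self):
        calls = np.vstack([np.zeros((6, 30), np.int8), np.full((6, 30), 2, np.int8)])
        gm = make_gm(calls)
        groups = {"A": gm.sample_ids[:6], "B": gm.sample_ids[6:]}
        res = cc.fst_subsampled(gm, groups, n_sub=3, iterations=50, seed=1)[("A", "B")]
        assert res.mean_fst == pytest.approx(1.0)

    def test_two_seeds_agree_within_monte_carlo_error(self):
        rng = np.random.default_rng(5)
        base = cc.generate_base_frequencies(200, 0.2, 0.5, rng)
        drifted = cc.generate_congener_frequencies(base, 0.2, rng)
        calls = np.vstack([hw_matrix(base, 8, rng), hw_matrix(drifted, 8, rng)])
        gm = make_gm(calls)
        groups = {"A": gm.sample_ids[:8], "B": gm.sample_ids[8:]}
        r1 = cc.fst_subsampled(gm, groups, n_sub=3, iterations=1000, seed=1)[("A", "B")]
        r2 = cc.fst_subsampled(gm, groups, n_sub=3, iterations=1000, seed=2)[("A", "B")]
        se = np.std(r1.iteration_values) / np.sqrt(r1.iterations)
        assert abs(r1.mean_fst - r2.mean_fst) < 2 * (se + np.std(r2.iteration_values) / np.sqrt(r2.iterations))

    def test_small_n_sub_rejected(self, toy_two_pop):
        with pytest.raises(ValueError):
            cc.fst_subsampled(toy_two_pop, {"A": ["a1"], "B": ["b1"]}, n_sub=1)

    def test_mean_equals_mean_of_defined_iterations(self, study_pipeline):
        gm1, groups = study_pipeline["gm1"], study_pipeline["groups1"]
        res = cc.fst_subsampled(
            gm1,
            {"wild": groups["wild"], "exsitu_adult": groups["exsitu_adult"]},
            n_sub=3,
            iterations=50,
            seed=3,
        )[("wild", "exsitu_adult")]
        vals = res.iteration_values
        assert res.mean_fst == pytest.approx(np.nanmean(vals))
        assert res.n_undefined == int(np.isnan(vals).sum())


class TestPcoa:
    def test_two_clone_clusters_put_everything_on_axis_one(self):
        g1, g2 = [0, 0, 2, 1, 0], [2, 1, 0, 1, 2]
        gm = make_gm([g1] * 3 + [g2] * 4)
        res = cc.pcoa(gm, k=2)
        assert res.percent_variation[0] == pytest.approx(100.0)
        coords = res.coordinates[:, 0]
        assert np.allclose(coords[:3], coords[0]) and np.allclose(coords[3:], coords[3])

    def test_identical_samples_degenerate(self):
        gm = make_gm([[0, 1, 2]] * 4)
        with pytest.warns(UserWarning, match="identical"):
            res = cc.pcoa(gm, k=2)
        assert res.coordinates.shape == (4, 0)

    def test_three_sample_hand_gram_oracle(self):
        # dosages (0,0), (1,1), (2,2): collinear points with pairwise squared
        # distances (2, 2, 8); hand eigendecomposition of the 3x3 double-
        # centred Gram matrix gives the single positive eigenvalue 4
        gm = make_gm([[0, 0], [1, 1], [2, 2]])
        res = cc.pcoa(gm, k=1)
        assert np.allclose(res.eigenvalues, [4.0], atol=1e-10)
        assert res.percent_variation[0] == pytest.approx(100.0)

    def test_gower_distance_reconstruction(self):
        from scipy.spatial.distance import pdist

        rng = np.random.default_rng(9)
        calls = rng.integers(0, 3, size=(8, 30)).astype(np.int8)
        gm = make_gm(calls)
        res = cc.pcoa(gm, k=7)  # all possible positive axes for 8 samples
        x = impute_centred_dosages(gm, gm.sample_ids)
        assert np.allclose(pdist(res.coordinates), pdist(x), atol=1e-8)

    def test_matches_scikit_bio(self):
        # independent implementation cross-check
        import warnings

        from scipy.spatial.distance import pdist, squareform
        from skbio import DistanceMatrix
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(21)
        calls = rng.integers(0, 3, size=(10, 25)).astype(np.int8)
        gm = make_gm(calls)
        res = cc.pcoa(gm, k=3)
        x = impute_centred_dosages(gm, gm.sample_ids)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = skbio_pcoa(DistanceMatrix(squareform(pdist(x)), ids=gm.sample_ids))
        ref_eig = np.sort(ref.eigvals.to_numpy())[::-1]
        k = min(len(res.eigenvalues), 3)
        assert np.allclose(res.eigenvalues[:k], ref_eig[:k], atol=1e-8)
        for axis in range(2):
            ours = res.coordinates[:, axis]
            theirs = ref.samples.iloc[:, axis].to_numpy()
            assert np.allclose(np.abs(ours), np.abs(theirs), atol=1e-6)
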