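"""Mendelian cross simulator: inheritance law, brood scoring, pair ranking."""

import numpy as np
import pytest
from scipy.stats import chisquare

import clonecross as cc
from clonecross.cross_sim import offspring_ho, pair_seed
from clonecross.matrix import MISSING

from conftest import make_gm

M = MISSING


class TestSimulateOffspring:
    def test_opposite_fixed_parents_force_heterozygotes(self):
        kids = cc.simulate_offspring(np.zeros(50, np.int8), np.full(50, 2, np.int8), 5)
        assert (kids == 1).all()

    def test_identical_homozygous_parents(self):
        kids = cc.simulate_offspring(np.zeros(50, np.int8), np.zeros(50, np.int8), 5)
        assert (kids == 0).all()

    def test_missing_parent_locus_begets_missing(self):
        p1 = np.array([0, M, 1], np.int8)
        p2 = np.array([M, 2, 1], np.int8)
        kids = cc.simulate_offspring(p1, p2, 10, seed=1)
        assert (kids[:, 0] == M).all() and (kids[:, 1] == M).all()
        assert (kids[:, 2] != M).all()

    def test_reproducible_from_seed(self):
        p = np.ones(100, np.int8)
        assert np.array_equal(
            cc.simulate_offspring(p, p, 5, seed=7), cc.simulate_offspring(p, p, 5, seed=7)
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cc.simulate_offspring(np.zeros(3, np.int8), np.zeros(3, np.int8), 0)
        with pytest.raises(cc.GenotypeError):
            cc.simulate_offspring(np.zeros(3, np.int8), np.zeros(4, np.int8), 1)

    def test_het_cross_segregates_one_two_one(self):
        # het x het at a single locus: genotype ratio 1:2:1
        p = np.array([1], np.int8)
        kids = cc.simulate_offspring(p, p, 10_000, seed=42)[:, 0]
        counts = [(kids == g).sum() for g in (0, 1, 2)]
        assert chisquare(counts, [2500, 5000, 2500]).pvalue > 0.001

    def test_offspring_never_violate_parents(self):
        # Mendelian impossibility of opposing homozygotes, across random pairs
        rng = np.random.default_rng(31)
        for _ in range(10):
            p1 = rng.integers(0, 3, 1000).astype(np.int8)
            p2 = rng.integers(0, 3, 1000).astype(np.int8)
            kids = cc.simulate_offspring(p1, p2, 3, seed=rng)
            gm = make_gm(np.vstack([p1, p2, kids]))
            for kid in gm.sample_ids[2:]:
                assert cc.violation_rate(gm, "s0", kid).rate == 0.0
                assert cc.violation_rate(gm, "s1", kid).rate == 0.0


class TestCrossMeanHo:
    def test_opposite_fixed_exactly_one(self):
        rep = cc.cross_mean_ho(np.zeros(100, np.int8), np.full(100, 2, np.int8), n=10, seed=0)
        assert rep.mean_ho == 1.0

    def test_identical_homozygous_exactly_zero(self):
        rep = cc.cross_mean_ho(np.zeros(100, np.int8), np.zeros(100, np.int8), n=10, seed=0)
        assert rep.mean_ho == 0.0

    def test_all_het_parents_near_half(self):
        L, n = 1000, 10
        p = np.ones(L, np.int8)
        rep = cc.cross_mean_ho(p, p, n=n, seed=3)
        assert abs(rep.mean_ho - 0.5) < 3 * np.sqrt(0.25 / (n * L))

    def test_mean_equals_mean_of_offspring_values(self):
        rng = np.random.default_rng(1)
        p1 = rng.integers(0, 3, 200).astype(np.int8)
        p2 = rng.integers(0, 3, 200).astype(np.int8)
        rep = cc.cross_mean_ho(p1, p2, n=7, seed=5)
        assert rep.mean_ho == pytest.approx(np.mean(rep.offspring_ho))

    @pytest.mark.parametrize(
        "g1, g2, expected",
        [(0, 2, 1.0), (0, 0, 0.0), (2, 2, 0.0), (1, 0, 0.5), (1, 2, 0.5), (1, 1, 0.5)],
    )
    def test_closed_form_per_category(self, g1, g2, expected):
        L = 400
        p1 = np.full(L, g1, np.int8)
        p2 = np.full(L, g2, np.int8)
        kids = cc.simulate_offspring(p1, p2, 50, seed=g1 * 3 + g2)
        observed = offspring_ho(kids).mean()
        tol = 0.0 if expected in (0.0, 1.0) else 4 * np.sqrt(0.25 / (50 * L))
        assert abs(observed - expected) <= tol


class TestAllCrosses:
    def test_study_composition_yields_130_pairs(self):
        # 17 genets: 1 known female, 4 known males, 12 unknown
        # C(17,2) - C(4,2) = 136 - 6 = 130
        rng = np.random.default_rng(2)
        genotypes = {f"g{i:02d}": rng.integers(0, 3, 20).astype(np.int8) for i in range(17)}
        sexes = {"g00": "female", "g01": "male", "g02": "male", "g03": "male", "g04": "male"}
        cm = cc.all_crosses(genotypes, sexes, n=2, seed=0)
        assert sum(r.permissible for r in cm.reports.values()) == 130

    def test_all_unknown_three_genets(self):
        g = {k: np.zeros(10, np.int8) for k in "abc"}
        cm = cc.all_crosses(g, {}, n=1)
        assert sum(r.permissible for r in cm.reports.values()) == 3

    def test_two_known_males_no_pairs(self):
        g = {"m1": np.zeros(10, np.int8), "m2": np.zeros(10, np.int8)}
        cm = cc.all_crosses(g, {"m1": "male", "m2": "male"}, n=1)
        assert sum(r.permissible for r in cm.reports.values()) == 0
        assert cm.mean_ho.isna().all().all()

    def test_matrix_symmetric_empty_diagonal(self):
        rng = np.random.default_rng(3)
        g = {k: rng.integers(0, 3, 30).astype(np.int8) for k in "abcd"}
        cm = cc.all_crosses(g, {}, n=3, seed=1)
        m = cm.mean_ho.to_numpy(float)
        assert np.isnan(np.diag(m)).all()
        assert np.allclose(m, m.T, equal_nan=True)

    def test_pair_seed_stable_under_collection_growth(self):
        rng = np.random.default_rng(4)
        g = {k: rng.integers(0, 3, 50).astype(np.int8) for k in "abcd"}
        before = cc.all_crosses(g, {}, n=5, seed=9)
        g["e"] = rng.integers(0, 3, 50).astype(np.int8)
        after = cc.all_crosses(g, {}, n=5, seed=9)
        for pair, rep in before.reports.items():
            assert np.array_equal(rep.offspring_ho, after.reports[pair].offspring_ho)

    def test_pair_seed_symmetric(self):
        assert pair_seed(5, "x", "y") == pair_seed(5, "y", "x")


class TestRanking:
    def test_single_pair_ranked_first(self):
        g = {"a": np.zeros(20, np.int8), "b": np.full(20, 2, np.int8)}
        cm = cc.all_crosses(g, {}, n=2)
        table = cc.rank_pairs(cm)
        assert len(table) == 1 and table.iloc[0]["rank"] == 1

    def test_hand_sorted_order_with_ties(self):
        g = {
            "a": np.zeros(40, np.int8),
            "b": np.full(40, 2, np.int8),
            "c": np.zeros(40, np.int8),
        }
        cm = cc.all_crosses(g, {}, n=2, seed=0)
        table = cc.rank_pairs(cm)
        # a-b and b-c both force all-het broods (mean 1.0); a-c gives 0.0;
        # the tie breaks on sorted pair ids
        assert table["mean_offspring_ho"].tolist() == [1.0, 1.0, 0.0]
        assert (table.iloc[0]["parent_a"], table.iloc[0]["parent_b"]) == ("a", "b")

    def test_highly_heterozygous_genet_dominates_top_ranks(self):
        rng = np.random.default_rng(37)
        g = {f"g{i}": np.zeros(200, np.int8) for i in range(5)}
        g["hot"] = np.ones(200, np.int8)  # fully heterozygous genet
        cm = cc.all_crosses(g, {}, n=10, seed=2)
        table = cc.rank_pairs(cm, top=5)
        assert all("hot" in (row.parent_a, row.parent_b) for row in table.itertuples())

    def test_group_summary_means(self):
        g = {"a": np.zeros(30, np.int8), "b": np.full(30, 2, np.int8)}
        cm = cc.all_crosses(g, {}, n=2)
        summary = cc.group_summary(cm, {"a": "X", "b": "Y"})
        assert summary.loc[0, "mean_offspring_ho"] == 1.0
        assert summary.loc[0, "n_pairs"] == 1
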