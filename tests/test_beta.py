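import numpy as np
import pandas as pd
import pytest
import skbio
from skbio import TreeNode
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.distance import mantel as skbio_mantel
from skbio.stats.ordination import pcoa as skbio_pcoa

from conftest import random_table, random_tree
from microeuk.beta import (
    anosim,
    bray_curtis,
    mantel,
    pcoa,
    unweighted_unifrac,
    upgma,
)
from microeuk.io import CountTable, distance_matrix
from oracles import naive_bray_curtis, naive_unweighted_unifrac


def table(mat, otus, samples):
    return CountTable(pd.DataFrame(mat, index=otus, columns=samples))


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        ct = table([[3, 3], [1, 1]], ["a", "b"], ["x", "y"])
        assert bray_curtis(ct)["x", "y"] == pytest.approx(0.0)

    def test_disjoint_samples_one(self):
        ct = table([[3, 0], [0, 5]], ["a", "b"], ["x", "y"])
        assert bray_curtis(ct)["x", "y"] == pytest.approx(1.0)

    def test_sqrt_transform_example(self):
        # rel abundances (1,0) vs (0.25,0.75): (0.5+sqrt(.75))/(1.5+sqrt(.75))
        ct = table([[4, 1], [0, 3]], ["a", "b"], ["x", "y"])
        expected = (0.5 + np.sqrt(0.75)) / (1.5 + np.sqrt(0.75))
        assert bray_curtis(ct)["x", "y"] == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(0.5774, abs=1e-4)

    def test_zero_sum_sample_rejected(self):
        ct = table([[1, 0], [1, 0]], ["a", "b"], ["x", "y"])
        with pytest.raises(ValueError):
            bray_curtis(ct)

    def test_matches_naive_reference(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            ct = random_table(rng)
            dm = bray_curtis(ct)
            cols = {s: ct.sample(s).tolist() for s in ct.sample_ids}
            for i, a in enumerate(ct.sample_ids):
                for b in ct.sample_ids[i + 1:]:
                    assert dm[a, b] == pytest.approx(
                        naive_bray_curtis(cols[a], cols[b]), rel=1e-10, abs=1e-12
                    )


class TestUnweightedUnifrac:
    def test_identical_presence_zero(self):
        tree = TreeNode.read(["((A:1,B:1):1,C:2);"])
        ct = table([[1, 2], [1, 1], [0, 0]], ["A", "B", "C"], ["x", "y"])
        assert unweighted_unifrac(ct, tree)["x", "y"] == pytest.approx(0.0)

    def test_disjoint_star_tree_one(self):
        tree = TreeNode.read(["(A:1,B:1,C:1,D:1);"])
        ct = table([[1, 0], [1, 0], [0, 1], [0, 1]], list("ABCD"), ["x", "y"])
        assert unweighted_unifrac(ct, tree)["x", "y"] == pytest.approx(1.0)

    def test_branch_enumeration_example(self):
        # unique = B(1) + C(2) = 3; union = 5 -> 0.6
        tree = TreeNode.read(["((A:1,B:1):1,C:2);"])
        ct = table([[1, 1], [1, 0], [0, 1]], ["A", "B", "C"], ["x", "y"])
        assert unweighted_unifrac(ct, tree)["x", "y"] == pytest.approx(0.6)

    def test_matches_naive_and_skbio(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            ct = random_table(rng, n_otus=12, n_samples=4)
            tree = random_tree(rng, ct.otu_ids)
            dm = unweighted_unifrac(ct, tree)
            presence = {s: [o for o in ct.otu_ids if ct.counts.loc[o, s] > 0]
                        for s in ct.sample_ids}
            for i, a in enumerate(ct.sample_ids):
                for b in ct.sample_ids[i + 1:]:
                    assert dm[a, b] == pytest.approx(
                        naive_unweighted_unifrac(presence[a], presence[b], tree),
                        rel=1e-10, abs=1e-12,
                    )
            skbio_dm = skbio.diversity.beta_diversity(
                "unweighted_unifrac", ct.counts.to_numpy().T,
                ids=ct.sample_ids, taxa=ct.otu_ids, tree=tree,
            )
            np.testing.assert_allclose(dm.data, skbio_dm.data, atol=1e-10)


class TestUpgma:
    def test_two_samples_join_at_half_distance(self):
        dm = distance_matrix([[0, 0.4], [0.4, 0]], ["x", "y"])
        tree = TreeNode.read([upgma(dm)])
        assert {t.name: t.length for t in tree.tips()} == {"x": 0.2, "y": 0.2}

    def test_closest_pair_merges_first(self):
        d = np.array([[0, 0.2, 0.8], [0.2, 0, 0.9], [0.8, 0.9, 0]])
        tree = TreeNode.read([upgma(distance_matrix(d, ["a", "b", "c"]))])
        # a and b must be siblings
        a = [t for t in tree.tips() if t.name == "a"][0]
        assert {t.name for t in a.parent.tips()} == {"a", "b"}

    def test_ultrametric_distances_recovered(self):
        # heights: (a,b) at 0.1, ((a,b),c) at 0.3
        d = np.array([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]])
        tree = TreeNode.read([upgma(distance_matrix(d, ["a", "b", "c"]))])
        tip = {t.name: t for t in tree.tips()}
        assert tip["a"].length == pytest.approx(0.1)
        assert tip["c"].length == pytest.approx(0.3)
        # cophenetic distance a-c reproduces input
        assert tree.tip_tip_distances(["a", "c"])["a", "c"] == pytest.approx(0.6)

    def test_heights_monotone_root_to_tip(self):
        rng = np.random.default_rng(8)
        n = 8
        pts = rng.normal(size=(n, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        tree = TreeNode.read([upgma(distance_matrix(d, [f"s{i}" for i in range(n)]))])
        for node in tree.traverse(include_self=False):
            assert node.length >= -1e-12


class TestPcoa:
    def test_two_samples_closed_form(self):
        dm = distance_matrix([[0, 1.0], [1.0, 0]], ["x", "y"])
        coords, evals = pcoa(dm, k=1)
        assert sorted(np.abs(coords["PC1"])) == pytest.approx([0.5, 0.5])
        assert evals[0] == pytest.approx(0.5)

    def test_equilateral_triple_equal_eigenvalues(self):
        d = np.ones((3, 3)) - np.eye(3)
        _, evals = pcoa(distance_matrix(d, list("abc")), k=2)
        assert evals[0] == pytest.approx(evals[1])
        assert evals[0] > 0

    def test_euclidean_distances_reconstructed(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(7, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = distance_matrix(d, [f"s{i}" for i in range(7)])
        coords, evals = pcoa(dm, k=4)
        rec = np.linalg.norm(coords.to_numpy()[:, None] - coords.to_numpy()[None, :],
                             axis=-1)
        np.testing.assert_allclose(rec, d, atol=1e-8)

    def test_agrees_with_skbio(self):
        rng = np.random.default_rng(13)
        ct = random_table(rng, n_otus=15, n_samples=6)
        dm = bray_curtis(ct)
        coords, evals = pcoa(dm, k=2)
        ref = skbio_pcoa(skbio.DistanceMatrix(dm.data, ids=list(dm.ids)))
        np.testing.assert_allclose(
            evals[:2], ref.eigvals.to_numpy()[:2], atol=1e-8
        )
        # coordinates agree up to per-axis sign
        for ax in range(2):
            ours = coords.to_numpy()[:, ax]
            theirs = ref.samples.to_numpy()[:, ax]
            assert min(np.abs(ours - theirs).max(),
                       np.abs(ours + theirs).max()) < 1e-8


class TestAnosim:
    def test_perfect_separation_r_one(self):
        d = np.array(
            [[0, 0.1, 0.9, 0.9],
             [0.1, 0, 0.9, 0.9],
             [0.9, 0.9, 0, 0.1],
             [0.9, 0.9, 0.1, 0]]
        )
        r, p = anosim(distance_matrix(d, list("abcd")), ["g1", "g1", "g2", "g2"],
                      n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_complete_ties_r_zero(self):
        d = np.ones((4, 4)) - np.eye(4)
        r, _ = anosim(distance_matrix(d, list("abcd")), ["g1", "g1", "g2", "g2"],
                      n_perm=99, seed=0)
        assert r == pytest.approx(0.0)

    def test_statistic_matches_skbio(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            n = 10
            pts = rng.normal(size=(n, 3))
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            ids = [f"s{i}" for i in range(n)]
            groups = ["a"] * 5 + ["b"] * 5
            r, _ = anosim(distance_matrix(d, ids), groups, n_perm=9, seed=0)
            ref = skbio_anosim(skbio.DistanceMatrix(d, ids=ids), groups,
                               permutations=9)
            assert r == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_seeded_p_reproducible(self):
        rng = np.random.default_rng(19)
        d = np.abs(rng.normal(size=(8, 8)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        dm = distance_matrix(d, [f"s{i}" for i in range(8)])
        groups = ["a"] * 4 + ["b"] * 4
        out1 = anosim(dm, groups, n_perm=499, seed=123)
        out2 = anosim(dm, groups, n_perm=499, seed=123)
        assert out1 == out2

    def test_singleton_group_rejected(self):
        d = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValueError):
            anosim(distance_matrix(d, list("abc")), ["a", "a", "b"], n_perm=9, seed=0)


class TestMantel:
    @staticmethod
    def random_dm(rng, n=8):
        d = np.abs(rng.normal(size=(n, n)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        return distance_matrix(d, [f"s{i}" for i in range(n)])

    def test_scaled_matrix_perfect_correlation(self):
        rng = np.random.default_rng(23)
        dm1 = self.random_dm(rng)
        dm2 = distance_matrix(2 * dm1.data, list(dm1.ids))
        r, p = mantel(dm1, dm2, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p < 0.05

    def test_constant_matrix_flagged(self):
        rng = np.random.default_rng(29)
        dm1 = self.random_dm(rng)
        dm2 = distance_matrix(np.ones((8, 8)) - np.eye(8), list(dm1.ids))
        r, p = mantel(dm1, dm2, n_perm=9, seed=0)
        assert np.isnan(r) and np.isnan(p)

    def test_statistic_matches_skbio(self):
        rng = np.random.default_rng(31)
        dm1, dm2 = self.random_dm(rng), self.random_dm(rng)
        r, _ = mantel(dm1, dm2, n_perm=9, seed=0)
        ref_r, _, _ = skbio_mantel(
            skbio.DistanceMatrix(dm1.data, ids=list(dm1.ids)),
            skbio.DistanceMatrix(dm2.data, ids=list(dm2.ids)),
            permutations=9,
        )
        assert r == pytest.approx(ref_r, abs=1e-12)

    def test_size_mismatch_rejected(self):
        rng = np.random.default_rng(37)
        with pytest.raises(ValueError):
            mantel(self.random_dm(rng, 8), self.random_dm(rng, 6), n_perm=9, seed=0)
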