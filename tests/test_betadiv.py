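"""UniFrac, PCoA and ANOSIM against independent oracles."""

import io
from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from refotu.betadiv import anosim, group_distance_summary, pcoa, unifrac
from refotu.mapping import AbundanceTable
from refotu.phylo import PhyloTree


def random_tree_newick(labels, rng):
    """Random binary tree with uniform edge lengths, built bottom-up."""
    nodes = [f"{l}:{rng.uniform(0.05, 0.4):.4f}" for l in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        merged = (f"({nodes[i]},{nodes[j]}):{rng.uniform(0.05, 0.4):.4f}")
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return f"({nodes[0]},{nodes[1]});"


def _table(counts, groups=None):
    samples = counts.columns
    if groups is None:
        groups = pd.Series(["HC"] * len(samples), index=samples)
    return AbundanceTable(counts, groups, depth=int(counts.sum(axis=0).max()))


class TestUnifrac:
    def test_identical_columns_give_zero(self):
        pt = PhyloTree.from_newick("((A:1,B:2):0.5,(C:1,D:1):0.5);")
        counts = pd.DataFrame({"s1": [3, 1, 2, 0], "s2": [3, 1, 2, 0]},
                              index=list("ABCD"))
        for weighted in (False, True):
            d = unifrac(_table(counts), pt, weighted=weighted)
            assert d.loc["s1", "s2"] == 0.0

    def test_disjoint_star_subtrees_reach_one(self):
        pt = PhyloTree.from_newick("(A:1,B:1,C:1,D:1);")
        counts = pd.DataFrame({"s1": [5, 5, 0, 0], "s2": [0, 0, 5, 5]},
                              index=list("ABCD"))
        d = unifrac(_table(counts), pt, weighted=False)
        assert d.loc["s1", "s2"] == 1.0

    def test_matches_skbio_on_random_instances(self):
        from skbio.diversity import beta_diversity
        from skbio.tree import TreeNode
        rng = np.random.default_rng(0)
        labels = [f"L{i}" for i in range(8)]
        for rep in range(5):
            newick = random_tree_newick(labels, rng)
            counts = pd.DataFrame(
                rng.integers(0, 30, size=(8, 4)), index=labels,
                columns=[f"s{k}" for k in range(4)])
            counts.iloc[:, 0] += 1  # avoid empty samples
            pt = PhyloTree.from_newick(newick)
            sk_tree = TreeNode.read(io.StringIO(newick))
            mat = counts.T.to_numpy()
            for weighted in (False, True):
                mine = unifrac(_table(counts), pt, weighted=weighted)
                metric = "weighted_unifrac" if weighted else "unweighted_unifrac"
                kwargs = {"normalized": True} if weighted else {}
                ref = beta_diversity(metric, mat, ids=list(counts.columns),
                                     taxa=labels, tree=sk_tree, **kwargs)
                np.testing.assert_allclose(mine.to_numpy(), ref.data,
                                           atol=1e-10)

    def test_unweighted_satisfies_triangle_inequality(self):
        rng = np.random.default_rng(1)
        labels = [f"L{i}" for i in range(10)]
        pt = PhyloTree.from_newick(random_tree_newick(labels, rng))
        counts = pd.DataFrame(rng.integers(0, 5, size=(10, 6)), index=labels,
                              columns=[f"s{k}" for k in range(6)])
        counts += (counts.sum(axis=1) == 0).astype(int).to_numpy()[:, None]
        d = unifrac(_table(counts), pt, weighted=False).to_numpy()
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_missing_leaf_is_an_error(self):
        pt = PhyloTree.from_newick("(A:1,B:1);")
        counts = pd.DataFrame({"s1": [1, 1], "s2": [1, 0]}, index=["A", "Z"])
        with pytest.raises(ValueError, match="Z"):
            unifrac(_table(counts), pt)


class TestPcoa:
    def test_planar_points_reconstruct_distances(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.3, 0.8]])
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        res = pcoa(pd.DataFrame(d, index=list("abcd"), columns=list("abcd")))
        coords = res.coordinates.to_numpy()[:, :2]
        rec = np.linalg.norm(coords[:, None] - coords[None], axis=2)
        np.testing.assert_allclose(rec, d, atol=1e-9)
        assert res.negative_eigenvalue_mass < 1e-9

    def test_zero_matrix_is_degenerate(self):
        d = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        res = pcoa(d)
        assert res.degenerate and res.explained[0] == 0.0

    def test_eigenvalues_match_skbio(self):
        from skbio import DistanceMatrix
        from skbio.stats.ordination import pcoa as sk_pcoa
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 4))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        ids = [f"s{i}" for i in range(10)]
        mine = pcoa(pd.DataFrame(d, index=ids, columns=ids))
        ref = sk_pcoa(DistanceMatrix(d, ids))
        np.testing.assert_allclose(
            mine.explained[:4], ref.proportion_explained.to_numpy()[:4],
            atol=1e-8)

    def test_asymmetric_input_rejected(self):
        d = pd.DataFrame([[0, 1.0], [2.0, 0]], index=["a", "b"],
                         columns=["a", "b"])
        with pytest.raises(ValueError):
            pcoa(d)


def _toy_distance(rng, n, sep=0.0):
    """Symmetric distances; first half vs second half separated by `sep`."""
    base = rng.uniform(0.2, 0.4, size=(n, n))
    d = (base + base.T) / 2
    d[: n // 2, n // 2:] += sep
    d[n // 2:, : n // 2] += sep
    np.fill_diagonal(d, 0.0)
    ids = [f"s{i}" for i in range(n)]
    labels = pd.Series(["A"] * (n // 2) + ["B"] * (n - n // 2), index=ids)
    return pd.DataFrame(d, index=ids, columns=ids), labels


class TestAnosim:
    def test_perfect_separation_has_r_one(self):
        rng = np.random.default_rng(3)
        d, labels = _toy_distance(rng, 8, sep=1.0)
        r, _p = anosim(d, labels, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_exhaustive_permutation_oracle_on_six_samples(self):
        rng = np.random.default_rng(4)
        d, labels = _toy_distance(rng, 6, sep=0.15)
        from scipy.stats import rankdata
        mat = d.to_numpy()
        iu = np.triu_indices(6, k=1)
        ranks = rankdata(mat[iu])
        m = len(ranks)

        def r_of(lv):
            within = np.array([lv[i] == lv[j] for i, j in zip(*iu)])
            return (ranks[~within].mean() - ranks[within].mean()) / (m / 2)

        obs = r_of(labels.to_numpy())
        tail = sum(r_of(np.array(p)) >= obs - 1e-12
                   for p in permutations(labels.to_numpy()))
        import math
        expected_p = tail / math.factorial(6)
        r, p = anosim(d, labels, exhaustive=True)
        assert r == pytest.approx(obs)
        assert p == pytest.approx(expected_p)

    def test_r_invariant_under_monotone_distance_transform(self):
        rng = np.random.default_rng(5)
        d, labels = _toy_distance(rng, 8, sep=0.1)
        r1, _ = anosim(d, labels, n_perm=9, seed=1)
        r2, _ = anosim(d ** 2, labels, n_perm=9, seed=1)
        assert r1 == pytest.approx(r2)
        assert -1.0 <= r1 <= 1.0

    def test_matches_skbio_statistic(self):
        from skbio import DistanceMatrix
        from skbio.stats.distance import anosim as sk_anosim
        rng = np.random.default_rng(6)
        d, labels = _toy_distance(rng, 10, sep=0.1)
        r, _ = anosim(d, labels, n_perm=9, seed=0)
        ref = sk_anosim(DistanceMatrix(d.to_numpy(), list(d.index)),
                        labels.to_numpy(), permutations=9)
        assert r == pytest.approx(ref["test statistic"])

    def test_group_size_validation(self):
        rng = np.random.default_rng(7)
        d, labels = _toy_distance(rng, 4)
        labels.iloc[:] = ["A", "A", "A", "B"]
        with pytest.raises(ValueError):
            anosim(d, labels, n_perm=9)


class TestGroupDistances:
    def test_all_zero_distances_have_zero_means(self):
        ids = [f"s{i}" for i in range(6)]
        d = pd.DataFrame(np.zeros((6, 6)), index=ids, columns=ids)
        labels = pd.Series(["HC"] * 3 + ["MS"] * 3, index=ids)
        out = group_distance_summary(d, labels, n_perm=9)
        assert (out["mean"] == 0).all()

    def test_pair_class_sizes_for_study_design(self):
        n_hc, n_ms = 40, 20
        ids = [f"h{i}" for i in range(n_hc)] + [f"m{i}" for i in range(n_ms)]
        rng = np.random.default_rng(8)
        base = rng.uniform(size=(60, 60))
        d = pd.DataFrame((base + base.T) / 2 - np.diag(np.diag(base)),
                         index=ids, columns=ids)
        d.values[np.diag_indices(60)] = 0.0
        labels = pd.Series(["HC"] * n_hc + ["MS"] * n_ms, index=ids)
        out = group_distance_summary(d, labels, n_perm=9)
        assert out.loc["HC-HC", "n_pairs"] == 40 * 39 // 2   # 780
        assert out.loc["HC-MS", "n_pairs"] == 40 * 20        # 800
        assert out.loc["MS-MS", "n_pairs"] == 20 * 19 // 2   # 190

    def test_planted_case_dispersion_is_detected(self):
        rng = np.random.default_rng(9)
        n = 16
        ids = [f"s{i}" for i in range(n)]
        base = rng.uniform(0.1, 0.2, size=(n, n))
        d = (base + base.T) / 2
        d[n // 2:, n // 2:] += 0.3   # MS block more dispersed
        np.fill_diagonal(d, 0.0)
        labels = pd.Series(["HC"] * (n // 2) + ["MS"] * (n // 2), index=ids)
        out = group_distance_summary(
            pd.DataFrame(d, index=ids, columns=ids), labels, n_perm=199,
            seed=3)
        assert out.loc["MS-MS", "mean"] > out.loc["HC-HC", "mean"]
        assert out.loc["HC-HC", "p_vs_MS-MS"] < 0.05
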