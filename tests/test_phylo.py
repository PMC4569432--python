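"""Neighbor joining exactness, Newick round-trips and bootstrap supports."""

import numpy as np
import pandas as pd
import pytest

from refotu.phylo import (PhyloTree, bootstrap_support, mafft_align, nj_tree,
                          p_distance_matrix, pairwise_identity)

from conftest import mutate, random_dna


def leaf_path_lengths(ptree: PhyloTree) -> pd.DataFrame:
    """Pairwise patristic distances, independent of rooting."""
    pdm = ptree.tree.phylogenetic_distance_matrix()
    taxa = sorted(ptree.tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    labels = [t.label for t in taxa]
    return pd.DataFrame(d, index=labels, columns=labels)


def random_additive_instance(n_taxa, rng):
    """Random binary tree -> its exact leaf distance matrix (additive)."""
    import dendropy
    labels = [f"T{i:02d}" for i in range(n_taxa)]
    taxa = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=taxa.get_taxon(l)) for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = dendropy.Node()
        for child in (nodes[i], nodes[j]):
            child.edge.length = float(rng.uniform(0.05, 0.5))
            parent.add_child(child)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = dendropy.Node()
    for child in nodes:
        child.edge.length = float(rng.uniform(0.05, 0.5))
        root.add_child(child)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    ptree = PhyloTree(tree=tree)
    return ptree, leaf_path_lengths(ptree)


class TestPairwiseIdentity:
    def test_self_identity_and_symmetry(self):
        rng = np.random.default_rng(0)
        seqs = [(f"s{i}", random_dna(rng, 200)) for i in range(4)]
        m = pairwise_identity(seqs)
        assert (np.diag(m) == 1.0).all()
        np.testing.assert_allclose(m, m.T)

    def test_engineered_divergence(self):
        rng = np.random.default_rng(1)
        a = random_dna(rng, 100)
        b = mutate(a, 4, rng)
        m = pairwise_identity([("a", a), ("b", b)])
        assert m.loc["a", "b"] == pytest.approx(0.96)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity([("a", "ACGT"), ("b", "")])


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        d = pd.DataFrame([[0.0, 0.3], [0.3, 0.0]], index=["A", "B"],
                         columns=["A", "B"])
        ptree = nj_tree(d)
        lengths = [e.length for e in ptree.tree.preorder_edge_iter()
                   if e.length]
        assert lengths == [pytest.approx(0.3)]

    def test_three_taxon_closed_form(self):
        d = pd.DataFrame([[0.0, 0.3, 0.4], [0.3, 0.0, 0.5], [0.4, 0.5, 0.0]],
                         index=list("ABC"), columns=list("ABC"))
        ptree = nj_tree(d)
        by_label = {leaf.taxon.label: leaf.edge.length
                    for leaf in ptree.tree.leaf_node_iter()}
        assert by_label["A"] == pytest.approx((0.3 + 0.4 - 0.5) / 2)
        assert by_label["B"] == pytest.approx((0.3 + 0.5 - 0.4) / 2)
        assert by_label["C"] == pytest.approx((0.4 + 0.5 - 0.3) / 2)

    @pytest.mark.parametrize("n_taxa", [5, 8, 12])
    def test_additive_matrices_recovered_exactly(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        for _rep in range(3):
            truth, d = random_additive_instance(n_taxa, rng)
            recon = nj_tree(d)
            assert recon.bipartitions() == truth.bipartitions()
            np.testing.assert_allclose(
                leaf_path_lengths(recon).to_numpy(), d.to_numpy(), atol=1e-9)
            assert recon.negative_branch_deficit == 0.0

    def test_topology_agrees_with_skbio(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as sk_nj
        rng = np.random.default_rng(13)
        _truth, d = random_additive_instance(7, rng)
        mine = nj_tree(d)
        sk = sk_nj(DistanceMatrix(d.to_numpy(), list(d.index)))
        sk_p = PhyloTree.from_newick(str(sk))
        assert mine.bipartitions() == sk_p.bipartitions()

    def test_invalid_matrices_rejected(self):
        bad = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]], index=["A", "B"],
                           columns=["A", "B"])
        with pytest.raises(ValueError):
            nj_tree(bad)
        nan = pd.DataFrame([[0.0, np.nan], [np.nan, 0.0]], index=["A", "B"],
                           columns=["A", "B"])
        with pytest.raises(ValueError):
            nj_tree(nan)


class TestNewick:
    def test_round_trip_is_byte_stable(self):
        rng = np.random.default_rng(21)
        _truth, d = random_additive_instance(6, rng)
        ptree = nj_tree(d)
        text1 = ptree.newick()
        text2 = PhyloTree.from_newick(text1).newick()
        assert text1 == text2


def clade_alignment(n_cols=60, wobble=0):
    """Alignment whose every column separates {A,B} from {C,D}."""
    rng = np.random.default_rng(3)
    rows = {"A": [], "B": [], "C": [], "D": []}
    for _ in range(n_cols):
        rows["A"].append("A")
        rows["B"].append("A")
        rows["C"].append("T")
        rows["D"].append("T")
    aln = {k: "".join(v) for k, v in rows.items()}
    # a little within-clade signal so distances are not all ties
    aln["B"] = "C" + aln["B"][1:]
    aln["D"] = "G" + aln["D"][1:]
    return list(aln.items())


class TestBootstrap:
    def test_invariant_split_gets_full_support(self):
        aln = clade_alignment()
        t = bootstrap_support(aln, n_reps=50, seed=1)
        assert set(t.supports.values()) == {50}

    def test_same_seed_same_supports(self):
        rng = np.random.default_rng(5)
        base = {f"L{i}": random_dna(rng, 80) for i in range(6)}
        aln = [(k, v) for k, v in base.items()]
        t1 = bootstrap_support(aln, n_reps=30, seed=7)
        t2 = bootstrap_support(aln, n_reps=30, seed=7)
        assert t1.supports == t2.supports

    def test_supports_invariant_to_row_order(self):
        aln = clade_alignment()
        t1 = bootstrap_support(aln, n_reps=40, seed=2)
        t2 = bootstrap_support(list(reversed(aln)), n_reps=40, seed=2)
        assert t1.supports == t2.supports

    def test_short_alignment_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support([("A", "G"), ("B", "T")], n_reps=5)


class TestPdistance:
    def test_gap_columns_excluded_pairwise(self):
        aln = [("A", "AC-GT"), ("B", "ACCGT"), ("C", "TTCGA")]
        d = p_distance_matrix(aln)
        assert d.loc["A", "B"] == 0.0            # 4 shared columns, all equal
        assert d.loc["A", "C"] == pytest.approx(3 / 4)
        assert d.loc["B", "C"] == pytest.approx(3 / 5)


def test_mafft_alignment_preserves_sequences():
    rng = np.random.default_rng(9)
    base = random_dna(rng, 150)
    seqs = [("s1", base), ("s2", mutate(base, 10, rng)),
            ("s3", mutate(base, 20, rng))]
    aln = mafft_align(seqs)
    assert [n for n, _ in aln] == ["s1", "s2", "s3"]
    assert len({len(s) for _n, s in aln}) == 1
    for (name, seq), (_n2, row) in zip(seqs, aln):
        assert row.replace("-", "") == seq
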