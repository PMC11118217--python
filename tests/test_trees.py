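import math

import numpy as np
import pytest

from oracles import ward_d2_reference

from crystkit.alignment import DistanceMatrix, Msa
from crystkit.errors import NewickParseError
from crystkit.synthetic_data import gen_additive_matrix
from crystkit.trees import (
    NucDistanceModel,
    bootstrap_supports,
    cut_dendrogram,
    dendrogram_to_tree,
    nj_tree,
    nuc_distance,
    path_length,
    read_newick,
    tree_bipartitions,
    ward_cluster,
    write_newick,
)


def random_dissimilarity(rng, n, scale=50.0):
    M = rng.uniform(1, scale, size=(n, n))
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0)
    return DistanceMatrix(labels=[f"L{i}" for i in range(n)], values=M)


def two_blob_matrix(n_a=4, n_b=4, within=1.0, between=100.0):
    n = n_a + n_b
    M = np.full((n, n), between)
    M[:n_a, :n_a] = within
    M[n_a:, n_a:] = within
    np.fill_diagonal(M, 0)
    labels = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    return DistanceMatrix(labels=labels, values=M)


class TestWardCluster:
    def test_two_leaves(self):
        D = DistanceMatrix(labels=["A", "B"],
                           values=np.array([[0, 10], [10, 0]], float))
        dend = ward_cluster(D)
        assert dend.merges == [(0, 1, 10.0, 2)]

    def test_matches_naive_reference(self, rng):
        """Merge heights agree with a from-scratch greedy Lance-Williams
        re-evaluation on random matrices up to n=6."""
        for _ in range(60):
            n = int(rng.integers(3, 7))
            D = random_dissimilarity(rng, n)
            mine = sorted(h for _, _, h, _ in ward_cluster(D).merges)
            ref = ward_d2_reference(D.labels, D.values)
            assert np.allclose(mine, ref)

    def test_matches_scipy_ward(self, rng):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        for _ in range(20):
            D = random_dissimilarity(rng, int(rng.integers(3, 9)))
            mine = sorted(h for _, _, h, _ in ward_cluster(D).merges)
            Z = linkage(squareform(D.values, checks=False), method="ward")
            assert np.allclose(mine, sorted(Z[:, 2]))

    def test_heights_monotone(self, rng):
        D = random_dissimilarity(rng, 10)
        heights = [h for _, _, h, _ in ward_cluster(D).merges]
        assert all(b >= a for a, b in zip(heights, heights[1:]))

    def test_final_merge_joins_two_blobs(self):
        D = two_blob_matrix()
        dend = ward_cluster(D)
        # The last merge must combine one all-A cluster with one all-B cluster.
        cut2 = cut_dendrogram(dend, 2)
        groups = {}
        for label, cid in cut2.items():
            groups.setdefault(cid, set()).add(label[0])
        assert sorted(groups.values(), key=sorted) == [{"A"}, {"B"}]

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(labels=["a", "b"],
                           values=np.array([[0, 1], [2, 0]], float))


class TestCutDendrogram:
    def test_k_extremes(self, rng):
        D = random_dissimilarity(rng, 6)
        dend = ward_cluster(D)
        assert len(set(cut_dendrogram(dend, 1).values())) == 1
        assert len(set(cut_dendrogram(dend, 6).values())) == 6

    def test_out_of_range_rejected(self, rng):
        dend = ward_cluster(random_dissimilarity(rng, 4))
        with pytest.raises(ValueError):
            cut_dendrogram(dend, 0)
        with pytest.raises(ValueError):
            cut_dendrogram(dend, 5)


class TestNucDistance:
    def test_identical_rows_zero(self):
        msa = Msa(ids=["a", "b"], rows=["ACGTACGT", "ACGTACGT"])
        D, flags = nuc_distance(msa)
        assert D.values[0, 1] == 0.0 and not flags

    def test_jc69_closed_form_p_030(self):
        # 3 of 10 sites differ: d = -(3/4) ln(1 - 0.4) = 0.3831
        msa = Msa(ids=["a", "b"], rows=["AAAAAAAAAA", "CCCAAAAAAA"])
        D, _ = nuc_distance(msa, NucDistanceModel(model="jc69"))
        assert D.values[0, 1] == pytest.approx(0.3831, abs=5e-5)

    def test_ambiguous_column_pairwise_deleted(self):
        msa = Msa(ids=["a", "b"], rows=["ACGTN", "ACGTA"])
        D, _ = nuc_distance(msa, NucDistanceModel(model="p_distance"))
        assert D.values[0, 1] == 0.0

    def test_gap_column_excluded_from_denominator(self):
        msa = Msa(ids=["a", "b"], rows=["ACG-", "ACGT"])
        Dp, _ = nuc_distance(msa, NucDistanceModel(model="p_distance"))
        assert Dp.values[0, 1] == 0.0

    def test_saturated_pair_flagged(self):
        msa = Msa(ids=["a", "b"], rows=["AAAA", "CCCC"])
        D, flags = nuc_distance(msa, NucDistanceModel(model="jc69"))
        assert ("a", "b") in flags
        assert np.isnan(D.values[0, 1])

    def test_jc69_first_order_agreement_at_small_p(self):
        p = 1e-4
        d = -0.75 * math.log(1 - 4 * p / 3)
        assert d == pytest.approx(p, abs=1e-6)


class TestNjTree:
    def test_three_point_formulas(self):
        D = DistanceMatrix(labels=["A", "B", "C"],
                           values=np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]],
                                           float))
        tree = nj_tree(D)
        assert tree.find("A").length == pytest.approx(1.0)
        assert tree.find("B").length == pytest.approx(1.0)
        assert tree.find("C").length == pytest.approx(3.0)

    def test_too_few_taxa_rejected(self):
        D = DistanceMatrix(labels=["A", "B"],
                           values=np.array([[0, 1], [1, 0]], float))
        with pytest.raises(ValueError):
            nj_tree(D)

    def test_additive_recovery_many_random_trees(self):
        """NJ reconstructs topology and branch lengths exactly from additive
        matrices (50 random trees, 4-12 leaves)."""
        for seed in range(50):
            n = 4 + seed % 9
            true_tree, D = gen_additive_matrix(n, seed=seed)
            est = nj_tree(D)
            assert tree_bipartitions(est) == tree_bipartitions(true_tree)
            for i, a in enumerate(D.labels):
                for b in D.labels[i + 1:]:
                    assert path_length(est, a, b) == pytest.approx(
                        D.get(a, b), abs=1e-9)

    def test_agrees_with_skbio_nj(self):
        from skbio.tree import nj as skbio_nj
        from skbio import DistanceMatrix as SkbioDM

        _, D = gen_additive_matrix(7, seed=99)
        mine = nj_tree(D)
        other = skbio_nj(SkbioDM(D.values, ids=D.labels))
        assert tree_bipartitions(mine) == tree_bipartitions(other)

    def test_ultrametric_matrix_path_lengths(self):
        # Ultrametric matrices are additive; NJ reproduces all entries.
        M = np.array([
            [0, 2, 6, 6],
            [2, 0, 6, 6],
            [6, 6, 0, 4],
            [6, 6, 4, 0],
        ], float)
        D = DistanceMatrix(labels=list("ABCD"), values=M)
        tree = nj_tree(D)
        for i, a in enumerate(D.labels):
            for b in D.labels[i + 1:]:
                assert path_length(tree, a, b) == pytest.approx(D.get(a, b))


class TestBootstrap:
    @staticmethod
    def strong_signal_msa():
        # Two clearly distinct haplotype pairs -> one strong internal edge.
        h1 = "ATGATGATGATGATGATG"
        h2 = "GCCGCCGCCGCCGCCGCC"
        return Msa(ids=["a", "b", "c", "d"],
                   rows=[h1, h1[:-3] + "CTG", h2, h2[:-3] + "TCC"])

    def test_identical_columns_full_support(self):
        row = "ATG" * 6
        msa = Msa(ids=["a", "b", "c", "d"],
                  rows=[row, row.replace("A", "C", 1),
                        row.replace("G", "T", 2), row])
        # Every resample draws from identical-information codon units only if
        # the alignment has a single distinct unit; use uniform units:
        uniform = Msa(ids=["a", "b", "c", "d"],
                      rows=["ATGATG", "CTGCTG", "AGGAGG", "ACGACG"])
        tree = bootstrap_supports(uniform, NucDistanceModel("p_distance"),
                                  replicates=25, seed=3, unit="codon")
        for node in tree.non_tips():
            if node.bootstrap_support is not None:
                assert node.bootstrap_support == 100.0

    def test_single_replicate_support_binary(self):
        tree = bootstrap_supports(self.strong_signal_msa(),
                                  NucDistanceModel("p_distance"),
                                  replicates=1, seed=9, unit="column")
        for node in tree.non_tips():
            if getattr(node, "bootstrap_support", None) is not None:
                assert node.bootstrap_support in (0.0, 100.0)

    def test_strong_signal_high_support(self):
        tree = bootstrap_supports(self.strong_signal_msa(),
                                  NucDistanceModel("p_distance"),
                                  replicates=100, seed=17, unit="codon")
        supports = [n.bootstrap_support for n in tree.non_tips()
                    if getattr(n, "bootstrap_support", None) is not None]
        assert supports and max(supports) >= 95.0

    def test_leaf_order_permutation_invariance(self):
        msa = self.strong_signal_msa()
        perm = Msa(ids=[msa.ids[i] for i in (2, 0, 3, 1)],
                   rows=[msa.rows[i] for i in (2, 0, 3, 1)])
        t1 = bootstrap_supports(msa, NucDistanceModel("p_distance"),
                                replicates=50, seed=7, unit="codon")
        t2 = bootstrap_supports(perm, NucDistanceModel("p_distance"),
                                replicates=50, seed=7, unit="codon")

        def support_map(t):
            out = {}
            leaves = sorted(x.name for x in t.tips())
            for n in t.non_tips():
                s = getattr(n, "bootstrap_support", None)
                if s is not None:
                    side = frozenset(x.name for x in n.tips())
                    if leaves[0] in side:
                        side = frozenset(leaves) - side
                    out[side] = s
            return out

        assert support_map(t1) == support_map(t2)

    def test_seed_required(self):
        with pytest.raises(ValueError, match="seed"):
            bootstrap_supports(self.strong_signal_msa(), replicates=5,
                               seed=None)


class TestNewickIO:
    def test_three_leaf_round_trip(self, tmp_path):
        _, D = gen_additive_matrix(4, seed=2)
        tree = nj_tree(D)
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        back = read_newick(p)
        assert tree_bipartitions(back) == tree_bipartitions(tree)

    def test_twenty_leaf_bipartition_set_preserved(self, tmp_path):
        tree, _ = gen_additive_matrix(20, seed=8)
        p = tmp_path / "t20.nwk"
        write_newick(tree, p)
        assert tree_bipartitions(read_newick(p)) == tree_bipartitions(tree)

    def test_simple_topology_parses(self, tmp_path):
        p = tmp_path / "s.nwk"
        p.write_text("(A,(B,C));\n")
        tree = read_newick(p)
        assert sorted(t.name for t in tree.tips()) == ["A", "B", "C"]

    def test_unbalanced_parentheses_rejected(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((A,B;\n")
        with pytest.raises(NewickParseError):
            read_newick(p)

    def test_dendrogram_serializes_ultrametric(self, tmp_path, rng):
        D = two_blob_matrix()
        dend = ward_cluster(D)
        tree = dendrogram_to_tree(dend)
        depths = {t.name: t.accumulate_to_ancestor(tree) for t in tree.tips()}
        assert len({round(d, 9) for d in depths.values()}) == 1
        p = tmp_path / "dend.nwk"
        write_newick(dend, p)
        assert sorted(t.name for t in read_newick(p).tips()) == sorted(D.labels)
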