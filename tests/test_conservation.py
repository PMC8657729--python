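"""Identity, Poisson distances, neighbor joining, and heatmap orderings."""

import math
from io import StringIO

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode

from xsci.conservation import (
    neighbor_joining,
    order_for_heatmap,
    percent_identity,
    poisson_distance,
    select_longest_isoforms,
)
from xsci.io import AlignedSequenceSet
from xsci.simulate import simulate_alignment


class TestPercentIdentity:
    def test_identical_is_100(self):
        aln = AlignedSequenceSet(["ref", "x"], ["ACDEFGHIKL", "ACDEFGHIKL"])
        assert percent_identity(aln, "ref")["x"] == 100.0

    def test_two_of_ten_differ(self):
        aln = AlignedSequenceSet(["ref", "x"], ["ACDEFGHIKL", "ACDEFGHIWW"])
        assert percent_identity(aln, "ref")["x"] == pytest.approx(80.0)

    def test_gap_columns_excluded_from_denominator(self):
        aln = AlignedSequenceSet(["ref", "x"], ["ACDEF-HIKL", "-CDEFGHIKW"])
        # comparable columns: positions 1-4 and 6-9 (eight), one mismatch
        assert percent_identity(aln, "ref")["x"] == pytest.approx(100 * 7 / 8)

    def test_symmetric_in_the_pair(self):
        aln = AlignedSequenceSet(["a", "b"], ["ACDEF-HIKL", "-CDEFGHIKW"])
        assert percent_identity(aln, "a")["b"] == percent_identity(aln, "b")["a"]

    def test_invariant_under_column_permutation(self):
        rng = np.random.default_rng(3)
        aln = simulate_alignment("(a:0.2,b:0.2);", 200, seed=1)
        perm = rng.permutation(aln.n_sites)
        shuffled = AlignedSequenceSet(
            aln.taxa, ["".join(r[i] for i in perm) for r in aln.rows]
        )
        assert percent_identity(aln, "a")["b"] == (
            percent_identity(shuffled, "a")["b"]
        )

    def test_low_divergence_matches_poisson_expectation(self):
        d = 0.05
        aln = simulate_alignment(f"(a:{d/2},b:{d/2});", 20000, seed=2)
        expected = 100.0 * math.exp(-d)
        assert percent_identity(aln, "a")["b"] == pytest.approx(expected, abs=1.0)

    def test_all_gap_overlap_is_an_error(self):
        aln = AlignedSequenceSet(["a", "b"], ["AC--", "--AC"])
        with pytest.raises(ValueError, match="comparable"):
            percent_identity(aln, "a")


class TestPoissonDistance:
    def test_identical_gives_zero(self):
        aln = AlignedSequenceSet(["a", "b"], ["ACDEF", "ACDEF"])
        assert poisson_distance(aln)["a", "b"] == 0.0

    def test_p_point_one(self):
        aln = AlignedSequenceSet(["a", "b"], ["A" * 9 + "C", "A" * 9 + "D"])
        assert poisson_distance(aln)["a", "b"] == pytest.approx(
            -math.log(0.9), abs=1e-10
        )
        assert -math.log(0.9) == pytest.approx(0.10536, abs=1e-5)

    def test_pairwise_deletion_third_taxon_irrelevant(self):
        base = AlignedSequenceSet(["a", "b"], ["ACDEFGHIKL", "ACDEFGHIKW"])
        with_c = AlignedSequenceSet(
            ["a", "b", "c"], ["ACDEFGHIKL", "ACDEFGHIKW", "AC-E-GHXKL"]
        )
        assert poisson_distance(base)["a", "b"] == (
            poisson_distance(with_c)["a", "b"]
        )

    def test_x_and_gap_columns_removed_per_pair(self):
        aln = AlignedSequenceSet(["a", "b"], ["XCDEFGHIK-", "ACDEFGHIKL"])
        # 8 comparable columns, all identical
        assert poisson_distance(aln)["a", "b"] == 0.0

    def test_saturated_pair_rejected(self):
        aln = AlignedSequenceSet(["a", "b"], ["AAAA", "CCCC"])
        with pytest.raises(ValueError, match="undefined"):
            poisson_distance(aln)

    def test_dominates_raw_p_distance(self):
        aln = simulate_alignment("(a:0.3,b:0.3);", 2000, seed=7)
        arr = [np.frombuffer(r.encode(), dtype="S1") for r in aln.rows]
        p = float((arr[0] != arr[1]).mean())
        assert poisson_distance(aln)["a", "b"] >= p

    def test_observed_fraction_matches_poisson_process(self):
        aln = simulate_alignment("(a:0.15,b:0.15);", 10000, seed=5)
        arr = [np.frombuffer(r.encode(), dtype="S1") for r in aln.rows]
        p = float((arr[0] != arr[1]).mean())
        assert p == pytest.approx(1 - math.exp(-0.3), abs=0.02)


class TestNeighborJoining:
    def test_additive_four_taxon_tree(self):
        dm = DistanceMatrix(
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]],
            ["A", "B", "C", "D"],
        )
        tree = neighbor_joining(dm)
        truth = TreeNode.read(StringIO("((A:1,B:1):2,C:1,D:1);"))
        assert tree.compare_rfd(truth) == 0.0
        # exact branch lengths on an additive matrix
        tips = {t.name: t.length for t in tree.tips()}
        assert tips == {"A": 1.0, "B": 1.0, "C": 1.0, "D": 1.0}
        internal = [n.length for n in tree.non_tips()]
        assert internal == [2.0]

    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ["a", "b", "c"])
        tree = neighbor_joining(dm)
        tips = {t.name: t.length for t in tree.tips()}
        assert tips["a"] == pytest.approx(1.0)
        assert tips["b"] == pytest.approx(2.0)
        assert tips["c"] == pytest.approx(3.0)

    def test_additive_path_lengths_reproduced(self):
        """On an additive matrix NJ reproduces every pairwise path length."""
        truth = TreeNode.read(StringIO(
            "((A:0.4,B:0.3):0.2,(C:0.5,(D:0.1,E:0.2):0.3):0.1,F:0.6);"
        ))
        taxa = sorted(t.name for t in truth.tips())
        d = np.zeros((len(taxa), len(taxa)))
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i < j:
                    d[i, j] = d[j, i] = truth.find(a).distance(truth.find(b))
        tree = neighbor_joining(DistanceMatrix(d, taxa))
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i < j:
                    got = tree.find(a).distance(tree.find(b))
                    assert got == pytest.approx(d[i, j], abs=1e-9)

    def test_matches_skbio_topology_on_random_matrices(self):
        from skbio.tree import nj as skbio_nj
        rng = np.random.default_rng(17)
        for _ in range(5):
            n = 7
            x = rng.uniform(0.5, 2.0, size=(n, 3))
            d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
            np.fill_diagonal(d, 0.0)
            ids = [f"t{i}" for i in range(n)]
            dm = DistanceMatrix(d, ids)
            assert neighbor_joining(dm).compare_rfd(skbio_nj(dm)) == 0.0

    def test_generating_topology_recovered_from_simulation(self):
        newick = "((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05,(E:0.1,F:0.1):0.05);"
        truth = TreeNode.read(StringIO(newick))
        aln = simulate_alignment(newick, 5000, seed=0)
        tree = neighbor_joining(poisson_distance(aln))
        assert tree.compare_rfd(truth) == 0.0

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix([[0, 1], [1, 0]], ["a", "b"]))


class TestHeatmapOrdering:
    def test_identical_species_columns_adjacent(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=20)
        values = pd.DataFrame(
            {"s1": base, "s2": -base, "s3": base * 2.0},
            index=[f"g{i}" for i in range(20)],
        )
        order, _ = order_for_heatmap(values, n_gene_clusters=2, seed=0)
        # s1 and s3 are colinear (cosine dissimilarity 0) -> merged first
        i1, i3 = order.index("s1"), order.index("s3")
        assert abs(i1 - i3) == 1

    def test_planted_direction_blocks_recovered(self):
        rng = np.random.default_rng(2)
        dirs = np.array(
            [[1, 1, 1, 1], [1, 1, -1, -1], [-1, -1, 1, 1], [-1, 1, -1, 1]],
            dtype=float,
        )
        rows, truth = [], []
        for b, d in enumerate(dirs):
            for _ in range(15):
                rows.append(d * rng.uniform(2.0, 3.0) + rng.normal(0, 0.05, 4))
                truth.append(b)
        values = pd.DataFrame(rows, columns=list("wxyz"))
        _, labels = order_for_heatmap(values, n_gene_clusters=4, seed=0)
        # exactly one k-means label per planted block
        mapping = {}
        for lab, t in zip(labels, truth):
            mapping.setdefault(t, set()).add(lab)
        assert all(len(v) == 1 for v in mapping.values())
        assert len({next(iter(v)) for v in mapping.values()}) == 4

    def test_row_permutation_same_partition(self):
        rng = np.random.default_rng(3)
        values = pd.DataFrame(
            np.vstack([
                rng.normal([3, 3, -3, -3], 0.1, size=(10, 4)),
                rng.normal([-3, 3, 3, -3], 0.1, size=(10, 4)),
            ]),
            index=[f"g{i}" for i in range(20)], columns=list("wxyz"),
        )
        _, labels = order_for_heatmap(values, n_gene_clusters=2, seed=0)
        perm = rng.permutation(20)
        _, labels_perm = order_for_heatmap(values.iloc[perm],
                                           n_gene_clusters=2, seed=0)
        # same partition up to label names
        joint = pd.crosstab(labels[values.index[perm]], labels_perm)
        assert (joint.to_numpy() > 0).sum() == 2

    def test_zero_rows_get_sentinel(self):
        values = pd.DataFrame(
            [[1, 2], [0, 0], [3, 4], [2, 1]], columns=["a", "b"],
            index=list("wxyz"),
        )
        _, labels = order_for_heatmap(values, n_gene_clusters=2, seed=0)
        assert labels["x"] == -1
        assert set(labels.drop("x")) <= {0, 1}

    def test_zero_column_rejected(self):
        values = pd.DataFrame([[1, 0], [2, 0]], columns=["a", "b"])
        with pytest.raises(ValueError, match="all-zero species"):
            order_for_heatmap(values, n_gene_clusters=1, seed=0)

    def test_k_larger_than_genes_rejected(self):
        values = pd.DataFrame([[1, 2], [3, 4]], columns=["a", "b"])
        with pytest.raises(ValueError, match="exceeds"):
            order_for_heatmap(values, n_gene_clusters=3, seed=0)


class TestLongestIsoform:
    def test_longest_kept_ties_by_id(self):
        seqs = {"r1": "ACDEF", "r2": "ACDEFGH", "r3": "ACDEFGH", "r4": "AC"}
        gene_of = {"r1": "G1", "r2": "G1", "r3": "G1", "r4": "G2"}
        best = select_longest_isoforms(seqs, gene_of)
        assert best["G1"] == ("r2", "ACDEFGH")
        assert best["G2"] == ("r4", "AC")
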