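import numpy as np
import pytest

from genophys import phylo, simulate

from oracles import pairwise_p_distance, random_additive_instance, tree_leaf_distances


class TestPDistance:
    def test_identical_rows(self):
        aln = phylo.MultipleAlignment(["a", "b"], ["ACGT", "ACGT"])
        d = phylo.p_distance(aln)
        assert np.all(d.matrix == 0)

    def test_quarter(self):
        aln = phylo.MultipleAlignment(["a", "b"], ["AAAA", "AAAT"])
        assert phylo.p_distance(aln).matrix[0, 1] == 0.25

    def test_matches_counting_oracle(self, rng):
        chars = np.array(list("ACGT-"))
        rows = ["".join(chars[rng.integers(0, 5, 60)]) for _ in range(5)]
        labels = [f"t{i}" for i in range(5)]
        d = phylo.p_distance(phylo.MultipleAlignment(labels, rows))
        for i in range(5):
            for j in range(i + 1, 5):
                assert d.matrix[i, j] == pytest.approx(
                    pairwise_p_distance(rows[i], rows[j])
                )

    def test_complete_delete_drops_gap_columns(self):
        aln = phylo.MultipleAlignment(["a", "b", "c"], ["A-GT", "ACGT", "ACGA"])
        d = phylo.p_distance(aln, gap_mode="complete-delete")
        # column 2 dropped: rows become AGT/AGT/AGA
        assert d.matrix[0, 1] == 0.0
        assert d.matrix[0, 2] == pytest.approx(1 / 3)

    def test_no_comparable_sites_names_pair(self):
        aln = phylo.MultipleAlignment(["a", "b"], ["A---", "---T"])
        with pytest.raises(ValueError, match="a.*b"):
            phylo.p_distance(aln)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = phylo.DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        )
        tree = phylo.neighbor_joining(D)
        lengths = {c.name: c.branch_length for c in tree.root.children}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_four_taxon_additive(self):
        D = phylo.DistanceMatrix(
            ["A", "B", "C", "D"],
            np.array([[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], float),
        )
        tree = phylo.neighbor_joining(D)
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        dists = tree_leaf_distances(tree)
        assert dists[("A", "B")] == pytest.approx(2.0)
        assert dists[("A", "C")] == pytest.approx(3.0)

    def test_additive_battery_exact(self):
        rng = np.random.default_rng(99)
        for trial in range(25):
            n = int(rng.integers(4, 13))
            labels, D, true_biparts = random_additive_instance(rng, n)
            tree = phylo.neighbor_joining(phylo.DistanceMatrix(labels, D))
            assert tree.bipartitions() == true_biparts
            dists = tree_leaf_distances(tree)
            for i, la in enumerate(labels):
                for j in range(i + 1, n):
                    assert dists[(la, labels[j])] == pytest.approx(
                        D[i, j], abs=1e-9
                    )

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            phylo.DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], float))

    def test_too_few_taxa(self):
        D = phylo.DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float))
        with pytest.raises(ValueError):
            phylo.neighbor_joining(D)

    def test_no_negative_branch_lengths(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = 6
            m = rng.uniform(0.1, 1.0, (n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            tree = phylo.neighbor_joining(
                phylo.DistanceMatrix([f"t{i}" for i in range(n)], m)
            )

            def check(node):
                assert node.branch_length >= 0
                for c in node.children:
                    check(c)

            check(tree.root)


class TestBootstrap:
    def test_perfect_signal_full_support(self):
        aln = phylo.MultipleAlignment(
            ["A", "B", "C", "D"],
            ["AAAAAAAA", "AAAAAAAA", "TTTTTTTT", "TTTTTTTT"],
        )
        # every column separates AB from CD
        tree = phylo.bootstrap_support(aln, n_reps=200, seed=1)
        supports = [
            node.support
            for node, _ in tree._internal_edges()
        ]
        assert supports and all(s == 100 for s in supports)

    def test_conflicting_signal_near_half(self):
        cols_ab = ["A", "A", "T", "T"]  # supports AB|CD
        cols_ac = ["A", "T", "A", "T"]  # supports AC|BD
        rows = ["".join(cols_ab[i] * 20 + cols_ac[i] * 20) for i in range(4)]
        aln = phylo.MultipleAlignment(["A", "B", "C", "D"], rows)
        tree = phylo.bootstrap_support(aln, n_reps=1000, seed=7)
        supports = [n.support for n, _ in tree._internal_edges()]
        assert len(supports) == 1
        assert 40 <= supports[0] <= 60

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(11)
        chars = np.array(list("ACGT"))
        rows = ["".join(chars[rng.integers(0, 4, 40)]) for _ in range(5)]
        aln = phylo.MultipleAlignment([f"t{i}" for i in range(5)], rows)
        t1 = phylo.bootstrap_support(aln, n_reps=50, seed=5)
        t2 = phylo.bootstrap_support(aln, n_reps=50, seed=5)
        assert t1.newick() == t2.newick()

    def test_nreps_validation(self):
        aln = phylo.MultipleAlignment(["a", "b", "c"], ["AC", "AC", "GT"])
        with pytest.raises(ValueError):
            phylo.bootstrap_support(aln, n_reps=0)


class TestConcatenate:
    def test_column_sum(self):
        b1 = phylo.MultipleAlignment(["a", "b"], ["A" * 10, "C" * 10])
        b2 = phylo.MultipleAlignment(["a", "b"], ["G" * 20, "T" * 20])
        aln, bounds = phylo.concatenate_alignments([b1, b2])
        assert aln.n_columns == 30
        assert bounds == [(0, 10), (10, 30)]

    def test_rows_matched_by_label_not_position(self):
        b1 = phylo.MultipleAlignment(["a", "b"], ["AA", "CC"])
        b2 = phylo.MultipleAlignment(["b", "a"], ["TT", "GG"])
        aln, _ = phylo.concatenate_alignments([b1, b2])
        assert aln.row("a") == "AAGG"
        assert aln.row("b") == "CCTT"

    def test_missing_label_names_block(self):
        b1 = phylo.MultipleAlignment(["a", "b"], ["AA", "CC"])
        b2 = phylo.MultipleAlignment(["a", "x"], ["TT", "GG"])
        with pytest.raises(ValueError, match="block 1"):
            phylo.concatenate_alignments([b1, b2])

    def test_concat_p_distance_is_length_weighted_average(self, rng):
        chars = np.array(list("ACGT"))
        labels = ["a", "b", "c"]
        blocks = []
        for ncol in (12, 24):
            rows = ["".join(chars[rng.integers(0, 4, ncol)]) for _ in labels]
            blocks.append(phylo.MultipleAlignment(labels, rows))
        aln, _ = phylo.concatenate_alignments(blocks)
        d_cat = phylo.p_distance(aln).matrix
        d1 = phylo.p_distance(blocks[0]).matrix
        d2 = phylo.p_distance(blocks[1]).matrix
        assert np.allclose(d_cat, (12 * d1 + 24 * d2) / 36)


class TestMarkerTreeRecovery:
    def test_three_markers_on_known_six_taxon_tree(self):
        spec = (
            [
                ([("A", 0.02), ("B", 0.02)], 0.04),
                ([("C", 0.02), ("D", 0.02)], 0.04),
                ([("E", 0.02), ("F", 0.02)], 0.04),
            ],
            0.0,
        )
        blocks = []
        for i, length in enumerate((500, 700, 900)):
            seqs = simulate.simulate_sequences_on_tree(spec, length, seed=20 + i)
            labels = sorted(seqs)
            blocks.append(phylo.MultipleAlignment(labels, [seqs[l] for l in labels]))
        aln, _ = phylo.concatenate_alignments(blocks)
        tree = phylo.neighbor_joining(phylo.p_distance(aln))
        # AB|CDEF canonicalizes to its complement because A is the anchor leaf
        expected = {
            frozenset({"C", "D"}),
            frozenset({"E", "F"}),
            frozenset({"C", "D", "E", "F"}),
        }
        assert tree.bipartitions() == expected


class TestAaiDendrogram:
    def test_distant_taxon_on_own_branch(self):
        labels = ["A", "B", "C", "Z"]
        m = np.array(
            [[0, 1, 1, 30], [1, 0, 1, 30], [1, 1, 0, 30], [30, 30, 30, 0]], float
        )
        tree = phylo.aai_dendrogram(phylo.DistanceMatrix(labels, m))
        dists = tree_leaf_distances(tree)
        assert dists[("A", "Z")] > 10 * dists[("A", "B")]

    def test_equal_distances_star_like(self):
        labels = list("ABCD")
        m = np.full((4, 4), 2.0)
        np.fill_diagonal(m, 0.0)
        tree = phylo.aai_dendrogram(phylo.DistanceMatrix(labels, m))
        for node, _ in tree._internal_edges():
            assert node.branch_length == pytest.approx(0.0, abs=1e-9)


class TestCenterStarAligner:
    def test_equal_length_substitution_only(self, rng):
        base = simulate.random_dna(rng, 300)
        seqs = [base]
        for _ in range(3):
            mutated, _ = simulate.substitute(base, rng, 15)
            seqs.append(mutated)
        labels = [f"s{i}" for i in range(4)]
        aln = phylo.align_markers(labels, seqs)
        assert aln.n_columns == 300
        assert aln.rows[0] == base

    def test_with_small_indel(self, rng):
        base = simulate.random_dna(rng, 200)
        deleted = base[:90] + base[100:]
        aln = phylo.align_markers(["full", "del", "full2"], [base, deleted, base])
        assert aln.n_columns == 200
        assert aln.row("del").count("-") == 10
        assert aln.row("full") == base

    def test_newick_quotes_odd_labels(self):
        D = phylo.DistanceMatrix(
            ["tax one", "b", "c"], np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float)
        )
        nwk = phylo.neighbor_joining(D).newick()
        assert "'tax one'" in nwk
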