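"""Block selection, distances, NJ exactness on additive matrices,
bootstrap supports and subclade extraction."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from gelpkit import phylogeny as ph


def random_tree_and_matrix(n, seed):
    """Random rooted binary tree with positive lengths + its exact
    path-length (additive) distance matrix."""
    import random as _random
    tree = dendropy.simulate.treesim.birth_death_tree(
        1.0, 0.0, num_extant_tips=n, rng=_random.Random(seed)
    )
    rng = np.random.default_rng(seed)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(rng.uniform(0.2, 2.0))
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = pdm.distance(taxa[i], taxa[j])
    return tree, D, [t.label for t in taxa]


def tree_matrix(tree, labels):
    """Path-length matrix of an inferred tree, for additivity checks."""
    pdm = tree.phylogenetic_distance_matrix()
    tax = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    M = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        M[i, j] = M[j, i] = pdm.distance(tax[labels[i]], tax[labels[j]])
    return M


class TestNeighborJoining:
    def test_four_taxon_cherries_exact(self):
        D = np.array([[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], float)
        tree = ph.neighbor_joining(D, list("ABCD"))
        assert ph.rf_distance(tree, "((A:1,B:1):0.5,(C:1,D:1):0.5);") == 0
        assert np.allclose(tree_matrix(tree, list("ABCD")), D, atol=1e-9)

    def test_three_taxon_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = ph.neighbor_joining(D, list("ABC"))
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    @pytest.mark.parametrize("seed", range(15))
    def test_five_taxon_additive_topology_recovered(self, seed):
        true_tree, D, labels = random_tree_and_matrix(5, seed)
        inferred = ph.neighbor_joining(D, labels)
        assert ph.rf_distance(inferred, true_tree) == 0
        assert np.allclose(tree_matrix(inferred, labels), D, atol=1e-9)

    def test_agrees_with_skbio_on_random_additive_matrix(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj
        _, D, labels = random_tree_and_matrix(8, 42)
        ours = ph.neighbor_joining(D, labels)
        theirs = skbio_nj(DistanceMatrix(D, labels))
        assert ph.rf_distance(ours, str(theirs)) == 0

    def test_nonsymmetric_rejected(self):
        D = np.array([[0, 1, 2], [1, 0, 3], [2, 3.5, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            ph.neighbor_joining(D, list("ABC"))

    def test_negative_branch_clamped_and_counted(self):
        # strongly non-additive matrix provokes negative estimates
        D = np.array([
            [0, 1, 10, 10], [1, 0, 1, 10], [10, 1, 0, 1], [10, 10, 1, 0],
        ], float)
        tree = ph.neighbor_joining(D, list("ABCD"))
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                assert node.edge.length >= 0.0
        assert tree.nj_clamped_branches >= 1


class TestDistances:
    def _aln(self, rows):
        ids = [f"s{i}" for i in range(len(rows))]
        return ph.ConcatAlignment(ids, rows, ["b"], [len(rows[0])])

    def test_identical_rows_zero_distance(self):
        D = ph.distance_matrix(self._aln(["ACDEFGHIKL"] * 3), model="kimura")
        assert np.allclose(D, 0.0)

    def test_kimura_closed_form_at_p_ten_percent(self):
        rows = ["ACDEFGHIKL", "ACDEFGHIKM"]  # 1 of 10 differs
        D = ph.distance_matrix(self._aln(rows), model="kimura")
        assert D[0, 1] == pytest.approx(-np.log(1 - 0.1 - 0.2 * 0.01), abs=1e-12)

    def test_poisson_closed_form(self):
        rows = ["ACDEFGHIKL", "ACDEFGHIKM"]
        D = ph.distance_matrix(self._aln(rows), model="poisson")
        assert D[0, 1] == pytest.approx(-np.log(0.9), abs=1e-12)

    def test_p_distance_is_mismatch_fraction(self):
        rows = ["AAAA", "AATT"]
        D = ph.distance_matrix(self._aln(rows), model="p")
        assert D[0, 1] == pytest.approx(0.5)

    def test_kimura_pole_error_names_pair(self):
        rows = ["AAAAAAAAAA", "CCCCCCCCCC"]
        with pytest.raises(ValueError, match="s0.*s1"):
            ph.distance_matrix(self._aln(rows), model="kimura")

    def test_symmetry_zero_diagonal_random(self, rng):
        from gelpkit.alphabet import AA
        rows = ["".join(AA[i] for i in rng.integers(0, 4, 30)) for _ in range(6)]
        D = ph.distance_matrix(self._aln(rows), model="p")
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0.0)


class TestSelectBlocks:
    def _occ(self, rows):
        return pd.DataFrame(rows, columns=["motif", "sequence", "start"])

    def test_universal_blocks_selected_no_exclusions(self):
        seqs = [f"s{i}" for i in range(10)]
        rows = []
        for s in seqs:
            for j, m in enumerate(["A", "B", "C", "D"]):
                rows.append((m, s, 10 + 30 * j))
            rows.append(("rare", s, 5) if s == "s0" else ("rare2", s, 7))
        sel = ph.select_blocks(
            self._occ(rows), seqs, {"A": 8, "B": 8, "C": 8, "D": 8, "rare": 6, "rare2": 6}
        )
        assert sel.selected == ["A", "B", "C", "D"]
        assert sel.excluded == {}

    def test_gap_rich_sequence_excluded_with_missing_list(self):
        seqs = [f"s{i}" for i in range(20)]
        rows = []
        for s in seqs:
            for j, m in enumerate(["A", "B", "C", "D"]):
                if s == "s0" and m in ("B", "C", "D"):
                    continue
                rows.append((m, s, 10 + 30 * j))
        sel = ph.select_blocks(
            self._occ(rows), seqs, {m: 8 for m in "ABCD"},
            min_coverage=0.9, min_blocks=3,
        )
        assert "s0" in sel.excluded
        assert sorted(sel.excluded["s0"]) == ["B", "C", "D"]
        assert "s0" not in sel.retained

    def test_order_inconsistent_motif_dropped(self):
        seqs = [f"s{i}" for i in range(4)]
        rows = []
        for s in seqs:
            rows.append(("A", s, 5))
            rows.append(("B", s, 50 if s != "s3" else 1))  # B swaps order in s3
        sel = ph.select_blocks(
            self._occ(rows), seqs, {"A": 8, "B": 8}, min_coverage=0.9
        )
        assert sel.selected == ["A"]

    def test_no_coverage_advises_lower_threshold(self):
        rows = [("A", "s0", 1)]
        with pytest.raises(ValueError, match="min_coverage"):
            ph.select_blocks(self._occ(rows), ["s0", "s1", "s2"], {"A": 8})


class TestConcatenate:
    def test_column_count_is_width_sum(self):
        occ = pd.DataFrame(
            [("A", "s0", 0), ("B", "s0", 10), ("A", "s1", 2), ("B", "s1", 12)],
            columns=["motif", "sequence", "start"],
        )
        sel = ph.BlockSelection(["A", "B"], {"A": 6, "B": 9}, {"A": 1, "B": 1},
                                ["s0", "s1"], {})
        seqs = {"s0": "ABCDEFGHIJKLMNOPQRSTUVW", "s1": "ZZABCDEFGHIJKLMNOPQRSTU"}
        aln = ph.concatenate_blocks(sel, occ, seqs)
        assert aln.n_columns == 15
        assert aln.rows[0] == seqs["s0"][0:6] + seqs["s0"][10:19]

    def test_out_of_bounds_occurrence_rejected(self):
        occ = pd.DataFrame([("A", "s0", 20)], columns=["motif", "sequence", "start"])
        sel = ph.BlockSelection(["A"], {"A": 10}, {"A": 1}, ["s0"], {})
        with pytest.raises(ValueError, match="out of bounds"):
            ph.concatenate_blocks(sel, occ, {"s0": "SHORTSEQ" * 3})

    def test_zero_divergence_family_identical_rows(self, zero_noise_family):
        fam = zero_noise_family
        aln = truth_block_alignment(fam)
        assert len(set(aln.rows)) == 1


def truth_block_alignment(fam):
    """Ungapped alignment cut at the generator's true block coordinates."""
    ids = sorted(fam.proteins)
    rows = [
        "".join(fam.proteins[s][a:b] for a, b in fam.truth.true_block_coords[s])
        for s in ids
    ]
    widths = [b - a for a, b in fam.truth.true_block_coords[ids[0]]]
    return ph.ConcatAlignment(ids, rows, fam.truth.block_labels, widths)


class TestBootstrap:
    @pytest.fixture(scope="class")
    def diagnostic_alignment(self):
        rows = {"A": "AAAA", "B": "AAAA", "C": "BBBB", "D": "BBBB",
                "E": "CCCC", "F": "CCCC", "G": "DDDD", "H": "DDDD"}
        return ph.ConcatAlignment(list(rows), list(rows.values()), ["x"], [4])

    def test_diagnostic_columns_full_support_any_seed(self, diagnostic_alignment):
        for seed in (0, 99):
            tree = ph.bootstrap_support(diagnostic_alignment, 40, model="p", seed=seed)
            sup = ph.split_support_map(tree)
            assert sup and all(v == 100.0 for v in sup.values())

    def test_single_replicate_supports_binary(self, small_family):
        aln = truth_block_alignment(small_family)
        tree = ph.bootstrap_support(aln, n_replicates=1, seed=5)
        assert set(ph.split_support_map(tree).values()) <= {0.0, 100.0}

    def test_fixed_seed_identical_supports(self, small_family):
        aln = truth_block_alignment(small_family)
        s1 = ph.split_support_map(ph.bootstrap_support(aln, 100, seed=8))
        s2 = ph.split_support_map(ph.bootstrap_support(aln, 100, seed=8))
        assert s1 == s2

    def test_supports_invariant_under_row_permutation(self, small_family):
        aln = truth_block_alignment(small_family)
        perm = list(reversed(range(len(aln.ids))))
        aln2 = ph.ConcatAlignment(
            [aln.ids[i] for i in perm], [aln.rows[i] for i in perm],
            aln.block_ids, aln.block_widths,
        )
        s1 = ph.split_support_map(ph.bootstrap_support(aln, 100, seed=8))
        s2 = ph.split_support_map(ph.bootstrap_support(aln2, 100, seed=8))
        assert s1 == s2

    def test_newick_hides_low_supports(self, small_family):
        aln = truth_block_alignment(small_family)
        tree = ph.bootstrap_support(aln, 100, seed=8)
        text = ph.newick_with_supports(tree, min_show=50)
        shown = [
            int(n.label) for n in tree.preorder_internal_node_iter() if n.label
        ]
        assert all(s >= 50 for s in shown)
        assert text.endswith(";")


class TestSubclades:
    def test_topology_recovered_at_low_divergence(self):
        # enough conserved-core columns that every internal edge carries
        # at least one substitution
        from gelpkit.synthetic import FamilySimConfig, simulate_family
        for seed in range(10):
            cfg = FamilySimConfig(
                n_taxa=12, n_blocks=4, block_width=50, block_sub_prob=0.05,
                planted_motifs=[], cluster_specs=[], tandem_specs=[],
                segmental_pairs=0, n_decoy_proteins=0, seed=seed,
            )
            fam = simulate_family(cfg)
            aln = truth_block_alignment(fam)
            tree = ph.neighbor_joining(ph.distance_matrix(aln, "p"), aln.ids)
            assert ph.rf_distance(tree, fam.truth.true_tree) == 0, f"seed {seed}"

    def test_balanced_mode_recovers_planted_clades(self):
        from gelpkit.synthetic import FamilySimConfig, simulate_family, clade_partition
        cfg = FamilySimConfig(
            n_taxa=12, n_blocks=4, block_width=50, block_sub_prob=0.05,
            planted_motifs=[], cluster_specs=[], tandem_specs=[],
            segmental_pairs=0, n_decoy_proteins=0, seed=2,
        )
        fam = simulate_family(cfg)
        aln = truth_block_alignment(fam)
        tree = ph.bootstrap_support(aln, 100, model="p", seed=1)
        got = ph.extract_subclades(tree, n_groups=3)
        by_label: dict[str, set] = {}
        for leaf, lab in got.assignment.items():
            by_label.setdefault(lab, set()).add(leaf)
        truth_parts = {frozenset(
            l for l, c in fam.truth.true_clades.items() if c == lab
        ) for lab in set(fam.truth.true_clades.values())}
        assert {frozenset(v) for v in by_label.values()} == truth_parts

    def test_curated_mode_flags_non_monophyletic_group(self, small_family):
        aln = truth_block_alignment(small_family)
        tree = ph.bootstrap_support(aln, 50, seed=3)
        leaves = sorted(small_family.proteins)
        clades = small_family.truth.true_clades
        mixed = [leaves[0]] + [l for l in leaves if clades[l] != clades[leaves[0]]][:1]
        got = ph.extract_subclades(tree, leaf_groups={"bad": mixed, "single": [leaves[1]]})
        assert got.monophyletic["bad"] is False
        assert got.monophyletic["single"] is True
        assert got.support["single"] == 100.0

    def test_singleton_groups_trivially_monophyletic(self, small_family):
        aln = truth_block_alignment(small_family)
        tree = ph.bootstrap_support(aln, 50, seed=3)
        groups = {f"g{i}": [l] for i, l in enumerate(sorted(small_family.proteins))}
        got = ph.extract_subclades(tree, leaf_groups=groups)
        assert all(got.monophyletic.values())
        assert all(v == 100.0 for v in got.support.values())
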