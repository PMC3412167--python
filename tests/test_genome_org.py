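"""Cluster, tandem and segmental rules against brute-force oracles, plus
gene-structure and repeat-overlap arithmetic."""

import numpy as np
import pytest

from gelpkit import genome_org as go
from gelpkit.genome_org import detect_clusters
from gelpkit.io import GeneLocus, Transcript


def layout_to_loci(pattern: str, chrom: str = "chr1") -> tuple[list, set]:
    """'F' = family gene, 'x' = unrelated gene, in positional order."""
    loci, family = [], set()
    for i, ch in enumerate(pattern):
        gid = f"{chrom}_{'F' if ch == 'F' else 'x'}{i}"
        loci.append(GeneLocus(gid, chrom, 1000 * (i + 1), 1000 * (i + 1) + 100))
        if ch == "F":
            family.add(gid)
    return loci, family


def oracle_clusters(pattern: str) -> list[list[int]]:
    """Independent union-find chaining of family genes by the <=4 rule."""
    fam_pos = [i for i, c in enumerate(pattern) if c == "F"]
    parent = {i: i for i in fam_pos}

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for a, b in zip(fam_pos, fam_pos[1:]):
        if b - a - 1 <= 4:
            parent[find(b)] = find(a)
    groups: dict[int, list[int]] = {}
    for i in fam_pos:
        groups.setdefault(find(i), []).append(i)
    return sorted(g for g in groups.values() if len(g) >= 2)


class TestDetectClusters:
    def test_four_intervening_joins(self):
        loci, family = layout_to_loci("FxxxxF")
        cs = detect_clusters(loci, family)
        assert len(cs.clusters) == 1 and len(cs.clusters[0]) == 2
        assert cs.intervening[0] == [4]

    def test_five_intervening_breaks(self):
        loci, family = layout_to_loci("FxxxxxF")
        cs = detect_clusters(loci, family)
        assert cs.clusters == []

    def test_adjacent_family_genes_cluster(self):
        loci, family = layout_to_loci("FFxF")
        cs = detect_clusters(loci, family)
        assert len(cs.clusters) == 1 and len(cs.clusters[0]) == 3

    def test_missing_family_id_is_an_error(self):
        loci, family = layout_to_loci("FxF")
        with pytest.raises(KeyError, match="ghost"):
            detect_clusters(loci, family | {"ghost"})

    def test_matches_bruteforce_oracle_on_random_layouts(self, rng):
        for trial in range(100):
            n = int(rng.integers(2, 21))
            pattern = "".join(rng.choice(["F", "x"], size=n, p=[0.4, 0.6]))
            loci, family = layout_to_loci(pattern)
            cs = detect_clusters(loci, family)
            got = sorted(
                [int(g.split("F")[-1]) for g in cluster] for cluster in cs.clusters
            )
            assert got == oracle_clusters(pattern), pattern


class TestDetectTandem:
    def _clusterset(self, members, counts):
        return go.ClusterSet([members], [counts], ["chr1"])

    def test_adjacent_identical_pair_is_tandem(self):
        cs = self._clusterset(["a", "b"], [0])
        recs = go.detect_tandem_groups(cs, {("a", "b"): 0.0})
        assert len(recs) == 1 and recs[0].members == ("a", "b")

    def test_distant_sequences_not_tandem(self):
        cs = self._clusterset(["a", "b"], [0])
        assert go.detect_tandem_groups(cs, {("a", "b"): 0.9}) == []

    def test_two_intervening_genes_break_tandem(self):
        cs = self._clusterset(["a", "b"], [2])
        assert go.detect_tandem_groups(cs, {("a", "b"): 0.0}) == []

    def test_missing_distance_is_an_error(self):
        cs = self._clusterset(["a", "b"], [0])
        with pytest.raises(KeyError):
            go.detect_tandem_groups(cs, {})

    def test_tandem_groups_subset_of_clusters(self, zero_noise_family):
        fam = zero_noise_family
        cs = detect_clusters(fam.loci, set(fam.proteins))
        dist = {}
        names = sorted(fam.proteins)
        for a in names:
            for b in names:
                sa = "".join(fam.proteins[a][s:e] for s, e in fam.truth.true_block_coords[a])
                sb = "".join(fam.proteins[b][s:e] for s, e in fam.truth.true_block_coords[b])
                dist[(a, b)] = np.mean([x != y for x, y in zip(sa, sb)])
        recs = go.detect_tandem_groups(cs, dist)
        cluster_sets = [set(c) for c in cs.clusters]
        for r in recs:
            assert any(set(r.members) <= c for c in cluster_sets)
        got = sorted(sorted(r.members) for r in recs)
        assert got == fam.truth.true_tandem_groups


class TestSegmental:
    def _setup(self, d_a, d_b):
        loci = [
            GeneLocus("anchorA", "chr1", 1_000_000, 1_001_000),
            GeneLocus("anchorB", "chr2", 2_000_000, 2_001_000),
            GeneLocus("famA", "chr1", 1_001_000 + d_a, 1_002_000 + d_a),
            GeneLocus("famB", "chr2", 2_001_000 + d_b, 2_002_000 + d_b),
        ]
        import pandas as pd
        anchors = pd.DataFrame([{
            "gene_a": "anchorA", "gene_b": "anchorB",
            "chrom_a": "chr1", "chrom_b": "chr2", "block_id": "B1",
        }])
        return loci, anchors

    def test_pair_within_bound_emitted(self):
        loci, anchors = self._setup(100_000, 499_000)
        recs = go.pair_segmental_duplicates(loci, {"famA", "famB"}, anchors)
        assert [r.members for r in recs] == [("famA", "famB")]

    def test_pair_over_bound_not_emitted(self):
        loci, anchors = self._setup(100_000, 501_000)
        assert go.pair_segmental_duplicates(loci, {"famA", "famB"}, anchors) == []

    def test_malformed_anchor_row_names_row(self):
        loci, anchors = self._setup(1, 1)
        anchors.loc[0, "gene_a"] = "nonexistent"
        with pytest.raises(ValueError, match="row 0"):
            go.pair_segmental_duplicates(loci, {"famA", "famB"}, anchors)

    def test_planted_pairs_recovered(self, zero_noise_family):
        fam = zero_noise_family
        recs = go.pair_segmental_duplicates(fam.loci, set(fam.proteins), fam.anchors)
        got = sorted(tuple(sorted(r.members)) for r in recs)
        assert got == sorted(fam.truth.true_segmental_pairs)


class TestGeneStructure:
    def _gene(self, exons):
        t = Transcript("t1", exons)
        return GeneLocus("g1", "chr1", exons[0][0], exons[-1][1], "+", [t])

    def test_single_intron_length(self):
        df, _ = go.summarize_gene_structure([self._gene([(1, 100), (201, 300)])])
        assert df.iloc[0]["intron_count"] == 1
        assert df.iloc[0]["intron_lengths"] == "100"

    def test_single_exon_is_intronless(self):
        df, hist = go.summarize_gene_structure([self._gene([(1, 500)])])
        assert bool(df.iloc[0]["intronless"])
        assert hist[(1, 0)] == 1

    def test_long_intron_flagged(self):
        df, _ = go.summarize_gene_structure([self._gene([(1, 100), (1102, 1200)])])
        assert bool(df.iloc[0]["has_long_intron"])
        df, _ = go.summarize_gene_structure([self._gene([(1, 100), (1101, 1200)])])
        assert not bool(df.iloc[0]["has_long_intron"])

    def test_exon_plus_intron_lengths_equal_span(self, rng):
        for _ in range(50):
            n_ex = int(rng.integers(1, 7))
            pos = 1
            exons = []
            for _ in range(n_ex):
                length = int(rng.integers(10, 400))
                exons.append((pos, pos + length - 1))
                pos += length + int(rng.integers(20, 900))
            df, _ = go.summarize_gene_structure([self._gene(exons)])
            row = df.iloc[0]
            exon_total = sum(e - s + 1 for s, e in exons)
            intron_total = sum(
                int(x) for x in row["intron_lengths"].split(",") if x
            )
            assert exon_total + intron_total == row["genomic_span"]

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError):
            Transcript("t1", [(1, 100), (50, 200)])


def oracle_repeat_counts(gene, repeats):
    """Naive all-pairs overlap count per region."""
    t = gene.transcripts[0]
    regions = {
        "exon": go._subtract(t.exons, t.utr5 + t.utr3),
        "intron": [
            (t.exons[i][1] + 1, t.exons[i + 1][0] - 1) for i in range(len(t.exons) - 1)
        ],
        "utr5": t.utr5, "utr3": t.utr3,
    }
    counts = {k: 0 for k in regions}
    for chrom, rs, re_ in repeats:
        if chrom != gene.chrom:
            continue
        for k, ivs in regions.items():
            hit = False
            for s, e in ivs:
                if max(s, rs) <= min(e, re_):
                    hit = True
            counts[k] += hit
    return counts


class TestRepeatOverlap:
    def _gene(self):
        exons = [(101, 300), (501, 700), (901, 1100)]
        t = Transcript("t1", exons, utr5=[(101, 150)], utr3=[(1051, 1100)])
        return GeneLocus("g1", "chr1", 101, 1100, "+", [t])

    def test_repeat_inside_intron_counts_once(self):
        df, skipped = go.annotate_repeat_overlap([self._gene()], [("chr1", 350, 450)])
        row = df.iloc[0]
        assert row["intron"] == 1 and row["exon"] == 0
        assert row["utr5"] == 0 and row["utr3"] == 0 and skipped == 0

    def test_repeat_spanning_junction_counts_in_both(self):
        df, _ = go.annotate_repeat_overlap([self._gene()], [("chr1", 250, 350)])
        row = df.iloc[0]
        assert row["exon"] == 1 and row["intron"] == 1

    def test_unknown_chromosome_skipped(self):
        df, skipped = go.annotate_repeat_overlap([self._gene()], [("chrZ", 1, 10)])
        assert skipped == 1 and df.iloc[0]["total"] == 0

    def test_matches_bruteforce_oracle_on_random_fixtures(self, rng):
        gene = self._gene()
        for _ in range(100):
            n = int(rng.integers(1, 30))
            repeats = []
            for _ in range(n):
                s = int(rng.integers(1, 1200))
                repeats.append(("chr1", s, s + int(rng.integers(1, 300))))
            df, _ = go.annotate_repeat_overlap([gene], repeats)
            expected = oracle_repeat_counts(gene, repeats)
            row = df.iloc[0]
            assert {k: int(row[k]) for k in expected} == expected
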