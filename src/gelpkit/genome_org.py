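"""Genomic organization of an accepted gene family: positional clusters,
tandem and segmental duplications, exon/intron structure summaries and
repeat-overlap annotation.

The cluster rule is positional: family genes on one chromosome belong to
one cluster when consecutive members are separated by at most
`max_intervening` unrelated annotated genes (TE-related genes count as
intervening). Tandem groups are cluster subsets of near-adjacent,
sequence-similar members; segmental pairs are family genes lying within a
fixed distance of the two sides of a precomputed collinear anchor block.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .io import GeneLocus, chromosome_sort_key

__all__ = [
    "ClusterSet", "DuplicationRecord",
    "detect_clusters", "detect_tandem_groups", "pair_segmental_duplicates",
    "summarize_gene_structure", "annotate_repeat_overlap", "text_ideogram",
]


@dataclass
class ClusterSet:
    clusters: list[list[str]]               # ordered member ids, positional order
    intervening: list[list[int]]            # per cluster, counts between consecutive members
    chromosomes: list[str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for members, counts in zip(self.clusters, self.intervening):
            if len(members) < 2:
                raise ValueError("cluster needs >= 2 members")
            if len(counts) != len(members) - 1:
                raise ValueError("intervening counts must be members-1")
            if seen & set(members):
                raise ValueError("clusters must be disjoint")
            seen |= set(members)


@dataclass
class DuplicationRecord:
    kind: str                               # "tandem" | "segmental"
    members: tuple[str, ...]
    evidence: dict = field(default_factory=dict)


def detect_clusters(
    loci: list[GeneLocus], family_ids: set[str] | list[str], max_intervening: int = 4
) -> ClusterSet:
    """Maximal runs of >= 2 family genes separated by <= `max_intervening`
    non-family genes, scanning each chromosome in positional order."""
    family = set(family_ids)
    present = {g.gene_id for g in loci}
    missing = family - present
    if missing:
        raise KeyError(f"family ids absent from loci: {sorted(missing)}")
    clusters, intervening, chroms = [], [], []
    by_chrom: dict[str, list[GeneLocus]] = {}
    for g in loci:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in sorted(by_chrom, key=chromosome_sort_key):
        genes = sorted(by_chrom[chrom], key=lambda g: (g.start, g.gene_id))
        run: list[str] = []
        counts: list[int] = []
        gap = 0

        def close() -> None:
            nonlocal run, counts
            if len(run) >= 2:
                clusters.append(run)
                intervening.append(counts)
                chroms.append(chrom)
            run, counts = [], []

        for g in genes:
            if g.gene_id in family:
                if run and gap <= max_intervening:
                    counts.append(gap)
                    run.append(g.gene_id)
                else:
                    close()
                    run = [g.gene_id]
                    counts = []
                gap = 0
            else:
                gap += 1
        close()
    return ClusterSet(clusters, intervening, chroms)


def _lookup_distance(distances, a: str, b: str) -> float:
    if callable(distances):
        return float(distances(a, b))
    for key in ((a, b), (b, a), frozenset((a, b))):
        if key in distances:
            return float(distances[key])
    raise KeyError(f"no pairwise distance for ({a}, {b})")


def detect_tandem_groups(
    clusters: ClusterSet,
    pairwise_distances,
    max_intervening_tandem: int = 1,
    max_distance: float = 0.6,
) -> list[DuplicationRecord]:
    """Within each cluster, maximal runs of members that are near-adjacent
    (<= `max_intervening_tandem` intervening genes) and similar in
    sequence (block p-distance <= `max_distance`).

    This is a reconstruction of the tandem criterion, not a database rule:
    both thresholds are configurable.
    """
    records = []
    for members, counts, chrom in zip(
        clusters.clusters, clusters.intervening, clusters.chromosomes
    ):
        run = [members[0]]
        dists: list[float] = []

        def close() -> None:
            nonlocal run, dists
            if len(run) >= 2:
                records.append(DuplicationRecord(
                    kind="tandem", members=tuple(run),
                    evidence={"chromosome": chrom, "max_pairwise_distance": max(dists)},
                ))
            run, dists = [run[-1]] if run else [], []

        for prev, cur, gap in zip(members, members[1:], counts):
            d = _lookup_distance(pairwise_distances, prev, cur)
            if gap <= max_intervening_tandem and d <= max_distance:
                run.append(cur)
                dists.append(d)
            else:
                close()
                run = [cur]
                dists = []
        close()
    return records


def _interval_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    if a[1] < b[0]:
        return b[0] - a[1]
    if b[1] < a[0]:
        return a[0] - b[1]
    return 0


def pair_segmental_duplicates(
    loci: list[GeneLocus],
    family_ids: set[str] | list[str],
    anchors: pd.DataFrame,
    max_collinear_distance: int = 500_000,
) -> list[DuplicationRecord]:
    """Family gene pairs within `max_collinear_distance` of the two sides
    of one collinear anchor block (the 500-kb collinearity rule)."""
    family = set(family_ids)
    by_id = {g.gene_id: g for g in loci}
    fam_by_chrom: dict[str, list[GeneLocus]] = {}
    for gid in sorted(family):
        g = by_id.get(gid)
        if g is not None:
            fam_by_chrom.setdefault(g.chrom, []).append(g)
    seen: set[tuple[str, str]] = set()
    records = []
    for idx, row in anchors.iterrows():
        for col in ("gene_a", "gene_b", "chrom_a", "chrom_b", "block_id"):
            if pd.isna(row.get(col)):
                raise ValueError(f"malformed anchor row {idx}: missing {col}")
        ga, gb = by_id.get(row["gene_a"]), by_id.get(row["gene_b"])
        if ga is None or gb is None:
            raise ValueError(f"malformed anchor row {idx}: unknown anchor gene")
        near_a = [
            (g, _interval_distance((g.start, g.end), (ga.start, ga.end)))
            for g in fam_by_chrom.get(row["chrom_a"], [])
        ]
        near_b = [
            (g, _interval_distance((g.start, g.end), (gb.start, gb.end)))
            for g in fam_by_chrom.get(row["chrom_b"], [])
        ]
        for fa, da in near_a:
            if da > max_collinear_distance:
                continue
            for fb, db in near_b:
                if db > max_collinear_distance or fa.gene_id == fb.gene_id:
                    continue
                pair = tuple(sorted((fa.gene_id, fb.gene_id)))
                if pair in seen:
                    continue
                seen.add(pair)
                records.append(DuplicationRecord(
                    kind="segmental", members=pair,
                    evidence={"block_id": row["block_id"],
                              "distance_a": da, "distance_b": db},
                ))
    return records


def summarize_gene_structure(
    loci: list[GeneLocus], long_intron_threshold: int = 1000
) -> tuple[pd.DataFrame, Counter]:
    """Per-transcript exon/intron statistics plus the family histogram of
    exon/intron count patterns. Introns are the gaps between sorted exons;
    exon and intron lengths always sum to the genomic span."""
    rows = []
    patterns: Counter = Counter()
    for g in loci:
        for t in g.transcripts:
            if not t.exons:
                raise ValueError(f"{t.transcript_id}: transcript without exons")
            introns = [
                (t.exons[i][1] + 1, t.exons[i + 1][0] - 1)
                for i in range(len(t.exons) - 1)
            ]
            intron_lengths = [e - s + 1 for s, e in introns]
            span = t.exons[-1][1] - t.exons[0][0] + 1
            rows.append({
                "gene": g.gene_id,
                "transcript": t.transcript_id,
                "exon_count": len(t.exons),
                "intron_count": len(introns),
                "intron_lengths": ",".join(map(str, intron_lengths)),
                "genomic_span": span,
                "intronless": len(introns) == 0,
                "has_long_intron": any(l > long_intron_threshold for l in intron_lengths),
            })
            patterns[(len(t.exons), len(introns))] += 1
    return pd.DataFrame(rows), patterns


def _subtract(intervals: list[tuple[int, int]], cuts: list[tuple[int, int]]):
    out = list(intervals)
    for cs, ce in cuts:
        nxt = []
        for s, e in out:
            if ce < s or cs > e:
                nxt.append((s, e))
                continue
            if s < cs:
                nxt.append((s, cs - 1))
            if ce < e:
                nxt.append((ce + 1, e))
        out = nxt
    return out


def annotate_repeat_overlap(
    loci: list[GeneLocus], repeats: list[tuple[int, int, int] | tuple[str, int, int]]
) -> tuple[pd.DataFrame, int]:
    """Per-gene repeat counts by region (exon, intron, 5'UTR, 3'UTR).

    A repeat counts in a region when it overlaps it by >= 1 bp; a repeat
    spanning a junction counts in both regions. Exonic regions exclude the
    UTR portions so the four region classes are disjoint. Repeats on
    chromosomes absent from the annotation are skipped and counted.
    Repeats are 1-based closed here (BED input is converted on read).
    """
    known = {g.chrom for g in loci}
    skipped = 0
    per_chrom: dict[str, list] = {}
    for chrom, s, e in repeats:
        if chrom not in known:
            skipped += 1
            continue
        per_chrom.setdefault(chrom, []).append((s, e))
    rows = []
    for g in loci:
        t = g.transcripts[0] if g.transcripts else None
        regions = {"exon": [], "intron": [], "utr5": [], "utr3": []}
        if t is not None:
            regions["exon"] = _subtract(t.exons, t.utr5 + t.utr3)
            regions["intron"] = [
                (t.exons[i][1] + 1, t.exons[i + 1][0] - 1)
                for i in range(len(t.exons) - 1)
            ]
            regions["utr5"] = list(t.utr5)
            regions["utr3"] = list(t.utr3)
        counts = {k: 0 for k in regions}
        for rs, re_ in per_chrom.get(g.chrom, []):
            for region, ivs in regions.items():
                if any(not (re_ < s or rs > e) for s, e in ivs):
                    counts[region] += 1
        rows.append({"gene": g.gene_id, **counts,
                     "total": sum(counts.values())})
    return pd.DataFrame(rows), skipped


def text_ideogram(
    loci: list[GeneLocus], family_ids: set[str], names: dict[str, str] | None = None,
    clusters: ClusterSet | None = None,
) -> str:
    """Plain-text chromosome map of the family (distribution-figure analog)."""
    names = names or {}
    in_cluster = {}
    if clusters is not None:
        for i, members in enumerate(clusters.clusters):
            for m in members:
                in_cluster[m] = f"cluster-{i + 1}"
    by_chrom: dict[str, list[GeneLocus]] = {}
    for g in loci:
        if g.gene_id in family_ids:
            by_chrom.setdefault(g.chrom, []).append(g)
    lines = []
    for chrom in sorted(by_chrom, key=chromosome_sort_key):
        genes = sorted(by_chrom[chrom], key=lambda g: g.start)
        lines.append(f"{chrom} ({len(genes)} family genes)")
        for g in genes:
            arrow = ">" if g.strand == "+" else "<"
            label = names.get(g.gene_id, g.gene_id)
            extra = f"  [{in_cluster[g.gene_id]}]" if g.gene_id in in_cluster else ""
            lines.append(f"  {g.start:>9}-{g.end:<9} {arrow} {label}{extra}")
    return "\n".join(lines) + "\n"
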