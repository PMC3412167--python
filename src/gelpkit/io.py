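"""File formats and genomic-coordinate containers.

All genomic coordinates held in :class:`GeneLocus`/:class:`Transcript` are
1-based closed intervals, matching GFF3 on disk. BED input is 0-based
half-open and is converted here, at the boundary, so that no other module
ever performs a coordinate conversion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Transcript",
    "GeneLocus",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_bed",
    "read_anchors",
    "read_ct_table",
    "chromosome_sort_key",
]


@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]]          # 1-based closed, sorted, non-overlapping
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.transcript_id}: exon start {s} > end {e}")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            prev_end = e


@dataclass
class GeneLocus:
    gene_id: str
    chrom: str
    start: int                            # 1-based closed
    end: int
    strand: str = "+"
    transcripts: list[Transcript] = field(default_factory=list)
    is_family_member: bool = False
    is_te_related: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        for t in self.transcripts:
            for s, e in t.exons:
                if s < self.start or e > self.end:
                    raise ValueError(
                        f"{self.gene_id}/{t.transcript_id}: exon ({s},{e}) outside gene"
                    )

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def chromosome_sort_key(chrom: str) -> tuple:
    """Natural ordering for chromosome names: chr2 before chr10."""
    parts = re.split(r"(\d+)", chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(loci: list[GeneLocus], path) -> None:
    """Emit gene/mRNA/exon/UTR features, 1-based closed per the GFF3 spec."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in loci:
            attrs = f"ID={g.gene_id}"
            if g.is_te_related:
                attrs += ";te_related=1"
            fh.write(
                f"{g.chrom}\tgelpkit\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for t in g.transcripts:
                fh.write(
                    f"{g.chrom}\tgelpkit\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={g.gene_id}\n"
                )
                for s, e in t.exons:
                    fh.write(
                        f"{g.chrom}\tgelpkit\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                        f"Parent={t.transcript_id}\n"
                    )
                for kind, ivs in (("five_prime_UTR", t.utr5), ("three_prime_UTR", t.utr3)):
                    for s, e in ivs:
                        fh.write(
                            f"{g.chrom}\tgelpkit\t{kind}\t{s}\t{e}\t.\t{g.strand}\t.\t"
                            f"Parent={t.transcript_id}\n"
                        )


def read_gff3(path) -> list[GeneLocus]:
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    loci = []
    for gene in db.features_of_type("gene"):
        transcripts = []
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
            utr5 = [(f.start, f.end) for f in db.children(mrna, featuretype="five_prime_UTR")]
            utr3 = [(f.start, f.end) for f in db.children(mrna, featuretype="three_prime_UTR")]
            transcripts.append(Transcript(mrna.id, exons, utr5, utr3))
        loci.append(
            GeneLocus(
                gene_id=gene.id,
                chrom=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand if gene.strand in ("+", "-") else "+",
                transcripts=transcripts,
                is_te_related=gene.attributes.get("te_related", ["0"])[0] == "1",
            )
        )
    loci.sort(key=lambda g: (chromosome_sort_key(g.chrom), g.start, g.gene_id))
    return loci


# ---------------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------------

def read_bed(path) -> list[tuple[str, int, int]]:
    """BED3 intervals, converted from 0-based half-open to 1-based closed."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.append((chrom, int(start) + 1, int(end)))
    return out


def read_anchors(path) -> pd.DataFrame:
    """Collinear-anchor table: gene_a, gene_b, chrom_a, chrom_b, block_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_a", "gene_b", "chrom_a", "chrom_b", "block_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"anchor table missing columns: {sorted(missing)}")
    return df


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "condition", "replicate", "ct_target", "ct_reference"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"CT table missing columns: {sorted(missing)}")
    return df
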