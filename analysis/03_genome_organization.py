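"""Genomic organization of the accepted family.

Positional clusters (<= 4 intervening unrelated genes), segmental
duplicate pairs (within 500 kb of collinear anchors), exon/intron
structure statistics and repeat overlap by gene region, plus a text
ideogram. Tandem groups need sequence distances and are produced by the
phylogeny stage (05) from the block alignment.
"""

import argparse
from collections import Counter
from pathlib import Path

import pandas as pd

from gelpkit import genome_org as go
from gelpkit.io import read_anchors, read_bed, read_gff3


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    data = args.outdir / "data"

    loci = read_gff3(data / "annotation.gff3")
    members = pd.read_csv(args.outdir / "members.tsv", sep="\t")
    family = [g for g in members["gene"] if any(l.gene_id == g for l in loci)]
    names = dict(zip(members["gene"], members["name"]))

    clusters = go.detect_clusters(loci, family)
    pd.DataFrame({
        "cluster": range(1, len(clusters.clusters) + 1),
        "chromosome": clusters.chromosomes,
        "members": [",".join(c) for c in clusters.clusters],
        "intervening": [",".join(map(str, c)) for c in clusters.intervening],
    }).to_csv(args.outdir / "clusters.tsv", sep="\t", index=False)

    segmental = go.pair_segmental_duplicates(
        loci, family, read_anchors(data / "collinear_anchors.tsv")
    )
    pd.DataFrame([
        {"gene_a": r.members[0], "gene_b": r.members[1], **r.evidence}
        for r in segmental
    ]).to_csv(args.outdir / "segmental_pairs.tsv", sep="\t", index=False)

    fam_loci = [l for l in loci if l.gene_id in set(family)]
    structure, patterns = go.summarize_gene_structure(fam_loci)
    structure.to_csv(args.outdir / "gene_structure.tsv", sep="\t", index=False)

    repeats_df, skipped = go.annotate_repeat_overlap(fam_loci, read_bed(data / "repeats.bed"))
    repeats_df.to_csv(args.outdir / "repeat_overlap.tsv", sep="\t", index=False)

    (args.outdir / "ideogram.txt").write_text(
        go.text_ideogram(loci, set(family), names=names, clusters=clusters)
    )

    in_cluster = sum(len(c) for c in clusters.clusters)
    print(f"{len(clusters.clusters)} clusters hold {in_cluster}/{len(family)} "
          f"family genes ({100 * in_cluster / len(family):.1f}%)")
    print(f"{len(segmental)} segmental duplicate pairs within 500 kb of anchors")
    top = Counter(dict(patterns)).most_common(1)[0]
    print(f"most common structure: {top[0][0]} exons / {top[0][1]} introns "
          f"({top[1]}/{len(structure)} transcripts); "
          f"{int(structure['intronless'].sum())} intronless")
    print(f"repeats overlapping family genes: "
          f"{int(repeats_df['total'].sum())} region hits ({skipped} repeats skipped)")


if __name__ == "__main__":
    main()
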