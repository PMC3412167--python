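"""Classify motifs as family-common or subclade-specific and map them
onto secondary-structure topology to flag the variable loops.
"""

import argparse
from pathlib import Path

import pandas as pd

from gelpkit.clade_map import (
    classify_motif_specificity,
    map_motifs_to_topology,
    text_architecture,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    occ = pd.read_csv(args.outdir / "occurrences.tsv", sep="\t")
    clades = pd.read_csv(args.outdir / "clades.tsv", sep="\t")
    assignment = dict(zip(clades["gene"], clades["subclade"]))
    motifs = pd.read_csv(args.outdir / "motif_summary.tsv", sep="\t")
    widths = dict(zip(motifs["motif"], motifs["width"]))
    topo = pd.read_csv(args.outdir / "data" / "topology.tsv", sep="\t")
    topologies = dict(zip(topo["protein"], topo["structure"]))

    calls = classify_motif_specificity(occ, assignment)
    pd.DataFrame([
        {"motif": c.motif_id, "class": c.call,
         "subclades": ",".join(c.subclades),
         "carrier_fraction": round(c.carrier_fraction, 3)}
        for c in calls
    ]).to_csv(args.outdir / "motif_specificity.tsv", sep="\t", index=False)

    table, majority, flagged = map_motifs_to_topology(
        occ, topologies, widths, specificity=calls
    )
    table.to_csv(args.outdir / "motif_topology.tsv", sep="\t", index=False)
    (args.outdir / "motif_architecture.txt").write_text(
        text_architecture(occ, assignment, calls)
    )

    counts = {k: sum(1 for c in calls if c.call == k)
              for k in ("common", "specific", "nonspecific")}
    print(f"motif classes: {counts}")
    for c in calls:
        if c.call == "specific":
            print(f"  {c.motif_id}: exclusive to {'/'.join(c.subclades)} "
                  f"({majority.get(c.motif_id, '?')} majority element)")
    print(f"variable loops carrying subclade-specific motifs: "
          f"{sorted(flagged) or 'none'}")


if __name__ == "__main__":
    main()
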