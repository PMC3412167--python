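"""Motif specificity classes and motif-to-topology mapping.

A motif is *common* when it occurs in at least `common_threshold` of the
retained proteins, *specific* when its carriers fall exclusively into one
to three subclades (each with a minimum carrier count), and *nonspecific*
otherwise; the precedence is common > specific > nonspecific. Specific
motifs are then mapped onto secondary-structure topology strings to flag
the variable loops that distinguish subclades.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "SpecificityCall", "TopologyAnnotation", "parse_topology",
    "classify_motif_specificity", "map_motifs_to_topology",
    "text_architecture",
]


@dataclass
class SpecificityCall:
    motif_id: str
    call: str                                   # common | specific | nonspecific
    subclades: tuple[str, ...] = ()
    carrier_counts: dict = field(default_factory=dict)
    carrier_fraction: float = 0.0


@dataclass
class TopologyAnnotation:
    """Per-protein secondary structure over {H, E, C} with the derived
    element list (alpha1.., beta1.., L1..) in N-to-C order.

    Element intervals are 0-based half-open, matching motif occurrence
    coordinates. Loops are maximal C-runs, including the termini.
    """

    protein: str
    structure: str
    elements: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.structure) - set("HEC")
        if bad:
            raise ValueError(f"{self.protein}: bad structure characters {sorted(bad)}")
        if not self.elements:
            self.elements = parse_topology(self.structure)


def parse_topology(structure: str) -> list[tuple[str, int, int]]:
    """Maximal runs of H (helices), E (strands) and C (loops), numbered
    per kind in N-to-C order: alpha1.., beta1.., L1.. ."""
    elements = []
    counters = {"H": 0, "E": 0, "C": 0}
    prefix = {"H": "alpha", "E": "beta", "C": "L"}
    i = 0
    while i < len(structure):
        j = i
        while j < len(structure) and structure[j] == structure[i]:
            j += 1
        kind = structure[i]
        counters[kind] += 1
        elements.append((f"{prefix[kind]}{counters[kind]}", i, j))
        i = j
    return elements


def classify_motif_specificity(
    occurrences: pd.DataFrame,
    clade_assignment: dict[str, str],
    common_threshold: float = 0.9,
    min_carriers: int = 2,
) -> list[SpecificityCall]:
    """One call per motif, mutually exclusive by precedence.

    Carriers labelled "unassigned" (or absent from the assignment) count
    against exclusivity: any such carrier blocks a "specific" call.
    """
    proteins = set(clade_assignment)
    n = len(proteins)
    if n == 0:
        raise ValueError("empty clade assignment")
    calls = []
    for motif, group in occurrences.groupby("motif", sort=True):
        carriers = sorted(set(group["sequence"]))
        labels = [clade_assignment.get(c, "unassigned") for c in carriers]
        counts = Counter(labels)
        fraction = len([c for c in carriers if c in proteins]) / n
        subclade_counts = {k: v for k, v in counts.items() if k != "unassigned"}
        if fraction >= common_threshold:
            call = SpecificityCall(str(motif), "common",
                                   carrier_counts=dict(counts),
                                   carrier_fraction=fraction)
        elif (
            "unassigned" not in counts
            and 1 <= len(subclade_counts) <= 3
            and all(v >= min_carriers for v in subclade_counts.values())
        ):
            call = SpecificityCall(str(motif), "specific",
                                   subclades=tuple(sorted(subclade_counts)),
                                   carrier_counts=dict(counts),
                                   carrier_fraction=fraction)
        else:
            call = SpecificityCall(str(motif), "nonspecific",
                                   carrier_counts=dict(counts),
                                   carrier_fraction=fraction)
        calls.append(call)
    return calls


def text_architecture(
    occurrences: pd.DataFrame,
    clade_assignment: dict[str, str] | None = None,
    specificity: list[SpecificityCall] | None = None,
) -> str:
    """Plain-text motif-architecture diagram: one line per protein with
    its motifs in N-to-C order, subclade-specific motifs starred."""
    specific = {c.motif_id for c in (specificity or []) if c.call == "specific"}
    lines = []
    for prot, group in occurrences.groupby("sequence", sort=True):
        motifs = [
            f"{m}*" if m in specific else str(m)
            for m in group.sort_values("start")["motif"]
        ]
        label = (clade_assignment or {}).get(prot, "")
        tag = f" [{label}]" if label else ""
        lines.append(f"{prot}{tag}: " + " - ".join(motifs))
    return "\n".join(lines) + "\n"


def map_motifs_to_topology(
    occurrences: pd.DataFrame,
    topologies: dict[str, TopologyAnnotation | str],
    motif_widths: dict[str, int],
    sequences: dict[str, str] | None = None,
    specificity: list[SpecificityCall] | None = None,
) -> tuple[pd.DataFrame, dict[str, str], set[str]]:
    """Assign each motif occurrence to every topology element it overlaps
    by >= 1 residue.

    Returns (per-occurrence element table, per-motif majority element,
    flagged loops). A loop is flagged when at least one subclade-specific
    motif occurrence overlaps it (requires `specificity`).
    """
    annos: dict[str, TopologyAnnotation] = {}
    for prot, t in topologies.items():
        annos[prot] = t if isinstance(t, TopologyAnnotation) else TopologyAnnotation(prot, t)
        if sequences is not None and prot in sequences:
            if len(annos[prot].structure) != len(sequences[prot]):
                raise ValueError(
                    f"topology length mismatch for protein {prot}: "
                    f"{len(annos[prot].structure)} != {len(sequences[prot])}"
                )
    specific_ids = {
        c.motif_id for c in (specificity or []) if c.call == "specific"
    }
    rows = []
    element_votes: dict[str, Counter] = {}
    flagged: set[str] = set()
    for _, occ in occurrences.iterrows():
        prot = occ["sequence"]
        if prot not in annos:
            continue
        motif = str(occ["motif"])
        start = int(occ["start"])
        end = start + motif_widths[motif]
        hit_elements = [
            name for name, s, e in annos[prot].elements
            if s < end and start < e
        ]
        rows.append({"motif": motif, "sequence": prot, "start": start,
                     "elements": ",".join(hit_elements)})
        votes = element_votes.setdefault(motif, Counter())
        for name in hit_elements:
            votes[name] += 1
        if motif in specific_ids:
            flagged |= {name for name in hit_elements if name.startswith("L")}
    majority = {
        motif: min(votes.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        for motif, votes in element_votes.items() if votes
    }
    table = pd.DataFrame(rows, columns=["motif", "sequence", "start", "elements"])
    return table, majority, flagged
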