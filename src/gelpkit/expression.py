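"""Relative expression by the ddCT method, 2-fold regulation calls,
qPCR/microarray concordance, and the tissue-evidence presence matrix.

ddCT = (mean target CT - mean reference CT) under treatment minus the same
difference under control; fold change = 2^(-ddCT), assuming perfect
doubling per cycle (no efficiency correction). Replicates are averaged on
the CT scale before differencing.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FoldChange", "EvidenceMatrix",
    "ddct_fold", "classify_regulation", "concordance", "build_evidence_matrix",
]

EVIDENCE_SOURCES = ("EST", "FL-cDNA", "MPSS", "microarray")


@dataclass
class FoldChange:
    gene: str
    fold: float
    sd_log2: float
    call: str | None = None

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold must be > 0")


@dataclass
class EvidenceMatrix:
    presence: pd.DataFrame                  # genes x tissues, bool
    sources: dict                           # (gene, tissue) -> sorted source list
    expressed: dict[str, bool]
    source_counts: Counter


def ddct_fold(table: pd.DataFrame, gene: str) -> FoldChange:
    """2^(-ddCT) for one gene, with the pooled replicate SD of the
    per-replicate dCT (already a log2-scale quantity)."""
    sub = table[table["gene"] == gene]
    if sub.empty:
        raise ValueError(f"gene {gene} not in CT table")
    dct = {}
    sds = []
    ns = []
    for cond in ("control", "treated"):
        rows = sub[sub["condition"] == cond]
        if rows.empty:
            raise ValueError(f"gene {gene}: missing condition {cond!r}")
        per_rep = rows["ct_target"].to_numpy() - rows["ct_reference"].to_numpy()
        if not np.isfinite(per_rep).all():
            raise ValueError(f"gene {gene}: non-finite CT values")
        dct[cond] = float(per_rep.mean())
        ns.append(len(per_rep))
        sds.append(float(per_rep.var(ddof=1)) if len(per_rep) > 1 else 0.0)
    ddct = dct["treated"] - dct["control"]
    dof = sum(n - 1 for n in ns)
    pooled = (
        np.sqrt(sum(v * (n - 1) for v, n in zip(sds, ns)) / dof) if dof > 0 else 0.0
    )
    return FoldChange(gene=gene, fold=float(2.0 ** (-ddct)), sd_log2=float(pooled))


def fold_table(table: pd.DataFrame) -> dict[str, FoldChange]:
    """ddct_fold for every gene in a CT table."""
    return {g: ddct_fold(table, g) for g in sorted(table["gene"].unique())}


def classify_regulation(
    folds: dict[str, float] | dict[str, FoldChange], cutoff: float = 2.0
) -> dict[str, str]:
    """up if fold > cutoff, down if fold < 1/cutoff, else ns."""
    if cutoff <= 1.0:
        raise ValueError("cutoff must be > 1")
    calls = {}
    for gene, f in folds.items():
        fold = f.fold if isinstance(f, FoldChange) else float(f)
        if fold <= 0:
            raise ValueError(f"gene {gene}: fold must be > 0")
        if fold > cutoff:
            calls[gene] = "up"
        elif fold < 1.0 / cutoff:
            calls[gene] = "down"
        else:
            calls[gene] = "ns"
    return calls


def concordance(
    qpcr_folds: dict[str, float],
    microarray_folds: dict[str, float],
    cutoff: float = 2.0,
) -> tuple[pd.DataFrame, Counter]:
    """Per-gene platform agreement: concordant iff both platforms give the
    same direction call at the cutoff."""
    shared = sorted(set(qpcr_folds) & set(microarray_folds))
    if not shared:
        raise ValueError("no genes shared between platforms")
    q_calls = classify_regulation({g: qpcr_folds[g] for g in shared}, cutoff)
    m_calls = classify_regulation({g: microarray_folds[g] for g in shared}, cutoff)
    rows = []
    summary: Counter = Counter()
    for g in shared:
        agree = "concordant" if q_calls[g] == m_calls[g] else "discordant"
        summary[agree] += 1
        rows.append({"gene": g, "qpcr_call": q_calls[g],
                     "microarray_call": m_calls[g], "agreement": agree})
    return pd.DataFrame(rows), summary


def build_evidence_matrix(
    records: pd.DataFrame,
    tissues: list[str],
    genes: list[str] | None = None,
) -> EvidenceMatrix:
    """Gene x tissue presence from expression-evidence records.

    `records` needs columns gene, tissue, source. A cell is present iff at
    least one record supports it; genes with zero records are flagged
    unexpressed. Unknown tissue or source labels raise.
    """
    for col in ("gene", "tissue", "source"):
        if col not in records.columns:
            raise ValueError(f"evidence records missing column {col!r}")
    bad_tissue = set(records["tissue"]) - set(tissues)
    if bad_tissue:
        raise ValueError(
            f"unknown tissue labels {sorted(bad_tissue)}; accepted: {list(tissues)}"
        )
    bad_source = set(records["source"]) - set(EVIDENCE_SOURCES)
    if bad_source:
        raise ValueError(
            f"unknown evidence sources {sorted(bad_source)}; accepted: {list(EVIDENCE_SOURCES)}"
        )
    gene_list = sorted(set(records["gene"]) | set(genes or []))
    presence = pd.DataFrame(False, index=gene_list, columns=list(tissues))
    sources: dict = {}
    source_counts: Counter = Counter()
    for _, row in records.iterrows():
        presence.loc[row["gene"], row["tissue"]] = True
        sources.setdefault((row["gene"], row["tissue"]), set()).add(row["source"])
        source_counts[row["source"]] += 1
    expressed = {g: bool(presence.loc[g].any()) for g in gene_list}
    sources = {k: sorted(v) for k, v in sources.items()}
    return EvidenceMatrix(presence, sources, expressed, source_counts)
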