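"""End-to-end survey over a synthetic family: identification, genomic
organization, motif discovery, block phylogeny, specificity calls and
expression quantification, with recovery metrics against the generator's
ground truth.

This is the glue the numbered analysis drivers and the acceptance script
run; every step is a library call from the stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import child_seed
from . import domain_scan as ds
from . import expression as expr
from . import genome_org as go
from . import motifs as mo
from . import phylogeny as ph
from .clade_map import classify_motif_specificity
from .synthetic import FamilyData, FamilySimConfig, simulate_family


def consensus_identity(discovered: str, planted: str) -> float:
    """Fraction of planted-consensus columns matched by the discovered
    consensus at the best ungapped offset."""
    best = 0
    for off in range(-len(discovered) + 1, len(planted)):
        matches = sum(
            1 for k in range(len(planted))
            if 0 <= k - off < len(discovered) and discovered[k - off] == planted[k]
        )
        best = max(best, matches)
    return best / len(planted)


def planted_motif_recovery(
    models: list[mo.MotifModel], config: FamilySimConfig
) -> dict[str, tuple[str | None, float]]:
    """Best-matching discovered motif (id, consensus identity) per planted
    motif consensus."""
    out = {}
    for i, (consensus, _w, _clade) in enumerate(config.planted_motifs):
        best_id, best_ident = None, 0.0
        for m in models:
            ident = consensus_identity(mo.summarize_motif(m).consensus, consensus)
            if ident > best_ident:
                best_id, best_ident = m.motif_id, ident
        out[f"planted{i + 1}"] = (best_id, best_ident)
    return out


def map_clade_labels(
    inferred: dict[str, str], truth: dict[str, str]
) -> dict[str, str]:
    """Inferred clade label -> truth clade label, matched by smallest leaf
    (both labellings order their groups by smallest member)."""
    by_inferred: dict[str, list[str]] = {}
    for leaf, lab in inferred.items():
        by_inferred.setdefault(lab, []).append(leaf)
    return {
        lab: truth.get(min(leaves), "unassigned")
        for lab, leaves in by_inferred.items() if lab != "unassigned"
    }


@dataclass
class SurveyResult:
    family: FamilyData
    profile: ds.BlockProfile
    hits: list[ds.DomainHit]
    accepted: list[str]
    rejection_ledger: pd.DataFrame
    names: dict[str, str]
    clusters: go.ClusterSet
    tandem: list[go.DuplicationRecord]
    segmental: list[go.DuplicationRecord]
    motif_models: list[mo.MotifModel]
    occurrences: pd.DataFrame
    selection: ph.BlockSelection
    alignment: ph.ConcatAlignment
    tree: "object"
    clade_assignment: ph.CladeAssignment
    specificity: list
    folds: dict[str, expr.FoldChange]
    regulation: dict[str, str]
    metrics: dict = field(default_factory=dict)


def run_survey(
    config: FamilySimConfig | None = None,
    seed: int = 0,
    n_bootstrap: int = 200,
    distance_model: str = "kimura",
    motif_kwargs: dict | None = None,
    scan_shuffles: int = 19,
) -> SurveyResult:
    config = config or FamilySimConfig(seed=seed)
    fam = simulate_family(config)
    family_ids = set(fam.proteins)

    # 1. identification
    profile = ds.build_profile(
        fam.seed_block_alignment(), catalytic=fam.truth.catalytic_positions
    )
    hits = ds.scan_proteins(
        profile, fam.all_proteins, n_shuffles=scan_shuffles,
        seed=child_seed(seed, "scan"),
    )
    accepted, ledger = ds.apply_filters(hits, fam.all_proteins)
    with_loci = [g for g in accepted if any(l.gene_id == g for l in fam.loci)]
    names = ds.assign_nomenclature(with_loci, fam.loci, prefix="GELP")

    # 2. genomic organization
    clusters = go.detect_clusters(fam.loci, [g for g in accepted if g in family_ids])
    segmental = go.pair_segmental_duplicates(
        fam.loci, [g for g in accepted if g in family_ids], fam.anchors
    )

    # 3. motif discovery on the accepted family
    member_proteins = {g: fam.all_proteins[g] for g in accepted if g in family_ids}
    models, occurrences = mo.discover_motifs(
        member_proteins, seed=child_seed(seed, "motifs"), **(motif_kwargs or {})
    )

    # 4. block phylogeny
    widths = {m.motif_id: m.width for m in models}
    evalues = {m.motif_id: m.evalue for m in models}
    selection = ph.select_blocks(
        occurrences, sorted(member_proteins), widths, evalues=evalues
    )
    alignment = ph.concatenate_blocks(selection, occurrences, member_proteins)
    tree = ph.bootstrap_support(
        alignment, n_replicates=n_bootstrap, model=distance_model,
        seed=child_seed(seed, "bootstrap"),
    )
    clades = ph.extract_subclades(tree, n_groups=config.n_clades)

    # tandem detection needs block p-distances for every cluster member,
    # including gap-rich ones excluded from the tree alignment
    pdist = ph.pairwise_block_pdistance(selection, occurrences, member_proteins)
    tandem = go.detect_tandem_groups(clusters, pdist)

    # 5. specificity, with inferred labels translated to truth labels
    label_map = map_clade_labels(clades.assignment, fam.truth.true_clades)
    relabelled = {
        leaf: label_map.get(lab, "unassigned")
        for leaf, lab in clades.assignment.items()
    }
    specificity = classify_motif_specificity(occurrences, relabelled)

    # 6. expression
    folds = expr.fold_table(fam.ct_table)
    regulation = expr.classify_regulation(folds)

    # recovery metrics against truth
    rf = ph.rf_distance(tree, fam.truth.true_tree)
    recovery = planted_motif_recovery(models, config)
    fold_err = {
        g: abs(np.log2(folds[g].fold) - np.log2(t))
        for g, t in fam.truth.true_folds.items()
    }
    metrics = {
        "n_family": len(family_ids),
        "n_decoys": len(fam.decoy_proteins),
        "n_accepted_family": len([g for g in accepted if g in family_ids]),
        "n_accepted_decoys": len([g for g in accepted if g not in family_ids]),
        "n_clusters": len(clusters.clusters),
        "n_tandem_groups": len(tandem),
        "n_segmental_pairs": len(segmental),
        "n_motifs": len(models),
        "n_blocks_selected": len(selection.selected),
        "n_retained": len(selection.retained),
        "n_excluded_gap_rich": len(selection.excluded),
        "rf_distance": rf,
        "planted_motif_identity": {k: v[1] for k, v in recovery.items()},
        "max_fold_log2_error": max(fold_err.values()) if fold_err else 0.0,
    }
    return SurveyResult(
        family=fam, profile=profile, hits=hits, accepted=accepted,
        rejection_ledger=ledger, names=names, clusters=clusters,
        tandem=tandem, segmental=segmental, motif_models=models,
        occurrences=occurrences, selection=selection, alignment=alignment,
        tree=tree, clade_assignment=clades, specificity=specificity,
        folds=folds, regulation=regulation, metrics=metrics,
    )
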