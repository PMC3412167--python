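"""Synthetic gene-family generator with machine-readable ground truth.

Emulates a divergent protein family of the GDSL esterase/lipase kind: a
conserved multi-block core evolved on a known tree at low substitution
rate, divergent inter-block linkers, clade-restricted planted motifs, a
chromosome layout with planted gene clusters, tandem arrays and segmental
duplicate pairs, and qPCR CT tables with planted fold changes. Every
planted feature is recorded in a :class:`SyntheticTruth` bundle so each
downstream analysis stage has a recovery test with known answers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from ._seeds import child_seed
from .alphabet import AA, AA_IDX as _AA_IDX
from .io import GeneLocus, Transcript, write_fasta, write_gff3
from .phylogeny import balanced_partition

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


def block_labels(n_blocks: int) -> list[str]:
    """Conserved-block labels. Four blocks use the family's canonical
    I/II/III/V naming (block IV of the original five-block scheme carries
    no catalytic residue and is the one most often lost)."""
    if n_blocks == 4:
        return ["I", "II", "III", "V"]
    return _ROMAN[:n_blocks] if n_blocks <= len(_ROMAN) else [f"B{i+1}" for i in range(n_blocks)]


@dataclass
class FamilySimConfig:
    """Study conditions for one synthetic family.

    Defaults describe a 24-member family with four conserved blocks of ten
    residues, three clade-restricted planted motifs, two planted gene
    clusters, one tandem array, two segmental duplicate pairs, and fold
    changes spanning 0.25x to 8x measured with 0.1-cycle CT noise.
    """

    n_taxa: int = 24
    n_blocks: int = 4
    block_width: int = 10
    block_sub_prob: float = 0.02
    linker_sub_rate: float = 0.5
    linker_len_range: tuple[int, int] = (20, 30)
    # consensi drawn from pairwise-disjoint residue sets, repeat-free:
    # two deterministic signals sharing even a couple of aligned residues
    # give a ZOOPS search a foothold to merge them into one bimodal
    # mixture PWM, which would make the planted signals unidentifiable by
    # construction rather than by any failure of the method
    planted_motifs: list[tuple[str, int, str]] = field(
        default_factory=lambda: [
            ("WYHKQFM", 7, "cladeA"),
            ("CRGPLIV", 7, "cladeB"),
            ("ATSNED", 6, "cladeC"),
        ]
    )
    n_clades: int = 3
    n_chromosomes: int = 5
    chromosome_length: int = 8_000_000
    # clusters use >= 2 intervening decoys between members so that planted
    # clusters are never also trivially tandem (tandem arrays are adjacent)
    cluster_specs: list[tuple[int, list[int]]] = field(
        default_factory=lambda: [(3, [2, 4]), (2, [2])]
    )
    tandem_specs: list[tuple[int, float]] = field(default_factory=lambda: [(2, 0.8)])
    segmental_pairs: int = 2
    n_decoy_proteins: int = 50
    decoy_protein_length: int = 180
    expression_effects: dict[str, float] | None = None
    ct_noise_sd: float = 0.1
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if not (0.0 <= self.block_sub_prob < 1.0):
            raise ValueError("block_sub_prob must lie in [0, 1)")
        for consensus, width, clade in self.planted_motifs:
            if not (6 <= width <= 15):
                raise ValueError(f"planted motif width {width} outside [6, 15]")
            if len(consensus) != width:
                raise ValueError(f"motif {consensus!r} length != declared width {width}")
        for _, intervening in self.cluster_specs:
            for c in intervening:
                if c not in (0, 1, 2, 3, 4):
                    raise ValueError("intervening gene counts must be in {0..4}")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        if self.expression_effects is not None:
            for g, f in self.expression_effects.items():
                if f <= 0:
                    raise ValueError(f"fold for {g} must be > 0")


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated family."""

    true_tree: str                                  # Newick, rooted, with lengths
    true_clades: dict[str, str]                     # leaf -> clade label
    true_motif_placements: list[tuple[str, str, int]]   # (motif id, seq id, 0-based start)
    true_block_coords: dict[str, list[tuple[int, int]]] # seq -> per-block (start, end) 0-based half-open
    block_labels: list[str]
    catalytic_positions: dict[str, tuple[str, int, str]]  # name -> (block label, offset, residue)
    true_clusters: list[list[str]]
    true_tandem_groups: list[list[str]]
    true_segmental_pairs: list[tuple[str, str]]
    true_folds: dict[str, float]
    decoy_gene_ids: list[str]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        d["true_motif_placements"] = [tuple(x) for x in d["true_motif_placements"]]
        d["true_block_coords"] = {k: [tuple(x) for x in v] for k, v in d["true_block_coords"].items()}
        d["catalytic_positions"] = {k: tuple(v) for k, v in d["catalytic_positions"].items()}
        d["true_segmental_pairs"] = [tuple(x) for x in d["true_segmental_pairs"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

def simulate_tree(n_taxa: int, seed: int) -> dendropy.Tree:
    """Pure-birth (Yule) tree with `n_taxa` leaves, unit speciation rate.

    Leaves are labelled fam001..famN in order of appearance; all branch
    lengths are strictly positive exponential waiting times.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    # start with two lineages born at time 0
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, 0.0))
    t = 0.0
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / k)
        i = int(rng.integers(k))
        node, birth = active.pop(i)
        node.edge.length = t - birth
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
    t += rng.exponential(1.0 / n_taxa)
    # freeze leaf order deterministically before labelling
    width = max(3, len(str(n_taxa)))
    for j, (node, birth) in enumerate(active):
        node.edge.length = t - birth
        taxon = tns.new_taxon(label=f"fam{j + 1:0{width}d}")
        node.taxon = taxon
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def _mutate_block(block: list[str], p: float, frozen: set[int], rng) -> list[str]:
    out = list(block)
    if p <= 0:
        return out
    for i in range(len(out)):
        if i in frozen:
            continue
        if rng.random() < p:
            out[i] = AA[(_AA_IDX[out[i]] + 1 + int(rng.integers(19))) % 20]
    return out


def _mutate_linker(linker: list[str], rate: float, lo: int, hi: int, rng) -> list[str]:
    out = list(linker)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = AA[(_AA_IDX[out[i]] + 1 + int(rng.integers(19))) % 20]
    # at most one geometric-length indel per branch, clamped to the
    # configured linker length range so downstream coordinates stay sane
    if rng.random() < rate:
        length = int(rng.geometric(0.5))
        if rng.random() < 0.5:
            pos = int(rng.integers(len(out) + 1))
            ins = [AA[int(rng.integers(20))] for _ in range(length)]
            out = out[:pos] + ins + out[pos:]
        else:
            pos = int(rng.integers(max(1, len(out))))
            del out[pos:pos + length]
        if len(out) > hi:
            out = out[:hi]
        while len(out) < lo:
            out.append(AA[int(rng.integers(20))])
    return out


def clade_partition(tree: dendropy.Tree, n_clades: int) -> dict[str, str]:
    """Leaf -> clade label, by balanced edge-cuts of the unrooted topology.

    Parts are labelled cladeA, cladeB, ... in order of their smallest leaf
    label, so the labelling depends only on the topology and leaf names.
    """
    parts = balanced_partition(tree, n_clades)
    parts = sorted(parts, key=lambda s: min(s))
    labels = {}
    for i, part in enumerate(parts):
        name = f"clade{chr(ord('A') + i)}"
        for leaf in part:
            labels[leaf] = name
    return labels


def evolve_family_sequences(
    tree: dendropy.Tree, config: FamilySimConfig
) -> tuple[dict[str, str], dict]:
    """Evolve block/linker proteins down the tree and plant clade motifs.

    Returns (sequences, partial-truth dict) where the partial truth holds
    clade labels, motif placements, per-sequence block coordinates, block
    labels and catalytic positions.
    """
    rng = np.random.default_rng(child_seed(config.seed, "sequences"))
    nb, w = config.n_blocks, config.block_width
    lo, hi = config.linker_len_range
    labels = block_labels(nb)

    clades = clade_partition(tree, config.n_clades)
    clade_names = set(clades.values())
    for consensus, _, target in config.planted_motifs:
        if target not in clade_names:
            raise ValueError(f"planted motif target clade {target!r} not in tree "
                             f"(available: {sorted(clade_names)})")
    n_linkers = nb + 1
    if len(config.planted_motifs) > max(0, n_linkers - 2):
        raise ValueError("more planted motifs than internal linker slots")

    # root sequence: alternating linkers and blocks, catalytic residues planted
    blocks = [[AA[int(rng.integers(20))] for _ in range(w)] for _ in range(nb)]
    catalytic: dict[str, tuple[str, int, str]] = {}
    frozen: list[set[int]] = [set() for _ in range(nb)]
    if nb >= 4 and w >= 6:
        plan = [("Ser", 0, 2, "S"), ("Gly", 1, 2, "G"), ("Asn", 2, 2, "N"),
                ("Asp", nb - 1, w - 5, "D"), ("His", nb - 1, w - 2, "H")]
        for name, bi, off, res in plan:
            blocks[bi][off] = res
            frozen[bi].add(off)
            catalytic[name] = (labels[bi], off, res)
    linkers = [
        [AA[int(rng.integers(20))] for _ in range(int(rng.integers(lo, hi + 1)))]
        for _ in range(n_linkers)
    ]

    # per-branch evolution, preorder
    node_state: dict = {tree.seed_node: (blocks, linkers)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        pb, pl = node_state[node.parent_node]
        nblocks = [_mutate_block(b, config.block_sub_prob, frozen[i], rng)
                   for i, b in enumerate(pb)]
        nlinkers = [_mutate_linker(l, config.linker_sub_rate, lo, hi, rng) for l in pl]
        node_state[node] = (nblocks, nlinkers)

    # leaf assembly + motif insertion
    slot_of_motif = {f"planted{i + 1}": 1 + i for i in range(len(config.planted_motifs))}
    sequences: dict[str, str] = {}
    placements: list[tuple[str, str, int]] = []
    block_coords: dict[str, list[tuple[int, int]]] = {}
    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label
        lblocks, llinkers = node_state[leaf]
        llinkers = [list(l) for l in llinkers]
        motif_pos_in_linker: dict[int, tuple[str, int]] = {}
        for i, (consensus, width, target) in enumerate(config.planted_motifs):
            if clades[name] != target:
                continue
            slot = slot_of_motif[f"planted{i + 1}"]
            linker = llinkers[slot]
            pos = len(linker) // 2
            llinkers[slot] = linker[:pos] + list(consensus) + linker[pos:]
            motif_pos_in_linker[slot] = (f"planted{i + 1}", pos)
        # assemble and record absolute coordinates
        seq_parts: list[str] = []
        coords: list[tuple[int, int]] = []
        cursor = 0
        for k in range(nb + 1):
            linker = llinkers[k]
            if k in motif_pos_in_linker:
                mid, pos = motif_pos_in_linker[k]
                placements.append((mid, name, cursor + pos))
            seq_parts.append("".join(linker))
            cursor += len(linker)
            if k < nb:
                seq_parts.append("".join(lblocks[k]))
                coords.append((cursor, cursor + w))
                cursor += w
        sequences[name] = "".join(seq_parts)
        block_coords[name] = coords

    truth_part = {
        "true_clades": clades,
        "true_motif_placements": placements,
        "true_block_coords": block_coords,
        "block_labels": labels,
        "catalytic_positions": catalytic,
    }
    return sequences, truth_part


def make_decoy_proteins(config: FamilySimConfig, ids: list[str]) -> dict[str, str]:
    """Background proteins (uniform residue usage) with no family signal."""
    rng = np.random.default_rng(child_seed(config.seed, "decoys"))
    n = config.decoy_protein_length
    return {
        i: "".join(AA[int(j)] for j in rng.integers(0, 20, size=n)) for i in ids
    }


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

def _pick_tandem_members(tree: dendropy.Tree | None, count: int,
                         available: list[str]) -> list[str]:
    """Prefer the most recently diverged subtree of `count` leaves so that
    tandem members are near-identical, as real tandem duplicates are."""
    if tree is not None:
        best = None
        avail = set(available)
        for node in tree.postorder_internal_node_iter():
            leaves = [l.taxon.label for l in node.leaf_iter()]
            if len(leaves) == count and set(leaves) <= avail:
                depth = sum(
                    (n.edge.length or 0.0)
                    for n in node.preorder_iter() if n is not node
                )
                key = (depth, sorted(leaves))
                if best is None or key < best[0]:
                    best = (key, leaves)
        if best is not None:
            return sorted(best[1])
    return available[:count]


def _make_family_locus(gene_id: str, chrom: str, start: int, rng) -> GeneLocus:
    n_exons = int(rng.choice([1, 2, 3, 4, 5, 5, 5, 5, 6]))
    exon_lens = [int(rng.integers(150, 400)) for _ in range(n_exons)]
    intron_lens = [int(rng.integers(80, 1400)) for _ in range(n_exons - 1)]
    exons = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el - 1))
        pos += el
        if i < n_exons - 1:
            pos += intron_lens[i]
    end = exons[-1][1]
    utr5 = [(exons[0][0], exons[0][0] + 99)]
    utr3 = [(exons[-1][1] - 99, exons[-1][1])]
    strand = "+" if rng.random() < 0.5 else "-"
    t = Transcript(f"{gene_id}.1", exons, utr5, utr3)
    return GeneLocus(gene_id, chrom, start, end, strand, [t], is_family_member=True)


def _make_decoy_locus(gene_id: str, chrom: str, start: int, te: bool = False) -> GeneLocus:
    end = start + 999
    t = Transcript(f"{gene_id}.1", [(start, end)])
    return GeneLocus(gene_id, chrom, start, end, "+", [t], is_te_related=te)


def emit_genome_layout(
    gene_ids: list[str], config: FamilySimConfig, tree: dendropy.Tree | None = None,
) -> tuple[list[GeneLocus], pd.DataFrame, dict]:
    """Place family genes and decoys on chromosomes per the planted specs.

    Returns (loci including decoys, collinear-anchor table, layout truth).
    Cluster specs dictate exact intervening decoy counts; tandem arrays are
    adjacent placements of near-identical members; segmental pairs sit on
    distinct chromosomes next to decoy anchor genes recorded in the anchor
    table; every planted feature is isolated by >= 6 decoy genes.
    """
    rng = np.random.default_rng(child_seed(config.seed, "layout"))
    pool = sorted(gene_ids)

    tandem_groups: list[list[str]] = []
    for count, _identity in config.tandem_specs:
        members = _pick_tandem_members(tree, count, pool)
        if len(members) < count:
            raise ValueError("not enough gene ids for tandem_specs")
        for m in members:
            pool.remove(m)
        tandem_groups.append(members)

    cluster_groups: list[tuple[list[str], list[int]]] = []
    for count, intervening in config.cluster_specs:
        if len(intervening) != count - 1:
            raise ValueError("cluster spec needs count-1 intervening counts")
        if len(pool) < count:
            raise ValueError("not enough gene ids for cluster_specs")
        members, pool = pool[:count], pool[count:]
        cluster_groups.append((members, intervening))

    seg_pairs: list[tuple[str, str]] = []
    for _ in range(config.segmental_pairs):
        if len(pool) < 2:
            raise ValueError("not enough gene ids for segmental_pairs")
        seg_pairs.append((pool[0], pool[1]))
        pool = pool[2:]
    singletons = list(pool)

    # features to lay out round-robin across chromosomes
    features: list[tuple[str, object]] = []
    for grp in tandem_groups:
        features.append(("tandem", grp))
    for grp, intervening in cluster_groups:
        features.append(("cluster", (grp, intervening)))
    for g in singletons:
        features.append(("single", g))

    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    cursor = {c: 50_000 for c in chroms}
    loci: list[GeneLocus] = []
    decoy_ids: list[str] = []
    decoy_counter = [0]
    GAP = 20_000
    ISOLATE = 6

    def new_decoy(chrom: str, te: bool = False) -> None:
        decoy_counter[0] += 1
        did = f"DEC{decoy_counter[0]:04d}"
        decoy_ids.append(did)
        loci.append(_make_decoy_locus(did, chrom, cursor[chrom], te))
        cursor[chrom] = loci[-1].end + GAP

    def place_family(gene: str, chrom: str) -> GeneLocus:
        g = _make_family_locus(gene, chrom, cursor[chrom], rng)
        loci.append(g)
        cursor[chrom] = g.end + GAP
        return g

    def isolate(chrom: str) -> None:
        for _ in range(ISOLATE):
            new_decoy(chrom, te=False)

    ci = 0
    for kind, payload in features:
        chrom = chroms[ci % len(chroms)]
        ci += 1
        isolate(chrom)
        if kind == "tandem":
            for g in payload:
                place_family(g, chrom)
        elif kind == "cluster":
            members, intervening = payload
            place_family(members[0], chrom)
            for j, g in enumerate(members[1:]):
                for _ in range(intervening[j]):
                    new_decoy(chrom, te=bool(rng.random() < 0.3))
                place_family(g, chrom)
        else:
            place_family(payload, chrom)
        isolate(chrom)

    # segmental pairs: distinct chromosomes, decoy anchors within 500 kb
    anchor_rows = []
    for k, (ga, gb) in enumerate(seg_pairs):
        ca = chroms[(2 * k) % len(chroms)]
        cb = chroms[(2 * k + 1) % len(chroms)]
        if ca == cb:
            raise ValueError("segmental pair needs >= 2 chromosomes")
        for chrom, gene in ((ca, ga), (cb, gb)):
            cursor[chrom] += 600_000          # keep other family genes out of range
            place_family(gene, chrom)
            cursor[chrom] -= GAP
            cursor[chrom] += 50_000           # anchor 50 kb downstream
            new_decoy(chrom)
            cursor[chrom] += 600_000
        anchor_rows.append({
            "gene_a": decoy_ids[-2], "gene_b": decoy_ids[-1],
            "chrom_a": ca, "chrom_b": cb, "block_id": f"SBK{k + 1}",
        })

    for c in chroms:
        if cursor[c] > config.chromosome_length:
            raise ValueError(f"layout overflows {c} ({cursor[c]} > {config.chromosome_length})")

    loci.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    anchors = pd.DataFrame(anchor_rows,
                           columns=["gene_a", "gene_b", "chrom_a", "chrom_b", "block_id"])
    layout_truth = {
        "true_clusters": sorted(
            [sorted(g) for g in tandem_groups]
            + [sorted(m) for m, _ in cluster_groups]
        ),
        "true_tandem_groups": sorted(sorted(g) for g in tandem_groups),
        "true_segmental_pairs": [tuple(sorted(p)) for p in seg_pairs],
        "decoy_gene_ids": decoy_ids,
    }
    return loci, anchors, layout_truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

_DEFAULT_FOLD_CYCLE = [1.0, 2.0, 4.0, 0.5, 0.25, 8.0, 1.5, 2.0 / 3.0]


def emit_expression(
    config: FamilySimConfig, gene_ids: list[str]
) -> tuple[pd.DataFrame, dict[str, float]]:
    """CT tables under the inverse ddCT model.

    Reference CT is a constant plus noise; the treated target CT sits
    log2(true fold) cycles below the control target CT, so downstream
    2^(-ddCT) quantification recovers the planted fold exactly at zero
    noise.
    """
    rng = np.random.default_rng(child_seed(config.seed, "expression"))
    if config.expression_effects is not None:
        folds = dict(config.expression_effects)
    else:
        genes = sorted(gene_ids)[: min(8, len(gene_ids))]
        folds = {g: _DEFAULT_FOLD_CYCLE[i % len(_DEFAULT_FOLD_CYCLE)]
                 for i, g in enumerate(genes)}
    for g, f in folds.items():
        if f <= 0:
            raise ValueError(f"fold for {g} must be > 0")
    sd = config.ct_noise_sd
    rows = []
    for g in sorted(folds):
        base = 22.0 + 6.0 * rng.random()
        for cond in ("control", "treated"):
            shift = 0.0 if cond == "control" else -float(np.log2(folds[g]))
            for r in range(config.n_replicates):
                rows.append({
                    "gene": g, "condition": cond, "replicate": r + 1,
                    "ct_target": base + shift + sd * rng.standard_normal(),
                    "ct_reference": 18.0 + sd * rng.standard_normal(),
                })
    return pd.DataFrame(rows), folds


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class FamilyData:
    """Everything one simulated family emits, in memory."""

    config: FamilySimConfig
    tree: dendropy.Tree
    proteins: dict[str, str]          # family members only
    decoy_proteins: dict[str, str]
    loci: list[GeneLocus]
    anchors: pd.DataFrame
    ct_table: pd.DataFrame
    truth: SyntheticTruth

    @property
    def all_proteins(self) -> dict[str, str]:
        merged = dict(self.proteins)
        merged.update(self.decoy_proteins)
        return merged

    def seed_block_alignment(self, n_seed: int = 8) -> dict[str, list[str]]:
        """Ungapped per-block alignment from the first `n_seed` members'
        true block coordinates — a stand-in for a curated seed alignment."""
        names = sorted(self.proteins)[:n_seed]
        aln: dict[str, list[str]] = {b: [] for b in self.truth.block_labels}
        for name in names:
            for lbl, (s, e) in zip(self.truth.block_labels,
                                   self.truth.true_block_coords[name]):
                aln[lbl].append(self.proteins[name][s:e])
        return aln

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.all_proteins, outdir / "proteins.fasta")
        write_gff3(self.loci, outdir / "annotation.gff3")
        self.anchors.to_csv(outdir / "collinear_anchors.tsv", sep="\t", index=False)
        self.ct_table.to_csv(outdir / "ct_table.tsv", sep="\t", index=False)
        (outdir / "true_tree.nwk").write_text(self.truth.true_tree + "\n")
        self.truth.to_json(outdir / "truth.json")


def simulate_family(config: FamilySimConfig) -> FamilyData:
    """Run the full generator: tree, sequences, layout, expression, truth."""
    tree = simulate_tree(config.n_taxa, child_seed(config.seed, "tree"))
    sequences, seq_truth = evolve_family_sequences(tree, config)
    loci, anchors, layout_truth = emit_genome_layout(sorted(sequences), config, tree=tree)
    ct_table, folds = emit_expression(config, sorted(sequences))
    decoy_gene_ids = layout_truth["decoy_gene_ids"]
    decoy_ids = decoy_gene_ids[: config.n_decoy_proteins]
    extra = config.n_decoy_proteins - len(decoy_ids)
    decoy_ids = decoy_ids + [f"DECX{i + 1:03d}" for i in range(max(0, extra))]
    decoys = make_decoy_proteins(config, decoy_ids)
    truth = SyntheticTruth(
        true_tree=tree.as_string(schema="newick").strip(),
        true_clades=seq_truth["true_clades"],
        true_motif_placements=seq_truth["true_motif_placements"],
        true_block_coords=seq_truth["true_block_coords"],
        block_labels=seq_truth["block_labels"],
        catalytic_positions=seq_truth["catalytic_positions"],
        true_clusters=layout_truth["true_clusters"],
        true_tandem_groups=layout_truth["true_tandem_groups"],
        true_segmental_pairs=layout_truth["true_segmental_pairs"],
        true_folds=folds,
        decoy_gene_ids=decoy_gene_ids,
    )
    # truth-consistency guard: placements stay inside bounds and inside the
    # target clade (the generator's own contract)
    for mid, sid, start in truth.true_motif_placements:
        width = len(config.planted_motifs[int(mid.replace("planted", "")) - 1][0])
        assert 0 <= start <= len(sequences[sid]) - width
    return FamilyData(config, tree, sequences, decoys, loci, anchors, ct_table, truth)
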