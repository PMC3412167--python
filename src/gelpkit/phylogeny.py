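"""Conserved-block phylogeny: block selection, ungapped concatenation,
protein distances, neighbour joining, bootstrap supports and subclade
extraction.

The alignment strategy is motif-anchored: instead of a full progressive
multiple alignment, the blocks shared by (nearly) all family members are
cut out at their discovered occurrences and concatenated, which yields an
ungapped alignment of the informative core by construction.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from ._seeds import child_seed

__all__ = [
    "BlockSelection", "ConcatAlignment", "CladeAssignment",
    "select_blocks", "concatenate_blocks", "distance_matrix",
    "neighbor_joining", "bootstrap_support", "extract_subclades",
    "balanced_partition", "split_support_map", "newick_with_supports",
    "rf_distance",
]


# ---------------------------------------------------------------------------
# Block selection and concatenation
# ---------------------------------------------------------------------------

@dataclass
class BlockSelection:
    selected: list[str]                     # motif ids in archetype order
    widths: dict[str, int]
    coverage: dict[str, float]
    retained: list[str]
    excluded: dict[str, list[str]]          # sequence -> missing block ids


@dataclass
class ConcatAlignment:
    ids: list[str]
    rows: list[str]
    block_ids: list[str]
    block_widths: list[int]

    def __post_init__(self) -> None:
        ncol = sum(self.block_widths)
        for sid, row in zip(self.ids, self.rows):
            if len(row) != ncol:
                raise ValueError(f"{sid}: row length {len(row)} != {ncol} columns")
            if "-" in row:
                raise ValueError(f"{sid}: gap character in ungapped alignment")

    @property
    def n_columns(self) -> int:
        return sum(self.block_widths)

    def matrix(self) -> np.ndarray:
        return np.array([list(r) for r in self.rows])


def select_blocks(
    occurrences: pd.DataFrame,
    sequence_ids: list[str],
    motif_widths: dict[str, int],
    min_coverage: float = 0.95,
    min_blocks: int | None = None,
    evalues: dict[str, float] | None = None,
) -> BlockSelection:
    """Pick motifs covering >= `min_coverage` of sequences with mutually
    consistent linear order; exclude gap-rich sequences missing too many.

    `occurrences` needs columns motif, sequence, start (one row per
    motif/sequence at most). Candidates are taken greedily by coverage,
    then E-value; a candidate whose order relative to an already-selected
    motif flips between sequences is dropped.
    """
    seq_ids = sorted(sequence_ids)
    n = len(seq_ids)
    if n == 0:
        raise ValueError("no sequences")
    occ = occurrences[occurrences["sequence"].isin(seq_ids)]
    starts: dict[str, dict[str, int]] = {
        m: dict(zip(g["sequence"], g["start"])) for m, g in occ.groupby("motif")
    }
    coverage = {m: len(s) / n for m, s in starts.items()}
    candidates = [m for m in starts if coverage[m] >= min_coverage]
    if not candidates:
        raise ValueError(
            f"no motif reaches coverage {min_coverage}; lower min_coverage "
            f"(best available: {max(coverage.values(), default=0.0):.2f})"
        )
    ev = evalues or {}
    candidates.sort(key=lambda m: (-coverage[m], ev.get(m, 0.0), str(m)))

    selected: list[str] = []
    for m in candidates:
        consistent = True
        for s in selected:
            rel = None
            for sid in seq_ids:
                if sid in starts[m] and sid in starts[s]:
                    r = starts[m][sid] < starts[s][sid]
                    if rel is None:
                        rel = r
                    elif rel != r:
                        consistent = False
                        break
            if not consistent:
                break
        if consistent:
            selected.append(m)

    # archetype order = mean start across carriers
    selected.sort(key=lambda m: float(np.mean(list(starts[m].values()))))

    need = len(selected) if min_blocks is None else min_blocks
    retained, excluded = [], {}
    for sid in seq_ids:
        missing = [m for m in selected if sid not in starts[m]]
        if len(selected) - len(missing) >= need:
            retained.append(sid)
        else:
            excluded[sid] = missing
    return BlockSelection(
        selected=selected,
        widths={m: motif_widths[m] for m in selected},
        coverage={m: coverage[m] for m in selected},
        retained=retained,
        excluded=excluded,
    )


def pairwise_block_pdistance(
    selection: BlockSelection, occurrences: pd.DataFrame, sequences: dict[str, str]
) -> dict[tuple[str, str], float]:
    """Pairwise-deletion block p-distances over all sequences.

    For each pair, the mismatch fraction over the selected blocks both
    sequences carry — defined even for gap-rich members excluded from the
    concatenated alignment, as long as a block is shared (tandem
    detection needs distances for every cluster member). Pairs sharing no
    block are omitted.
    """
    occ = {
        (row["motif"], row["sequence"]): int(row["start"])
        for _, row in occurrences.iterrows()
    }
    ids = sorted(sequences)
    segments = {
        sid: {
            m: sequences[sid][occ[(m, sid)]:occ[(m, sid)] + selection.widths[m]]
            for m in selection.selected if (m, sid) in occ
        }
        for sid in ids
    }
    out: dict[tuple[str, str], float] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            shared = [m for m in segments[a] if m in segments[b]]
            if not shared:
                continue
            total = mism = 0
            for m in shared:
                for x, y in zip(segments[a][m], segments[b][m]):
                    total += 1
                    mism += x != y
            out[(a, b)] = mism / total if total else 0.0
    return out


def concatenate_blocks(
    selection: BlockSelection, occurrences: pd.DataFrame, sequences: dict[str, str]
) -> ConcatAlignment:
    """Cut each selected block at its occurrence and concatenate in order."""
    occ = {}
    for _, row in occurrences.iterrows():
        occ[(row["motif"], row["sequence"])] = int(row["start"])
    rows = []
    for sid in selection.retained:
        parts = []
        for m in selection.selected:
            key = (m, sid)
            if key not in occ:
                raise ValueError(f"retained sequence {sid} lacks block {m}")
            start, w = occ[key], selection.widths[m]
            seq = sequences[sid]
            if start < 0 or start + w > len(seq):
                raise ValueError(f"occurrence of {m} in {sid} out of bounds")
            parts.append(seq[start:start + w])
        rows.append("".join(parts))
    return ConcatAlignment(
        ids=list(selection.retained),
        rows=rows,
        block_ids=list(selection.selected),
        block_widths=[selection.widths[m] for m in selection.selected],
    )


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

_KIMURA_POLE = (np.sqrt(1.8) - 1.0) / 0.4      # p at which 1 - p - 0.2 p^2 = 0


def distance_matrix(
    alignment: ConcatAlignment, model: str = "kimura", clamp_pole: bool = False,
) -> np.ndarray:
    """Pairwise distances: p (mismatch fraction), poisson -ln(1-p), or the
    kimura protein correction -ln(1 - p - 0.2 p^2).

    A pair at or beyond the model's divergence pole raises, naming the
    pair; with `clamp_pole` the mismatch fraction is clamped just below
    the pole instead (used inside bootstrap replicates, where a column
    resample can exceed the pole even though the point estimate does not).
    """
    if model not in ("p", "poisson", "kimura"):
        raise ValueError(f"unknown model {model!r}")
    X = alignment.matrix()
    n = len(alignment.ids)
    if n < 2:
        raise ValueError("need >= 2 rows")
    pole = {"p": np.inf, "poisson": 1.0, "kimura": _KIMURA_POLE}[model]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = float(np.mean(X[i] != X[j]))
            if p >= pole:
                if not clamp_pole:
                    raise ValueError(
                        f"p={p:.4f} >= {pole:.4f}, {model} divergence pole, pair "
                        f"({alignment.ids[i]}, {alignment.ids[j]})"
                    )
                p = pole - 1e-4
            if model == "p":
                d = p
            elif model == "poisson":
                d = -np.log(1.0 - p)
            else:
                d = -np.log(1.0 - p - 0.2 * p * p)
            D[i, j] = D[j, i] = d
    return D


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------

def neighbor_joining(matrix: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Saitou-Nei agglomeration with the Q criterion.

    Ties in Q are broken by the smallest (i, j) index pair in the current
    working matrix; negative branch-length estimates are clamped to zero
    and counted in ``tree.nj_clamped_branches``. The result is unrooted
    (seed node is the final trifurcation).
    """
    D = np.asarray(matrix, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("matrix must be square")
    if n != len(labels):
        raise ValueError("labels length mismatch")
    if n < 3:
        raise ValueError("need >= 3 taxa")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("matrix must be symmetric")
    if (D < -1e-12).any():
        raise ValueError("matrix must be non-negative")

    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for lab in labels:
        node = dendropy.Node()
        node.taxon = tns.new_taxon(label=lab)
        nodes.append(node)
    d = D.copy()
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        Q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        ties = sorted((int(i), int(j)) for i, j in ties if i < j)
        i, j = ties[0]
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = clamp(li)
        parent.add_child(nodes[j])
        nodes[j].edge.length = clamp(lj)
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = dnew[keep]
        d2[:-1, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        d = d2

    center = dendropy.Node()
    l0 = clamp(0.5 * (d[0, 1] + d[0, 2] - d[1, 2]))
    l1 = clamp(0.5 * (d[0, 1] + d[1, 2] - d[0, 2]))
    l2 = clamp(0.5 * (d[0, 2] + d[1, 2] - d[0, 1]))
    for node, length in zip(nodes, (l0, l1, l2)):
        center.add_child(node)
        node.edge.length = length
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    tree.nj_clamped_branches = clamped
    return tree


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _edge_leafsets(tree: dendropy.Tree) -> dict:
    """Map each internal (non-pendant, non-root) edge to the frozenset of
    leaf labels below its head node."""
    out = {}
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            s = frozenset().union(*(below[c] for c in node.child_nodes()))
            below[node] = s
            if node.parent_node is not None and 1 < len(s) < len(all_leaves) - 1:
                out[node] = s
    return out


def _normalize_split(side: frozenset, all_leaves: frozenset) -> frozenset:
    other = all_leaves - side
    if (len(side), tuple(sorted(side))) <= (len(other), tuple(sorted(other))):
        return side
    return other


def split_support_map(tree: dendropy.Tree) -> dict:
    """Bipartition -> bootstrap support, keyed by the normalized (smaller,
    then lexicographically first) side of each internal split."""
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out = {}
    for node, side in _edge_leafsets(tree).items():
        sup = getattr(node.edge, "bootstrap_support", None)
        out[_normalize_split(side, all_leaves)] = sup
    return out


def bootstrap_support(
    alignment: ConcatAlignment,
    n_replicates: int = 1000,
    model: str = "kimura",
    seed: int = 0,
) -> dendropy.Tree:
    """NJ point-estimate tree with per-split bootstrap percentages.

    Columns are resampled with replacement per replicate, a tree is built
    per replicate, and each internal split of the point tree is annotated
    with the percentage of replicate trees containing it.
    """
    if len(alignment.ids) < 4:
        raise ValueError("need >= 4 rows to bootstrap")
    # canonicalize row order so supports do not depend on how the caller
    # happened to order the alignment (NJ tie-breaks are index-based)
    order = sorted(range(len(alignment.ids)), key=lambda i: alignment.ids[i])
    alignment = ConcatAlignment(
        ids=[alignment.ids[i] for i in order],
        rows=[alignment.rows[i] for i in order],
        block_ids=alignment.block_ids,
        block_widths=alignment.block_widths,
    )
    rng = np.random.default_rng(seed)
    X = alignment.matrix()
    ncol = X.shape[1]
    point = neighbor_joining(distance_matrix(alignment, model), alignment.ids)
    all_leaves = frozenset(alignment.ids)
    point_splits = {
        node: _normalize_split(side, all_leaves)
        for node, side in _edge_leafsets(point).items()
    }
    counts = {s: 0 for s in point_splits.values()}
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rows = ["".join(r) for r in X[:, cols]]
        rep_aln = ConcatAlignment(
            ids=alignment.ids, rows=rows,
            block_ids=["resampled"], block_widths=[ncol],
        )
        rep_tree = neighbor_joining(
            distance_matrix(rep_aln, model, clamp_pole=True), alignment.ids
        )
        rep_splits = {
            _normalize_split(side, all_leaves)
            for side in _edge_leafsets(rep_tree).values()
        }
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    for node, split in point_splits.items():
        node.edge.bootstrap_support = 100.0 * counts[split] / n_replicates
    return point


def newick_with_supports(tree: dendropy.Tree, min_show: float = 50.0) -> str:
    """Newick string with supports as internal-node labels; supports below
    `min_show` are hidden (display convention only)."""
    for node in tree.preorder_internal_node_iter():
        sup = getattr(node.edge, "bootstrap_support", None)
        if sup is not None and sup >= min_show:
            node.label = str(int(round(sup)))
        else:
            node.label = None
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def rf_distance(tree_a, tree_b) -> int:
    """Robinson-Foulds (symmetric-difference) distance between two trees,
    given as dendropy trees or Newick strings; compared unrooted on their
    shared leaf set (each tree is pruned to the common taxa first, so a
    tree with excluded members is compared on the leaves it retains)."""
    tns = dendropy.TaxonNamespace()
    def load(t):
        s = t if isinstance(t, str) else t.as_string(schema="newick")
        tr = dendropy.Tree.get(data=s, schema="newick", taxon_namespace=tns)
        tr.is_rooted = False
        return tr
    a, b = load(tree_a), load(tree_b)
    common = {l.taxon.label for l in a.leaf_node_iter()} & {
        l.taxon.label for l in b.leaf_node_iter()
    }
    if len(common) < 4:
        raise ValueError("trees share fewer than 4 leaves")
    for tr in (a, b):
        tr.retain_taxa_with_labels(sorted(common))
        tr.update_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(a, b))


# ---------------------------------------------------------------------------
# Balanced partition of an unrooted topology
# ---------------------------------------------------------------------------

def _adjacency(tree: dendropy.Tree):
    adj: dict[int, set[int]] = {}
    leaf_label: dict[int, str] = {}
    nodes: dict[int, dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        nodes[id(node)] = node
        adj.setdefault(id(node), set())
        if node.parent_node is not None:
            adj[id(node)].add(id(node.parent_node))
            adj.setdefault(id(node.parent_node), set()).add(id(node))
        if node.is_leaf():
            leaf_label[id(node)] = node.taxon.label
    return adj, leaf_label


def _component(start: int, adj, cut: set[frozenset]) -> set[int]:
    seen = {start}
    queue = deque([start])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if frozenset((u, v)) in cut or v in seen:
                continue
            seen.add(v)
            queue.append(v)
    return seen


def balanced_partition_detailed(tree: dendropy.Tree, k: int):
    """Cut k-1 edges of the unrooted topology, greedily minimizing the
    larger side at each step, to split the leaves into k parts.

    Deterministic given topology and leaf labels only: candidate cuts are
    compared by (size of larger piece, sorted leaf labels of the smaller
    piece), so the result is independent of node ordering and rooting.

    Returns (parts, bounding_splits): parts as leaf-label sets, and per
    part the list of full-tree bipartitions (leaf set of one side) of the
    cut edges bordering that part — the splits whose bootstrap supports
    qualify the part as a clade.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    adj, leaf_label = _adjacency(tree)
    n_leaves = len(leaf_label)
    if k > n_leaves:
        raise ValueError(f"cannot cut {n_leaves} leaves into {k} parts")
    cut: set[frozenset] = set()
    for _ in range(k - 1):
        remaining = set(adj)
        comps = []
        while remaining:
            c = _component(next(iter(sorted(remaining))), adj, cut)
            remaining -= c
            leaves = {leaf_label[x] for x in c if x in leaf_label}
            comps.append((c, leaves))
        comps.sort(key=lambda cl: (-len(cl[1]), min(cl[1]) if cl[1] else ""))
        target_nodes, target_leaves = comps[0]
        best = None
        for u in target_nodes:
            for v in adj[u]:
                if v not in target_nodes or u >= v:
                    continue
                e = frozenset((u, v))
                if e in cut:
                    continue
                side_nodes = _component(u, adj, cut | {e})
                side = {leaf_label[x] for x in side_nodes if x in leaf_label}
                other = target_leaves - side
                if not side or not other:
                    continue
                small, big = sorted((side, other), key=lambda s: (len(s), sorted(s)))
                key = (len(big), tuple(sorted(small)))
                if best is None or key < best[0]:
                    best = (key, e)
        if best is None:
            raise ValueError("component cannot be split further")
        cut.add(best[1])
    # final components (node sets), their leaves, and cut-edge adjacency
    remaining = set(adj)
    comp_nodes: list[set[int]] = []
    while remaining:
        c = _component(next(iter(sorted(remaining))), adj, cut)
        remaining -= c
        comp_nodes.append(c)
    parts, bounding = [], []
    for c in comp_nodes:
        leaves = {leaf_label[x] for x in c if x in leaf_label}
        if leaves:
            parts.append(leaves)
            bounding.append([])
    part_of = {}
    idx = 0
    for c in comp_nodes:
        leaves = {leaf_label[x] for x in c if x in leaf_label}
        if leaves:
            for node in c:
                part_of[node] = idx
            idx += 1
    for e in cut:
        u, v = tuple(e)
        # the full-tree bipartition of this edge, ignoring other cuts
        side_nodes = _component(u, adj, {e})
        side = frozenset(leaf_label[x] for x in side_nodes if x in leaf_label)
        for node in (u, v):
            p = part_of.get(node)
            if p is not None:
                bounding[p].append(side)
    return parts, bounding


def balanced_partition_with_cuts(tree: dendropy.Tree, k: int):
    """(parts, full-tree splits of the cut edges); see
    :func:`balanced_partition_detailed`."""
    parts, bounding = balanced_partition_detailed(tree, k)
    splits = []
    seen = set()
    for blist in bounding:
        for s in blist:
            key = frozenset(s)
            if key not in seen:
                seen.add(key)
                splits.append(key)
    return parts, splits


def balanced_partition(tree: dendropy.Tree, k: int) -> list[set[str]]:
    return balanced_partition_detailed(tree, k)[0]


# ---------------------------------------------------------------------------
# Subclade extraction
# ---------------------------------------------------------------------------

@dataclass
class CladeAssignment:
    assignment: dict[str, str]              # leaf -> label ("unassigned" possible)
    support: dict[str, float]               # label -> support
    monophyletic: dict[str, bool] = field(default_factory=dict)


def extract_subclades(
    tree: dendropy.Tree,
    min_support: float = 50.0,
    min_leaves: int = 2,
    leaf_groups: dict[str, list[str]] | None = None,
    n_groups: int | None = None,
) -> CladeAssignment:
    """Leaf -> subclade labelling.

    Three modes:
      * curated (`leaf_groups` given): verify each group's monophyly on the
        unrooted tree and report its split support (singletons count as
        trivially monophyletic with support 100); non-monophyletic groups
        are flagged, never silently accepted.
      * balanced (`n_groups` given): cut the unrooted topology into
        `n_groups` parts by greedy balanced edge-cuts — the same criterion
        the synthetic generator uses to define its true clades — and check
        each bounding split's support against `min_support`.
      * automatic (default): midpoint-root a copy of the tree and take the
        outermost clades with support >= `min_support` and >= `min_leaves`
        leaves, in preorder; uncovered leaves stay "unassigned".
    """
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    supports = split_support_map(tree)

    def support_of(side: frozenset) -> float:
        if len(side) <= 1 or len(side) >= len(all_leaves) - 1:
            return 100.0
        sup = supports.get(_normalize_split(side, all_leaves))
        return 100.0 if sup is None else float(sup)

    if leaf_groups is not None:
        assignment = {leaf: "unassigned" for leaf in all_leaves}
        support: dict[str, float] = {}
        mono: dict[str, bool] = {}
        sides = {frozenset(s) for s in _edge_leafsets(tree).values()}
        sides |= {all_leaves - s for s in sides}
        sides |= {frozenset([l]) for l in all_leaves}
        sides |= {all_leaves - frozenset([l]) for l in all_leaves}
        for label, leaves in leaf_groups.items():
            group = frozenset(leaves)
            missing = group - all_leaves
            if missing:
                raise ValueError(f"group {label}: unknown leaves {sorted(missing)}")
            ok = group in sides or group == all_leaves
            mono[label] = ok
            support[label] = support_of(group) if ok else float("nan")
            if ok:
                for leaf in group:
                    assignment[leaf] = label
        return CladeAssignment(assignment, support, mono)

    if n_groups is not None:
        parts, bounding = balanced_partition_detailed(tree, n_groups)
        order = sorted(range(len(parts)), key=lambda i: min(parts[i]))
        assignment, support, mono = {}, {}, {}
        for rank, i in enumerate(order):
            label = f"C{rank + 1}"
            sup = min((support_of(s) for s in bounding[i]), default=100.0)
            ok = sup >= min_support
            mono[label] = True
            support[label] = sup
            for leaf in parts[i]:
                assignment[leaf] = label if ok else "unassigned"
        return CladeAssignment(assignment, support, mono)

    # automatic mode: outermost qualifying clades under midpoint rooting
    clone = dendropy.Tree(tree)
    clone.is_rooted = True
    clone.reroot_at_midpoint(update_bipartitions=False)
    assignment = {leaf: "unassigned" for leaf in all_leaves}
    support, mono = {}, {}
    counter = [0]

    def descend(node) -> None:
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        if node.parent_node is not None and len(leaves) >= min_leaves:
            sup = support_of(leaves)
            if sup >= min_support and len(leaves) < len(all_leaves):
                counter[0] += 1
                label = f"C{counter[0]}"
                support[label] = sup
                mono[label] = True
                for leaf in leaves:
                    assignment[leaf] = label
                return
        for child in node.child_nodes():
            descend(child)

    descend(clone.seed_node)
    return CladeAssignment(assignment, support, mono)
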