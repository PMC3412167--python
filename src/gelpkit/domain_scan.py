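"""Family identification by conserved-block profile scanning.

Each conserved block of the seed alignment becomes an ungapped position
weight matrix; a candidate protein is scored by the best chained placement
of all blocks in their canonical order (I < II < III < V) without overlap,
via dynamic programming. The chained bit score is thresholded against the
family's gathering cutoff, an empirical shuffle E-value, and a minimum
length; catalytic residues (Ser/Gly/Asn/His and the DxxH pattern) are
verified at their profile offsets, and accepted members are named in
chromosome order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import AA_IDX as _AA_IDX
from .io import GeneLocus, chromosome_sort_key

_SKIP = -1.0e7          # chain penalty forcing a block to be skipped only when infeasible


@dataclass
class ScanThresholds:
    """Acceptance rule set: empirical E-value below `max_evalue`, chained
    bit score above the gathering cutoff `min_score`, protein length above
    `min_length` residues."""

    max_evalue: float = 0.1
    min_score: float = -69.0
    min_length: int = 100

    def __post_init__(self) -> None:
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be > 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass
class BlockProfile:
    block_ids: list[str]
    pwms: dict[str, np.ndarray]                     # width x 20, rows sum to 1
    background: np.ndarray                          # length 20
    catalytic: dict[str, tuple[str, int, str]] = field(default_factory=dict)
    log_odds: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for b, pwm in self.pwms.items():
            if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"block {b}: PWM rows must sum to 1")
        for name, (block, offset, res) in self.catalytic.items():
            if block not in self.pwms:
                raise ValueError(f"catalytic {name}: unknown block {block}")
            if not (0 <= offset < self.pwms[block].shape[0]):
                raise ValueError(f"catalytic {name}: offset outside block {block}")
        if not self.log_odds:
            for b, pwm in self.pwms.items():
                lo = np.zeros((pwm.shape[0], 21))
                lo[:, :20] = np.log2(pwm / self.background[None, :])
                self.log_odds[b] = lo              # column 20: masked residue, scores 0

    def width(self, block: str) -> int:
        return self.pwms[block].shape[0]


@dataclass
class DomainHit:
    sequence_id: str
    block_starts: dict[str, int | None]
    block_scores: dict[str, float]
    total_score: float
    blocks_found: list[str]
    evalue: float | None = None
    ser_near_n_terminus: bool | None = None


def build_profile(
    seed_alignment: dict[str, list[str]],
    pseudocount: float = 0.01,
    catalytic: dict[str, tuple[str, int, str]] | None = None,
) -> BlockProfile:
    """PWMs from per-block seed rows: (count + pseudocount) / (n + 20 pc);
    background from the overall seed residue composition."""
    if not seed_alignment or not any(rows for rows in seed_alignment.values()):
        raise ValueError("empty seed alignment")
    pwms = {}
    bg_counts = np.zeros(20)
    for block, rows in seed_alignment.items():
        if len(rows) < 2:
            raise ValueError(f"block {block}: need >= 2 seed rows")
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise ValueError(f"block {block}: rows differ in width")
        w = widths.pop()
        counts = np.zeros((w, 20))
        for row in rows:
            for k, aa in enumerate(row):
                counts[k, _AA_IDX[aa]] += 1
        bg_counts += counts.sum(axis=0)
        pwms[block] = (counts + pseudocount) / (len(rows) + 20 * pseudocount)
        pwms[block] /= pwms[block].sum(axis=1, keepdims=True)
    # seed alignments are small, so the raw composition assigns near-zero
    # frequency to unseen residues; interpolate with uniform to keep
    # mismatch log-odds negative for every residue
    empirical = bg_counts / bg_counts.sum()
    background = 0.75 * empirical + 0.25 * (1.0 / 20.0)
    return BlockProfile(
        block_ids=list(seed_alignment),
        pwms=pwms,
        background=background,
        catalytic=dict(catalytic or {}),
    )


def _encode(protein: str) -> np.ndarray:
    return np.array([_AA_IDX.get(a, 20) for a in protein], dtype=np.int64)


def scan_sequence(profile: BlockProfile, protein: str) -> DomainHit:
    """Chained block placement plus forward-style bit scores.

    Placements are the best in-order non-overlapping chain of all blocks
    (Viterbi over placements). Each placed block's bit score is the
    marginal log2 likelihood ratio of the block within its allowed window
    range under a uniform placement prior: log2(sum of likelihood ratios
    over starts compatible with the chain) - log2(L - w + 1). A random
    protein therefore scores strongly negative per block (the uniform
    prior penalizes the placement uncertainty), a profile identical to
    the background scores about 0, and a true member scores its match
    log-odds minus the placement entropy. A block wider than the sequence
    is reported absent and contributes nothing. The total is the exact
    sum of the placed blocks' bit scores.
    """
    enc = _encode(protein)
    L = len(enc)
    f = np.zeros(L + 1)
    layers = []
    for bid in profile.block_ids:
        lo = profile.log_odds[bid]
        w = lo.shape[0]
        if w > L:
            layers.append((bid, w, None, None, f.copy(), f + _SKIP))
            f = f + _SKIP
            continue
        windows = np.lib.stride_tricks.sliding_window_view(enc, w)
        s = lo[np.arange(w)[None, :], windows].sum(axis=1)
        ends = np.full(L + 1, -np.inf)
        ends[w:] = s + f[: L - w + 1]
        run = np.maximum.accumulate(ends)
        fnew = np.maximum(run, f + _SKIP)
        layers.append((bid, w, s, ends, f.copy(), fnew))
        f = fnew

    # backtrack placements from the right
    pos = L
    starts: dict[str, int | None] = {}
    raw: dict[str, np.ndarray] = {}
    for bid, w, s, ends, fprev, fnew in reversed(layers):
        if s is None:
            starts[bid] = None
            continue
        raw[bid] = s
        run_here = np.max(ends[: pos + 1])
        if run_here >= fprev[pos] + _SKIP - 1e-9 and np.isfinite(run_here):
            e = int(np.argmax(ends[: pos + 1] >= run_here - 1e-12))
            starts[bid] = e - w
            pos = e - w
        else:
            starts[bid] = None
    found = [b for b in profile.block_ids if starts[b] is not None]

    # forward-style bit score per placed block within its chain window
    scores: dict[str, float] = {}
    for bi, bid in enumerate(found):
        w = profile.width(bid)
        lo_bound = 0
        for prev in found[:bi]:
            lo_bound = max(lo_bound, starts[prev] + profile.width(prev))
        hi_bound = L - w
        for nxt in found[bi + 1:]:
            hi_bound = min(hi_bound, starts[nxt] - w)
        s = raw[bid][lo_bound:hi_bound + 1]
        mx = float(s.max())
        scores[bid] = (
            mx + np.log2(np.exp2(s - mx).sum()) - np.log2(L - w + 1)
        )
    total = float(sum(scores[b] for b in found))
    ser_near = None
    first = profile.block_ids[0] if profile.block_ids else None
    if first in scores and L > 0:
        ser_near = starts[first] <= L / 3
    return DomainHit(
        sequence_id="", block_starts=starts, block_scores=scores,
        total_score=total, blocks_found=found, ser_near_n_terminus=ser_near,
    )


def empirical_evalue(
    profile: BlockProfile, protein: str, n_shuffles: int = 19, seed: int = 0,
    family_size_scaling: float = 1.0,
) -> float:
    """Composition-preserving shuffle null for the chained score:
    E = (exceedances + 1) / (n_shuffles + 1) * scaling."""
    if n_shuffles < 19:
        raise ValueError("n_shuffles must be >= 19")
    rng = np.random.default_rng(seed)
    observed = scan_sequence(profile, protein).total_score
    chars = np.array(list(protein))
    exceed = 0
    for _ in range(n_shuffles):
        shuffled = "".join(rng.permutation(chars))
        if scan_sequence(profile, shuffled).total_score >= observed:
            exceed += 1
    return (exceed + 1) / (n_shuffles + 1) * family_size_scaling


def scan_proteins(
    profile: BlockProfile, proteins: dict[str, str],
    n_shuffles: int = 19, seed: int = 0,
) -> list[DomainHit]:
    """Scan + empirical E-value for every protein, deterministic in `seed`."""
    hits = []
    for i, (name, seq) in enumerate(sorted(proteins.items())):
        hit = scan_sequence(profile, seq)
        hit.sequence_id = name
        hit.evalue = empirical_evalue(profile, seq, n_shuffles=n_shuffles, seed=seed + i)
        hits.append(hit)
    return hits


def apply_filters(
    hits: list[DomainHit],
    proteins: dict[str, str],
    thresholds: ScanThresholds | None = None,
    exclusion_list: set[str] | frozenset[str] = frozenset(),
) -> tuple[list[str], pd.DataFrame]:
    """Accept iff E < max_evalue AND score > min_score AND length >
    min_length AND not on the exclusion list; the ledger records the first
    failing rule per rejection, in that order."""
    th = thresholds or ScanThresholds()
    excluded = set(exclusion_list)
    accepted, rows = [], []
    for hit in hits:
        if hit.sequence_id not in proteins:
            raise KeyError(f"hit {hit.sequence_id} has no protein")
        length = len(proteins[hit.sequence_id])
        reason = None
        if hit.evalue is None or not hit.evalue < th.max_evalue:
            reason = "max_evalue"
        elif not hit.total_score > th.min_score:
            reason = "min_score"
        elif not length > th.min_length:
            reason = "min_length"
        elif hit.sequence_id in excluded:
            reason = "excluded"
        if reason is None:
            accepted.append(hit.sequence_id)
        else:
            rows.append({"sequence": hit.sequence_id, "reason": reason,
                         "score": hit.total_score, "evalue": hit.evalue,
                         "length": length})
    ledger = pd.DataFrame(rows, columns=["sequence", "reason", "score", "evalue", "length"])
    return accepted, ledger


def check_catalytic_residues(
    profile: BlockProfile, hit: DomainHit, protein: str
) -> dict[str, object]:
    """Per-residue report for Ser/Gly/Asn/His plus the DxxH pattern (Asp
    exactly three positions before the His). Blocks absent from the hit
    yield "not-evaluable"."""
    report: dict[str, object] = {}
    for name in ("Ser", "Gly", "Asn", "His"):
        entry = profile.catalytic.get(name)
        if entry is None:
            report[name] = "not-evaluable"
            continue
        block, offset, expected = entry
        start = hit.block_starts.get(block)
        if start is None:
            report[name] = "not-evaluable"
            continue
        report[name] = protein[start + offset] == expected
    his = profile.catalytic.get("His")
    if his is None or hit.block_starts.get(his[0]) is None:
        report["DxxH"] = "not-evaluable"
    else:
        block, offset, _ = his
        his_pos = hit.block_starts[block] + offset
        report["DxxH"] = (
            his_pos - 3 >= 0
            and protein[his_pos - 3] == "D"
            and protein[his_pos] == "H"
        )
    return report


def assign_nomenclature(
    accepted_ids: list[str], loci: list[GeneLocus], prefix: str = "OsGELP"
) -> dict[str, str]:
    """Name accepted genes prefix1..prefixN by chromosome (top to bottom)
    then start coordinate; ties broken by gene id. Input order irrelevant."""
    by_id = {g.gene_id: g for g in loci}
    keyed = []
    for gid in accepted_ids:
        if gid not in by_id:
            raise KeyError(f"no locus for accepted gene {gid}")
        g = by_id[gid]
        keyed.append(((chromosome_sort_key(g.chrom), g.start, g.gene_id), gid))
    keyed.sort()
    return {gid: f"{prefix}{i + 1}" for i, (_, gid) in enumerate(keyed)}
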