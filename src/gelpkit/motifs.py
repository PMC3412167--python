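"""ZOOPS motif discovery by expectation-maximization with sequential erasure.

The occurrence model is zero-or-one-per-sequence: a sequence contains the
motif with prior probability gamma, and if so at a uniformly chosen
position. EM alternates occurrence posteriors (E) with PWM/gamma
re-estimation (M, pseudocount 0.01). Discovery seeds EM from data k-mers
(one iteration each, then the best seed runs to convergence), picks the
width with the lowest empirical shuffle E-value, masks the accepted
occurrences and repeats. The penalized (MAP) objective is checked to be
non-decreasing at every iteration; a decrease raises immediately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeds import child_seed
from .alphabet import AA, AA_IDX, MASK, MASK_IDX

_PC = 0.01                      # Dirichlet pseudocount, per residue
MIN_WIDTH, MAX_WIDTH = 6, 15


@dataclass
class MotifModel:
    motif_id: str | None
    width: int
    pwm: np.ndarray                 # width x 20, rows sum to 1
    gamma: float
    llr: float                      # log2 likelihood ratio vs background
    ic: float                       # information content, bits
    evalue: float | None = None

    def __post_init__(self) -> None:
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma outside [0, 1]")
        if not (-1e-9 <= self.ic <= self.width * np.log2(20.0) + 1e-9):
            raise ValueError("information content out of range")


@dataclass
class MotifSummary:
    consensus: str
    regex: str
    ic: float
    n_occurrences: int


def residue_background(sequences: dict[str, str]) -> np.ndarray:
    """0th-order residue frequencies over all unmasked residues."""
    counts = np.zeros(20)
    for seq in sequences.values():
        for a in seq:
            i = AA_IDX.get(a)
            if i is not None:
                counts[i] += 1
    return (counts + 0.01) / (counts.sum() + 0.2)


# ---------------------------------------------------------------------------
# Width-indexed window data
# ---------------------------------------------------------------------------

class _WidthData:
    """All valid (mask-free) length-w windows of a sequence set, flattened."""

    def __init__(self, sequences: dict[str, str], width: int):
        self.ids = sorted(sequences)
        self.width = width
        W_parts, seq_parts, pos_parts = [], [], []
        for si, sid in enumerate(self.ids):
            seq = sequences[sid]
            if len(seq) < width:
                raise ValueError(f"sequence {sid} shorter than width {width}")
            enc = np.array([AA_IDX.get(a, MASK_IDX) for a in seq], dtype=np.int64)
            win = np.lib.stride_tricks.sliding_window_view(enc, width)
            ok = ~(win == MASK_IDX).any(axis=1)
            W_parts.append(win[ok])
            pos_parts.append(np.nonzero(ok)[0])
            seq_parts.append(np.full(int(ok.sum()), si, dtype=np.int64))
        self.W = np.concatenate(W_parts) if W_parts else np.empty((0, width), dtype=np.int64)
        self.pos = np.concatenate(pos_parts) if pos_parts else np.empty(0, dtype=np.int64)
        self.seq_of = np.concatenate(seq_parts) if seq_parts else np.empty(0, dtype=np.int64)
        self.n_seqs = len(self.ids)
        self.m = np.bincount(self.seq_of, minlength=self.n_seqs).astype(float)
        nz = np.nonzero(self.m > 0)[0]
        self.nonempty = nz
        self.starts = np.searchsorted(self.seq_of, nz)
        self.seg_of = np.searchsorted(nz, self.seq_of)   # window -> index into nonempty

    @property
    def n_windows(self) -> int:
        return self.W.shape[0]


def _estep(data: _WidthData, log_pwm: np.ndarray, log_bg: np.ndarray, gamma: float):
    """Occurrence posteriors z per window, per-sequence totals Q, and the
    observed-data log-likelihood relative to the background model (nats)."""
    s = (log_pwm[np.arange(data.width)[None, :], data.W] - log_bg[data.W]).sum(axis=1)
    a = s + np.log(gamma) - np.log(data.m[data.seq_of])
    log_noocc = np.log1p(-gamma)
    if data.n_windows == 0:
        return (np.empty(0), np.zeros(data.n_seqs), data.n_seqs * log_noocc)
    mx = np.maximum.reduceat(a, data.starts)
    sumexp = np.add.reduceat(np.exp(a - mx[data.seg_of]), data.starts)
    lse = mx + np.log(sumexp)
    tot = np.logaddexp(log_noocc, lse)
    z = np.exp(a - tot[data.seg_of])
    Q = np.zeros(data.n_seqs)
    Q[data.nonempty] = np.add.reduceat(z, data.starts)
    n_empty = data.n_seqs - len(data.nonempty)
    ll = float(tot.sum() + n_empty * log_noocc)
    return z, Q, ll


def _em(
    data: _WidthData, background: np.ndarray, pwm0: np.ndarray, gamma0: float,
    max_iter: int = 200, tol: float = 1e-6,
):
    """Run EM; returns (pwm, gamma, z, ll_nats, n_iter).

    The MAP objective (log-likelihood plus the Dirichlet pseudocount
    prior on the PWM) must not decrease between iterations; a decrease
    beyond rounding noise raises RuntimeError.
    """
    log_bg = np.log(background)
    pwm, gamma = pwm0, float(np.clip(gamma0, 1e-8, 1 - 1e-8))
    prev_obj = -np.inf
    z = np.empty(0)
    ll = -np.inf
    for it in range(max_iter):
        log_pwm = np.log(pwm)
        z, Q, ll = _estep(data, log_pwm, log_bg, gamma)
        obj = ll + _PC * float(log_pwm.sum())
        if obj < prev_obj - 1e-7:
            raise RuntimeError(
                f"EM objective decreased at iteration {it}: {prev_obj} -> {obj}"
            )
        if it > 0 and obj - prev_obj < tol:
            break
        prev_obj = obj
        counts = np.zeros((data.width, 20))
        for k in range(data.width):
            counts[k] = np.bincount(data.W[:, k], weights=z, minlength=20)[:20]
        total = z.sum()
        pwm = (counts + _PC) / (total + 20 * _PC)
        pwm /= pwm.sum(axis=1, keepdims=True)
        gamma = float(np.clip(Q.mean(), 1e-8, 1 - 1e-8))
    return pwm, gamma, z, ll, it + 1


def _occurrences(data: _WidthData, z: np.ndarray, threshold: float = 0.5):
    """Best window per sequence where the occurrence posterior exceeds the
    threshold — at most one per sequence, the ZOOPS contract."""
    rows = []
    for gi, si in enumerate(data.nonempty):
        lo = data.starts[gi]
        hi = data.starts[gi + 1] if gi + 1 < len(data.starts) else data.n_windows
        if hi <= lo:
            continue
        j = lo + int(np.argmax(z[lo:hi]))
        if z[j] > threshold:
            rows.append({"sequence": data.ids[si], "start": int(data.pos[j]),
                         "posterior": float(z[j])})
    return rows


def _information_content(pwm: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(pwm > 0, pwm * np.log2(pwm), 0.0).sum(axis=1)
    return float((np.log2(20.0) - h).sum())


def _seed_pwm(kmer_codes: np.ndarray) -> np.ndarray:
    w = len(kmer_codes)
    pwm = np.full((w, 20), 0.4 / 19.0)
    pwm[np.arange(w), kmer_codes] = 0.6
    return pwm


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def em_zoops(
    sequences: dict[str, str],
    width: int,
    seed_kmer: str,
    background: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> tuple[MotifModel, pd.DataFrame]:
    """Fit one ZOOPS motif of the given width from a seed k-mer."""
    if not (MIN_WIDTH <= width <= MAX_WIDTH):
        raise ValueError(f"width {width} outside [{MIN_WIDTH}, {MAX_WIDTH}]")
    if len(seed_kmer) != width:
        raise ValueError("seed_kmer length must equal width")
    bg = residue_background(sequences) if background is None else background
    data = _WidthData(sequences, width)
    codes = np.array([AA_IDX[a] for a in seed_kmer])
    pwm, gamma, z, ll, _ = _em(data, bg, _seed_pwm(codes), 0.5, max_iter, tol)
    model = MotifModel(
        motif_id=None, width=width, pwm=pwm, gamma=gamma,
        llr=ll / np.log(2.0), ic=_information_content(pwm),
    )
    occ = pd.DataFrame(_occurrences(data, z), columns=["sequence", "start", "posterior"])
    return model, occ


def _fit_best_width(
    sequences: dict[str, str], width: int, background: np.ndarray,
    rng: np.random.Generator, max_seeds: int,
) -> tuple[MotifModel, pd.DataFrame] | None:
    """Seed EM from (a deterministic subsample of) every distinct data
    k-mer for one iteration, then run the best-scoring seed to
    convergence."""
    data = _WidthData(sequences, width)
    if data.n_windows == 0:
        return None
    uniq = np.unique(data.W, axis=0)
    if len(uniq) > max_seeds:
        idx = np.sort(rng.choice(len(uniq), size=max_seeds, replace=False))
        uniq = uniq[idx]
    log_bg = np.log(background)
    best_seed, best_score = None, -np.inf
    for kmer in uniq:
        pwm = _seed_pwm(kmer)
        z, Q, _ = _estep(data, np.log(pwm), log_bg, 0.5)
        counts = np.zeros((width, 20))
        for k in range(width):
            counts[k] = np.bincount(data.W[:, k], weights=z, minlength=20)[:20]
        pwm1 = (counts + _PC) / (z.sum() + 20 * _PC)
        pwm1 /= pwm1.sum(axis=1, keepdims=True)
        gamma1 = float(np.clip(Q.mean(), 1e-8, 1 - 1e-8))
        _, _, ll1 = _estep(data, np.log(pwm1), log_bg, gamma1)
        if ll1 > best_score:
            best_score, best_seed = ll1, kmer
    pwm, gamma, z, ll, _ = _em(data, background, _seed_pwm(best_seed), 0.5)
    model = MotifModel(
        motif_id=None, width=width, pwm=pwm, gamma=gamma,
        llr=ll / np.log(2.0), ic=_information_content(pwm),
    )
    occ = pd.DataFrame(_occurrences(data, z), columns=["sequence", "start", "posterior"])
    return model, occ


def _refit_trimmed(
    model: MotifModel, sequences: dict[str, str], background: np.ndarray,
    ic_threshold: float,
) -> tuple[MotifModel, pd.DataFrame] | None:
    """Trim low-information edge columns off an accepted motif and refit.

    Wide EM fits routinely drag in flanking columns that are pure
    small-sample noise; those overfit columns both blur the motif's
    boundaries (so erasure bites into neighbouring sequence) and attract
    spurious low-quality occurrences. Edge columns with information
    content below `ic_threshold` bits are dropped (never below the
    minimum width) and the trimmed PWM is re-converged.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(model.pwm > 0, model.pwm * np.log2(model.pwm), 0.0).sum(axis=1)
    ic = np.log2(20.0) - h
    lo, hi = 0, model.width
    while hi - lo > MIN_WIDTH and ic[lo] < ic_threshold:
        lo += 1
    while hi - lo > MIN_WIDTH and ic[hi - 1] < ic_threshold:
        hi -= 1
    if (lo, hi) == (0, model.width):
        return None
    data = _WidthData(sequences, hi - lo)
    if data.n_windows == 0:
        return None
    pwm0 = model.pwm[lo:hi].copy()
    pwm0 /= pwm0.sum(axis=1, keepdims=True)
    pwm, gamma, z, ll, _ = _em(data, background, pwm0, model.gamma)
    trimmed = MotifModel(
        motif_id=model.motif_id, width=hi - lo, pwm=pwm, gamma=gamma,
        llr=ll / np.log(2.0), ic=_information_content(pwm), evalue=model.evalue,
    )
    occ = pd.DataFrame(_occurrences(data, z), columns=["sequence", "start", "posterior"])
    return trimmed, occ


def _filter_occurrences(
    model: MotifModel, occ: pd.DataFrame, sequences: dict[str, str],
    tolerance: float = 0.25, ic_min: float = 1.0,
) -> pd.DataFrame:
    """Drop occurrences that disagree with the motif's informative columns.

    A ZOOPS posterior competes only against the no-occurrence prior, so
    once gamma is moderate, a window matching a mere handful of sharp
    columns can reach posterior ~1 in a sequence that does not carry the
    motif at all. Such stray sites corrupt specificity calls and erase
    unrelated sequence.

    Per occurrence, agreement is the fraction of columns with >= `ic_min`
    bits whose residue the PWM rates >= 0.2 (the regex-class rule). The
    cutoff adapts to the cohort: median agreement minus `tolerance`,
    clipped to [0.5, 0.9] — exact carriers make the cutoff strict, while
    genuinely divergent carrier sets keep their own spread. If nothing
    survives, the unfiltered set is returned: a motif whose own training
    windows fail its PWM is left untouched rather than silently emptied.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(model.pwm > 0, model.pwm * np.log2(model.pwm), 0.0).sum(axis=1)
    informative = np.nonzero((np.log2(20.0) - h) >= ic_min)[0]
    if len(informative) == 0 or occ.empty:
        return occ
    agreements = {}
    for idx, row in occ.iterrows():
        window = sequences[row["sequence"]][
            int(row["start"]):int(row["start"]) + model.width
        ]
        agree = sum(
            1 for k in informative
            if k < len(window) and model.pwm[k, AA_IDX.get(window[k], 0)] >= 0.2
        )
        agreements[idx] = agree / len(informative)
    cutoff = float(np.clip(np.median(list(agreements.values())) - tolerance, 0.5, 0.9))
    keep = [idx for idx, a in agreements.items() if a >= cutoff]
    if not keep:
        return occ
    return occ.loc[keep].reset_index(drop=True)


def motif_evalue(
    model: MotifModel,
    sequences: dict[str, str],
    n_shuffles: int = 20,
    seed: int = 0,
    widths_tried: int = 1,
    max_seeds: int = 50,
    stop_after_exceedances: int | None = None,
) -> float:
    """Empirical motif E-value from a within-sequence shuffle null.

    Per shuffle, residues are permuted within each sequence and the best
    single-width EM log-likelihood ratio is recorded;
    E = ((exceedances) + 1) / (n_shuffles + 1) * widths_tried.

    With `stop_after_exceedances` the null loop stops early once that many
    nulls beat the observed LLR: the returned value is then a conservative
    lower bound, sufficient to decide that a motif is not acceptable.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    bg = residue_background(sequences)

    def shuffle_unmasked(seq: str) -> str:
        # permute residues among unmasked positions only: scattering the
        # erasure sentinels would destroy valid windows and weaken the null
        chars = list(seq)
        idx = [i for i, a in enumerate(chars) if a != MASK]
        vals = rng.permutation([chars[i] for i in idx])
        for i, v in zip(idx, vals):
            chars[i] = v
        return "".join(chars)

    exceed = 0
    for _ in range(n_shuffles):
        shuffled = {sid: shuffle_unmasked(seq) for sid, seq in sorted(sequences.items())}
        fit = _fit_best_width(shuffled, model.width, bg, rng, max_seeds)
        if fit is not None and fit[0].llr >= model.llr:
            exceed += 1
            if stop_after_exceedances is not None and exceed >= stop_after_exceedances:
                break
    return (exceed + 1) / (n_shuffles + 1) * widths_tried


def discover_motifs(
    sequences: dict[str, str],
    max_motifs: int = 45,
    min_width: int = MIN_WIDTH,
    max_width: int = MAX_WIDTH,
    accept_threshold: float = 0.05,
    n_shuffles: int = 20,
    max_seeds: int = 400,
    null_max_seeds: int | None = None,
    trim_termini: int = 0,
    trim_edge_ic: float | None = 2.0,
    seed: int = 0,
) -> tuple[list[MotifModel], pd.DataFrame]:
    """Sequential ZOOPS discovery with erasure.

    Each round fits every width in [min_width, max_width], scores each
    converged model with an empirical shuffle E-value, and accepts the
    best (lowest E, then highest LLR, then widest); its occurrences are
    masked before the next round. Discovery stops at `max_motifs` or when
    the best model's raw exceedance probability (its E-value without the
    width-count multiplier) exceeds `accept_threshold`.

    `trim_termini` masks that many residues at both ends of every
    sequence before the search (off by default; termini are searched).
    `null_max_seeds` defaults to `max_seeds`: the shuffle null must spend
    the same seeding effort as the real fit, otherwise observed LLRs are
    systematically favoured and weak motifs are over-accepted.
    `trim_edge_ic` drops accepted motifs' edge columns below that many
    bits of information and re-converges the trimmed model (None to
    disable).
    """
    if null_max_seeds is None:
        null_max_seeds = max_seeds
    widths = list(range(min_width, max_width + 1))
    work = {sid: list(seq) for sid, seq in sequences.items()}
    if trim_termini > 0:
        for sid in work:
            n = min(trim_termini, len(work[sid]))
            work[sid][:n] = MASK * n
            work[sid][-n:] = MASK * n
    bg = residue_background(sequences)
    models: list[MotifModel] = []
    occ_frames: list[pd.DataFrame] = []
    for rnd in range(max_motifs):
        current = {sid: "".join(chars) for sid, chars in work.items()}
        fits = []
        for w in widths:
            rng = np.random.default_rng(child_seed(seed, f"round{rnd}-w{w}"))
            fit = _fit_best_width(current, w, bg, rng, max_seeds)
            if fit is not None:
                fits.append(fit)
        if not fits:
            break
        # a width is acceptable only with zero null exceedances, and ties at
        # the minimal E are broken by LLR (then width) — so evaluating
        # widths in descending LLR order and stopping at the first width
        # whose raw exceedance probability passes the threshold computes
        # the argmin over (E, -LLR, -width) exactly, at a fraction of the
        # null-fitting cost
        fits.sort(key=lambda f: (-f[0].llr, -f[0].width))
        best = None
        for model, occ in fits:
            ev = motif_evalue(
                model, current, n_shuffles=n_shuffles,
                seed=child_seed(seed, f"null-round{rnd}-w{model.width}"),
                widths_tried=len(widths), max_seeds=null_max_seeds,
                stop_after_exceedances=1,
            )
            model.evalue = ev
            if ev / len(widths) <= accept_threshold:
                best = (model, occ)
                break
        if best is None:
            break
        model, occ = best
        if trim_edge_ic is not None:
            refit = _refit_trimmed(model, current, bg, trim_edge_ic)
            if refit is not None:
                model, occ = refit
        occ = _filter_occurrences(model, occ, current)
        model.motif_id = f"M{len(models) + 1}"
        occ = occ.copy()
        occ.insert(0, "motif", model.motif_id)
        models.append(model)
        occ_frames.append(occ)
        for _, row in occ.iterrows():
            s = int(row["start"])
            work[row["sequence"]][s:s + model.width] = MASK * model.width
    if occ_frames:
        occurrences = pd.concat(occ_frames, ignore_index=True)
    else:
        occurrences = pd.DataFrame(columns=["motif", "sequence", "start", "posterior"])
    return models, occurrences


def summarize_motif(model: MotifModel, occurrences: pd.DataFrame | None = None) -> MotifSummary:
    """Consensus (argmax residue per column), bracketed regular expression
    (residues with probability >= 0.2; 'x' when no residue qualifies) and
    information content in bits."""
    consensus = "".join(AA[int(i)] for i in model.pwm.argmax(axis=1))
    parts = []
    for col in model.pwm:
        qual = [(p, AA[i]) for i, p in enumerate(col) if p >= 0.2]
        qual.sort(key=lambda t: (-t[0], t[1]))
        if not qual:
            parts.append("x")
        elif len(qual) == 1:
            parts.append(qual[0][1])
        else:
            parts.append("[" + "".join(a for _, a in qual) + "]")
    n_occ = 0 if occurrences is None else len(occurrences)
    return MotifSummary(consensus, "".join(parts), _information_content(model.pwm), n_occ)


def write_meme(models: list[MotifModel], background: np.ndarray, path) -> None:
    """Minimal MEME-format motif file (version 4 text format)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= " + AA + "\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{a} {f:.5f}" for a, f in zip(AA, background)) + "\n\n")
        for m in models:
            fh.write(f"MOTIF {m.motif_id or 'motif'}\n")
            fh.write(
                f"letter-probability matrix: alength= 20 w= {m.width} "
                f"nsites= {max(1, round(m.gamma * 100))} E= {m.evalue if m.evalue is not None else 1.0:g}\n"
            )
            for row in m.pwm:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")
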