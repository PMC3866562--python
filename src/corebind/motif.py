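"""PWM scanning against a first-order Markov background.

The weight of a word w of PWM width W is the log2 likelihood ratio

    weight(w) = log2 P_pwm(w) - log2 [ pi(w_1) * prod_{i>1} P(w_i | w_{i-1}) ]

with the background fitted from the scanned sequences themselves.  Matches
at weight >= the threshold (default 4) are retrieved on both strands.
Bases outside ACGT break the scan window: no wildcard scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def encode(seq: str) -> np.ndarray:
    """Map a sequence to int codes (A=0..T=3); non-ACGT bases become -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int8)
    for b, i in _CODE.items():
        lut[ord(b)] = i
    return lut[arr].astype(np.int64)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWMCounts:
    """Per-position base counts, shape (4, W) ordered A,C,G,T."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must have shape (4, W)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.counts.sum(axis=0) <= 0):
            raise ValueError("every column needs at least one positive count")

    @property
    def width(self) -> int:
        return self.counts.shape[1]


@dataclass
class PWMModel:
    """Pseudocount-smoothed per-position probabilities, shape (4, W)."""

    probs: np.ndarray
    pseudocount: float = 0.25

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if not np.allclose(self.probs.sum(axis=0), 1.0):
            raise ValueError("each PWM column must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    def max_weight(self, bg: "MarkovBackground") -> float:
        """Upper bound on the achievable weight: per-position best base over
        the worst background step (loose but cheap)."""
        best = np.log2(self.probs.max(axis=0)).sum()
        worst_bg = np.log2(bg.pi.min()) + (self.width - 1) * np.log2(bg.trans.min())
        return float(best - worst_bg)


@dataclass
class MarkovBackground:
    """First-order Markov chain over ACGT."""

    pi: np.ndarray  # (4,)
    trans: np.ndarray  # (4, 4) rows: previous base
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        if not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("pi must sum to 1")
        if not np.allclose(self.trans.sum(axis=1), 1.0):
            raise ValueError("each transition row must sum to 1")


def build_pwm(counts: PWMCounts, pseudocount: float = 0.25) -> PWMModel:
    """p(b at i) = (count + eps) / (column total + 4 eps)."""
    c = counts.counts
    if pseudocount == 0 and np.any(c.sum(axis=0) == 0):
        raise ValueError("all-zero column with zero pseudocount")
    probs = (c + pseudocount) / (c.sum(axis=0, keepdims=True) + 4 * pseudocount)
    return PWMModel(probs=probs, pseudocount=pseudocount)


def fit_markov1(
    seqs: Iterable[str] | Mapping[str, str], pseudocount: float = 1.0
) -> MarkovBackground:
    """Fit the first-order background from the input sequences.

    Initial probabilities come from overall single-nucleotide frequencies,
    transitions from dinucleotide counts; both add-pseudocount smoothed.
    Non-ACGT bases are skipped and break the transition chain.
    """
    if isinstance(seqs, Mapping):
        seqs = seqs.values()
    base_counts = np.zeros(4)
    trans_counts = np.zeros((4, 4))
    total_len = 0
    for seq in seqs:
        enc = encode(seq)
        total_len += enc.size
        valid = enc >= 0
        base_counts += np.bincount(enc[valid], minlength=4)
        prev, nxt = enc[:-1], enc[1:]
        ok = (prev >= 0) & (nxt >= 0)
        if ok.any():
            np.add.at(trans_counts, (prev[ok], nxt[ok]), 1)
    if total_len < 2:
        raise ValueError("background fit needs total sequence length >= 2")
    pi = (base_counts + pseudocount) / (base_counts.sum() + 4 * pseudocount)
    row_tot = trans_counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        trans = (trans_counts + pseudocount) / (row_tot + 4 * pseudocount)
    # a base never observed as a predecessor carries no information:
    # uniform row (only reachable with zero pseudocount)
    empty = (row_tot[:, 0] + 4 * pseudocount) == 0
    trans[empty] = 0.25
    return MarkovBackground(pi=pi, trans=trans, pseudocount=pseudocount)


def score_word(word: str, pwm: PWMModel, bg: MarkovBackground) -> Optional[float]:
    """Weight (log2 likelihood ratio) of a single word; None if the word
    contains an ambiguous base."""
    if len(word) != pwm.width:
        raise ValueError(f"word length {len(word)} != PWM width {pwm.width}")
    enc = encode(word)
    if np.any(enc < 0):
        return None
    with np.errstate(divide="ignore"):
        fg = np.log2(pwm.probs[enc, np.arange(pwm.width)]).sum()
        bg_log = np.log2(bg.pi[enc[0]])
        if pwm.width > 1:
            bg_log += np.log2(bg.trans[enc[:-1], enc[1:]]).sum()
    return float(fg - bg_log)


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    offset: int  # 0-based position of the window start on the forward strand
    strand: str  # '+' or '-'
    weight: float


def _scan_encoded(enc: np.ndarray, pwm: PWMModel, bg: MarkovBackground) -> np.ndarray:
    """Weights for every window of the encoded sequence; NaN where the
    window contains an ambiguous base."""
    W = pwm.width
    L = enc.size
    n = L - W + 1
    if n <= 0:
        return np.empty(0)
    safe = np.where(enc < 0, 0, enc)
    with np.errstate(divide="ignore"):
        logp = np.log2(pwm.probs)
        logpi = np.log2(bg.pi)
        logtr = np.log2(bg.trans)
    win = np.lib.stride_tricks.sliding_window_view(safe, W)
    fg = logp[win, np.arange(W)].sum(axis=1)
    # background: log pi(first) + sum of transition logs inside the window
    t = logtr[safe[:-1], safe[1:]] if L > 1 else np.empty(0)
    ct = np.concatenate([[0.0], np.cumsum(t)])
    bg_scores = logpi[safe[:n]]
    if W > 1:
        bg_scores = bg_scores + (ct[np.arange(n) + W - 1] - ct[np.arange(n)])
    weights = fg - bg_scores
    bad = np.lib.stride_tricks.sliding_window_view(enc < 0, W).any(axis=1)
    weights[bad] = np.nan
    return weights


def scan_sequences(
    seqs: Mapping[str, str] | Sequence[tuple[str, str]],
    pwm: PWMModel,
    bg: MarkovBackground,
    threshold: float = 4.0,
    strands: str = "both",
) -> list[MotifHit]:
    """Score every window of every sequence on the requested strands and
    return hits with weight >= threshold, sorted by (sequence, offset).

    Reverse-strand hits are reported at the forward-strand offset of the
    window start; their weight equals the forward score of the reverse
    complement of the window.
    """
    if strands not in ("both", "+", "-"):
        raise ValueError("strands must be 'both', '+' or '-'")
    items = seqs.items() if isinstance(seqs, Mapping) else seqs
    hits: list[MotifHit] = []
    W = pwm.width
    for seq_id, seq in items:
        if len(seq) < W:
            continue
        enc = encode(seq)
        per_offset: list[tuple[int, str, float]] = []
        if strands in ("both", "+"):
            w = _scan_encoded(enc, pwm, bg)
            for off in np.nonzero(w >= threshold)[0]:
                per_offset.append((int(off), "+", float(w[off])))
        if strands in ("both", "-"):
            rc = encode(reverse_complement(seq))
            wrc = _scan_encoded(rc, pwm, bg)
            n = len(wrc)
            for off_rc in np.nonzero(wrc >= threshold)[0]:
                off = n - 1 - int(off_rc)  # window start in forward coordinates
                per_offset.append((off, "-", float(wrc[off_rc])))
        per_offset.sort(key=lambda h: (h[0], h[1]))
        hits.extend(MotifHit(seq_id, off, strand, wt) for off, strand, wt in per_offset)
    return hits


def interval_match_fraction(
    intervals,
    sequences: Mapping[str, str],
    pwm: PWMModel,
    bg: MarkovBackground,
    threshold: float = 4.0,
) -> float:
    """Fraction of intervals whose sequence contains >= 1 hit.

    ``sequences`` maps chromosome name to sequence; interval coordinates
    must lie within the corresponding sequence.
    """
    from .core import CoreInterval  # local import to avoid a cycle

    spans = [c.span if isinstance(c, CoreInterval) else c for c in intervals]
    if not spans:
        return float("nan")
    n_hit = 0
    for iv in spans:
        if iv.chrom not in sequences:
            raise ValueError(f"no sequence for chromosome {iv.chrom!r}")
        seq = sequences[iv.chrom]
        if iv.end > len(seq):
            raise ValueError(f"interval {iv.name} outside sequence bounds")
        sub = seq[iv.start : iv.end]
        if scan_sequences({iv.name: sub}, pwm, bg, threshold=threshold):
            n_hit += 1
    return n_hit / len(spans)


def consensus(pwm: PWMModel) -> str:
    return "".join(BASES[i] for i in pwm.probs.argmax(axis=0))


def sample_word(pwm: PWMModel, rng: np.random.Generator) -> str:
    """Draw one word from the PWM's per-position distributions."""
    return "".join(
        BASES[rng.choice(4, p=pwm.probs[:, j])] for j in range(pwm.width)
    )


def read_pwm_counts(path: str | Path) -> PWMCounts:
    """Read a 4-row whitespace-separated count matrix (rows A, C, G, T;
    an optional leading base label per row is allowed)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", ">")):
                continue
            parts = line.replace(":", " ").split()
            if parts and parts[0].upper() in ("A", "C", "G", "T"):
                parts = parts[1:]
            rows.append([float(x) for x in parts])
    if len(rows) != 4:
        raise ValueError(f"expected 4 rows (A,C,G,T) in {path}, found {len(rows)}")
    return PWMCounts(np.array(rows))


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
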