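"""Resampling-based co-occurrence test for two TF binding-interval sets.

The observed statistic is the number of first-set intervals overlapped by
at least one second-set interval.  The null re-places every second-set
interval uniformly at random on its original chromosome, preserving its
length; the one-sided enrichment p-value uses the add-one estimator
p = (1 + #{S* >= S}) / (nsamples + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import Interval, IntervalSet, SeqSpace, union_merge
from .stats import benjamini_hochberg

RESULT_COLUMNS = [
    "tf1", "tf2",
    "overlapped_in_tf1", "n_tf1", "percent_in_tf1",
    "overlapped_in_tf2", "n_tf2", "percent_in_tf2",
    "nsamples", "pvalue", "padjust",
]


@dataclass
class CooccurResult:
    tf1: str
    tf2: str
    overlapped_in_tf1: int
    n_tf1: int
    percent_in_tf1: float
    overlapped_in_tf2: int
    n_tf2: int
    percent_in_tf2: float
    nsamples: int
    pvalue: float
    padjust: Optional[float] = None

    def to_dict(self) -> dict:
        return {c: getattr(self, c) for c in RESULT_COLUMNS}


# ---------------------------------------------------------------------------
# fast per-chromosome representation


def _chrom_arrays(intervals) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, rows in by.items():
        rows.sort()
        starts = np.array([r[0] for r in rows], dtype=np.int64)
        ends = np.array([r[1] for r in rows], dtype=np.int64)
        out[chrom] = (starts, np.maximum.accumulate(ends))
    return out


def _count_overlapped(
    a_starts: np.ndarray, a_ends: np.ndarray, b: Mapping[str, tuple[np.ndarray, np.ndarray]], chrom: str
) -> int:
    """Number of intervals (a_starts, a_ends) overlapped by >= 1 b interval."""
    if chrom not in b:
        return 0
    b_starts, b_prefmax = b[chrom]
    j = np.searchsorted(b_starts, a_ends, side="left")
    hit = (j > 0) & (b_prefmax[np.maximum(j - 1, 0)] > a_starts)
    return int(hit.sum())


def overlap_stats(a: IntervalSet, b: IntervalSet) -> tuple[int, int]:
    """(number of a-intervals overlapping b, number of b-intervals overlapping a)."""
    a_raw, b_raw = _raw_arrays(a), _raw_arrays(b)
    a_arr = {c: (s, np.maximum.accumulate(e)) for c, (s, e) in a_raw.items()}
    b_arr = {c: (s, np.maximum.accumulate(e)) for c, (s, e) in b_raw.items()}
    in_a = sum(_count_overlapped(s, e, b_arr, c) for c, (s, e) in a_raw.items())
    in_b = sum(_count_overlapped(s, e, a_arr, c) for c, (s, e) in b_raw.items())
    return in_a, in_b


def _raw_arrays(iset) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by: dict[str, list[tuple[int, int]]] = {}
    for iv in iset:
        by.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, rows in by.items():
        rows.sort()
        out[chrom] = (
            np.array([r[0] for r in rows], dtype=np.int64),
            np.array([r[1] for r in rows], dtype=np.int64),
        )
    return out


# ---------------------------------------------------------------------------
# resampling null


def _draw_starts(
    rng: np.random.Generator, lengths_by_chrom: dict[str, np.ndarray], space: SeqSpace
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """One uniform re-placement of all intervals; chromosomes visited in
    sorted order so the draw sequence is reproducible."""
    out = {}
    for chrom in sorted(lengths_by_chrom):
        lens = lengths_by_chrom[chrom]
        clen = space[chrom]
        if np.any(lens > clen):
            raise ValueError(f"interval longer than chromosome {chrom}")
        starts = rng.integers(0, clen - lens + 1)
        order = np.argsort(starts, kind="stable")
        s = starts[order]
        e = s + lens[order]
        out[chrom] = (s, np.maximum.accumulate(e))
    return out


def resample_null(b: IntervalSet, space: SeqSpace, seed) -> IntervalSet:
    """Uniformly re-place each interval of ``b`` on its own chromosome,
    keeping its length.  ``seed`` may be an int or a Generator; the same
    draw order (chromosomes sorted) is used by :func:`cooccur_test`."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by: dict[str, list[int]] = {}
    for iv in b:
        by.setdefault(iv.chrom, []).append(iv.length)
    out = []
    for chrom in sorted(by):
        lens = np.array(by[chrom], dtype=np.int64)
        clen = space[chrom]
        if np.any(lens > clen):
            raise ValueError(f"interval longer than chromosome {chrom}")
        starts = rng.integers(0, clen - lens + 1)
        for s, ln in zip(starts, lens):
            out.append(Interval(chrom, int(s), int(s + ln)))
    out.sort(key=lambda iv: (iv.chrom, iv.start))
    return IntervalSet(
        label=f"{b.label}_resampled", intervals=out, technique=b.technique,
        fdr_tier=b.fdr_tier, seqspace=space,
    )


def cooccur_test(
    a: IntervalSet,
    b: IntervalSet,
    space: SeqSpace,
    nsamples: int = 1000,
    seed=None,
) -> CooccurResult:
    """One-sided enrichment test of the overlap of ``a`` by ``b``.

    ``b`` is re-placed ``nsamples`` times; descriptive counts and percents
    for both directions come from the observed data.
    """
    if nsamples < 1:
        raise ValueError("nsamples must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    in_a, in_b = overlap_stats(a, b)
    a_raw = _raw_arrays(a)
    by: dict[str, list[int]] = {}
    for iv in b:
        by.setdefault(iv.chrom, []).append(iv.length)
    lengths = {c: np.array(v, dtype=np.int64) for c, v in by.items()}
    exceed = 0
    for _ in range(nsamples):
        placed = _draw_starts(rng, lengths, space)
        s_star = sum(
            _count_overlapped(s, e, placed, c) for c, (s, e) in a_raw.items()
        )
        if s_star >= in_a:
            exceed += 1
    pvalue = (1 + exceed) / (nsamples + 1)
    n_a, n_b = len(a), len(b)
    return CooccurResult(
        tf1=a.label,
        tf2=b.label,
        overlapped_in_tf1=in_a,
        n_tf1=n_a,
        percent_in_tf1=in_a / n_a if n_a else float("nan"),
        overlapped_in_tf2=in_b,
        n_tf2=n_b,
        percent_in_tf2=in_b / n_b if n_b else float("nan"),
        nsamples=nsamples,
        pvalue=pvalue,
    )


def pairwise_cooccur(
    tf_sets: Mapping[str, Sequence[IntervalSet]],
    space: SeqSpace,
    nsamples: int = 1000,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Exhaustive pairwise co-occurrence over TFs.

    Each TF's datasets are first union-merged.  Every unordered pair is
    tested once with labels in lexicographic order (the second is
    resampled); p-values are Benjamini-Hochberg adjusted across all pairs.
    """
    labels = sorted(tf_sets)
    if len(labels) < 2:
        raise ValueError("need at least two TFs")
    unions = {lab: union_merge(list(tf_sets[lab]), label=lab) for lab in labels}
    pairs = list(combinations(labels, 2))
    children = np.random.SeedSequence(seed).spawn(len(pairs))
    rows = []
    for (t1, t2), child in zip(pairs, children):
        res = cooccur_test(
            unions[t1], unions[t2], space, nsamples=nsamples,
            seed=np.random.default_rng(child),
        )
        rows.append(res.to_dict())
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df["padjust"] = benjamini_hochberg(df["pvalue"].to_numpy())
    return df
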