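"""Interval-to-gene assignment: overlap-else-nearest within a range cap.

Every gene overlapping an interval (>= 1 bp, using the full interval) is a
hit; an interval overlapping no gene is assigned its single closest gene
within ``max_range`` bp of either edge, with equidistant ties all kept.
Distances are edge-to-edge gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Set

from .core import CoreInterval
from .genome import GenomeAnnotation, Interval, IntervalSet


@dataclass(frozen=True)
class GeneHit:
    interval_id: str
    gene_id: str
    mode: str  # "overlap" | "nearest"
    distance: int  # 0 for overlap; edge-to-edge gap for nearest


@dataclass(frozen=True)
class AssignmentConfig:
    max_range: int = 10_000

    def __post_init__(self) -> None:
        if self.max_range < 0:
            raise ValueError("max_range must be >= 0")


def _as_spans(intervals) -> list[Interval]:
    if isinstance(intervals, IntervalSet):
        return list(intervals.intervals)
    out = []
    for x in intervals:
        out.append(x.span if isinstance(x, CoreInterval) else x)
    return out


def assign_genes(
    intervals: IntervalSet | Iterable[Interval | CoreInterval],
    ann: GenomeAnnotation,
    cfg: AssignmentConfig = AssignmentConfig(),
) -> list[GeneHit]:
    """Assign genes to intervals by the overlap-else-nearest rule.

    Returns one :class:`GeneHit` per (interval, gene) pair.  For an
    interval abutting (but not overlapping) a gene the gap is 0 and the
    gene is still a "nearest" hit.
    """
    spans = _as_spans(intervals)
    by_chrom = ann.genes_by_chrom()
    hits: list[GeneHit] = []
    for iv in spans:
        genes = by_chrom.get(iv.chrom, [])
        over = [g for g in genes if g.start < iv.end and g.end > iv.start]
        if over:
            for g in sorted(over, key=lambda g: g.gene_id):
                hits.append(GeneHit(iv.name, g.gene_id, "overlap", 0))
            continue
        gaps = []
        for g in genes:
            if g.end <= iv.start:
                gaps.append((iv.start - g.end, g.gene_id))
            else:  # g.start >= iv.end, no overlap by construction
                gaps.append((g.start - iv.end, g.gene_id))
        if not gaps:
            continue
        best = min(gap for gap, _ in gaps)
        if best > cfg.max_range:
            continue
        for gap, gid in sorted(gaps):
            if gap == best:
                hits.append(GeneHit(iv.name, gid, "nearest", gap))
    return hits


def bound_genes(hits: Sequence[GeneHit]) -> Set[str]:
    """Deduplicated union of gene ids over all hits."""
    return {h.gene_id for h in hits}
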