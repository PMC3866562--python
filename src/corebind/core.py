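"""Cross-technique reconciliation of tiered binding-interval sets, and
annotation of the reconciled core set against genes, TSSs, introns and
enhancer catalogues.

The reconciliation rule: an interval called at the stringent FDR tier in
one technique enters the core set iff it is confirmed by (overlaps by at
least 1 bp) an interval called at or below the permissive tier in a
*different* technique.  Confirmed stringent spans are emitted as-is, then
overlapping emissions are merged with their support lists concatenated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .genome import (
    GeneModel,
    GenomeAnnotation,
    Interval,
    IntervalSet,
    derive_introns,
    gene_tss,
    interval_center,
)
from .stats import rank_sum_test

logger = logging.getLogger(__name__)


@dataclass
class CoreInterval:
    """A reconciled binding interval with provenance.

    ``support`` lists every (dataset label, fdr tier) pair that contributed;
    ``primary_evidence`` names the stringent-tier dataset(s) whose spans the
    interval derives from.
    """

    span: Interval
    support: list[tuple[str, float]] = field(default_factory=list)
    primary_evidence: list[str] = field(default_factory=list)


@dataclass
class FeatureAnnotation:
    interval_id: str
    location_class: str  # exonic | intronic | intergenic
    genic: bool
    host_gene: Optional[str] = None


@dataclass
class TssProfile:
    """Signed distances from interval centres to their nearest TSS."""

    distances: np.ndarray
    window: int
    count_within_window: int

    @property
    def fraction_within_window(self) -> float:
        return self.count_within_window / len(self.distances) if len(self.distances) else float("nan")


@dataclass
class IntronLengthReport:
    bound_lengths: np.ndarray
    unbound_lengths: np.ndarray
    mean_bound: float
    mean_unbound: float
    median_bound: float
    median_unbound: float
    W: float
    p_value: float


@dataclass
class EnhancerOverlapReport:
    """Per-category counts of enhancers overlapped by >= 1 query interval."""

    categories: dict[str, tuple[int, int, float]]  # name -> (total, overlapped, fraction)


# ---------------------------------------------------------------------------


def _sorted_arrays(intervals: Iterable[Interval]) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, list[int]]]:
    """Per chromosome: starts (sorted), ends, running max of ends, original indices."""
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, iv in enumerate(intervals):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, i))
    out = {}
    for chrom, rows in by_chrom.items():
        rows.sort()
        starts = np.array([r[0] for r in rows])
        ends = np.array([r[1] for r in rows])
        out[chrom] = (starts, ends, np.maximum.accumulate(ends), [r[2] for r in rows])
    return out


def overlapping_indices(
    iv: Interval, arrays: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray, list[int]]]
) -> list[int]:
    """Original indices of catalogued intervals overlapping ``iv``."""
    if iv.chrom not in arrays:
        return []
    starts, ends, _prefmax, idx = arrays[iv.chrom]
    j = int(np.searchsorted(starts, iv.end, side="left"))
    hits = np.nonzero(ends[:j] > iv.start)[0]
    return [idx[h] for h in hits]


def reconcile_core(
    datasets: Sequence[IntervalSet],
    high_tier: float = 1.0,
    low_tier: float = 25.0,
) -> list[CoreInterval]:
    """Build the core binding set from tiered datasets of >= 2 techniques.

    Every interval from a dataset at the stringent tier (``fdr_tier <=
    high_tier``) is emitted iff it overlaps at least one interval from a
    dataset of a different technique at ``fdr_tier <= low_tier``.
    Overlapping emitted spans are merged, concatenating support.
    """
    if high_tier >= low_tier:
        raise ValueError("high (stringent) tier must be numerically below the low tier")
    techniques = {d.technique for d in datasets}
    if len(techniques) < 2:
        raise ValueError(
            "core reconciliation needs datasets from at least two techniques; "
            f"got {sorted(techniques)}"
        )
    for d in datasets:
        if d.fdr_tier is None:
            raise ValueError(f"dataset {d.label!r} has no fdr_tier")

    # permissive-tier evidence per technique, with source bookkeeping
    evidence: dict[str, list[tuple[Interval, str, float]]] = {}
    for d in datasets:
        if d.fdr_tier <= low_tier:
            for iv in d:
                evidence.setdefault(d.technique, []).append((iv, d.label, d.fdr_tier))

    emitted: list[CoreInterval] = []
    for d in datasets:
        if d.fdr_tier > high_tier:
            continue
        confirm_pool = [
            rec for tech, recs in evidence.items() if tech != d.technique for rec in recs
        ]
        arrays = _sorted_arrays([rec[0] for rec in confirm_pool])
        for iv in d:
            hits = overlapping_indices(iv, arrays)
            if not hits:
                continue
            support = [(d.label, float(d.fdr_tier))]
            for h in sorted(hits):
                entry = (confirm_pool[h][1], float(confirm_pool[h][2]))
                if entry not in support:
                    support.append(entry)
            emitted.append(CoreInterval(span=iv, support=support, primary_evidence=[d.label]))

    # merge overlapping emissions
    emitted.sort(key=lambda c: (c.span.chrom, c.span.start, c.span.end))
    merged: list[CoreInterval] = []
    for c in emitted:
        if (
            merged
            and merged[-1].span.chrom == c.span.chrom
            and c.span.start < merged[-1].span.end
        ):
            prev = merged[-1]
            prev.span = Interval(prev.span.chrom, prev.span.start, max(prev.span.end, c.span.end))
            for entry in c.support:
                if entry not in prev.support:
                    prev.support.append(entry)
            for lab in c.primary_evidence:
                if lab not in prev.primary_evidence:
                    prev.primary_evidence.append(lab)
        else:
            merged.append(
                CoreInterval(
                    span=Interval(c.span.chrom, c.span.start, c.span.end),
                    support=list(c.support),
                    primary_evidence=list(c.primary_evidence),
                )
            )
    logger.info("core reconciliation: %d stringent emissions -> %d merged core intervals", len(emitted), len(merged))
    return merged


def core_to_intervals(core: Sequence[CoreInterval]) -> list[Interval]:
    """Core intervals as plain spans, support encoded in the name field."""
    out = []
    for c in core:
        name = ";".join(f"{lab}:{tier:g}" for lab, tier in c.support)
        out.append(Interval(c.span.chrom, c.span.start, c.span.end, id=name))
    return out


# ---------------------------------------------------------------------------


def annotate_location(
    core: Sequence[CoreInterval | Interval],
    ann: GenomeAnnotation,
) -> tuple[list[FeatureAnnotation], dict[str, float]]:
    """Classify each interval by its centre point as exonic/intronic/intergenic.

    A centre inside any gene span is genic; a genic centre inside the merged
    exons of a containing gene is exonic, otherwise intronic.  When several
    genes contain the centre, a gene whose exons contain it is preferred and
    ties break on the lexicographically smallest gene id.  The summary holds
    ``fraction_genic`` and ``fraction_intronic_of_genic``.
    """
    spans = [c.span if isinstance(c, CoreInterval) else c for c in core]
    by_chrom = ann.genes_by_chrom()
    exon_cache: dict[str, list[tuple[int, int]]] = {}
    results: list[FeatureAnnotation] = []
    n_genic = n_intronic = 0
    for iv in spans:
        centre = interval_center(iv)
        containing = [
            g for g in by_chrom.get(iv.chrom, []) if g.start <= centre < g.end
        ]
        if not containing:
            results.append(FeatureAnnotation(iv.name, "intergenic", False))
            continue
        n_genic += 1
        exonic_hosts, intronic_hosts = [], []
        for g in containing:
            if g.gene_id not in exon_cache:
                exon_cache[g.gene_id] = g.merged_exons()
            if any(s <= centre < e for s, e in exon_cache[g.gene_id]):
                exonic_hosts.append(g.gene_id)
            else:
                intronic_hosts.append(g.gene_id)
        if exonic_hosts:
            results.append(FeatureAnnotation(iv.name, "exonic", True, min(exonic_hosts)))
        else:
            n_intronic += 1
            results.append(FeatureAnnotation(iv.name, "intronic", True, min(intronic_hosts)))
    n = len(spans)
    summary = {
        "n_intervals": float(n),
        "fraction_genic": n_genic / n if n else float("nan"),
        "fraction_intronic_of_genic": n_intronic / n_genic if n_genic else float("nan"),
    }
    return results, summary


def tss_distance_profile(
    core: Sequence[CoreInterval | Interval],
    ann: GenomeAnnotation,
    window: int = 500,
    tss_mode: str = "strand_aware",
) -> TssProfile:
    """Signed distance from each interval centre to its nearest TSS.

    Sign convention in strand_aware mode: positive means the centre lies
    downstream of the TSS in the gene's reading direction.  literal_start
    mode reports the raw difference centre - gene.start.  Equidistant TSSs
    break ties on the smallest gene id.  Intervals on chromosomes without
    genes are skipped with a warning.
    """
    spans = [c.span if isinstance(c, CoreInterval) else c for c in core]
    by_chrom = ann.genes_by_chrom()
    tss_tables: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
    for chrom, genes in by_chrom.items():
        coords = np.array([gene_tss(g, tss_mode) for g in genes])
        tss_tables[chrom] = (coords, genes)
    distances = []
    for iv in spans:
        if iv.chrom not in tss_tables:
            logger.warning("interval %s on chromosome with no genes; skipped", iv.name)
            continue
        coords, genes = tss_tables[iv.chrom]
        centre = interval_center(iv)
        absd = np.abs(coords - centre)
        best = absd.min()
        tied = np.nonzero(absd == best)[0]
        g = genes[min(tied, key=lambda i: genes[i].gene_id)]
        tss = coords[min(tied, key=lambda i: genes[i].gene_id)]
        if tss_mode == "strand_aware" and g.strand == "-":
            d = int(tss - centre)
        else:
            d = int(centre - tss)
        distances.append(d)
    distances = np.array(distances, dtype=int)
    count = int(np.sum(np.abs(distances) <= window)) if distances.size else 0
    return TssProfile(distances=distances, window=window, count_within_window=count)


def intron_length_test(
    core: Sequence[CoreInterval | Interval],
    ann: GenomeAnnotation,
) -> IntronLengthReport:
    """Compare lengths of bound vs unbound introns (two-sided rank-sum test).

    An intron is bound when it overlaps (>= 1 bp) at least one core
    interval.  Introns are pooled over all genes.
    """
    spans = [c.span if isinstance(c, CoreInterval) else c for c in core]
    arrays = _sorted_arrays(spans)
    bound, unbound = [], []
    for g in ann.genes:
        if not g.transcripts:
            continue
        for intron in derive_introns(g):
            if overlapping_indices(intron, arrays):
                bound.append(intron.length)
            else:
                unbound.append(intron.length)
    if not bound or not unbound:
        raise ValueError("both bound and unbound intron groups must be non-empty")
    bound_a = np.array(bound, dtype=float)
    unbound_a = np.array(unbound, dtype=float)
    w, p = rank_sum_test(bound_a, unbound_a, alternative="two-sided")
    return IntronLengthReport(
        bound_lengths=bound_a,
        unbound_lengths=unbound_a,
        mean_bound=float(bound_a.mean()),
        mean_unbound=float(unbound_a.mean()),
        median_bound=float(np.median(bound_a)),
        median_unbound=float(np.median(unbound_a)),
        W=w,
        p_value=p,
    )


def enhancer_overlap(
    core: Sequence[CoreInterval | Interval],
    enhancers: Sequence[IntervalSet],
) -> EnhancerOverlapReport:
    """Per enhancer category: how many enhancers a core interval touches."""
    spans = [c.span if isinstance(c, CoreInterval) else c for c in core]
    arrays = _sorted_arrays(spans)
    categories: dict[str, tuple[int, int, float]] = {}
    for eset in enhancers:
        total = len(eset)
        hit = sum(1 for e in eset if overlapping_indices(e, arrays))
        categories[eset.label] = (total, hit, hit / total if total else float("nan"))
        logger.info("enhancer category %s: %d/%d overlapped", eset.label, hit, total)
    return EnhancerOverlapReport(categories=categories)
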