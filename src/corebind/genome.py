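"""Genomic interval and annotation data model.

All coordinates are 0-based half-open internally.  BED input is passed
through unchanged; GFF3 (1-based closed) is converted on read.  Overlap
requires at least one shared base pair, so abutting intervals are distinct.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

TECHNIQUES = ("damid", "chip", "other")


class MalformedRecordError(ValueError):
    """A line in an input file violates the format contract."""


@dataclass(frozen=True)
class SeqSpace:
    """Coordinate frame: chromosome name -> length in bp.

    The assembly is whatever the caller loaded; nothing is hard-coded.
    """

    chrom_sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        for name, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {size}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes

    def __getitem__(self, chrom: str) -> int:
        return self.chrom_sizes[chrom]

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)


@dataclass(frozen=True)
class Interval:
    """A genomic span [start, end) with optional score and label."""

    chrom: str
    start: int
    end: int
    score: Optional[float] = None
    id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return self.id if self.id is not None else f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class IntervalSet:
    """A named collection of intervals from one dataset.

    ``technique`` records the experimental method ("damid", "chip" or
    "other") and ``fdr_tier`` the false-discovery-rate percentage the set
    was called at (e.g. 1 for stringent, 25 for permissive).
    """

    label: str
    intervals: list[Interval] = field(default_factory=list)
    technique: str = "other"
    fdr_tier: Optional[float] = None
    seqspace: Optional[SeqSpace] = None

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise ValueError(f"unknown technique {self.technique!r}; expected one of {TECHNIQUES}")
        if self.fdr_tier is not None and self.fdr_tier <= 0:
            raise ValueError("fdr_tier must be positive")
        if self.seqspace is not None:
            for iv in self.intervals:
                self._check_in_space(iv)

    def _check_in_space(self, iv: Interval) -> None:
        assert self.seqspace is not None
        if iv.chrom not in self.seqspace:
            raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
        if iv.end > self.seqspace[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} extends past chromosome "
                f"end {self.seqspace[iv.chrom]}"
            )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


@dataclass
class GeneModel:
    """A gene with one or more transcripts given as exon-coordinate lists."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "?"  # '+', '-' or '?' (unknown)
    transcripts: list[list[tuple[int, int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-", "?"):
            raise ValueError(f"invalid strand {self.strand!r}")
        for exons in self.transcripts:
            for s, e in exons:
                if s < self.start or e > self.end:
                    raise ValueError(
                        f"exon [{s},{e}) outside gene span of {self.gene_id}"
                    )

    def merged_exons(self) -> list[tuple[int, int]]:
        """Union of all exons over all transcripts, merged where overlapping."""
        spans = sorted(x for exons in self.transcripts for x in exons)
        return merge_spans(spans)


@dataclass
class GenomeAnnotation:
    """Gene models plus the coordinate frame they live in."""

    seqspace: SeqSpace
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.chrom not in self.seqspace:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom!r}")

    def genes_by_chrom(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        for lst in out.values():
            lst.sort(key=lambda g: (g.start, g.gene_id))
        return out

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


# ---------------------------------------------------------------------------
# elementary interval arithmetic


def merge_spans(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping (but not merely abutting) sorted-or-not spans."""
    spans = sorted(spans)
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def interval_center(iv: Interval) -> int:
    """Single-bp approximation of the binding event: floor((start+end)/2)."""
    return (iv.start + iv.end) // 2


def overlaps(a: Interval, b: Interval) -> bool:
    """True iff the two half-open spans share >= 1 bp on the same chromosome."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def union_merge(sets: IntervalSet | Sequence[IntervalSet], label: Optional[str] = None) -> IntervalSet:
    """Union of one or more interval sets with overlapping spans merged.

    Abutting intervals (zero shared bp) stay separate.  Output is sorted by
    (chrom, start).  Scores and ids are dropped: the merged span is a new
    object.
    """
    if isinstance(sets, IntervalSet):
        sets = [sets]
    sets = list(sets)
    space = None
    for s in sets:
        if s.seqspace is not None:
            if space is not None and space is not s.seqspace and space.chrom_sizes != s.seqspace.chrom_sizes:
                raise ValueError("interval sets live in different coordinate frames")
            space = s.seqspace
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in sets:
        for iv in s:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: list[Interval] = []
    for chrom in sorted(by_chrom):
        for s, e in merge_spans(by_chrom[chrom]):
            out.append(Interval(chrom, s, e))
    if label is None:
        label = "union(" + ",".join(s.label for s in sets) + ")"
    techniques = {s.technique for s in sets}
    technique = techniques.pop() if len(techniques) == 1 else "other"
    return IntervalSet(label=label, intervals=out, technique=technique, seqspace=space)


# ---------------------------------------------------------------------------
# gene-derived features


def derive_introns(gene: GeneModel) -> list[Interval]:
    """Introns of a gene: per-transcript gaps between merged exons, unioned
    over transcripts and deduplicated.  Single-exon transcripts contribute
    nothing.
    """
    if not gene.transcripts:
        raise ValueError(f"gene {gene.gene_id} has no transcripts")
    seen: set[tuple[int, int]] = set()
    out: list[Interval] = []
    for exons in gene.transcripts:
        merged = merge_spans(exons)
        for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
            key = (e1, s2)
            if key not in seen:
                seen.add(key)
                out.append(Interval(gene.chrom, e1, s2, id=f"{gene.gene_id}_intron_{e1}_{s2}"))
    out.sort(key=lambda iv: (iv.start, iv.end))
    return out


def gene_tss(gene: GeneModel, mode: str = "strand_aware") -> int:
    """Approximate TSS coordinate of a gene.

    ``literal_start`` returns gene.start regardless of strand (the simple
    convention of taking the annotated start coordinate); ``strand_aware``
    returns the 5' end (start on '+', end on '-').  Unknown strand falls
    back to literal_start with a warning.
    """
    if mode == "literal_start":
        return gene.start
    if mode == "strand_aware":
        if gene.strand == "+":
            return gene.start
        if gene.strand == "-":
            return gene.end
        logger.warning(
            "gene %s has unknown strand; using literal start for TSS", gene.gene_id
        )
        return gene.start
    raise ValueError(f"unknown TSS mode {mode!r}")


# ---------------------------------------------------------------------------
# readers / writers


def read_chrom_sizes(path: str | Path) -> SeqSpace:
    """Two-column file: chromosome name, length."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise MalformedRecordError(f"{path}:{lineno}: expected 'name<TAB>length'")
            name = parts[0]
            if name in sizes:
                raise MalformedRecordError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            sizes[name] = int(parts[1])
    return SeqSpace(sizes)


def write_chrom_sizes(space: SeqSpace, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, size in space.chrom_sizes.items():
            fh.write(f"{name}\t{size}\n")


def read_bed(
    path: str | Path,
    label: Optional[str] = None,
    technique: str = "other",
    fdr_tier: Optional[float] = None,
    seqspace: Optional[SeqSpace] = None,
) -> IntervalSet:
    """Read a 3-6 column BED file, preserving its 0-based half-open coordinates.

    Column 4 becomes the interval id, column 5 the score.  Malformed records
    (end <= start, too few columns) raise :class:`MalformedRecordError` with
    the offending line number; with a ``seqspace`` attached, unknown
    chromosomes are an error too.
    """
    if label is None:
        label = Path(path).stem
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise MalformedRecordError(f"{path}:{lineno}: fewer than 3 tab-separated columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise MalformedRecordError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start or start < 0:
                raise MalformedRecordError(
                    f"{path}:{lineno}: invalid span [{start},{end})"
                )
            name = parts[3] if len(parts) > 3 and parts[3] not in (".", "") else None
            score: Optional[float] = None
            if len(parts) > 4 and parts[4] not in (".", ""):
                score = float(parts[4])
            if seqspace is not None and chrom not in seqspace:
                raise MalformedRecordError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            intervals.append(Interval(chrom, start, end, score=score, id=name))
    return IntervalSet(
        label=label, intervals=intervals, technique=technique, fdr_tier=fdr_tier, seqspace=seqspace
    )


def write_bed(iset: IntervalSet | Iterable[Interval], path: str | Path) -> None:
    """Write intervals as BED; name/score columns emitted when present."""
    intervals = iset.intervals if isinstance(iset, IntervalSet) else list(iset)
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.id is not None or iv.score is not None:
                cols.append(iv.id if iv.id is not None else ".")
            if iv.score is not None:
                cols.append(f"{iv.score:g}")
            fh.write("\t".join(cols) + "\n")


def _gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            continue
        k, v = item.split("=", 1)
        out[k] = v
    return out


def read_gff_genes(path: str | Path, seqspace: Optional[SeqSpace] = None) -> GenomeAnnotation:
    """Read gene/mRNA/exon features from a GFF3-style file.

    Coordinates are converted from GFF's 1-based closed convention to the
    internal 0-based half-open one.  Features other than gene, mRNA and
    exon are ignored.  An exon or mRNA whose Parent cannot be resolved, or
    a gene/mRNA without an ID, is an error.

    If no ``seqspace`` is given it is taken from ``##sequence-region``
    pragmas, falling back to the maximal feature end per chromosome.
    """
    genes: dict[str, GeneModel] = {}
    mrna_gene: dict[str, str] = {}
    mrna_exons: dict[str, list[tuple[int, int]]] = {}
    region_sizes: dict[str, int] = {}
    max_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    region_sizes[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise MalformedRecordError(f"{path}:{lineno}: expected 9 GFF columns")
            chrom, _src, ftype, start1, end1, _score, strand, _frame, attrs = parts[:9]
            if ftype not in ("gene", "mRNA", "exon"):
                continue
            start, end = int(start1) - 1, int(end1)
            if end <= start:
                raise MalformedRecordError(f"{path}:{lineno}: invalid span")
            max_end[chrom] = max(max_end.get(chrom, 0), end)
            a = _gff_attributes(attrs)
            if ftype == "gene":
                if "ID" not in a:
                    raise MalformedRecordError(f"{path}:{lineno}: gene without ID")
                genes[a["ID"]] = GeneModel(
                    gene_id=a["ID"], chrom=chrom, start=start, end=end,
                    strand=strand if strand in "+-" else "?", transcripts=[],
                )
            elif ftype == "mRNA":
                if "ID" not in a or "Parent" not in a:
                    raise MalformedRecordError(f"{path}:{lineno}: mRNA without ID/Parent")
                mrna_gene[a["ID"]] = a["Parent"]
                mrna_exons.setdefault(a["ID"], [])
            else:  # exon
                if "Parent" not in a:
                    raise MalformedRecordError(f"{path}:{lineno}: exon without Parent")
                for parent in a["Parent"].split(","):
                    mrna_exons.setdefault(parent, []).append((start, end))
    for mrna_id, parent in mrna_gene.items():
        if parent not in genes:
            raise MalformedRecordError(
                f"{path}: mRNA {mrna_id} has unresolvable Parent {parent!r}"
            )
    for parent_id, exons in mrna_exons.items():
        exons.sort()
        if parent_id in mrna_gene:
            gene_id = mrna_gene[parent_id]
        elif parent_id in genes:
            gene_id = parent_id  # exon attached directly to the gene
        else:
            raise MalformedRecordError(
                f"{path}: exon parent {parent_id!r} matches no gene or mRNA"
            )
        genes[gene_id].transcripts.append(exons)
    for g in genes.values():
        if not g.transcripts:
            g.transcripts.append([(g.start, g.end)])  # exonless gene: whole span
    if seqspace is None:
        sizes = dict(region_sizes)
        for chrom, end in max_end.items():
            sizes.setdefault(chrom, end)
        seqspace = SeqSpace(sizes)
    return GenomeAnnotation(seqspace=seqspace, genes=sorted(genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id)))


def write_gff_genes(ann: GenomeAnnotation, path: str | Path) -> None:
    """Emit gene/mRNA/exon features in GFF3 (converting back to 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, size in ann.seqspace.chrom_sizes.items():
            fh.write(f"##sequence-region {chrom} 1 {size}\n")
        for g in sorted(ann.genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            strand = g.strand if g.strand in "+-" else "."
            fh.write(
                f"{g.chrom}\t.\tgene\t{g.start + 1}\t{g.end}\t.\t{strand}\t.\tID={g.gene_id}\n"
            )
            for t, exons in enumerate(g.transcripts):
                tid = f"{g.gene_id}.t{t + 1}"
                ts = min(s for s, _ in exons)
                te = max(e for _, e in exons)
                fh.write(
                    f"{g.chrom}\t.\tmRNA\t{ts + 1}\t{te}\t.\t{strand}\t.\tID={tid};Parent={g.gene_id}\n"
                )
                for s, e in exons:
                    fh.write(
                        f"{g.chrom}\t.\texon\t{s + 1}\t{e}\t.\t{strand}\t.\tParent={tid}\n"
                    )
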