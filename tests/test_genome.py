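"""Interval/annotation data model: readers, writers, interval arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from corebind.genome import (
    GeneModel,
    Interval,
    IntervalSet,
    MalformedRecordError,
    SeqSpace,
    derive_introns,
    gene_tss,
    interval_center,
    merge_spans,
    overlaps,
    read_bed,
    read_gff_genes,
    union_merge,
    write_bed,
    write_gff_genes,
)
from conftest import make_set


class TestBed:
    def test_round_trip_preserves_coordinates_ids_scores(self, tmp_path):
        path = tmp_path / "in.bed"
        path.write_text("chr2L\t100\t200\tpk1\t7.5\nchr2L\t300\t450\npk_x\t1\t2\n".replace("pk_x", "chr3R"))
        iset = read_bed(path, label="x")
        iv = iset.intervals[0]
        assert (iv.chrom, iv.start, iv.end, iv.id, iv.score) == ("chr2L", 100, 200, "pk1", 7.5)
        out = tmp_path / "out.bed"
        write_bed(iset, out)
        again = read_bed(out)
        assert [(i.chrom, i.start, i.end, i.id) for i in again] == [
            (i.chrom, i.start, i.end, i.id) for i in iset
        ]

    def test_empty_file_gives_empty_set(self, tmp_path):
        p = tmp_path / "e.bed"
        p.write_text("")
        assert len(read_bed(p)) == 0

    @pytest.mark.parametrize(
        "content", ["chr2L\t300\t200\n", "chr2L\t100\n", "chr2L\tx\t200\n"]
    )
    def test_malformed_records_error_with_line_number(self, tmp_path, content):
        p = tmp_path / "bad.bed"
        p.write_text(content)
        with pytest.raises(MalformedRecordError, match=":1"):
            read_bed(p)

    def test_unknown_chromosome_rejected_with_seqspace(self, tmp_path, space):
        p = tmp_path / "u.bed"
        p.write_text("chrUn\t0\t10\n")
        with pytest.raises(MalformedRecordError):
            read_bed(p, seqspace=space)


class TestGff:
    GFF = (
        "##gff-version 3\n"
        "##sequence-region chr1 1 50000\n"
        "chr1\t.\tgene\t1001\t2000\t.\t+\t.\tID=gA\n"
        "chr1\t.\tmRNA\t1001\t1300\t.\t+\t.\tID=gA.t1;Parent=gA\n"
        "chr1\t.\texon\t1001\t1100\t.\t+\t.\tParent=gA.t1\n"
        "chr1\t.\texon\t1201\t1300\t.\t+\t.\tParent=gA.t1\n"
    )

    def test_coordinates_converted_to_half_open(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(self.GFF)
        ann = read_gff_genes(p)
        g = ann.genes[0]
        assert (g.start, g.end) == (1000, 2000)
        assert g.transcripts == [[(1000, 1100), (1200, 1300)]]
        assert ann.seqspace["chr1"] == 50_000

    def test_unresolvable_parent_errors(self, tmp_path):
        p = tmp_path / "b.gff3"
        p.write_text("chr1\t.\texon\t10\t20\t.\t+\t.\tParent=ghost\n")
        with pytest.raises(MalformedRecordError, match="ghost"):
            read_gff_genes(p)

    def test_gene_without_id_errors(self, tmp_path):
        p = tmp_path / "c.gff3"
        p.write_text("chr1\t.\tgene\t10\t20\t.\t+\t.\tName=x\n")
        with pytest.raises(MalformedRecordError):
            read_gff_genes(p)

    def test_write_read_round_trip(self, tmp_path, tiny_annotation):
        p = tmp_path / "rt.gff3"
        write_gff_genes(tiny_annotation, p)
        again = read_gff_genes(p)
        for orig, back in zip(tiny_annotation.genes, again.genes):
            assert (orig.gene_id, orig.chrom, orig.start, orig.end, orig.strand) == (
                back.gene_id, back.chrom, back.start, back.end, back.strand
            )
            assert orig.transcripts == back.transcripts


class TestIntrons:
    def test_gaps_between_exons(self):
        g = GeneModel("g", "c", 0, 300, "+", transcripts=[[(0, 100), (200, 300)]])
        introns = derive_introns(g)
        assert [(i.start, i.end) for i in introns] == [(100, 200)]
        assert introns[0].length == 100

    def test_single_exon_yields_none(self):
        g = GeneModel("g", "c", 0, 300, "+", transcripts=[[(0, 300)]])
        assert derive_introns(g) == []

    def test_overlapping_exons_merged_before_gaps(self):
        g = GeneModel(
            "g", "c", 0, 300, "+",
            transcripts=[[(0, 100), (50, 150), (200, 300)]],
        )
        assert [(i.start, i.end) for i in derive_introns(g)] == [(150, 200)]

    def test_exon_plus_intron_lengths_cover_merged_envelope(self, rng):
        # sum(merged exon lengths) + sum(intron lengths) == envelope span
        for _ in range(50):
            n = int(rng.integers(1, 8))
            bounds = np.sort(rng.choice(np.arange(1, 500), size=2 * n, replace=False))
            exons = [(int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n)]
            g = GeneModel("g", "c", 0, 500, "+", transcripts=[exons])
            merged = g.merged_exons()
            introns = derive_introns(g)
            total = sum(e - s for s, e in merged) + sum(i.length for i in introns)
            assert total == merged[-1][1] - merged[0][0]


class TestTss:
    @pytest.mark.parametrize(
        "strand,mode,expected",
        [
            ("+", "strand_aware", 1000),
            ("+", "literal_start", 1000),
            ("-", "strand_aware", 2000),
            ("-", "literal_start", 1000),
        ],
    )
    def test_modes(self, strand, mode, expected):
        g = GeneModel("g", "c", 1000, 2000, strand, transcripts=[[(1000, 2000)]])
        assert gene_tss(g, mode) == expected

    def test_unknown_strand_falls_back_to_literal(self, caplog):
        g = GeneModel("g", "c", 1000, 2000, "?", transcripts=[[(1000, 2000)]])
        assert gene_tss(g, "strand_aware") == 1000


class TestCenterOverlap:
    @pytest.mark.parametrize(
        "start,end,expected", [(100, 201, 150), (100, 101, 100), (0, 2, 1)]
    )
    def test_center_floor(self, start, end, expected):
        assert interval_center(Interval("c", start, end)) == expected

    @given(st.integers(0, 10_000), st.integers(1, 5_000))
    def test_center_inside_interval(self, start, length):
        iv = Interval("c", start, start + length)
        assert iv.start <= interval_center(iv) < iv.end

    def test_abutting_do_not_overlap(self):
        assert not overlaps(Interval("c", 0, 10), Interval("c", 10, 20))
        assert overlaps(Interval("c", 0, 10), Interval("c", 9, 20))
        assert not overlaps(Interval("c1", 0, 10), Interval("c2", 0, 10))


spans_strategy = st.lists(
    st.tuples(st.integers(0, 1000), st.integers(1, 200)).map(lambda t: (t[0], t[0] + t[1])),
    min_size=0,
    max_size=30,
)


class TestUnionMerge:
    def test_overlapping_merged_abutting_kept(self):
        s = make_set("a", [("c", 100, 200), ("c", 150, 250), ("c", 300, 400)])
        merged = union_merge(s)
        assert [(i.start, i.end) for i in merged] == [(100, 250), (300, 400)]
        s2 = make_set("b", [("c", 0, 10), ("c", 10, 20)])
        assert len(union_merge(s2)) == 2

    def test_empty_input(self):
        assert len(union_merge(make_set("e", []))) == 0

    @settings(deadline=None, max_examples=50)
    @given(spans_strategy, spans_strategy)
    def test_idempotent_order_independent_never_grows(self, spans1, spans2):
        a = make_set("a", [("c", s, e) for s, e in spans1])
        b = make_set("b", [("c", s, e) for s, e in spans2])
        ab = union_merge([a, b])
        ba = union_merge([b, a])
        assert [(i.start, i.end) for i in ab] == [(i.start, i.end) for i in ba]
        twice = union_merge(ab)
        assert [(i.start, i.end) for i in twice] == [(i.start, i.end) for i in ab]
        covered = sum(i.length for i in ab)
        raw = sum(e - s for s, e in spans1 + spans2)
        assert covered <= raw


class TestValidation:
    def test_interval_rejects_empty_span(self):
        with pytest.raises(ValueError):
            Interval("c", 5, 5)

    def test_seqspace_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            SeqSpace({"c": 0})

    def test_intervalset_rejects_out_of_bounds(self, space):
        with pytest.raises(ValueError):
            IntervalSet("x", [Interval("chr1", 0, 200_000)], seqspace=space)
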