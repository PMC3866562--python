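"""Core reconciliation and binding-feature annotation."""

import numpy as np
import pytest

from corebind.core import (
    annotate_location,
    enhancer_overlap,
    intron_length_test,
    reconcile_core,
    tss_distance_profile,
)
from corebind.genome import GeneModel, GenomeAnnotation, Interval, SeqSpace
from corebind.stats import rank_sum_test
from conftest import make_set


def spans_of(core):
    return sorted((c.span.chrom, c.span.start, c.span.end) for c in core)


class TestReconcile:
    def test_high_confirmed_by_other_technique_low(self):
        damid = make_set("d1", [("c", 100, 200)], "damid", 1)
        chip = make_set("c25", [("c", 150, 300)], "chip", 25)
        core = reconcile_core([damid, chip])
        assert spans_of(core) == [("c", 100, 200)]
        assert ("d1", 1.0) in core[0].support and ("c25", 25.0) in core[0].support

    def test_high_without_cross_technique_overlap_excluded(self):
        damid = make_set("d1", [("c", 100, 200)], "damid", 1)
        chip = make_set("c25", [("c", 5000, 5100)], "chip", 25)
        assert reconcile_core([damid, chip]) == []

    def test_two_low_tiers_never_emit(self):
        damid = make_set("d25", [("c", 100, 200)], "damid", 25)
        chip = make_set("c25", [("c", 150, 300)], "chip", 25)
        assert reconcile_core([damid, chip]) == []

    def test_same_technique_does_not_confirm(self):
        chip1 = make_set("chip_a", [("c", 100, 200)], "chip", 1)
        chip2 = make_set("chip_b", [("c", 150, 300)], "chip", 25)
        damid = make_set("d", [("c", 90_000, 90_100)], "damid", 25)
        assert reconcile_core([chip1, chip2, damid]) == []

    def test_single_technique_errors(self):
        a = make_set("a", [("c", 0, 10)], "chip", 1)
        b = make_set("b", [("c", 0, 10)], "chip", 25)
        with pytest.raises(ValueError, match="technique"):
            reconcile_core([a, b])

    def test_monotone_in_datasets(self, rng):
        def random_sets(n_sets):
            sets = []
            for i in range(n_sets):
                tech = "damid" if i % 2 else "chip"
                tier = 1 if i < 2 else 25
                spans = []
                for _ in range(30):
                    s = int(rng.integers(0, 9000))
                    spans.append(("c", s, s + int(rng.integers(50, 400))))
                sets.append(make_set(f"s{i}", spans, tech, tier))
            return sets

        sets = random_sets(5)
        # every base core region remains covered after adding a dataset
        base_core = reconcile_core(sets[:4])
        more_core = reconcile_core(sets)
        for c in base_core:
            assert any(
                m.span.chrom == c.span.chrom
                and m.span.start <= c.span.start
                and m.span.end >= c.span.end
                for m in more_core
            )


def brute_force_core(datasets, high_tier=1.0, low_tier=25.0):
    """Independent oracle: double loop over every stringent interval and
    every permissive interval of the other techniques, then a simple merge."""
    emitted = []
    for d in datasets:
        if d.fdr_tier > high_tier:
            continue
        for iv in d:
            confirmed = False
            for d2 in datasets:
                if d2.technique == d.technique or d2.fdr_tier > low_tier:
                    continue
                for jv in d2:
                    if iv.chrom == jv.chrom and iv.start < jv.end and jv.start < iv.end:
                        confirmed = True
            if confirmed:
                emitted.append((iv.chrom, iv.start, iv.end))
    emitted.sort()
    merged = []
    for c, s, e in emitted:
        if merged and merged[-1][0] == c and s < merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], e)
        else:
            merged.append([c, s, e])
    return [tuple(m) for m in merged]


def test_reconcile_matches_brute_force_on_random_instances(rng):
    for _ in range(30):
        datasets = []
        for i, (tech, tier) in enumerate(
            [("damid", 1), ("damid", 25), ("chip", 1), ("chip", 25)]
        ):
            spans = []
            for _ in range(int(rng.integers(5, 40))):
                chrom = f"c{rng.integers(1, 3)}"
                s = int(rng.integers(0, 8000))
                spans.append((chrom, s, s + int(rng.integers(20, 500))))
            datasets.append(make_set(f"s{i}", spans, tech, tier))
        assert spans_of(reconcile_core(datasets)) == brute_force_core(datasets)


class TestAnnotateLocation:
    def test_exonic_intronic_intergenic(self, tiny_annotation):
        core = [
            Interval("chr1", 520, 581),    # centre 550 in exon of geneA
            Interval("chr1", 750, 851),    # centre 800 in intron of geneA
            Interval("chr1", 40_000, 40_100),  # intergenic
            Interval("chr2", 100, 200),    # chr2 has geneC but centre outside
        ]
        feats, summary = annotate_location(core, tiny_annotation)
        assert feats[0].location_class == "exonic" and feats[0].host_gene == "geneA"
        assert feats[1].location_class == "intronic" and feats[1].host_gene == "geneA"
        assert feats[2].location_class == "intergenic" and not feats[2].genic
        assert summary["fraction_genic"] == pytest.approx(0.5)
        assert summary["fraction_intronic_of_genic"] == pytest.approx(0.5)

    def test_genic_fractions_sum_to_one(self, tiny_annotation, rng):
        core = [
            Interval("chr1", int(s), int(s) + 100)
            for s in rng.integers(0, 90_000, size=50)
        ]
        feats, summary = annotate_location(core, tiny_annotation)
        n_genic = sum(f.genic for f in feats)
        assert summary["fraction_genic"] == pytest.approx(n_genic / 50)
        assert all(f.host_gene for f in feats if f.genic)
        assert all(f.host_gene is None for f in feats if not f.genic)


class TestTssProfile:
    def test_zero_distance_counts_in_window(self, tiny_annotation):
        # geneA TSS (strand-aware, +) is at 500
        prof = tss_distance_profile([Interval("chr1", 450, 551)], tiny_annotation)
        assert prof.distances.tolist() == [0]
        assert prof.count_within_window == 1

    def test_downstream_sign_plus_strand(self, tiny_annotation):
        # centre 1100, geneA TSS 500 (+): downstream -> +600, outside window
        prof = tss_distance_profile([Interval("chr1", 1050, 1151)], tiny_annotation)
        assert prof.distances.tolist() == [600]
        assert prof.count_within_window == 0

    def test_downstream_sign_minus_strand(self, tiny_annotation):
        # geneB is '-' with TSS at end=2600; centre 2200 is downstream: +400
        prof = tss_distance_profile([Interval("chr1", 2150, 2251)], tiny_annotation)
        assert prof.distances.tolist() == [400]
        assert prof.count_within_window == 1

    def test_literal_start_mode_uses_raw_difference(self, tiny_annotation):
        prof = tss_distance_profile(
            [Interval("chr1", 2150, 2251)], tiny_annotation, tss_mode="literal_start"
        )
        assert prof.distances.tolist() == [200]  # centre 2200 - geneB.start 2000


class TestIntronLengthTest:
    def test_exact_small_sample_p(self, space):
        # bound introns {1000, 2000}, unbound {100, 200}: the one-sided
        # enumeration p is 1/6; two-sided doubles it
        genes = [
            GeneModel("gL1", "chr1", 0, 2100, "+", transcripts=[[(0, 50), (1050, 2100)]]),
            GeneModel("gL2", "chr1", 3000, 7100, "+", transcripts=[[(3000, 3050), (5050, 7100)]]),
            GeneModel("gS1", "chr1", 10_000, 10_250, "+",
                      transcripts=[[(10_000, 10_050), (10_150, 10_250)]]),
            GeneModel("gS2", "chr1", 20_000, 20_350, "+",
                      transcripts=[[(20_000, 20_050), (20_250, 20_350)]]),
        ]
        ann = GenomeAnnotation(seqspace=space, genes=genes)
        core = [Interval("chr1", 100, 300), Interval("chr1", 3500, 3700)]
        rep = intron_length_test(core, ann)
        assert sorted(rep.bound_lengths) == [1000, 2000]
        assert sorted(rep.unbound_lengths) == [100, 200]
        assert rep.mean_bound == 1500 and rep.mean_unbound == 150
        assert rep.p_value == pytest.approx(2 / 6)

    def test_identical_groups_give_p_one(self):
        w, p = rank_sum_test([5, 7], [5, 7])
        assert p == 1.0

    def test_error_when_a_group_is_empty(self, tiny_annotation):
        with pytest.raises(ValueError):
            intron_length_test([Interval("chr1", 40_000, 40_100)], tiny_annotation)
            # no intron overlaps -> bound group empty


class TestEnhancerOverlap:
    def test_counting_and_half_open_boundary(self):
        core = [Interval("c", 150, 160), Interval("c", 200, 300)]
        enh = make_set("validated", [("c", 100, 200), ("c", 500, 600)])
        rep = enhancer_overlap(core, [enh])
        total, hit, frac = rep.categories["validated"]
        assert (total, hit) == (2, 1)  # [200,300) does not touch [100,200)
        assert frac == pytest.approx(0.5)

    def test_fraction(self, rng):
        core = [Interval("c", 1000 * i, 1000 * i + 100) for i in range(4)]
        enh = make_set("cat", [("c", 1000 * i, 1000 * i + 50) for i in range(10)])
        rep = enhancer_overlap(core, [enh])
        total, hit, frac = rep.categories["cat"]
        assert (total, hit, frac) == (10, 4, 0.4)
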