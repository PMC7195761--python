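"""Segment parsing, LOH views, interval intersection, genome fractions.

Interval operations are checked against per-base boolean bitmaps on toy
genomes, the slow-but-obviously-correct oracle.
"""

import numpy as np
import pytest

from duohit.loh_segments import (
    GenomeModel,
    Segment,
    SegmentSet,
    genome_fraction,
    grch37_genome,
    intersect_sets,
    loh_view,
    mb,
    parse_event,
    read_segments,
    write_segments,
)
from oracles import (
    bitmap_contains,
    bitmap_intersection_segments,
    bitmap_union_length,
    random_segment_set,
)

TOY = GenomeModel({"1": 10_000, "2": 8_000, "3": 5_000})


class TestSegmentModel:
    def test_bounds_invariant(self):
        with pytest.raises(ValueError):
            Segment("1", 10, 10, "LOH")
        with pytest.raises(ValueError):
            Segment("1", -1, 10, "LOH")

    def test_event_vocabulary(self):
        with pytest.raises(ValueError):
            Segment("1", 0, 10, "DELETION")

    @pytest.mark.parametrize(
        "label,event",
        [
            ("LOH", "LOH"),
            ("loh", "LOH"),
            ("CN Loss", "CN_LOSS"),
            ("CN Loss/LOH", "CN_LOSS_LOH"),
            ("cn  loss/loh", "CN_LOSS_LOH"),
            ("CN Gain", "CN_GAIN"),
        ],
    )
    def test_event_labels_parse_case_insensitively(self, label, event):
        assert parse_event(label) == event

    def test_unknown_label_errors(self):
        with pytest.raises(ValueError, match="uniparental"):
            parse_event("uniparental")


class TestNormalization:
    def test_same_event_overlaps_and_bookends_merge(self):
        s = SegmentSet("t", [
            Segment("1", 0, 100, "LOH"),
            Segment("1", 100, 200, "LOH"),     # book-ended
            Segment("1", 150, 300, "LOH"),     # overlapping
            Segment("1", 400, 500, "LOH"),
            Segment("1", 100, 250, "CN_LOSS"), # different event: untouched
        ]).normalized()
        loh = [x for x in s if x.event == "LOH"]
        assert [(x.start, x.end) for x in loh] == [(0, 300), (400, 500)]
        assert len([x for x in s if x.event == "CN_LOSS"]) == 1

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        s = random_segment_set(rng, TOY, 40)
        once = s.normalized()
        assert once.normalized().segments == once.segments


class TestReadSegments:
    def test_bed_passes_through(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr2\t0\t10\tLOH\n")
        s = read_segments(p, dialect="BED")
        assert s.segments == [Segment("2", 0, 10, "LOH")]

    def test_seg_shifts_one_based_inclusive_start(self, tmp_path):
        p = tmp_path / "x.seg"
        p.write_text("sample\tchrom\tstart\tend\tevent\nT1\t1\t1\t100\tLOH\n")
        s = read_segments(p, dialect="SEG")
        assert s.segments == [Segment("1", 0, 100, "LOH")]
        assert s.sample_id == "T1"

    def test_table_row_with_thousands_separators(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("chrom\tstart\tend\tevent\n2\t241,428,066\t243,199,373\tCN Loss/LOH\n")
        s = read_segments(p, dialect="TABLE")
        assert s.segments == [Segment("2", 241_428_066, 243_199_373, "CN_LOSS_LOH")]

    def test_bad_event_names_row(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("1\t0\t10\tLOH\n1\t20\t30\tBOGUS\n")
        with pytest.raises(ValueError, match="row 1"):
            read_segments(p, dialect="BED")

    def test_start_not_below_end_rejected(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("1\t50\t40\tLOH\n")
        with pytest.raises(ValueError, match="start >= end"):
            read_segments(p, dialect="BED")

    def test_write_read_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        s = random_segment_set(rng, TOY, 15).normalized()
        p = tmp_path / "rt.bed"
        write_segments(s, p)
        back = read_segments(p, dialect="BED")
        assert back.segments == s.segments


class TestLohView:
    def test_pure_gain_yields_empty_view(self):
        s = SegmentSet("t", [Segment("1", 0, 100, "CN_GAIN")])
        assert len(loh_view(s)) == 0

    def test_pure_loss_included_only_on_request(self):
        s = SegmentSet("t", [
            Segment("1", 0, 100, "CN_LOSS"),
            Segment("2", 0, 100, "LOH"),
            Segment("3", 0, 100, "CN_LOSS_LOH"),
        ])
        assert {x.chrom for x in loh_view(s)} == {"2", "3"}
        assert {x.chrom for x in loh_view(s, include_pure_loss=True)} == {"1", "2", "3"}

    def test_random_mix_equals_predicate_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            s = random_segment_set(rng, TOY, 25)
            view = loh_view(s, include_pure_loss=False).normalized()
            manual = SegmentSet("t", [
                x for x in s if x.event in ("LOH", "CN_LOSS_LOH")
            ]).normalized()
            assert view.union_length() == manual.union_length()


class TestIntersection:
    def test_worked_overlap_on_chromosome_2(self):
        a = SegmentSet("P1", [Segment("2", 99_377_108, 243_199_373, "LOH")])
        b = SegmentSet("P2", [Segment("2", 241_428_066, 243_199_373, "LOH")])
        inter = intersect_sets(a, b)
        assert inter.segments == [Segment("2", 241_428_066, 243_199_373, "LOH")]
        assert inter.union_length() == 1_771_307
        assert mb(inter.union_length()) == 1.77

    def test_disjoint_sets_empty(self):
        a = SegmentSet("a", [Segment("1", 0, 10, "LOH")])
        b = SegmentSet("b", [Segment("1", 20, 30, "LOH")])
        assert intersect_sets(a, b).segments == []

    def test_matches_perbase_bitmap_oracle_on_random_sets(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a = random_segment_set(rng, TOY, int(rng.integers(0, 8)))
            b = random_segment_set(rng, TOY, int(rng.integers(0, 8)))
            got = [(s.chrom, s.start, s.end) for s in intersect_sets(a, b)]
            want = bitmap_intersection_segments(a, b, TOY)
            assert sorted(got) == sorted(want)

    def test_commutative_and_associative(self):
        rng = np.random.default_rng(4)
        a, b, c = (random_segment_set(rng, TOY, 6) for _ in range(3))
        ab = intersect_sets(a, b)
        ba = intersect_sets(b, a)
        assert ab.segments == ba.segments
        abc = intersect_sets(intersect_sets(a, b), c)
        acb = intersect_sets(a, intersect_sets(b, c))
        assert abc.segments == acb.segments

    def test_self_intersection_preserves_union_length(self):
        rng = np.random.default_rng(5)
        a = random_segment_set(rng, TOY, 10)
        assert intersect_sets(a, a).union_length() == a.union_length()


class TestGenomeFraction:
    def test_full_single_chromosome_genome_is_one(self):
        g = GenomeModel({"1": 1000})
        s = SegmentSet("t", [Segment("1", 0, 1000, "LOH")])
        assert genome_fraction(s, g) == 1.0

    def test_empty_set_is_zero(self):
        assert genome_fraction(SegmentSet("t", []), TOY) == 0.0

    def test_matches_bitmap_oracle_and_bounds(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            s = random_segment_set(rng, TOY, int(rng.integers(0, 12)))
            frac = genome_fraction(s, TOY)
            assert frac == pytest.approx(bitmap_union_length(s, TOY) / TOY.total_length)
            assert 0.0 <= frac <= 1.0

    def test_monotone_under_segment_addition(self):
        rng = np.random.default_rng(7)
        s = random_segment_set(rng, TOY, 5)
        extra = random_segment_set(rng, TOY, 1)
        bigger = SegmentSet("t", s.segments + extra.segments)
        assert genome_fraction(bigger, TOY) >= genome_fraction(s, TOY)

    def test_segment_past_chromosome_end_errors(self):
        s = SegmentSet("t", [Segment("1", 0, 20_000, "LOH")])
        with pytest.raises(ValueError, match="extends past"):
            genome_fraction(s, TOY)

    def test_unknown_chromosome_errors(self):
        s = SegmentSet("t", [Segment("99", 0, 10, "LOH")])
        with pytest.raises(ValueError, match="absent"):
            genome_fraction(s, TOY)


class TestPublishedTables:
    def test_loh_views_exclude_the_pure_loss_rows(self, p2_segments):
        view = loh_view(p2_segments, include_pure_loss=False)
        # chromosome 10 carries only a pure copy-number loss: out of the view
        assert "10" not in {s.chrom for s in view}
        assert not bitmap_contains(view, "10", 1_000_000)
        # every LOH / CN Loss/LOH row survives
        for s in p2_segments:
            if s.event in ("LOH", "CN_LOSS_LOH"):
                assert bitmap_contains(view, s.chrom, s.start)

    def test_single_shared_loh_region_on_chromosome_2(self, p1_segments, p2_segments):
        inter = intersect_sets(loh_view(p1_segments), loh_view(p2_segments))
        assert len(inter) == 1
        region = inter.segments[0]
        assert (region.chrom, region.start, region.end) == ("2", 241_428_066, 243_199_373)
        assert mb(region.length) == 1.77

    def test_segments_fit_reference_genome(self, p1_segments, p2_segments):
        g = grch37_genome()
        for segs in (p1_segments, p2_segments):
            frac = genome_fraction(loh_view(segs, include_pure_loss=True), g)
            assert 0.0 < frac < 0.5


class TestMbReporting:
    @pytest.mark.parametrize(
        "bp,expect",
        [(1_771_307, 1.77), (1_775_000, 1.78), (1_765_000, 1.77), (5_000, 0.01), (0, 0.0)],
    )
    def test_rounds_half_away_from_zero_to_two_decimals(self, bp, expect):
        assert mb(bp) == expect
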