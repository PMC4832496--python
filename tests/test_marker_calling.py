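"""Marker mining, screening, ranking, deduplication and table output."""

import pytest

from ampindel import (Contig, ContigSet, PipelineConfig, classify_indel_size,
                      call_markers, annotate_reference, score_marker,
                      write_marker_table, read_marker_frame, SIZE_CLASSES)
from ampindel.insilico_pcr import AmpliconHit, Site
from ampindel.marker_calling import InDelMarker, MarkerTable, write_summary
from ampindel.primer_engine import PrimerPair


def make_pair(pair_id="P1", contig="c1", fwd_start=10, rev_end=260,
              penalty=2.0) -> PrimerPair:
    return PrimerPair(
        pair_id=pair_id, contig_id=contig, window_start=0, window_end=300,
        fwd_seq="A" * 20, rev_seq="T" * 20, fwd_start=fwd_start,
        rev_end=rev_end, designed_product=rev_end - fwd_start,
        fwd_tm=60.0, rev_tm=60.0, fwd_gc=0.5, rev_gc=0.5, penalty=penalty)


def make_hit(contig="c1", start=10, product=250, mismatches=0) -> AmpliconHit:
    return AmpliconHit(
        contig_id=contig, start=start, end=start + product, product=product,
        fwd_site=Site(contig, start, "+", mismatches),
        rev_site=Site(contig, start + product - 20, "-", 0),
        total_mismatches=mismatches)


def make_marker(indel_size=50, optimum=True, penalty=0.0, signed=None,
                start=10, source_product=250, contig="c1") -> InDelMarker:
    signed = signed if signed is not None else indel_size
    m = InDelMarker(
        marker_id="M1", pair=make_pair(contig=contig, fwd_start=start,
                                       rev_end=start + source_product,
                                       penalty=penalty),
        source_hit=make_hit(contig, start, source_product),
        target_hit=make_hit(contig, start, source_product + signed),
        source_product=source_product, target_product=source_product + signed,
        signed_diff=signed, indel_size=indel_size,
        size_class=classify_indel_size(indel_size),
        source_copies=1, target_copies=1, optimum=optimum)
    m.score = score_marker(m)
    return m


class TestClassifyIndelSize:
    @pytest.mark.parametrize("size,expected", [
        (1, "1~10"), (5, "1~10"), (10, "1~10"),
        (11, "11~20"), (20, "11~20"),
        (21, "21~100"), (100, "21~100"),
        (101, ">100"), (387, ">100")])
    def test_bin_boundaries(self, size, expected):
        assert classify_indel_size(size) == expected

    @pytest.mark.parametrize("size", [0, -3])
    def test_rejects_nonpositive(self, size):
        with pytest.raises(ValueError):
            classify_indel_size(size)

    def test_classes_partition_positive_sizes(self):
        assert {classify_indel_size(s) for s in range(1, 500)} == set(SIZE_CLASSES)


class TestScoreMarker:
    def test_capped_size_optimum_zero_penalty_scores_100(self):
        assert score_marker(make_marker(200, True, 0.0)) == pytest.approx(100.0)

    def test_larger_indel_scores_higher_up_to_cap(self):
        scores = [score_marker(make_marker(s)) for s in (30, 90, 200, 350)]
        assert scores[0] < scores[1] < scores[2] == scores[3]

    def test_optimum_always_outranks_equal_non_optimum(self):
        assert score_marker(make_marker(60, True)) == \
            pytest.approx(score_marker(make_marker(60, False)) + 30.0)

    def test_penalty_reduces_quality_term_to_floor(self):
        assert score_marker(make_marker(60, True, penalty=5.0)) == \
            pytest.approx(score_marker(make_marker(60, True, penalty=0.0)) - 5.0)
        # quality term floors at 0 for very poor primers
        assert score_marker(make_marker(60, True, penalty=100.0)) == \
            pytest.approx(min(60, 200) / 200 * 50 + 30)


class TestCallMarkers:
    def cfg(self, **kw):
        return PipelineConfig(**kw)

    def test_single_copy_size_difference_yields_optimum_marker(self):
        pair = make_pair()
        table = call_markers([pair], [[make_hit(product=300)]],
                             [[make_hit(product=250)]], self.cfg())
        assert len(table) == 1
        m = table.markers[0]
        assert (m.source_product, m.target_product) == (300, 250)
        assert m.indel_size == 50 and m.size_class == "21~100"
        assert m.signed_diff == -50
        assert m.optimum and m.source_copies == m.target_copies == 1
        assert m.marker_id == "M000001"

    def test_equal_products_yield_no_marker(self):
        pair = make_pair()
        table = call_markers([pair], [[make_hit(product=250)]],
                             [[make_hit(product=250)]], self.cfg())
        assert len(table) == 0

    def test_multi_copy_marker_never_optimum(self):
        pair = make_pair()
        table = call_markers(
            [pair], [[make_hit(product=300)]],
            [[make_hit(product=240), make_hit(start=900, product=290)]],
            self.cfg())
        assert len(table) == 1
        m = table.markers[0]
        assert not m.optimum and m.target_copies == 2
        # best target hit: both 0 mismatches, smaller |delta| wins (290)
        assert m.target_product == 290 and m.indel_size == 10

    def test_lower_mismatch_hit_preferred_over_smaller_delta(self):
        pair = make_pair()
        table = call_markers(
            [pair], [[make_hit(product=300)]],
            [[make_hit(product=299, mismatches=2), make_hit(start=900, product=250)]],
            self.cfg())
        assert table.markers[0].target_product == 250

    def test_small_indel_not_optimum_at_default_threshold(self):
        pair = make_pair()
        table = call_markers([pair], [[make_hit(product=300)]],
                             [[make_hit(product=285)]], self.cfg())
        m = table.markers[0]
        assert m.indel_size == 15 and not m.optimum

    def test_boundary_indel_21_is_optimum_20_is_not(self):
        for size, expect in ((20, False), (21, True)):
            table = call_markers([make_pair()], [[make_hit(product=300)]],
                                 [[make_hit(product=300 - size)]], self.cfg())
            assert table.markers[0].optimum is expect

    def test_missing_hits_on_either_side_yield_no_marker(self):
        pairs = [make_pair("P1"), make_pair("P2")]
        table = call_markers(pairs, [[make_hit()], []],
                             [[], [make_hit()]], self.cfg())
        assert len(table) == 0

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError, match="one-to-one"):
            call_markers([make_pair()], [[]], [[], []], self.cfg())

    def test_duplicates_from_overlapping_windows_collapse(self):
        # same signed difference, overlapping source amplicons -> one marker,
        # higher score (larger quality term) survives
        p1 = make_pair("P1", fwd_start=10, rev_end=280, penalty=1.0)
        p2 = make_pair("P2", fwd_start=160, rev_end=430, penalty=3.0)
        table = call_markers(
            [p1, p2],
            [[make_hit(start=10, product=270)], [make_hit(start=160, product=270)]],
            [[make_hit(start=10, product=220)], [make_hit(start=160, product=220)]],
            self.cfg())
        assert len(table) == 1
        assert table.markers[0].pair.pair_id == "P1"

    def test_distinct_signed_differences_with_small_overlap_kept(self):
        p1 = make_pair("P1", fwd_start=10, rev_end=280)
        p2 = make_pair("P2", fwd_start=220, rev_end=490)
        table = call_markers(
            [p1, p2],
            [[make_hit(start=10, product=270)], [make_hit(start=220, product=270)]],
            [[make_hit(start=10, product=220)], [make_hit(start=220, product=300)]],
            self.cfg())
        assert len(table) == 2

    def test_majority_overlap_collapses_even_with_different_sizes(self):
        p1 = make_pair("P1", fwd_start=10, rev_end=280)
        p2 = make_pair("P2", fwd_start=30, rev_end=300)
        table = call_markers(
            [p1, p2],
            [[make_hit(start=10, product=270)], [make_hit(start=30, product=270)]],
            [[make_hit(start=10, product=220)], [make_hit(start=30, product=230)]],
            self.cfg())
        assert len(table) == 1

    def test_ranking_descends_by_score(self):
        p1 = make_pair("P1", fwd_start=0, rev_end=270)
        p2 = make_pair("P2", contig="c2", fwd_start=0, rev_end=270)
        table = call_markers(
            [p1, p2],
            [[make_hit(start=0, product=270)],
             [make_hit(contig="c2", start=0, product=270)]],
            [[make_hit(start=0, product=260)],
             [make_hit(contig="c2", start=0, product=180)]],
            self.cfg())
        scores = [m.score for m in table]
        assert scores == sorted(scores, reverse=True)
        assert [m.marker_id for m in table] == ["M000001", "M000002"]


class TestAnnotateReference:
    def _marker_table_and_pair(self, rng):
        from conftest import random_dna
        from ampindel import Window, design_primer_pairs, PrimerParams
        locus = random_dna(rng, 300)
        pairs = design_primer_pairs(Window("c1", 0, 300, locus), PrimerParams())
        assert pairs
        pair = pairs[0]
        table = call_markers(
            [pair], [[make_hit(start=pair.fwd_start, product=pair.designed_product)]],
            [[make_hit(start=pair.fwd_start, product=pair.designed_product - 40)]],
            PipelineConfig())
        return table, pair, locus

    def test_unique_reference_hit_sets_location(self, rng):
        table, pair, locus = self._marker_table_and_pair(rng)
        from conftest import random_dna
        ref = ContigSet([Contig("chr1", random_dna(rng, 400) + locus)])
        out = annotate_reference(table, ref, PipelineConfig())
        m = out.markers[0]
        assert m.ref_copies == 1
        assert m.ref_location == f"chr1:{400 + pair.fwd_start + 1}"
        assert m.optimum

    def test_duplicated_reference_locus_demotes_optimum(self, rng):
        table, pair, locus = self._marker_table_and_pair(rng)
        from conftest import random_dna
        ref = ContigSet([Contig("chr1", locus + random_dna(rng, 500) + locus)])
        out = annotate_reference(table, ref, PipelineConfig())
        m = out.markers[0]
        assert m.ref_copies == 2 and not m.optimum
        assert m.ref_location is None

    def test_no_reference_returns_table_unchanged(self):
        table = MarkerTable([make_marker()])
        assert annotate_reference(table, None, PipelineConfig()) is table


class TestMarkerTableOutput:
    def test_empty_table_writes_header_and_zero_summary(self, tmp_path):
        path = tmp_path / "markers.tsv"
        write_marker_table(MarkerTable(), path)
        df = read_marker_frame(path)
        assert len(df) == 0 and "marker_id" in df.columns
        summary = (tmp_path / "markers.summary.tsv").read_text()
        assert "total_indels\t0" in summary
        assert "mean_size_bp\t0.0" in summary

    def test_write_then_parse_reproduces_fields(self, tmp_path):
        markers = [make_marker(158, True, 1.5, start=100),
                   make_marker(15, False, 0.5, signed=-15, start=900)]
        table = MarkerTable(markers)
        path = tmp_path / "markers.tsv"
        write_marker_table(table, path)
        df = read_marker_frame(path)
        assert list(df["indel_size"]) == [158, 15]
        assert list(df["size_class"]) == [">100", "11~20"]
        assert list(df["optimum"]) == [1, 0]
        assert list(df["source_start"]) == [101, 901]  # 1-based in tables
        assert list(df["fwd_primer"]) == ["A" * 20] * 2
        assert df["score"][0] == pytest.approx(markers[0].score, abs=1e-3)

    def test_summary_counts_partition_the_table(self, tmp_path):
        sizes = [3, 14, 40, 150, 7, 22]
        table = MarkerTable([make_marker(s) for s in sizes])
        s = table.summary()
        assert sum(s["counts"].values()) == len(sizes) == s["total"]
        assert s["mean_indel_size"] == pytest.approx(sum(sizes) / len(sizes))
        write_summary(table, tmp_path / "s.tsv")
        text = (tmp_path / "s.tsv").read_text()
        assert f"mean_size_bp\t{sum(sizes) / len(sizes):.1f}" in text
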