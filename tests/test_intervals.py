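"""Interval arithmetic, genome binning and BED I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from footprint_bench.intervals import (
    BedParseError,
    GenomeBinning,
    GenomicInterval,
    IntervalSet,
    intersect,
    make_bins,
    merge,
    overlap_fraction,
    read_bed,
    read_chrom_sizes,
    write_bed,
    write_chrom_sizes,
)

from conftest import random_interval_set


class TestGenomicInterval:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)  # zero length
        assert GenomicInterval("chr1", 100, 200).length == 100

    def test_overlap_is_half_open(self):
        a = GenomicInterval("chr1", 100, 200)
        assert a.overlap_bp(GenomicInterval("chr1", 150, 250)) == 50
        assert a.overlap_bp(GenomicInterval("chr1", 200, 300)) == 0  # abutting
        assert a.overlap_bp(GenomicInterval("chr2", 100, 200)) == 0


class TestBedIO:
    def test_parse_minimal_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        s = read_bed(p)
        assert len(s) == 1 and s[0] == GenomicInterval("chr1", 100, 200)

    def test_output_sorted_across_chromosomes(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr2\t0\t10\nchr1\t5\t15\n")
        s = read_bed(p)
        assert [iv.chrom for iv in s] == ["chr1", "chr2"] and s.is_sorted

    def test_invalid_coordinates_name_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t10\nchr1\t200\t100\n")
        with pytest.raises(BedParseError, match=":2"):
            read_bed(p)
        p.write_text("chr1\tx\t10\n")
        with pytest.raises(BedParseError, match=":1"):
            read_bed(p)

    def test_track_and_comment_lines_skipped_and_empty_ok(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("track name=x\n# c\nbrowser position\n\nchr1\t0\t5\n")
        assert len(read_bed(p)) == 1
        p.write_text("")
        assert len(read_bed(p)) == 0

    def test_empty_set_writes_empty_file(self, tmp_path):
        p = tmp_path / "o.bed"
        write_bed(IntervalSet([]), p)
        assert p.read_text() == ""

    def test_scored_set_written_as_bed5(self, tmp_path):
        p = tmp_path / "o.bed"
        write_bed(IntervalSet([GenomicInterval("chr1", 0, 9, score=2.5)]), p)
        assert p.read_text() == "chr1\t0\t9\t.\t2.5\n"

    @pytest.mark.parametrize("with_labels", [False, True])
    def test_round_trip_is_lossless(self, tmp_path, with_labels):
        rng = np.random.default_rng(11)
        s = random_interval_set(rng, 100, with_scores=True, with_labels=with_labels)
        p = tmp_path / "rt.bed"
        write_bed(s.sorted(), p)
        back = read_bed(p, has_score=True)
        assert list(back) == list(s.sorted())

    def test_chrom_sizes_round_trip(self, tmp_path):
        sizes = {"chr1": 1000, "chr2": 2500}
        p = tmp_path / "g.sizes"
        write_chrom_sizes(sizes, p)
        assert read_chrom_sizes(p) == sizes


class TestIntersect:
    def test_overlap_arithmetic(self):
        a = IntervalSet([GenomicInterval("chr1", 100, 200)])
        b = IntervalSet([GenomicInterval("chr1", 150, 250)])
        assert intersect(a, b) == [(a[0], b[0], 50)]

    def test_abutting_is_not_overlap(self):
        a = IntervalSet([GenomicInterval("chr1", 100, 200)])
        b = IntervalSet([GenomicInterval("chr1", 200, 300)])
        assert intersect(a, b) == []

    def test_matches_all_pairs_scan_and_symmetry(self):
        rng = np.random.default_rng(7)
        a = random_interval_set(rng, 50, max_pos=2000)
        b = random_interval_set(rng, 50, max_pos=2000)
        brute = {
            (ia.sort_key(), ib.sort_key(), ia.overlap_bp(ib))
            for ia in a
            for ib in b
            if ia.overlap_bp(ib) > 0
        }
        fast = {(ia.sort_key(), ib.sort_key(), ov) for ia, ib, ov in intersect(a, b)}
        assert fast == brute
        transposed = {(ib.sort_key(), ia.sort_key(), ov) for ia, ib, ov in intersect(b, a)}
        assert transposed == fast


class TestMerge:
    def test_gap_at_min_dist_fuses(self):
        s = IntervalSet([GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 150, 300)])
        merged = merge(s, min_dist=50)
        assert [(iv.start, iv.end) for iv in merged] == [(0, 300)]

    def test_min_dist_zero_keeps_gapped_intervals(self):
        s = IntervalSet([GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 150, 300)])
        assert [(iv.start, iv.end) for iv in merge(s, 0)] == [(0, 100), (150, 300)]
        # but abutting intervals fuse
        t = IntervalSet([GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 100, 150)])
        assert [(iv.start, iv.end) for iv in merge(t, 0)] == [(0, 150)]

    def test_single_interval_identity(self):
        s = IntervalSet([GenomicInterval("chr1", 5, 9)])
        assert list(merge(s, 1000)) == [GenomicInterval("chr1", 5, 9)]

    @pytest.mark.parametrize("min_dist", [0, 10, 200])
    def test_idempotent_and_non_overlapping(self, min_dist):
        rng = np.random.default_rng(min_dist + 3)
        s = random_interval_set(rng, 80, max_pos=3000)
        once = merge(s, min_dist)
        assert merge(once, min_dist) == once
        for prev, nxt in zip(list(once), list(once)[1:]):
            if prev.chrom == nxt.chrom:
                assert nxt.start - prev.end > min_dist


intervals_st = st.lists(
    st.tuples(
        st.sampled_from(["chr1", "chr2"]),
        st.integers(0, 1000),
        st.integers(1, 100),
    ).map(lambda t: GenomicInterval(t[0], t[1], t[1] + t[2])),
    min_size=0,
    max_size=30,
)


class TestMergeProperties:
    @settings(max_examples=60, derandomize=True)
    @given(ivs=intervals_st, min_dist=st.integers(0, 120))
    def test_merge_idempotent_covers_inputs(self, ivs, min_dist):
        merged = merge(IntervalSet(ivs), min_dist)
        assert merge(merged, min_dist) == merged
        for iv in ivs:
            assert any(
                m.chrom == iv.chrom and m.start <= iv.start and iv.end <= m.end
                for m in merged
            )

    @settings(max_examples=60, derandomize=True)
    @given(a=intervals_st, b=intervals_st)
    def test_intersect_pairs_symmetric(self, a, b):
        fwd = {(x.sort_key(), y.sort_key(), ov) for x, y, ov in intersect(IntervalSet(a), IntervalSet(b))}
        rev = {(y.sort_key(), x.sort_key(), ov) for x, y, ov in intersect(IntervalSet(b), IntervalSet(a))}
        assert fwd == rev


class TestOverlapFraction:
    def test_is_relative_to_query(self):
        a = GenomicInterval("chr1", 100, 200)
        b = GenomicInterval("chr1", 150, 250)
        assert overlap_fraction(a, b) == 0.5
        assert overlap_fraction(a, a) == 1.0
        assert overlap_fraction(a, GenomicInterval("chr2", 100, 200)) == 0.0

    def test_cross_fraction_identity(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            s = random_interval_set(rng, 2, chroms=("chr1",), max_pos=500, max_len=100)
            a, b = s[0], s[1]
            ov = a.overlap_bp(b)
            assert overlap_fraction(a, b) * a.length == pytest.approx(ov)
            assert overlap_fraction(b, a) * b.length == pytest.approx(ov)

    def test_symmetric_mode_uses_longer_interval(self):
        a = GenomicInterval("chr1", 0, 10)
        b = GenomicInterval("chr1", 0, 40)
        assert overlap_fraction(a, b, mode="symmetric") == 0.25


class TestGenomeBinning:
    def test_last_bin_shortened(self):
        bins = make_bins(GenomeBinning({"chr1": 25_000}, 10_000))
        assert [(b.start, b.end) for b in bins] == [(0, 10_000), (10_000, 20_000), (20_000, 25_000)]

    def test_exact_fit_single_bin(self):
        assert len(make_bins(GenomeBinning({"chr1": 10_000}, 10_000))) == 1

    def test_bins_cover_genome_exactly_once(self):
        binning = GenomeBinning({"chr1": 10_000, "chr2": 25_000}, 10_000)
        bins = make_bins(binning)
        assert len(bins) == 4 == binning.total_bins
        assert sum(b.length for b in bins) == 35_000

    def test_bin_index_and_errors(self):
        binning = GenomeBinning({"chr1": 25_000, "chr2": 10_000}, 10_000)
        assert binning.bin_index("chr1", 0) == 0
        assert binning.bin_index("chr1", 10_000) == 1  # half-open boundary
        assert binning.bin_index("chr2", 5) == 3
        with pytest.raises(KeyError):
            binning.bin_index("chrX", 0)
        with pytest.raises(ValueError):
            GenomeBinning({"chr1": 100}, 0)
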