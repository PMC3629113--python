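"""Interval algebra against per-base brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snpdesert.intervals import (
    GenomicInterval,
    filter_min_length,
    inter_snp_gaps,
    intersect_any,
    merge,
    subtract,
)
from snpdesert.ucsc_io import FeatureInterval, SnpRecord

from conftest import array_to_intervals, chroms_of, cover_array

MAX_COORD = 5000


def ivs(chrom, *pairs):
    return [GenomicInterval(chrom, s, e) for s, e in pairs]


interval_st = st.builds(
    lambda chrom, start, length: GenomicInterval(chrom, start, start + length),
    st.sampled_from(["chrA", "chrB"]),
    st.integers(0, MAX_COORD - 300),
    st.integers(1, 300),
)
interval_sets = st.lists(interval_st, max_size=50)


class TestMerge:
    def test_overlapping_pair_merges(self):
        assert merge(ivs("chr1", (0, 10), (5, 20))) == ivs("chr1", (0, 20))

    def test_distinct_chromosomes_untouched(self):
        got = merge([GenomicInterval("chr2", 0, 10), GenomicInterval("chr1", 0, 10)])
        assert got == [GenomicInterval("chr1", 0, 10), GenomicInterval("chr2", 0, 10)]

    def test_abutting_intervals_merge(self):
        assert merge(ivs("chr1", (0, 5), (5, 9))) == ivs("chr1", (0, 9))

    @settings(derandomize=True, max_examples=200)
    @given(interval_sets)
    def test_matches_membership_oracle(self, intervals):
        got = merge(intervals)
        for chrom in chroms_of(intervals):
            want = array_to_intervals(cover_array(intervals, MAX_COORD, chrom), chrom)
            assert [iv for iv in got if iv.chrom == chrom] == want

    @settings(derandomize=True, max_examples=100)
    @given(interval_sets)
    def test_conservation_of_covered_length(self, intervals):
        total = sum(iv.length for iv in merge(intervals))
        by_base = sum(
            int(cover_array(intervals, MAX_COORD, chrom).sum())
            for chrom in chroms_of(intervals)
        )
        assert total == by_base


class TestSubtract:
    def test_cnv_splits_region_into_published_pair(self):
        # The chrX desert minus its internal CNV leaves the two flanking
        # variant-free regions.
        got = subtract(
            ivs("chrX", (52098738, 52395914)), ivs("chrX", (52231295, 52267361))
        )
        assert got == ivs("chrX", (52098738, 52231295), (52267361, 52395914))
        assert [iv.length for iv in got] == [132557, 128553]

    def test_empty_subtrahend_is_identity(self):
        a = ivs("chr1", (5, 50), (100, 130))
        assert subtract(a, []) == a

    @settings(derandomize=True, max_examples=200)
    @given(interval_sets, interval_sets)
    def test_matches_membership_oracle(self, minuend, subtrahend):
        got = subtract(minuend, subtrahend)
        for chrom in sorted(set(chroms_of(minuend)) | set(chroms_of(subtrahend))):
            want_mask = cover_array(minuend, MAX_COORD, chrom) & ~cover_array(
                subtrahend, MAX_COORD, chrom
            )
            assert [iv for iv in got if iv.chrom == chrom] == array_to_intervals(
                want_mask, chrom
            )


class TestInterSnpGaps:
    def test_flanking_snps_define_published_desert(self):
        snps = [
            SnpRecord("chr1", 145883117, 145883118, "rsL"),
            SnpRecord("chr1", 145989503, 145989504, "rsR"),
        ]
        assert inter_snp_gaps(snps) == ivs("chr1", (145883118, 145989503))
        assert inter_snp_gaps(snps)[0].length == 106385

    def test_abutting_snps_leave_no_gap(self):
        snps = [SnpRecord("chr1", 10, 11, "a"), SnpRecord("chr1", 11, 12, "b")]
        assert inter_snp_gaps(snps) == []

    def test_zero_length_insertion_splits_gap(self):
        snps = [
            SnpRecord("chr1", 0, 1, "a"),
            SnpRecord("chr1", 50, 50, "ins"),
            SnpRecord("chr1", 100, 101, "b"),
        ]
        assert inter_snp_gaps(snps) == ivs("chr1", (1, 50), (50, 100))

    def test_single_snp_chromosome_yields_nothing(self):
        assert inter_snp_gaps([SnpRecord("chr9", 5, 6, "only")]) == []

    def test_chrom_whitelist_filters(self):
        snps = [
            SnpRecord("chr1", 0, 1, "a"), SnpRecord("chr1", 10, 11, "b"),
            SnpRecord("chr2", 0, 1, "c"), SnpRecord("chr2", 10, 11, "d"),
        ]
        got = inter_snp_gaps(snps, chrom_whitelist={"chr2"})
        assert got == ivs("chr2", (1, 10))

    def test_random_instance_matches_complement_oracle(self):
        rng = np.random.default_rng(7)
        size = 10_000
        positions = np.unique(rng.integers(0, size, 200))
        snps = [SnpRecord("chrT", int(p), int(p) + 1, f"rs{p}") for p in positions]
        got = inter_snp_gaps(snps)
        mask = np.ones(size, dtype=bool)  # True = not covered by a SNP
        for s in snps:
            mask[s.start : s.end] = False
        mask[: positions[0] + 1] = False  # leading segment excluded
        mask[positions[-1] :] = False  # trailing segment excluded
        assert got == array_to_intervals(mask, "chrT")

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.integers(0, 2000), min_size=2, max_size=80, unique=True))
    def test_gaps_never_overlap_snp_spans(self, positions):
        snps = [SnpRecord("chrP", p, p + 1, f"rs{p}") for p in sorted(positions)]
        for gap in inter_snp_gaps(snps):
            assert not intersect_any(
                gap, [FeatureInterval(s.chrom, s.start, s.end, "extra_snp")
                      for s in snps]
            )


class TestFilterMinLength:
    def test_keeps_length_equal_to_threshold(self):
        kept = filter_min_length(ivs("chrY", (6577215, 6677618)), 100_000)
        assert kept and kept[0].length == 100403

    def test_drops_one_below_threshold(self):
        assert filter_min_length(ivs("chr1", (0, 99_999)), 100_000) == []

    def test_min_len_one_is_identity(self):
        a = ivs("chr1", (0, 1), (5, 9))
        assert filter_min_length(a, 1) == a

    def test_nonpositive_min_len_rejected(self):
        with pytest.raises(ValueError):
            filter_min_length([], 0)

    @settings(derandomize=True, max_examples=50)
    @given(interval_sets, st.integers(1, 400), st.integers(0, 200))
    def test_idempotent_and_monotone(self, intervals, min_len, extra):
        once = filter_min_length(intervals, min_len)
        assert filter_min_length(once, min_len) == once
        stricter = filter_min_length(intervals, min_len + extra)
        assert set(stricter) <= set(once)


class TestIntersectAny:
    def test_constructed_overlap_is_found(self):
        region = GenomicInterval("chrX", 52290698, 52395914)
        segdup = FeatureInterval("chrX", 52300000, 52400000, "segdup", "eichler")
        assert intersect_any(region, [segdup]) == [segdup]

    def test_other_chromosomes_do_not_hit(self):
        region = GenomicInterval("chr1", 0, 1000)
        features = [FeatureInterval("chr2", 0, 1000, "cnv")]
        assert intersect_any(region, features) == []

    @settings(derandomize=True, max_examples=100)
    @given(interval_st, interval_sets)
    def test_matches_all_pairs_oracle(self, region, intervals):
        features = [
            FeatureInterval(iv.chrom, iv.start, iv.end, "cnv") for iv in intervals
        ]
        want = [
            f
            for f in features
            if f.chrom == region.chrom
            and max(f.start, region.start) < min(f.end, region.end)
        ]
        assert intersect_any(region, features) == want


class TestGenomicInterval:
    @pytest.mark.parametrize("start,end", [(10, 10), (10, 5), (-1, 4)])
    def test_degenerate_spans_rejected(self, start, end):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", start, end)
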