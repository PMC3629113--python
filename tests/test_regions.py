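"""Region-calling stages: CSFR, CVFR, residual filtering, reports."""

import numpy as np
import pytest

from snpdesert.intervals import GenomicInterval, intersect_any
from snpdesert.regions import (
    RegionCall,
    call_csfrs,
    call_cvfrs,
    probe_coverage_report,
    segdup_overlap_report,
    subtract_point_variants,
    variant_hit_report,
)
from snpdesert.ucsc_io import FeatureInterval, ProbeRecord, SnpRecord


def region(chrom, start, end, stage="CSFR"):
    return RegionCall(GenomicInterval(chrom, start, end), stage)


def snp(chrom, start, end=None, rsid="rs"):
    return SnpRecord(chrom, start, start + 1 if end is None else end, rsid)


def feat(chrom, start, end, cls, label=""):
    return FeatureInterval(chrom, start, end, cls, label)


class TestCallCsfrs:
    def test_flanking_snps_give_published_chr1_region(self):
        snps = [snp("chr1", 145883117), snp("chr1", 145989503)]
        (call,) = call_csfrs(snps, [], min_len=100_000)
        assert (call.start, call.end, call.length) == (145883118, 145989503, 106385)
        assert call.stage == "CSFR" and call.id == "CSFR_chr1_145883118"

    def test_assembly_gap_covering_candidate_removes_it(self):
        snps = [snp("chr1", 145883117), snp("chr1", 145989503)]
        gap = feat("chr1", 145800000, 146000000, "assembly_gap")
        assert call_csfrs(snps, [gap], min_len=100_000) == []

    def test_empty_snps_empty_result(self):
        assert call_csfrs([], [], min_len=100_000) == []

    def test_planted_desert_recovered_from_poisson_background(self):
        rng = np.random.default_rng(11)
        length, desert = 2_000_000, GenomicInterval("chrS", 900_000, 1_050_000)
        positions = np.unique(rng.integers(0, length, rng.poisson(length * 1e-3)))
        positions = positions[(positions < desert.start) | (positions >= desert.end)]
        snps = [snp("chrS", int(p)) for p in positions]
        calls = call_csfrs(snps, [], min_len=100_000)
        assert len(calls) == 1
        got = calls[0].interval
        assert got.start <= desert.start and got.end >= desert.end
        # no SNP base inside any call (emptiness invariant)
        feats = [feat("chrS", s.start, s.end, "extra_snp") for s in snps]
        assert intersect_any(got, feats) == []

    def test_no_region_contains_gap_base(self):
        snps = [snp("chrG", 0), snp("chrG", 400_000)]
        gap = feat("chrG", 150_000, 160_000, "assembly_gap")
        calls = call_csfrs(snps, [gap], min_len=100_000)
        assert [(c.start, c.end) for c in calls] == [(1, 150_000), (160_000, 400_000)]


class TestCallCvfrs:
    def test_chrx_cnv_split_reproduces_published_pair(self):
        csfr = region("chrX", 52098738, 52395914)
        cnv = feat("chrX", 52231295, 52267361, "cnv", "dgv")
        got = call_cvfrs([csfr], [cnv], min_len=100_000)
        assert [(c.start, c.end, c.length) for c in got] == [
            (52098738, 52231295, 132557),
            (52267361, 52395914, 128553),
        ]
        assert all(c.stage == "CVFR" for c in got)
        assert all("cnv" in c.subtracted_classes for c in got)

    def test_covering_cnv_removes_region(self):
        csfr = region("chr9", 39379250, 39551456)
        cnv = feat("chr9", 39000000, 40000000, "cnv")
        assert call_cvfrs([csfr], [cnv], min_len=100_000) == []

    def test_one_bp_cnv_splits_contiguous_span(self):
        csfr = region("chrY", 4834281, 5205540)
        cnv = feat("chrY", 4935713, 4935714, "cnv")
        got = call_cvfrs([csfr], [cnv], min_len=100_000)
        assert [(c.start, c.end, c.length) for c in got] == [
            (4834281, 4935713, 101432),
            (4935714, 5205540, 269826),
        ]

    def test_rejects_non_csfr_input(self):
        with pytest.raises(ValueError):
            call_cvfrs([region("chr1", 0, 200_000, stage="CVFR")], [], 100_000)

    def test_nesting_invariant(self):
        csfrs = [region("chr1", 0, 500_000), region("chr2", 0, 300_000)]
        cnvs = [feat("chr1", 100_000, 150_000, "cnv"),
                feat("chr2", 0, 10_000, "cnv")]
        for cv in call_cvfrs(csfrs, cnvs, min_len=100_000):
            assert any(
                cv.chrom == cs.chrom and cs.start <= cv.start and cv.end <= cs.end
                for cs in csfrs
            )


class TestSubtractPointVariants:
    def test_published_final_residual(self):
        # Two newly catalogued SNPs truncate the last surviving region to
        # chrX:52,290,698-52,395,914 (105,216 bp).
        reg = region("chrX", 52267361, 52395914, stage="CVFR")
        variants = [feat("chrX", 52290697, 52290698, "extra_snp", "updated_dbsnp")]
        got = subtract_point_variants([reg], variants, min_len=100_000)
        assert [(c.start, c.end, c.length) for c in got] == [
            (52290698, 52395914, 105216)
        ]
        assert got[0].stage == "residual"

    def test_no_variants_keeps_interval_changes_stage(self):
        reg = region("chr1", 0, 200_000, stage="CVFR")
        (got,) = subtract_point_variants([reg], [], min_len=100_000)
        assert got.interval == reg.interval and got.stage == "residual"

    def test_tiling_variants_empty_result(self):
        reg = region("chr1", 0, 150_000, stage="CVFR")
        tiles = [feat("chr1", i, i + 1000, "personal_variant")
                 for i in range(0, 150_000, 1000)]
        assert subtract_point_variants([reg], tiles, min_len=100_000) == []


class TestVariantHitReport:
    def test_zero_hit_list_is_exactly_unhit_region(self):
        regions = [region("chr1", 0, 200_000), region("chr2", 0, 200_000),
                   region("chr3", 0, 200_000)]
        variants = {"pgA": [feat("chr1", 5, 6, "personal_variant", "pgA"),
                            feat("chr2", 5, 6, "personal_variant", "pgA")]}
        report = variant_hit_report(regions, variants)
        assert report.zero_hit_ids == [regions[2].id]
        assert report.total_hits(regions[0].id) == 1

    def test_empty_sets_all_zero_hit(self):
        regions = [region("chr1", 0, 200_000)]
        report = variant_hit_report(regions, {"pgA": []})
        assert report.zero_hit_ids == [regions[0].id]

    def test_counts_match_all_pairs_oracle(self):
        rng = np.random.default_rng(3)
        regions = [region("chrR", int(s), int(s) + 500)
                   for s in rng.integers(0, 10_000, 10) * 1]
        regions = sorted({r.id: r for r in regions}.values(),
                         key=lambda r: r.start)
        variants = [feat("chrR", int(p), int(p) + 10, "personal_variant", "pg")
                    for p in rng.integers(0, 10_500, 60)]
        report = variant_hit_report(regions, {"pg": variants})
        for r in regions:
            want = sum(1 for v in variants
                       if v.start < r.end and r.start < v.end)
            assert report.hits[r.id]["pg"] == want


class TestProbeCoverage:
    def test_counts_and_polymorphism(self):
        reg = region("chr1", 1000, 2000)
        probes = [
            ProbeRecord("p1", "chr1", 1000, {"CEU": 0.0}),
            ProbeRecord("p2", "chr1", 1500, {"CEU": 0.1}),
            ProbeRecord("p3", "chr1", 1999, {"CEU": 0.0, "YRI": 0.2}),
            ProbeRecord("p4", "chr1", 1998, {}),
            ProbeRecord("p5", "chr1", 1001, {"JPT": 0.0}),
            ProbeRecord("p6", "chr1", 2500, {"CEU": 0.4}),  # outside
        ]
        report = probe_coverage_report([reg], probes)
        assert report.probe_count == 5
        assert report.polymorphic_count == 2
        assert report.polymorphic_probe_ids == ["p2", "p3"]

    def test_probe_at_region_end_is_outside(self):
        reg = region("chr1", 1000, 2000)
        report = probe_coverage_report(
            [reg], [ProbeRecord("edge", "chr1", 2000, {"CEU": 0.3})]
        )
        assert report.probe_count == 0

    def test_membership_matches_oracle(self):
        rng = np.random.default_rng(5)
        regions = [region("chrQ", 100, 600), region("chrQ", 900, 1400)]
        probes = [ProbeRecord(f"p{i}", "chrQ", int(pos), {"CEU": float(m)})
                  for i, (pos, m) in enumerate(
                      zip(rng.integers(0, 1500, 50), rng.uniform(0, 0.5, 50)))]
        report = probe_coverage_report(regions, probes)
        want = sum(
            1 for p in probes
            if any(r.start <= p.position < r.end for r in regions)
        )
        assert report.probe_count == want


class TestSegdupOverlap:
    def test_final_region_flagged(self):
        reg = region("chrX", 52290698, 52395914, stage="residual")
        segdup = feat("chrX", 52300000, 52400000, "segdup", "pairs")
        report = segdup_overlap_report([reg], [segdup])
        assert report.is_flagged(reg.id)
        assert report.flagged[reg.id] == [segdup]

    def test_no_segdups_unflagged(self):
        reg = region("chr1", 0, 200_000)
        assert not segdup_overlap_report([reg], []).is_flagged(reg.id)
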