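"""Detection of common-variant-free regions.

Stages, in fixed order:

1. **CSFR** (common SNP-free region): gaps between adjacent common SNPs,
   minus assembly gaps, kept if still >= ``min_len`` (default 100 kb).
2. **CVFR** (common variant-free region): CSFR residuals after subtracting
   CNV intervals, kept if still >= ``min_len``.
3. **residual**: CVFR residuals after subtracting further point variants
   (personal-genome calls, newly catalogued SNPs), kept if >= ``min_len``.

Each stage re-applies the length threshold, so every emitted region is a
subset of a region from the previous stage.  Alongside the calls, this
module builds the verification reports: per-source variant hits, array-probe
coverage with population polymorphism, and segmental-duplication overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .intervals import (
    GenomicInterval,
    filter_min_length,
    inter_snp_gaps,
    intersect_any,
    subtract,
)
from .ucsc_io import FeatureInterval, ProbeRecord, SnpRecord

STAGES = ("CSFR", "CVFR", "residual")


@dataclass(frozen=True, order=True)
class RegionCall:
    """A called variant-free region with stage label and subtraction provenance."""

    interval: GenomicInterval
    stage: str
    subtracted_classes: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def id(self) -> str:
        return f"{self.stage}_{self.interval.chrom}_{self.interval.start}"

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class VariantHitReport:
    """Per-region variant hit counts, per source, plus the zero-hit regions."""

    hits: dict  # region id -> {source_label: count}
    zero_hit_ids: list

    def total_hits(self, region_id: str) -> int:
        return sum(self.hits.get(region_id, {}).values())


@dataclass
class ProbeCoverageReport:
    probe_count: int
    polymorphic_count: int
    polymorphic_probe_ids: list
    per_region: dict  # region id -> probe count

    def __post_init__(self) -> None:
        if self.polymorphic_count > self.probe_count:
            raise ValueError("polymorphic count exceeds probe count")


def _subtract_stage(
    regions: Sequence[RegionCall],
    features: Iterable[FeatureInterval],
    min_len: int,
    new_stage: str,
    new_class: str,
) -> list[RegionCall]:
    feats = list(features)
    out: list[RegionCall] = []
    for call in sorted(regions, key=lambda c: c.interval):
        residuals = subtract([call.interval], feats)
        classes = call.subtracted_classes | {new_class}
        for iv in filter_min_length(residuals, min_len):
            out.append(RegionCall(iv, new_stage, classes))
    out.sort(key=lambda c: c.interval)
    return out


def call_csfrs(
    snps: Sequence[SnpRecord],
    gaps: Iterable[FeatureInterval],
    min_len: int = 100_000,
) -> list[RegionCall]:
    """Call common SNP-free regions.

    ``filter_min_length(subtract(inter_snp_gaps(snps), gaps), min_len)``,
    stamped with stage ``CSFR``.  No returned region contains a SNP base or
    an assembly-gap base.
    """
    candidate = inter_snp_gaps(sorted(snps, key=lambda s: (s.chrom, s.start, s.end)))
    # Subtract per candidate, not over the merged set: two candidate gaps may
    # abut (split only by a zero-length insertion SNP) and must stay distinct.
    gap_list = list(gaps)
    clean: list[GenomicInterval] = []
    for iv in candidate:
        clean.extend(subtract([iv], gap_list))
    clean.sort()
    return [
        RegionCall(iv, "CSFR", frozenset({"assembly_gap"}))
        for iv in filter_min_length(clean, min_len)
    ]


def call_cvfrs(
    csfrs: Sequence[RegionCall],
    cnvs: Iterable[FeatureInterval],
    min_len: int = 100_000,
) -> list[RegionCall]:
    """Subtract CNVs from CSFRs; residuals still >= min_len become CVFRs."""
    for call in csfrs:
        if call.stage != "CSFR":
            raise ValueError(f"expected CSFR input, got stage {call.stage}")
    return _subtract_stage(csfrs, cnvs, min_len, "CVFR", "cnv")


def subtract_point_variants(
    regions: Sequence[RegionCall],
    variants: Iterable[FeatureInterval],
    min_len: int = 100_000,
) -> list[RegionCall]:
    """Subtract point/short variants (personal-genome calls, extra SNPs)."""
    variants = list(variants)
    classes = {v.feature_class for v in variants} or {"extra_snp"}
    out: list[RegionCall] = []
    for call in sorted(regions, key=lambda c: c.interval):
        residuals = subtract([call.interval], variants)
        merged_classes = call.subtracted_classes | classes
        for iv in filter_min_length(residuals, min_len):
            out.append(RegionCall(iv, "residual", merged_classes))
    out.sort(key=lambda c: c.interval)
    return out


def variant_hit_report(
    regions: Sequence[RegionCall],
    variant_sets: Mapping[str, Sequence[FeatureInterval]],
) -> VariantHitReport:
    """Count >= 1 bp overlaps of each region with each named variant set."""
    hits: dict = {}
    zero: list = []
    for call in regions:
        per_source = {}
        for label, variants in variant_sets.items():
            per_source[label] = len(intersect_any(call.interval, variants))
        hits[call.id] = per_source
        if sum(per_source.values()) == 0:
            zero.append(call.id)
    return VariantHitReport(hits=hits, zero_hit_ids=zero)


def probe_coverage_report(
    regions: Sequence[RegionCall],
    probes: Sequence[ProbeRecord],
) -> ProbeCoverageReport:
    """Array probes whose base lies inside a region; polymorphic iff any
    population MAF is strictly positive.  Half-open: a probe exactly at a
    region end is outside."""
    per_region = {call.id: 0 for call in regions}
    inside: list[ProbeRecord] = []
    for probe in probes:
        for call in regions:
            if (
                probe.chrom == call.chrom
                and call.start <= probe.position < call.end
            ):
                per_region[call.id] += 1
                inside.append(probe)
                break
    polymorphic = sorted(
        {p.probe_id for p in inside if any(m > 0 for m in p.pop_mafs.values())}
    )
    return ProbeCoverageReport(
        probe_count=len(inside),
        polymorphic_count=len(polymorphic),
        polymorphic_probe_ids=polymorphic,
        per_region=per_region,
    )


@dataclass
class SegdupOverlapReport:
    flagged: dict  # region id -> list of overlapping segdup FeatureIntervals

    def is_flagged(self, region_id: str) -> bool:
        return bool(self.flagged.get(region_id))


def segdup_overlap_report(
    regions: Sequence[RegionCall],
    segdups: Sequence[FeatureInterval],
) -> SegdupOverlapReport:
    """Flag regions sharing >= 1 bp with any segmental duplication."""
    return SegdupOverlapReport(
        flagged={
            call.id: intersect_any(call.interval, segdups) for call in regions
        }
    )
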