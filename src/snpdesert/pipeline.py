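"""One-shot orchestration of the full variant-free-region analysis.

``run_pipeline`` wires the stages in their fixed order — common-SNP gap
extraction, assembly-gap subtraction, length filter, CNV subtraction,
length filter, point-variant subtraction, length filter — then runs the
optional verification layers (gene annotation, isochore classification,
array-probe coverage, segdup overlap, per-source variant hits) for which
inputs were provided, writes BED/TSV artifacts, and returns a
:class:`SummaryReport` whose totals are consistent with the written files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Optional, Sequence, Union

from . import genes as genes_mod
from . import isochores as iso_mod
from . import regions as regions_mod
from . import ucsc_io

logger = logging.getLogger("snpdesert")


@dataclass
class PipelineConfig:
    snp_path: Union[str, Path]
    gap_path: Optional[Union[str, Path]] = None
    cnv_path: Optional[Union[str, Path]] = None
    refgene_path: Optional[Union[str, Path]] = None
    personal_variant_paths: Sequence[Union[str, Path]] = ()
    extra_snp_path: Optional[Union[str, Path]] = None
    segdup_path: Optional[Union[str, Path]] = None
    probe_path: Optional[Union[str, Path]] = None
    fasta_path: Optional[Union[str, Path]] = None
    min_len: int = 100_000
    maf_min: float = 0.01
    flank_len: int = 100_000
    threshold_pp: float = 2.0
    border_rule: str = "both"
    outdir: Optional[Union[str, Path]] = None

    def __post_init__(self) -> None:
        if self.min_len <= 0 or self.flank_len <= 0:
            raise ValueError("min_len and flank_len must be positive")
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError(f"maf_min out of [0, 0.5]: {self.maf_min}")
        if not Path(self.snp_path).exists():
            raise FileNotFoundError(f"required SNP table missing: {self.snp_path}")
        for label, path in [
            ("gap", self.gap_path), ("cnv", self.cnv_path),
            ("refgene", self.refgene_path), ("extra_snp", self.extra_snp_path),
            ("segdup", self.segdup_path), ("probe", self.probe_path),
            ("fasta", self.fasta_path),
        ]:
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{label} input missing: {path}")


@dataclass
class SummaryReport:
    stage_counts: dict = field(default_factory=dict)  # stage -> count
    per_chrom: dict = field(default_factory=dict)  # stage -> {chrom: count}
    gene_bearing_regions: Optional[int] = None
    unique_genes: Optional[int] = None
    label_counts: Optional[dict] = None
    zero_hit_regions: Optional[int] = None
    probe_count: Optional[int] = None
    polymorphic_probe_count: Optional[int] = None
    segdup_flagged: Optional[int] = None

    def flat(self) -> dict:
        out = {}
        for stage, count in sorted(self.stage_counts.items()):
            out[f"count.{stage}"] = count
            for chrom, n in sorted(self.per_chrom.get(stage, {}).items()):
                out[f"count.{stage}.{chrom}"] = n
        if self.gene_bearing_regions is not None:
            out["genes.regions_with_genes"] = self.gene_bearing_regions
            out["genes.unique_symbols"] = self.unique_genes
        if self.label_counts is not None:
            for label, n in sorted(self.label_counts.items()):
                out[f"isochore.{label}"] = n
        if self.zero_hit_regions is not None:
            out["variants.zero_hit_regions"] = self.zero_hit_regions
        if self.probe_count is not None:
            out["probes.in_regions"] = self.probe_count
            out["probes.polymorphic"] = self.polymorphic_probe_count
        if self.segdup_flagged is not None:
            out["segdup.flagged_regions"] = self.segdup_flagged
        return out


def _per_chrom(calls) -> dict:
    counts: dict = {}
    for call in calls:
        counts[call.chrom] = counts.get(call.chrom, 0) + 1
    return counts


def run_pipeline(config: PipelineConfig):
    """Execute all configured stages.

    Returns ``(report, artifacts)`` where ``artifacts`` maps stage names to
    in-memory results (``csfrs``, ``cvfrs``, ``residuals``, ``annotations``,
    ``isochore_calls``, ...).  When ``config.outdir`` is set, BED files per
    stage, the annotation/isochore TSVs and ``report.txt`` are written there.
    """
    snps = ucsc_io.read_common_snps(config.snp_path, maf_min=config.maf_min)
    gaps = (
        ucsc_io.read_feature_table(config.gap_path, "assembly_gap")
        if config.gap_path
        else []
    )
    logger.info("parsed %d common SNPs, %d assembly gaps", len(snps), len(gaps))

    csfrs = regions_mod.call_csfrs(snps, gaps, min_len=config.min_len)
    report = SummaryReport()
    report.stage_counts["CSFR"] = len(csfrs)
    report.per_chrom["CSFR"] = _per_chrom(csfrs)
    artifacts: dict = {"csfrs": csfrs}

    final_regions = csfrs
    if config.cnv_path is not None:
        cnvs = ucsc_io.read_feature_table(config.cnv_path, "cnv")
        cvfrs = regions_mod.call_cvfrs(csfrs, cnvs, min_len=config.min_len)
        report.stage_counts["CVFR"] = len(cvfrs)
        report.per_chrom["CVFR"] = _per_chrom(cvfrs)
        artifacts["cvfrs"] = cvfrs
        final_regions = cvfrs

    variant_sets: dict = {}
    for path in config.personal_variant_paths:
        label = Path(path).name
        variant_sets[label] = ucsc_io.read_feature_table(path, "personal_variant")
    if config.extra_snp_path is not None:
        variant_sets[Path(config.extra_snp_path).name] = ucsc_io.read_feature_table(
            config.extra_snp_path, "extra_snp"
        )
    if variant_sets:
        hit_report = regions_mod.variant_hit_report(final_regions, variant_sets)
        report.zero_hit_regions = len(hit_report.zero_hit_ids)
        artifacts["variant_hits"] = hit_report
        all_variants = [v for vs in variant_sets.values() for v in vs]
        residuals = regions_mod.subtract_point_variants(
            final_regions, all_variants, min_len=config.min_len
        )
        report.stage_counts["residual"] = len(residuals)
        report.per_chrom["residual"] = _per_chrom(residuals)
        artifacts["residuals"] = residuals

    if config.refgene_path is not None:
        transcripts = ucsc_io.read_refgene(config.refgene_path)
        spans = genes_mod.canonical_spans(transcripts)
        annotations = genes_mod.annotate_regions(csfrs, spans)
        report.gene_bearing_regions = genes_mod.gene_bearing_region_count(annotations)
        report.unique_genes = genes_mod.unique_gene_count(annotations)
        artifacts["annotations"] = annotations

    if config.fasta_path is not None:
        import pyfaidx

        genome = pyfaidx.Fasta(str(config.fasta_path))
        iso_calls = iso_mod.classify_all(
            genome,
            csfrs,
            flank_len=config.flank_len,
            threshold_pp=config.threshold_pp,
            border_rule=config.border_rule,
        )
        report.label_counts = iso_mod.label_counts(iso_calls)
        artifacts["isochore_calls"] = iso_calls

    if config.probe_path is not None:
        probes = ucsc_io.read_probe_table(config.probe_path)
        probe_report = regions_mod.probe_coverage_report(csfrs, probes)
        report.probe_count = probe_report.probe_count
        report.polymorphic_probe_count = probe_report.polymorphic_count
        artifacts["probe_report"] = probe_report

    if config.segdup_path is not None:
        segdups = ucsc_io.read_feature_table(config.segdup_path, "segdup")
        segdup_report = regions_mod.segdup_overlap_report(final_regions, segdups)
        report.segdup_flagged = sum(
            1 for rid in segdup_report.flagged if segdup_report.is_flagged(rid)
        )
        artifacts["segdup_report"] = segdup_report

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ucsc_io.write_bed(csfrs, outdir / "csfr.bed")
        if "cvfrs" in artifacts:
            ucsc_io.write_bed(artifacts["cvfrs"], outdir / "cvfr.bed")
        if "residuals" in artifacts:
            ucsc_io.write_bed(artifacts["residuals"], outdir / "residual.bed")
        if "annotations" in artifacts:
            with open(outdir / "annotations.tsv", "wt") as fh:
                fh.write("#region_id\tgenes\n")
                for ann in artifacts["annotations"]:
                    fh.write(f"{ann.region_id}\t{', '.join(ann.symbols)}\n")
        if "isochore_calls" in artifacts:
            with open(outdir / "isochore.tsv", "wt") as fh:
                fh.write("#region_id\tgc_left\tgc_region\tgc_right\tlabel\n")
                for call in artifacts["isochore_calls"]:
                    gl, gm, gr = call.profile.as_floats()
                    fmt = lambda g: "NA" if g is None else f"{g:.3f}"
                    fh.write(
                        f"{call.region_id}\t{fmt(gl)}\t{fmt(gm)}\t{fmt(gr)}"
                        f"\t{call.label}\n"
                    )
        with open(outdir / "report.txt", "wt") as fh:
            write_report(report, fh)

    return report, artifacts


def write_report(report: SummaryReport, sink: IO) -> None:
    """Machine-readable key-value block (sorted keys), then a commented
    human-readable summary."""
    flat = report.flat()
    for key in sorted(flat):
        sink.write(f"{key}\t{flat[key]}\n")
    sink.write("\n")
    sink.write("# Variant-free region summary\n")
    for stage in ("CSFR", "CVFR", "residual"):
        if stage in report.stage_counts:
            chroms = report.per_chrom.get(stage, {})
            detail = ", ".join(f"{c}: {n}" for c, n in sorted(chroms.items()))
            sink.write(
                f"# {stage}: {report.stage_counts[stage]} regions ({detail})\n"
            )


def parse_report(source: IO) -> dict:
    """Read back the machine-readable block of a report file."""
    out = {}
    for line in source:
        line = line.strip()
        if not line:
            break
        if line.startswith("#"):
            continue
        key, value = line.split("\t")
        try:
            out[key] = int(value)
        except ValueError:
            out[key] = value
    return out
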