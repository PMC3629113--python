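"""Synthetic input bundles with known ground truth.

Emulates, at configurable scale, every data source the pipeline consumes:
per-chromosome common-SNP positions (homogeneous Poisson process), planted
zero-SNP deserts, assembly gaps, CNV intervals, multi-isoform gene models,
personal-genome variant tracks, segmental duplications, an array-probe
annotation table, and FASTA sequence built from GC-content blocks.  All
files are written in the UCSC table dialects that :mod:`snpdesert.ucsc_io`
parses with its default column maps, so a bundle exercises the whole
pipeline end to end without any real downloads.

Determinism: a single global ``seed`` is expanded into per-component
substreams as ``numpy.random.default_rng(seed + offset)`` with a fixed
offset per component (sequence=1, snps=2, personal variants=3, mafs=4),
so regenerating one table never perturbs the others.

Default scale is desk-sized: 2 Mb chromosomes and a SNP rate of 1e-3 per
bp (roughly one common SNP per kb).  Note the scale effect on false
positives: a spontaneous SNP gap of k times the mean spacing occurs with
probability ~exp(-k) per gap, so a 10 kb gap at this rate is rare
(~0.09 expected per chromosome) but not impossible, whereas at the
genome-scale ratio (100 kb threshold, same rate) it is vanishingly so.
Genome-scale parameters are plain configuration away.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .intervals import GenomicInterval, merge
from .ucsc_io import ProbeRecord, SnpRecord

_SUBSTREAM = {"sequence": 1, "snps": 2, "personal": 3, "mafs": 4}


@dataclass
class SyntheticBundleConfig:
    """Full specification of one synthetic input bundle."""

    seed: int = 0
    chromosomes: Sequence[tuple[str, int]] = (("chrS1", 2_000_000),)
    snp_rate: float = 1e-3  # Poisson intensity per bp, outside deserts
    planted_deserts: Sequence[GenomicInterval] = ()
    planted_gaps: Sequence[GenomicInterval] = ()
    planted_cnvs: Sequence[GenomicInterval] = ()
    planted_segdups: Sequence[GenomicInterval] = ()
    # (symbol, chrom, [(tx_start, tx_end), ...]) - one tuple per isoform
    gene_spec: Sequence[tuple[str, str, Sequence[tuple[int, int]]]] = ()
    # (interval, target GC percent); blocks must tile each chromosome
    gc_blocks: Sequence[tuple[GenomicInterval, float]] = ()
    personal_variant_rate: float = 1e-4
    probe_spec: Sequence[ProbeRecord] = ()
    default_gc: float = 41.0  # used when gc_blocks omit a chromosome

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        for iv in [*self.planted_deserts, *self.planted_gaps, *self.planted_cnvs,
                   *self.planted_segdups]:
            if iv.chrom not in lengths or iv.end > lengths[iv.chrom]:
                raise ValueError(f"planted interval out of bounds: {iv}")
        by_chrom: dict = {}
        for iv, gc in self.gc_blocks:
            if not 0.0 <= gc <= 100.0:
                raise ValueError(f"GC percent out of range: {gc}")
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, blocks in by_chrom.items():
            blocks.sort(key=lambda b: b.start)
            cursor = 0
            for b in blocks:
                if b.start < cursor:
                    raise ValueError(f"overlapping gc_blocks on {chrom}")
                cursor = b.end
            if blocks[0].start != 0 or cursor != lengths[chrom]:
                raise ValueError(f"gc_blocks do not tile {chrom}")

    def rng(self, component: str) -> np.random.Generator:
        return np.random.default_rng(self.seed + _SUBSTREAM[component])


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _draw_block(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p_gc = gc / 100.0
    p = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    return rng.choice(_BASES, size=length, p=p)


def generate_sequence(config: SyntheticBundleConfig) -> dict:
    """FASTA content per chromosome: i.i.d. bases, P(G)+P(C) = block GC/100
    split equally, P(A) = P(T).  Deterministic under the config seed."""
    rng = config.rng("sequence")
    blocks_by_chrom: dict = {}
    for iv, gc in config.gc_blocks:
        blocks_by_chrom.setdefault(iv.chrom, []).append((iv, gc))
    genome = {}
    for chrom, length in config.chromosomes:
        blocks = sorted(blocks_by_chrom.get(chrom, []), key=lambda b: b[0].start)
        if not blocks:
            blocks = [(GenomicInterval(chrom, 0, length), config.default_gc)]
        parts = [_draw_block(rng, iv.length, gc) for iv, gc in blocks]
        genome[chrom] = np.concatenate(parts).tobytes().decode("ascii")
    return genome


def _poisson_positions(
    rng: np.random.Generator, length: int, rate: float
) -> np.ndarray:
    if rate <= 0:
        return np.empty(0, dtype=np.int64)
    n = rng.poisson(rate * length)
    return np.unique(rng.integers(0, length, size=n))


def place_snps(config: SyntheticBundleConfig) -> list[SnpRecord]:
    """Common SNPs from a homogeneous Poisson process, with every position
    inside a planted desert removed (deserts are SNP-free by construction).
    1 bp spans, sorted, deterministic under the seed."""
    rng = config.rng("snps")
    maf_rng = config.rng("mafs")
    deserts = merge(config.planted_deserts)
    records: list[SnpRecord] = []
    for chrom, length in config.chromosomes:
        positions = _poisson_positions(rng, length, config.snp_rate)
        holes = [(d.start, d.end) for d in deserts if d.chrom == chrom]
        for hole_start, hole_end in holes:
            positions = positions[(positions < hole_start) | (positions >= hole_end)]
        mafs = maf_rng.uniform(0.01, 0.5, size=len(positions))
        for pos, maf in zip(positions, mafs):
            pos = int(pos)
            records.append(
                SnpRecord(chrom, pos, pos + 1, f"rsS{chrom}_{pos}", round(float(maf), 4))
            )
    records.sort(key=lambda r: (r.chrom, r.start))
    return records


def place_personal_variants(config: SyntheticBundleConfig) -> list[SnpRecord]:
    """Rare personal-genome variants: Poisson everywhere, deserts included —
    rare variation persists where the common-SNP map has holes."""
    rng = config.rng("personal")
    records = []
    for chrom, length in config.chromosomes:
        for pos in _poisson_positions(rng, length, config.personal_variant_rate):
            pos = int(pos)
            records.append(SnpRecord(chrom, pos, pos + 1, f"pvS{chrom}_{pos}", None))
    records.sort(key=lambda r: (r.chrom, r.start))
    return records


def _snp_row(rec: SnpRecord) -> str:
    # snp135Common layout: 26 tab-separated columns, alleleFreqs at index 24.
    fields = ["0"] * 26
    fields[1] = rec.chrom
    fields[2] = str(rec.start)
    fields[3] = str(rec.end)
    fields[4] = rec.rsid
    fields[6] = "+"
    fields[11] = "single"
    if rec.maf is not None:
        fields[21] = "2"
        fields[22] = "A,C,"
        fields[24] = f"{1 - rec.maf:.4f},{rec.maf:.4f},"
    else:
        fields[24] = ""
    return "\t".join(fields)


def _feature_row(iv: GenomicInterval, name: str) -> str:
    return f"0\t{iv.chrom}\t{iv.start}\t{iv.end}\t{name}"


def _refgene_row(symbol: str, chrom: str, tx_start: int, tx_end: int,
                 transcript_id: str) -> str:
    fields = ["0"] * 16
    fields[1] = transcript_id
    fields[2] = chrom
    fields[3] = "+"
    fields[4] = str(tx_start)
    fields[5] = str(tx_end)
    fields[6] = str(tx_start)
    fields[7] = str(tx_end)
    fields[8] = "1"
    fields[9] = f"{tx_start},"
    fields[10] = f"{tx_end},"
    fields[12] = symbol
    return "\t".join(fields)


def write_fasta(genome: dict, path: Path, width: int = 70) -> None:
    with open(path, "wt") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bundle(config: SyntheticBundleConfig, outdir) -> dict:
    """Write the full bundle; returns a manifest (also saved as
    ``manifest.txt``) mapping file roles to paths plus the ground-truth
    planted desert intervals."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    paths = {
        "snp_table": outdir / "snp_common.txt",
        "gap_table": outdir / "gap.txt",
        "cnv_table": outdir / "dgv.txt",
        "refgene_table": outdir / "refGene.txt",
        "personal_table": outdir / "pgSynthetic.txt",
        "segdup_table": outdir / "segdup.txt",
        "probe_table": outdir / "probes.txt",
        "fasta": outdir / "genome.fa",
    }

    snps = place_snps(config)
    with open(paths["snp_table"], "wt") as fh:
        for rec in snps:
            fh.write(_snp_row(rec) + "\n")

    for key, intervals, prefix in (
        ("gap_table", config.planted_gaps, "gap"),
        ("cnv_table", config.planted_cnvs, "cnv"),
        ("segdup_table", config.planted_segdups, "segdup"),
    ):
        with open(paths[key], "wt") as fh:
            for i, iv in enumerate(sorted(intervals)):
                fh.write(_feature_row(iv, f"{prefix}_{i + 1}") + "\n")

    with open(paths["refgene_table"], "wt") as fh:
        for symbol, chrom, isoforms in config.gene_spec:
            for j, (tx_start, tx_end) in enumerate(isoforms):
                fh.write(
                    _refgene_row(symbol, chrom, tx_start, tx_end,
                                 f"SYN_{symbol}_{j + 1}") + "\n"
                )

    personal = place_personal_variants(config)
    with open(paths["personal_table"], "wt") as fh:
        for rec in personal:
            fh.write(_feature_row(
                GenomicInterval(rec.chrom, rec.start, rec.end), rec.rsid) + "\n")

    populations = sorted({p for probe in config.probe_spec for p in probe.pop_mafs})
    with open(paths["probe_table"], "wt") as fh:
        fh.write("#probe_id\tchrom\tpos\t" + "\t".join(populations) + "\n")
        for probe in sorted(config.probe_spec, key=lambda p: (p.chrom, p.position)):
            mafs = "\t".join(
                f"{probe.pop_mafs[p]:.4f}" if p in probe.pop_mafs else "NA"
                for p in populations
            )
            fh.write(f"{probe.probe_id}\t{probe.chrom}\t{probe.position}\t{mafs}\n")

    genome = generate_sequence(config)
    write_fasta(genome, paths["fasta"])

    manifest = {key: str(path) for key, path in paths.items()}
    manifest["seed"] = str(config.seed)
    for i, d in enumerate(sorted(config.planted_deserts)):
        manifest[f"desert_{i + 1}"] = f"{d.chrom}:{d.start}-{d.end}"
    with open(outdir / "manifest.txt", "wt") as fh:
        for key in sorted(manifest):
            fh.write(f"{key}\t{manifest[key]}\n")
    manifest["manifest"] = str(outdir / "manifest.txt")
    return manifest
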