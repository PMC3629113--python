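"""Packaged catalog of published hg19 variant-free regions, with builders
that reconstruct minimal pipeline inputs reproducing it.

The package ships two small TSV tables transcribed from the published hg19
screen: the 50-region common-SNP-free catalog (with gene lists and isochore
labels) and the 20-region common-variant-free catalog.  Real dbSNP/DGV
dumps are hundreds of megabytes; for testing and for reproducing the
published summary numbers, this module inverts the catalog into compact
inputs instead:

* :func:`bracketing_snps` places common SNPs so that the inter-SNP gaps are
  exactly the catalog regions (zero-length insertion records are used where
  two catalog regions abut, mirroring dbSNP insertion rows);
* :func:`infer_cnvs` derives the CNV set as the part of the CSFR cover not
  retained in the CVFR catalog;
* :func:`transcripts_from_catalog` builds one refGene-style transcript per
  gene symbol spanning all catalog regions that list it;
* :func:`isochore_genome` builds one GC-block contig per region whose
  flank/region GC levels realize the catalogued label.

Note one quirk reproduced faithfully: the published CVFR table contains two
rows that are not nested inside any published CSFR (chrY 17559652-17661377,
and chrY 4935714-5205540 which reaches left of the printed CSFR at
5012892).  Because CNV subtraction can only shrink regions, those two rows
cannot re-emerge from the 50-region CSFR catalog; the reconstructed
pipeline therefore yields 19 CVFRs, 18 of them coordinate-exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

from .intervals import GenomicInterval, merge, subtract
from .ucsc_io import FeatureInterval, SnpRecord, TranscriptRecord, normalize_symbol


@dataclass(frozen=True)
class CatalogRegion:
    interval: GenomicInterval
    genes: tuple  # raw symbols as printed (normalize downstream)
    label: Optional[str] = None  # isochore / isochore_border / unknown

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


def _load(name: str, with_label: bool) -> list[CatalogRegion]:
    text = resources.files("snpdesert.data").joinpath(name).read_text()
    out = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        size = int(fields[3])
        iv = GenomicInterval(chrom, start, end)
        assert iv.length == size, f"catalog size mismatch at {chrom}:{start}"
        genes_raw = fields[4] if len(fields) > 4 else ""
        genes = tuple(g.strip() for g in genes_raw.split(",") if g.strip())
        label = fields[5] if with_label and len(fields) > 5 else None
        out.append(CatalogRegion(iv, genes, label))
    return out


def load_csfr_catalog() -> list[CatalogRegion]:
    """The published 50 common-SNP-free regions (hg19), with gene lists and
    isochore labels."""
    return _load("csfr_catalog_hg19.tsv", with_label=True)


def load_cvfr_catalog() -> list[CatalogRegion]:
    """The published 20 common-variant-free regions (hg19)."""
    return _load("cvfr_catalog_hg19.tsv", with_label=False)


def chromosome_bounds(regions: Sequence[CatalogRegion], margin: int = 10_000) -> dict:
    bounds: dict = {}
    for r in regions:
        lo, hi = bounds.get(r.chrom, (r.start, r.end))
        bounds[r.chrom] = (min(lo, r.start), max(hi, r.end + margin))
    return bounds


def bracketing_snps(
    regions: Sequence[CatalogRegion],
    fill_spacing: int = 50_000,
    maf: float = 0.25,
) -> list[SnpRecord]:
    """Common-SNP records whose inter-SNP gaps are exactly the catalog regions.

    Each region boundary gets a flanking 1 bp SNP just outside the region;
    where two regions share a boundary (abutting rows), a zero-length
    insertion record at the shared coordinate splits the gap without
    occupying a base.  Stretches between regions longer than
    ``fill_spacing`` receive filler SNPs so no spurious desert survives a
    length filter above ``fill_spacing``.
    """
    by_chrom: dict = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r.interval)
    spans: set = set()
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts = {iv.start for iv in ivs}
        ends = {iv.end for iv in ivs}
        for iv in ivs:
            # left bracket: must end exactly at iv.start
            if iv.start in ends:  # abuts the previous region: insertion record
                spans.add((chrom, iv.start, iv.start))
            else:
                spans.add((chrom, iv.start - 1, iv.start))
            # right bracket: must start exactly at iv.end
            if iv.end in starts:
                spans.add((chrom, iv.end, iv.end))
            else:
                spans.add((chrom, iv.end, iv.end + 1))
        # fillers between consecutive regions
        for prev, nxt in zip(ivs, ivs[1:]):
            pos = prev.end + fill_spacing
            while pos < nxt.start - 1:
                spans.add((chrom, pos, pos + 1))
                pos += fill_spacing
    records = [
        SnpRecord(chrom, start, end, f"rsB_{chrom}_{start}_{end - start}", maf)
        for chrom, start, end in sorted(spans)
    ]
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    return records


def infer_cnvs(
    csfrs: Sequence[CatalogRegion],
    cvfrs: Sequence[CatalogRegion],
    source_label: str = "dgv_inferred",
) -> list[FeatureInterval]:
    """CNV intervals = CSFR cover minus CVFR cover.

    Subtracting these from the CSFR catalog retains exactly the CVFR rows
    that are nested in it.
    """
    residual = subtract(
        merge([r.interval for r in csfrs]),
        merge([r.interval for r in cvfrs]),
    )
    return [
        FeatureInterval(iv.chrom, iv.start, iv.end, "cnv", source_label)
        for iv in residual
    ]


def transcripts_from_catalog(
    regions: Sequence[CatalogRegion],
) -> list[TranscriptRecord]:
    """One transcript per gene symbol, spanning the union of all catalog
    regions that list it (genes such as PCDH11Y genuinely cross several
    deserts)."""
    span: dict = {}
    for r in regions:
        for raw in r.genes:
            symbol = normalize_symbol(raw)
            key = (symbol, r.chrom)
            lo, hi = span.get(key, (r.start, r.end))
            span[key] = (min(lo, r.start), max(hi, r.end))
    records = [
        TranscriptRecord(symbol, f"CAT_{symbol}", chrom, lo, hi)
        for (symbol, chrom), (lo, hi) in span.items()
    ]
    records.sort(key=lambda t: (t.chrom, t.tx_start, t.symbol))
    return records


POLYMORPHIC_PROBE_IDS = ("rs11681529", "rs2571764", "rs2874557", "rs35516764")


def affy_probe_fixture(
    regions: Sequence[CatalogRegion],
    n_probes: int = 25,
    n_polymorphic: int = 4,
    populations: Sequence[str] = ("CEU", "YRI", "CHB", "JPT"),
) -> list:
    """Synthetic array-probe annotation emulating the published genotyping
    check: the catalog regions contain 25 assayed probes of which 4 are
    polymorphic in at least one population.

    Probe genomic positions were never published, so this fixture is
    constructed: one probe is placed at the midpoint of each of the first
    ``n_probes`` regions; the first ``n_polymorphic`` carry the published
    polymorphic rsids with a nonzero CEU frequency, the rest are monomorphic
    across all populations.
    """
    from .ucsc_io import ProbeRecord

    probes = []
    for i, r in enumerate(regions[:n_probes]):
        mid = (r.start + r.end) // 2
        if i < n_polymorphic:
            pid = POLYMORPHIC_PROBE_IDS[i]
            mafs = {"CEU": 0.05, "YRI": 0.0, "CHB": 0.0, "JPT": 0.0}
        else:
            pid = f"SNP_A-MONO{i + 1}"
            mafs = {p: 0.0 for p in populations}
        probes.append(ProbeRecord(pid, r.chrom, mid, mafs))
    return probes


# GC targets (left flank, region, right flank) realizing each label under
# the 2-percentage-point rule, far enough apart that binomial fluctuation
# over >= 100 kb windows (sigma ~ 0.16 pp) cannot flip a call.
LABEL_GC_TARGETS = {
    "isochore": (41.0, 45.0, 41.0),
    "isochore_border": (40.0, 45.0, 50.0),
    "unknown": (45.0, 45.0, 45.0),
}


def isochore_genome(
    regions: Sequence[CatalogRegion],
    flank_len: int = 100_000,
    seed: int = 0,
):
    """Per-region contigs with GC blocks realizing each catalog label.

    Returns ``(genome dict, region calls)`` where each catalog region is
    remapped onto its own contig ``iso_<n>`` as [flank_len, flank_len + L),
    so classification needs only region + flank sequence, not whole
    chromosomes.
    """
    from .regions import RegionCall
    from .simulate import SyntheticBundleConfig, generate_sequence

    chroms = []
    blocks = []
    calls = []
    for i, r in enumerate(regions):
        label = r.label or "unknown"
        gc_l, gc_m, gc_r = LABEL_GC_TARGETS[label]
        name = f"iso_{i + 1}"
        length = 2 * flank_len + r.interval.length
        chroms.append((name, length))
        blocks.append((GenomicInterval(name, 0, flank_len), gc_l))
        blocks.append(
            (GenomicInterval(name, flank_len, flank_len + r.interval.length), gc_m)
        )
        blocks.append(
            (GenomicInterval(name, flank_len + r.interval.length, length), gc_r)
        )
        calls.append(
            RegionCall(
                GenomicInterval(name, flank_len, flank_len + r.interval.length),
                "CSFR",
            )
        )
    config = SyntheticBundleConfig(
        seed=seed, chromosomes=tuple(chroms), gc_blocks=tuple(blocks),
        snp_rate=0.0, personal_variant_rate=0.0,
    )
    return generate_sequence(config), calls
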