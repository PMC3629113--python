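"""Readers for UCSC Table Browser-style dumps and BED, writer for BED.

The annotation tables consumed here (common-SNP table in the snp135Common
layout, assembly gap table, refGene, DGV CNV table, personal-genome variant
tracks, segmental-duplication pairs) are plain tab-separated files with
positional columns, all 0-based half-open.  Gzip is sniffed transparently
from the magic bytes when a path is given.  Every reader:

* returns records sorted by ``(chrom, start)``,
* tolerates arbitrary trailing columns,
* raises :class:`TableParseError` with the 1-based line number on a
  malformed row,
* returns an empty collection for empty input.

Column positions can be overridden with a ``column_map`` (a mapping from
field name to 0-based column index) to absorb dialect drift between table
vintages, e.g. Eichler-lab segdup pair files that lack the leading ``bin``
column.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Optional, Union

from .intervals import GenomicInterval

FEATURE_CLASSES = frozenset(
    {"assembly_gap", "cnv", "personal_variant", "segdup", "extra_snp"}
)


class TableParseError(ValueError):
    """A malformed row in a tab-separated annotation table."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True, order=True)
class SnpRecord:
    """One SNP from a common-SNP table.

    ``start == end`` is allowed and denotes an insertion (zero-length span,
    the dbSNP "between" location type); such records still act as cut points
    in inter-SNP gap extraction.  ``maf`` is the minor allele frequency when
    the table carries parseable allele frequencies, else None.
    """

    chrom: str
    start: int
    end: int
    rsid: str
    maf: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"bad SNP span {self.chrom}:{self.start}-{self.end}")


@dataclass(frozen=True, order=True)
class FeatureInterval:
    """A non-SNP genomic feature: assembly gap, CNV, personal variant, segdup."""

    chrom: str
    start: int
    end: int
    feature_class: str
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise ValueError(
                f"bad feature span {self.chrom}:{self.start}-{self.end}"
            )
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, order=True)
class TranscriptRecord:
    """One refGene row: a transcript (``name``) of a gene symbol (``name2``)."""

    symbol: str
    transcript_id: str
    chrom: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.tx_end <= self.tx_start:
            raise ValueError(
                f"bad transcript span {self.chrom}:{self.tx_start}-{self.tx_end}"
            )
        if not self.symbol:
            raise ValueError("empty gene symbol")


@dataclass(frozen=True)
class ProbeRecord:
    """A genotyping-array probe with per-population minor allele frequencies."""

    probe_id: str
    chrom: str
    position: int
    pop_mafs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pop, maf in self.pop_mafs.items():
            if not 0.0 <= maf <= 0.5:
                raise ValueError(f"probe {self.probe_id}: MAF {maf} for {pop}")


# Default 0-based column positions.  The snp track layout is
# bin, chrom, chromStart, chromEnd, name, ..., alleleFreqs at 24.
SNP_COLUMNS = {"chrom": 1, "start": 2, "end": 3, "name": 4, "allele_freqs": 24}
FEATURE_COLUMNS = {"chrom": 1, "start": 2, "end": 3}
REFGENE_COLUMNS = {"name": 1, "chrom": 2, "tx_start": 4, "tx_end": 5, "name2": 12}


def normalize_symbol(symbol: str) -> str:
    """Canonical gene symbol: strip then remove internal whitespace.

    Reconciles table artifacts such as ``"LIMS3 L"`` vs ``"LIMS3L"``.
    """
    return "".join(symbol.split())


def _open_text(source: Union[str, Path, IO]) -> tuple[IO, bool]:
    """Return (text handle, caller_should_close).  Sniffs gzip on paths."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, "rt"), True
        return open(path, "rt"), True
    return source, False


def _rows(source) -> Iterator[tuple[int, list[str]]]:
    handle, close = _open_text(source)
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")
    finally:
        if close:
            handle.close()


def _coord(fields: list[str], idx: int, lineno: int, what: str) -> int:
    try:
        raw = fields[idx]
    except IndexError:
        raise TableParseError(f"missing {what} column (index {idx})", lineno)
    try:
        value = int(raw)
    except ValueError:
        raise TableParseError(f"non-integer {what}: {raw!r}", lineno)
    if value < 0:
        raise TableParseError(f"negative {what}: {value}", lineno)
    return value


def parse_maf(allele_freqs: str) -> Optional[float]:
    """Minor allele frequency = smallest nonzero frequency listed.

    Returns None when no frequency is parseable (the record then passes any
    MAF filter unscathed: common-SNP tables are pre-filtered upstream).
    """
    freqs = []
    for token in allele_freqs.strip().strip(",").split(","):
        token = token.strip()
        if not token:
            continue
        try:
            f = float(token)
        except ValueError:
            return None
        if f > 0:
            freqs.append(f)
    return min(freqs) if freqs else None


def read_common_snps(
    source,
    maf_min: float = 0.0,
    column_map: Optional[Mapping[str, int]] = None,
) -> list[SnpRecord]:
    """Parse a common-SNP table; drop rows with parseable MAF below ``maf_min``.

    Rows without frequency data are retained.  Insertion rows
    (chromStart == chromEnd) are kept as zero-length records.
    """
    cols = dict(SNP_COLUMNS, **(column_map or {}))
    records = []
    for lineno, fields in _rows(source):
        start = _coord(fields, cols["start"], lineno, "chromStart")
        end = _coord(fields, cols["end"], lineno, "chromEnd")
        if end < start:
            raise TableParseError(f"chromEnd {end} < chromStart {start}", lineno)
        chrom = fields[cols["chrom"]]
        if not chrom:
            raise TableParseError("empty chrom", lineno)
        name_idx = cols["name"]
        rsid = fields[name_idx] if name_idx < len(fields) else ""
        maf = None
        freq_idx = cols["allele_freqs"]
        if freq_idx is not None and freq_idx < len(fields):
            maf = parse_maf(fields[freq_idx])
        if maf is not None and maf < maf_min:
            continue
        records.append(SnpRecord(chrom, start, end, rsid, maf))
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    return records


def read_feature_table(
    source,
    feature_class: str,
    column_map: Optional[Mapping[str, int]] = None,
    source_label: Optional[str] = None,
) -> list[FeatureInterval]:
    """Parse a gap/DGV/personal-variant/segdup table into FeatureIntervals."""
    if feature_class not in FEATURE_CLASSES:
        raise ValueError(f"unknown feature class {feature_class!r}")
    if source_label is None:
        if isinstance(source, (str, Path)):
            source_label = Path(source).name
        else:
            source_label = feature_class
    cols = dict(FEATURE_COLUMNS, **(column_map or {}))
    records = []
    for lineno, fields in _rows(source):
        start = _coord(fields, cols["start"], lineno, "chromStart")
        end = _coord(fields, cols["end"], lineno, "chromEnd")
        if end <= start:
            raise TableParseError(f"chromEnd {end} <= chromStart {start}", lineno)
        chrom = fields[cols["chrom"]]
        if not chrom:
            raise TableParseError("empty chrom", lineno)
        records.append(FeatureInterval(chrom, start, end, feature_class, source_label))
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    return records


def read_refgene(
    source,
    column_map: Optional[Mapping[str, int]] = None,
) -> list[TranscriptRecord]:
    """Parse a refGene table; one TranscriptRecord per row.

    Gene symbols (name2) are whitespace-normalized; longest-isoform selection
    happens downstream in gene annotation.
    """
    cols = dict(REFGENE_COLUMNS, **(column_map or {}))
    records = []
    for lineno, fields in _rows(source):
        if cols["name2"] >= len(fields):
            raise TableParseError("missing name2 column", lineno)
        symbol = normalize_symbol(fields[cols["name2"]])
        if not symbol:
            raise TableParseError("empty name2", lineno)
        tx_start = _coord(fields, cols["tx_start"], lineno, "txStart")
        tx_end = _coord(fields, cols["tx_end"], lineno, "txEnd")
        if tx_end <= tx_start:
            raise TableParseError(f"txEnd {tx_end} <= txStart {tx_start}", lineno)
        records.append(
            TranscriptRecord(symbol, fields[cols["name"]], fields[cols["chrom"]], tx_start, tx_end)
        )
    records.sort(key=lambda r: (r.chrom, r.tx_start, r.tx_end, r.transcript_id))
    return records


def read_probe_table(source) -> list[ProbeRecord]:
    """Parse an array-annotation table: probe_id, chrom, pos, then one MAF
    column per population (population names on a leading ``#``-header line)."""
    handle, close = _open_text(source)
    try:
        populations: list[str] = []
        records = []
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith("#"):
                populations = line.lstrip("#").split("\t")[3:]
                continue
            fields = line.split("\t")
            pos = _coord(fields, 2, lineno, "position")
            mafs = {}
            for pop, raw in zip(populations, fields[3:]):
                raw = raw.strip()
                if raw in ("", "NA", "."):
                    continue
                mafs[pop] = float(raw)
            records.append(ProbeRecord(fields[0], fields[1], pos, mafs))
        records.sort(key=lambda r: (r.chrom, r.position, r.probe_id))
        return records
    finally:
        if close:
            handle.close()


def read_bed(source) -> list[GenomicInterval]:
    """Read BED3+ into intervals (names and extra columns ignored)."""
    out = []
    for lineno, fields in _rows(source):
        if len(fields) < 3:
            raise TableParseError("BED row needs >= 3 columns", lineno)
        start = _coord(fields, 1, lineno, "start")
        end = _coord(fields, 2, lineno, "end")
        if end <= start:
            raise TableParseError(f"end {end} <= start {start}", lineno)
        out.append(GenomicInterval(fields[0], start, end))
    return out


def _bearing_interval(record) -> GenomicInterval:
    iv = getattr(record, "interval", record)
    return GenomicInterval(iv.chrom, iv.start, iv.end)


def write_bed(regions: Iterable, sink: Union[str, Path, IO]) -> None:
    """Write BED4 (chrom, start, end, name), 0-based half-open.

    Accepts bare intervals or any records bearing an ``interval`` attribute;
    the name column comes from a record's ``id`` attribute when present.
    """
    own = isinstance(sink, (str, Path))
    handle = open(sink, "wt") if own else sink
    try:
        for i, rec in enumerate(regions):
            iv = _bearing_interval(rec)
            name = getattr(rec, "id", None) or f"region_{i + 1}"
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")
    finally:
        if own:
            handle.close()


def write_bed_string(regions: Iterable) -> str:
    buf = io.StringIO()
    write_bed(regions, buf)
    return buf.getvalue()
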