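"""Gene annotation of called regions.

A gene is represented by its longest splicing form: per (symbol, chromosome)
the transcript maximizing ``tx_end - tx_start`` defines the gene span (ties:
smaller start, then lexicographic transcript id).  A gene is assigned to a
region when its span overlaps the region by at least one base pair
(half-open intersection nonempty).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .intervals import GenomicInterval
from .ucsc_io import TranscriptRecord


@dataclass(frozen=True, order=True)
class GeneSpan:
    """The canonical (longest-isoform) span of a gene symbol on one chromosome."""

    chrom: str
    start: int
    end: int
    symbol: str
    chosen_transcript: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"bad gene span {self.symbol}: {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RegionGeneAnnotation:
    region_id: str
    symbols: tuple  # ordered by span start, then name
    overlap_bp: tuple  # parallel to symbols, each >= 1


def canonical_spans(transcripts: Iterable[TranscriptRecord]) -> list[GeneSpan]:
    """One GeneSpan per (symbol, chrom): the longest transcript wins."""
    best: dict = {}
    for t in transcripts:
        key = (t.symbol, t.chrom)
        rank = (-(t.tx_end - t.tx_start), t.tx_start, t.transcript_id)
        if key not in best or rank < best[key][0]:
            best[key] = (rank, t)
    spans = [
        GeneSpan(t.chrom, t.tx_start, t.tx_end, symbol, t.transcript_id)
        for (symbol, _), (_, t) in best.items()
    ]
    spans.sort()
    return spans


def annotate_regions(
    regions: Sequence,
    spans: Sequence[GeneSpan],
) -> list[RegionGeneAnnotation]:
    """List, per region, the gene spans overlapping it by >= 1 bp.

    ``regions`` are RegionCalls (or anything bearing interval + id).
    Symbols are ordered by span start then name and are unique per region.
    """
    out = []
    for call in regions:
        iv: GenomicInterval = getattr(call, "interval", call)
        hits = []
        for span in spans:
            if span.chrom == iv.chrom and span.start < iv.end and iv.start < span.end:
                overlap = min(span.end, iv.end) - max(span.start, iv.start)
                hits.append((span.start, span.symbol, overlap))
        hits.sort()
        seen = set()
        symbols, overlaps = [], []
        for _, symbol, overlap in hits:
            if symbol in seen:
                continue
            seen.add(symbol)
            symbols.append(symbol)
            overlaps.append(overlap)
        out.append(
            RegionGeneAnnotation(
                region_id=getattr(call, "id", f"{iv.chrom}_{iv.start}"),
                symbols=tuple(symbols),
                overlap_bp=tuple(overlaps),
            )
        )
    return out


def unique_gene_count(annotations: Iterable[RegionGeneAnnotation]) -> int:
    """Number of distinct gene symbols across all region annotations."""
    symbols = set()
    for ann in annotations:
        symbols.update(ann.symbols)
    return len(symbols)


def gene_bearing_region_count(annotations: Iterable[RegionGeneAnnotation]) -> int:
    return sum(1 for ann in annotations if ann.symbols)
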