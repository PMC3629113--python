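"""Exact algebra over half-open genomic intervals.

All coordinates are 0-based half-open ([start, end), UCSC chromStart/chromEnd
convention), so ``length == end - start``.  The operations here are the
building blocks of SNP-desert detection: merging feature covers, subtracting
covers from candidate regions, extracting the gaps between adjacent SNPs, and
length/overlap filtering.

Abutting intervals (``a.end == b.start``) merge: a cover is always represented
by disjoint, non-touching, sorted intervals, which keeps subtraction chains
free of zero-length artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A non-empty half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the half-open intersection is nonempty (>= 1 shared base)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def _as_interval(obj) -> GenomicInterval:
    """Accept GenomicInterval or any record with chrom/start/end attributes."""
    if isinstance(obj, GenomicInterval):
        return obj
    return GenomicInterval(obj.chrom, obj.start, obj.end)


def _spans_by_chrom(items) -> dict:
    by_chrom: dict = {}
    for it in items:
        chrom = it.chrom
        by_chrom.setdefault(chrom, []).append((it.start, it.end))
    for spans in by_chrom.values():
        spans.sort()
    return by_chrom


def merge(intervals: Iterable) -> list[GenomicInterval]:
    """Merge overlapping and abutting intervals into a disjoint sorted cover.

    Union-preserving: the set of covered bases is unchanged.
    """
    out: list[GenomicInterval] = []
    for chrom in sorted(_spans := _spans_by_chrom(intervals)):
        cur_start: Optional[int] = None
        cur_end = 0
        for start, end in _spans[chrom]:
            if cur_start is None:
                cur_start, cur_end = start, end
            elif start <= cur_end:  # overlap or abut
                cur_end = max(cur_end, end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = start, end
        if cur_start is not None:
            out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def subtract(minuend: Iterable, subtrahend: Iterable) -> list[GenomicInterval]:
    """Maximal residual sub-intervals of ``minuend`` not covered by ``subtrahend``.

    Both inputs are merged internally; the result is sorted and disjoint.
    """
    minus = merge(minuend)
    sub_by_chrom = _spans_by_chrom(merge(subtrahend))
    out: list[GenomicInterval] = []
    for iv in minus:
        cursor = iv.start
        for s, e in sub_by_chrom.get(iv.chrom, ()):
            if e <= cursor:
                continue
            if s >= iv.end:
                break
            if s > cursor:
                out.append(GenomicInterval(iv.chrom, cursor, s))
            cursor = max(cursor, e)
            if cursor >= iv.end:
                break
        if cursor < iv.end:
            out.append(GenomicInterval(iv.chrom, cursor, iv.end))
    out.sort()
    return out


def inter_snp_gaps(
    snps: Sequence,
    chrom_whitelist: Optional[set] = None,
) -> list[GenomicInterval]:
    """Gaps between adjacent SNP spans, per chromosome.

    For each chromosome the SNP spans are swept in coordinate order and one
    interval ``(prev.end, next.start)`` is emitted per consecutive pair with
    ``next.start > prev.end``.  Segments before the first and after the last
    SNP of a chromosome are not emitted.  Zero-length spans (insertion
    records, ``start == end``) act as cut points: they split a gap without
    consuming any base.
    """
    by_chrom: dict = {}
    for rec in snps:
        if chrom_whitelist is not None and rec.chrom not in chrom_whitelist:
            continue
        by_chrom.setdefault(rec.chrom, []).append((rec.start, rec.end))
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        if len(spans) < 2:
            continue
        cur_end = spans[0][1]
        for start, end in spans[1:]:
            if start > cur_end:
                out.append(GenomicInterval(chrom, cur_end, start))
            cur_end = max(cur_end, end)
    return out


def filter_min_length(intervals: Iterable, min_len: int) -> list:
    """Keep exactly the intervals with ``end - start >= min_len``; order preserved."""
    if min_len <= 0:
        raise ValueError(f"min_len must be positive, got {min_len}")
    return [iv for iv in intervals if (iv.end - iv.start) >= min_len]


def intersect_any(region, features: Iterable) -> list:
    """All features sharing >= 1 base with ``region`` (same chromosome only)."""
    reg = _as_interval(region)
    return [
        f
        for f in features
        if f.chrom == reg.chrom and f.start < reg.end and reg.start < f.end
    ]
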