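"""GC-content isochore classification of called regions.

An isochore is a long stretch of DNA with relatively uniform GC content.
Each region is compared against its two flanking windows (default 100 kb
each, truncated at chromosome ends):

* **isochore** — the region's GC content is at least ``threshold_pp``
  percentage points above both flanks, or below both flanks (the region is
  a compositional unit distinct from its surroundings);
* **isochore_border** — the two flanks differ by more than ``threshold_pp``
  and that flank-to-flank difference exceeds the region-to-flank
  differences (the region sits on a compositional transition);
* **unknown** — neither, or a window is too N-rich to trust.

GC percentages are computed case-insensitively over A/C/G/T only; N and
other characters count toward neither numerator nor denominator.  Threshold
comparisons use exact rational arithmetic on the base counts, so a
difference of exactly 2.00 percentage points is handled without float
round-off.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

from .intervals import GenomicInterval

LABELS = ("isochore", "isochore_border", "unknown")



def gc_percent(sequence: str) -> tuple[Optional[float], int]:
    """GC percentage of a window and its usable (unambiguous) base count.

    Returns ``(None, 0)``-style undefined percent when no base is usable;
    undefined is never encoded as 0.0.
    """
    frac, usable = _gc_fraction(sequence)
    return (None if frac is None else float(frac), usable)


def _gc_fraction(sequence: str) -> tuple[Optional[Fraction], int]:
    data = sequence.upper().encode("ascii", errors="replace")
    gc = data.count(b"G") + data.count(b"C")
    usable = gc + data.count(b"A") + data.count(b"T")
    if usable == 0:
        return None, 0
    return Fraction(100 * gc, usable), usable


@dataclass(frozen=True)
class GcProfile:
    """GC triple (left flank, region, right flank) with usable-base counts.

    Percentages are exact rationals; None marks an undefined window (no
    usable base or truncated-away flank).
    """

    gc_left: Optional[Fraction]
    gc_region: Optional[Fraction]
    gc_right: Optional[Fraction]
    usable_left: int
    usable_region: int
    usable_right: int

    def as_floats(self) -> tuple:
        return tuple(
            None if g is None else float(g)
            for g in (self.gc_left, self.gc_region, self.gc_right)
        )


@dataclass(frozen=True)
class IsochoreCall:
    region_id: str
    interval: GenomicInterval
    profile: GcProfile
    label: str
    reason: str = ""

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Slice genome[chrom][start:end] for dict-of-str or pyfaidx.Fasta."""
    seq = genome[chrom][start:end]
    return seq if isinstance(seq, str) else str(seq)


def _chrom_length(genome, chrom: str) -> int:
    return len(genome[chrom])


def classify_region(
    genome,
    region,
    flank_len: int = 100_000,
    threshold_pp: float = 2.0,
    min_usable_fraction: float = 0.5,
    border_rule: str = "both",
    region_id: Optional[str] = None,
) -> IsochoreCall:
    """Classify one region from the genome sequence.

    ``genome`` is any chromosome-indexable sequence source (a dict of
    strings, or a :class:`pyfaidx.Fasta`).  Flanks are truncated at
    chromosome boundaries; a window whose usable bases fall below
    ``min_usable_fraction`` of its nominal length degrades the call to
    ``unknown``.  ``border_rule`` selects whether the flank-to-flank
    difference must exceed *both* region-to-flank differences ("both",
    default) or at least one of them ("either").
    """
    iv: GenomicInterval = getattr(region, "interval", region)
    rid = region_id or getattr(region, "id", f"{iv.chrom}_{iv.start}")
    if border_rule not in ("both", "either"):
        raise ValueError(f"border_rule must be 'both' or 'either', got {border_rule!r}")
    try:
        chrom_len = _chrom_length(genome, iv.chrom)
    except KeyError:
        raise ValueError(f"chromosome {iv.chrom!r} absent from genome") from None
    if iv.end > chrom_len:
        raise ValueError(
            f"region {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
            f"length {chrom_len}"
        )

    left_start = max(0, iv.start - flank_len)
    right_end = min(chrom_len, iv.end + flank_len)

    gc_region, usable_region = _gc_fraction(_fetch(genome, iv.chrom, iv.start, iv.end))
    gc_left, usable_left = _gc_fraction(_fetch(genome, iv.chrom, left_start, iv.start))
    gc_right, usable_right = _gc_fraction(_fetch(genome, iv.chrom, iv.end, right_end))

    profile = GcProfile(
        gc_left, gc_region, gc_right, usable_left, usable_region, usable_right
    )

    def _unknown(reason: str) -> IsochoreCall:
        return IsochoreCall(rid, iv, profile, "unknown", reason)

    # Usable fractions are measured against the *nominal* window lengths, so
    # a flank truncated below min_usable_fraction * flank_len is unusable.
    if gc_left is None or Fraction(usable_left, flank_len) < Fraction(
        str(min_usable_fraction)
    ):
        return _unknown("left flank unusable")
    if gc_right is None or Fraction(usable_right, flank_len) < Fraction(
        str(min_usable_fraction)
    ):
        return _unknown("right flank unusable")
    if gc_region is None or Fraction(usable_region, iv.length) < Fraction(
        str(min_usable_fraction)
    ):
        return _unknown("region window unusable")

    thr = Fraction(str(threshold_pp))
    d_left = gc_region - gc_left
    d_right = gc_region - gc_right
    d_flank = abs(gc_left - gc_right)

    if (d_left >= thr and d_right >= thr) or (d_left <= -thr and d_right <= -thr):
        return IsochoreCall(rid, iv, profile, "isochore")
    exceeds = (d_flank > abs(d_left), d_flank > abs(d_right))
    if d_flank > thr and (all(exceeds) if border_rule == "both" else any(exceeds)):
        return IsochoreCall(rid, iv, profile, "isochore_border")
    return _unknown("")


def classify_all(
    genome,
    regions: Sequence,
    flank_len: int = 100_000,
    threshold_pp: float = 2.0,
    min_usable_fraction: float = 0.5,
    border_rule: str = "both",
) -> list[IsochoreCall]:
    """Classify every region; per-region errors degrade to unknown with a
    reason instead of aborting the batch."""
    calls = []
    for region in regions:
        try:
            calls.append(
                classify_region(
                    genome,
                    region,
                    flank_len=flank_len,
                    threshold_pp=threshold_pp,
                    min_usable_fraction=min_usable_fraction,
                    border_rule=border_rule,
                )
            )
        except ValueError as exc:
            iv = getattr(region, "interval", region)
            rid = getattr(region, "id", f"{iv.chrom}_{iv.start}")
            profile = GcProfile(None, None, None, 0, 0, 0)
            calls.append(IsochoreCall(rid, iv, profile, "unknown", str(exc)))
    return calls


def label_counts(calls: Sequence[IsochoreCall]) -> dict:
    counts = {label: 0 for label in LABELS}
    for call in calls:
        counts[call.label] += 1
    return counts
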