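"""Shared fixtures and brute-force oracles.

The oracles deliberately take the dumbest correct route — per-base boolean
membership arrays — so they stay independent of the sweep-line
implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from snpdesert.intervals import GenomicInterval


def cover_array(intervals, size: int, chrom: str) -> np.ndarray:
    """Boolean membership array for one chromosome."""
    mask = np.zeros(size, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            mask[iv.start : iv.end] = True
    return mask


def array_to_intervals(mask: np.ndarray, chrom: str) -> list[GenomicInterval]:
    """Maximal runs of True as intervals."""
    out = []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for s, e in zip(starts, ends):
        out.append(GenomicInterval(chrom, int(s), int(e)))
    return out


def chroms_of(intervals) -> list[str]:
    return sorted({iv.chrom for iv in intervals})


def random_intervals(rng, n, chroms=("chrA", "chrB"), max_coord=5000,
                     max_len=300) -> list[GenomicInterval]:
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, max_coord - 1))
        length = int(rng.integers(1, max_len + 1))
        out.append(GenomicInterval(chrom, start, min(start + length, max_coord)))
    return out


@pytest.fixture(scope="session")
def csfr_catalog():
    from snpdesert.catalog import load_csfr_catalog

    return load_csfr_catalog()


@pytest.fixture(scope="session")
def cvfr_catalog():
    from snpdesert.catalog import load_cvfr_catalog

    return load_cvfr_catalog()


@pytest.fixture(scope="session")
def catalog_csfr_calls(csfr_catalog):
    """CSFR calls reconstructed from the packaged catalog via the pipeline."""
    from snpdesert.catalog import bracketing_snps
    from snpdesert.regions import call_csfrs

    snps = bracketing_snps(csfr_catalog)
    return call_csfrs(snps, [], min_len=100_000)
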