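"""Read-alignment QC: qualifying-read filter, N50, and FACS enrichment factor.

A *qualifying read* is a primary alignment spanning at least 20 kb of
reference with mapping quality at least 20 (both thresholds inclusive) — the
minimum criteria for analogue detection on a nanopore read.  N50 is computed
by sorting qualifying read lengths in descending order and returning the
length of the first read at which the running cumulative sum reaches half of
the total (ties included via >=).

The FACS (FINE) enrichment factor compares, between a sorted and a bulk
sample, the fraction of qualifying reads whose alignment midpoint falls in the
ecDNA interval: enrichment = ratio_sorted / ratio_bulk.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .layout import Region

MIN_ALIGNED_LENGTH = 20_000
MIN_MAPQ = 20


def qualifying_reads(
    reads: pd.DataFrame,
    min_aligned_length: int = MIN_ALIGNED_LENGTH,
    min_mapq: int = MIN_MAPQ,
) -> pd.DataFrame:
    """Filter to reads with aligned length and MAPQ at or above the thresholds."""
    length = reads["end"] - reads["start"]
    mask = (length >= min_aligned_length) & (reads["mapq"] >= min_mapq)
    return reads[mask].reset_index(drop=True)


def n50(lengths: Sequence[int]) -> int:
    """N50 of a set of read lengths.

    Sort descending, accumulate, and return the length of the first read
    whose running sum is >= half the total.  Order-invariant; errors on
    empty input.
    """
    arr = np.sort(np.asarray(lengths))[::-1]
    if arr.size == 0:
        raise ValueError("N50 of empty read set")
    csum = np.cumsum(arr)
    idx = int(np.searchsorted(csum, csum[-1] / 2, side="left"))
    return int(arr[idx])


def region_read_ratio(reads: pd.DataFrame, region: Region) -> float:
    """Fraction of reads whose alignment midpoint lies in ``region``."""
    if len(reads) == 0:
        raise ValueError("empty read set")
    mid = (reads["start"] + reads["end"]) // 2
    in_region = (
        (reads["chrom"] == region.chrom) & (mid >= region.start) & (mid < region.end)
    )
    return float(in_region.sum() / len(reads))


def enrichment_factor(
    sorted_reads: pd.DataFrame, bulk_reads: pd.DataFrame, region: Region
) -> float:
    """Fold enrichment of region-mapped reads, sorted sample over bulk.

    Both inputs must already be qualifying reads.  Errors when the bulk
    sample has no region-mapped reads (undefined baseline).
    """
    r_sorted = region_read_ratio(sorted_reads, region)
    r_bulk = region_read_ratio(bulk_reads, region)
    if r_bulk == 0:
        raise ValueError("no region-mapped reads in baseline (bulk) sample")
    return r_sorted / r_bulk


def qc_report(
    reads: pd.DataFrame,
    min_aligned_length: int = MIN_ALIGNED_LENGTH,
    min_mapq: int = MIN_MAPQ,
) -> dict:
    """Counts before/after the qualifying filter plus N50 of the survivors."""
    kept = qualifying_reads(reads, min_aligned_length, min_mapq)
    lengths = (kept["end"] - kept["start"]).to_numpy()
    return {
        "n_reads": int(len(reads)),
        "n_qualifying": int(len(kept)),
        "min_aligned_length": min_aligned_length,
        "min_mapq": min_mapq,
        "n50": int(n50(lengths)) if len(kept) else None,
    }
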