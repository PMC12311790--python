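"""Replication-origin density per segment and uniformity testing.

forkSense origin calls (intervals between diverging fork pairs on one read)
are reduced to their midpoints, grouped into 50-kb segments, and normalized by
the number of qualifying reads per segment to correct for uneven read depth.
Uniformity of the origin distribution over a region is assessed with a
one-sample Kolmogorov–Smirnov test, in two variants:

* ``counts`` (default) — the empirical CDF of origins accumulated over the
  ordered 50-kb segments is compared against the uniform CDF over segments;
* ``positions`` — raw origin midpoints are tested against a uniform
  distribution over the region.

GC content per segment can be annotated from a FASTA; G-quadruplex scores are
consumed as an optional pre-computed BED, never recomputed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .layout import GenomeLayout, Region


def _midpoints(origins: pd.DataFrame) -> pd.Series:
    return (origins["start"] + origins["end"]) // 2


def _in_region(origins: pd.DataFrame, region: Region | None) -> pd.Series:
    if region is None:
        return pd.Series(True, index=origins.index)
    mid = _midpoints(origins)
    return (
        (origins["chrom"] == region.chrom)
        & (mid >= region.start)
        & (mid < region.end)
    )


def count_origin_reads(
    origins: pd.DataFrame, region: Region | None = None
) -> tuple[int, int]:
    """(distinct reads with >= 1 origin call in the region, origin calls).

    Membership is by call midpoint; a read with calls inside and outside the
    region is counted once for the region.
    """
    sub = origins[_in_region(origins, region)]
    return int(sub["read_id"].nunique()), int(len(sub))


def _segment_edges(region: Region, width: int) -> np.ndarray:
    return np.arange(region.start, region.end + width, width).clip(max=region.end)


def normalized_origin_density(
    origins: pd.DataFrame,
    qualifying_reads: pd.DataFrame,
    layout: GenomeLayout,
    segment_width: int = 50_000,
    region_name: str = "ecDNA",
) -> pd.DataFrame:
    """Per-segment origin counts normalized by qualifying read depth.

    Reads must already be filtered to the qualifying set (>= 20 kb aligned,
    MAPQ >= 20); both origins and reads enter a segment by midpoint.  Density
    is origins/reads; segments with zero qualifying reads get NaN density and
    ``depth_undefined = True``.
    """
    region = layout.region(region_name)
    edges = _segment_edges(region, segment_width)
    omid = _midpoints(origins[_in_region(origins, region)]).to_numpy()
    rsub = qualifying_reads[qualifying_reads["chrom"] == region.chrom]
    rmid = ((rsub["start"] + rsub["end"]) // 2).to_numpy()
    rmid = rmid[(rmid >= region.start) & (rmid < region.end)]
    ocount, _ = np.histogram(omid, bins=edges)
    rcount, _ = np.histogram(rmid, bins=edges)
    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(rcount > 0, ocount / np.maximum(rcount, 1), np.nan)
    return pd.DataFrame(
        {
            "chrom": region.chrom,
            "start": edges[:-1],
            "end": edges[1:],
            "origins": ocount,
            "reads": rcount,
            "density": density,
            "depth_undefined": rcount == 0,
        }
    )


def ks_uniformity(
    origins: pd.DataFrame,
    region: Region,
    segment_width: int = 50_000,
    variant: str = "counts",
) -> dict:
    """One-sample two-sided KS test of origin placement against uniformity.

    ``variant="counts"``: D is the maximum gap between the origin CDF
    accumulated over ordered segments and the uniform CDF over segments
    (evaluated at segment boundaries); the p-value uses the one-sample KS
    null with n = number of origins.  ``variant="positions"``: origin
    midpoints, rescaled to [0, 1] over the region, tested directly against
    the uniform distribution.  The report records the variant used.
    """
    if region.length <= 0:
        raise ValueError("empty region")
    sub = origins[_in_region(origins, region)]
    n = len(sub)
    if n == 0:
        raise ValueError("no origins in region")
    mids = _midpoints(sub).to_numpy()
    if variant == "counts":
        edges = _segment_edges(region, segment_width)
        counts, _ = np.histogram(mids, bins=edges)
        ecdf = np.cumsum(counts) / n
        # uniform mass proportional to segment width (last segment may be short)
        uni = (edges[1:] - region.start) / region.length
        d = float(np.max(np.abs(ecdf - uni)))
        p = float(stats.kstwo.sf(d, n))
    elif variant == "positions":
        x = (mids - region.start) / region.length
        res = stats.kstest(x, "uniform")
        d, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown uniformity variant {variant!r}")
    return {"variant": variant, "statistic": d, "pvalue": p, "n_origins": n}


def gc_per_segment(
    fasta_path: str,
    layout: GenomeLayout,
    segment_width: int = 50_000,
    region_name: str = "ecDNA",
) -> pd.DataFrame:
    """GC fraction per segment: (#G + #C) / (#ACGT); ambiguous bases excluded."""
    from pyfaidx import Fasta

    region = layout.region(region_name)
    fa = Fasta(fasta_path)
    if region.chrom not in fa:
        raise ValueError(f"no sequence for {region.chrom!r} in {fasta_path}")
    edges = _segment_edges(region, segment_width)
    rows = []
    for s, e in zip(edges[:-1], edges[1:]):
        seq = str(fa[region.chrom][int(s):int(e)]).upper()
        gc = seq.count("G") + seq.count("C")
        acgt = gc + seq.count("A") + seq.count("T")
        rows.append((region.chrom, int(s), int(e), gc / acgt if acgt else np.nan))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gc_fraction"])
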