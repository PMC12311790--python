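"""Five-fraction Repli-seq binning: counts, RPKM, and per-bin fraction distributions.

Repli-seq sorts BrdU-labelled cells into five S-phase fractions (S1 early →
S5 late) and sequences each fraction.  This module turns per-fraction coverage
into, per 10-kb bin, the categorical distribution p = (p1..p5) of where in S
phase that bin replicates — the input of the synchronicity statistic.

Reads are assigned to exactly one bin by alignment midpoint (default); a
bp-weighted overlap mode is available for bedGraph input whose intervals
straddle bin edges.  Library size is normalized away with RPKM before the
per-bin proportions are formed, so p is invariant to per-fraction depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io
from .layout import GenomeLayout, bin_bounds, n_bins

FRACTION_LABELS = ("S1", "S2", "S3", "S4", "S5")


@dataclass
class FractionCoverage:
    """Per-(fraction, bin) read counts plus per-fraction totals."""

    fractions: tuple[str, ...]
    counts: dict[str, np.ndarray]  # chrom -> (n_fractions, n_bins)
    totals: np.ndarray  # (n_fractions,) total mapped units per fraction
    bin_width: int

    def __post_init__(self) -> None:
        if len(self.fractions) != 5:
            raise ValueError(f"expected exactly five fractions, got {len(self.fractions)}")
        if np.any(self.totals < 0):
            raise ValueError("negative fraction totals")
        for chrom, arr in self.counts.items():
            if arr.shape[0] != len(self.fractions):
                raise ValueError(f"count matrix for {chrom} has wrong fraction axis")
            if np.any(arr < 0):
                raise ValueError(f"negative counts on {chrom}")


@dataclass
class BinDistribution:
    """Per-bin categorical distribution over the five S-phase fractions.

    ``probs[chrom]`` is an ``(n_bins, 5)`` array; rows of bins with zero reads
    across all fractions are NaN and flagged ``defined == False``.
    """

    probs: dict[str, np.ndarray]
    defined: dict[str, np.ndarray]
    bin_width: int
    fractions: tuple[str, ...] = FRACTION_LABELS

    def n_defined(self) -> int:
        return int(sum(mask.sum() for mask in self.defined.values()))


def _assign_midpoint(
    starts: np.ndarray, ends: np.ndarray, values: np.ndarray, width: int, nb: int
) -> np.ndarray:
    # left-median midpoint: an interval whose exact midpoint falls on a bin
    # boundary stays in the earlier bin
    mids = (starts + ends - 1) // 2
    idx = np.clip(mids // width, 0, nb - 1)
    return np.bincount(idx, weights=values, minlength=nb)


def _assign_overlap(
    starts: np.ndarray, ends: np.ndarray, values: np.ndarray, width: int, nb: int
) -> np.ndarray:
    out = np.zeros(nb)
    for s, e, v in zip(starts, ends, values):
        span = e - s
        if span <= 0:
            continue
        first, last = s // width, (e - 1) // width
        for b in range(first, min(last, nb - 1) + 1):
            bs, be = b * width, (b + 1) * width
            ov = min(e, be) - max(s, bs)
            out[b] += v * ov / span
    return out


def bin_counts(
    sources: Mapping[str, str | Path | pd.DataFrame],
    layout: GenomeLayout,
    width: int = 10_000,
    mode: str = "midpoint",
) -> FractionCoverage:
    """Count per-fraction coverage into fixed-width bins.

    ``sources`` maps the five fraction labels (early → late order) to either a
    bedGraph path (value column taken as read counts over the interval) or an
    alignment-summary DataFrame (one unit per read).  ``mode`` is ``"midpoint"``
    (each unit lands in the bin containing the interval midpoint) or
    ``"overlap"`` (bp-weighted split across bins; bedGraph-style input only).
    """
    if len(sources) != 5:
        raise ValueError(f"expected five fraction sources, got {len(sources)}")
    if mode not in ("midpoint", "overlap"):
        raise ValueError(f"unknown assignment mode {mode!r}")
    fractions = tuple(sources)
    nb = {chrom: n_bins(layout, chrom, width) for chrom in layout.chrom_names}
    counts = {chrom: np.zeros((5, n)) for chrom, n in nb.items()}
    totals = np.zeros(5)
    for fi, (label, src) in enumerate(sources.items()):
        if isinstance(src, (str, Path)):
            df = io.read_bedgraph(src)
        else:
            df = src.copy()
            if "value" not in df.columns:
                df["value"] = 1.0
        unknown = sorted(set(df["chrom"]) - set(layout.chromosomes))
        if unknown:
            raise ValueError(f"fraction {label!r}: unknown chromosomes {unknown}")
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            values = sub["value"].to_numpy(dtype=float)
            assign = _assign_midpoint if mode == "midpoint" else _assign_overlap
            counts[chrom][fi] += assign(starts, ends, values, width, nb[chrom])
        totals[fi] += float(df["value"].sum())
    return FractionCoverage(fractions, counts, totals, width)


def rpkm(coverage: FractionCoverage, width: int | None = None) -> dict[str, np.ndarray]:
    """Reads-per-kilobase-per-million per (fraction, bin).

    RPKM = count / ((width/1e3) × (total/1e6)) with the nominal bin width; see
    :func:`rpkm_with_layout` for true trailing-bin widths.  A fraction with
    zero total mapped reads is an error.
    """
    width = width or coverage.bin_width
    for fi, label in enumerate(coverage.fractions):
        if coverage.totals[fi] <= 0:
            raise ValueError(f"fraction {label!r} has zero total mapped reads")
    out: dict[str, np.ndarray] = {}
    scale = coverage.totals[:, None] / 1e6  # (5,1)
    for chrom, arr in coverage.counts.items():
        out[chrom] = arr / (width / 1e3) / scale
    return out


def rpkm_with_layout(
    coverage: FractionCoverage, layout: GenomeLayout
) -> dict[str, np.ndarray]:
    """Like :func:`rpkm` but uses true (possibly short) trailing-bin widths."""
    width = coverage.bin_width
    for fi, label in enumerate(coverage.fractions):
        if coverage.totals[fi] <= 0:
            raise ValueError(f"fraction {label!r} has zero total mapped reads")
    scale = coverage.totals[:, None] / 1e6
    out: dict[str, np.ndarray] = {}
    for chrom, arr in coverage.counts.items():
        nb = arr.shape[1]
        L = layout.length(chrom)
        widths = np.minimum((np.arange(nb) + 1) * width, L) - np.arange(nb) * width
        out[chrom] = arr / (widths / 1e3) / scale
    return out


def fraction_distributions(rpkm_values: Mapping[str, np.ndarray], bin_width: int = 10_000) -> BinDistribution:
    """Normalize per-bin RPKM across the five fractions into p = (p1..p5).

    Bins with zero RPKM in every fraction are flagged undefined (NaN row),
    not an error: zero-read bins later disqualify null fragments.
    """
    probs: dict[str, np.ndarray] = {}
    defined: dict[str, np.ndarray] = {}
    for chrom, arr in rpkm_values.items():
        total = arr.sum(axis=0)
        mask = total > 0
        p = np.full((arr.shape[1], 5), np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[mask] = (arr[:, mask] / total[mask]).T
        probs[chrom] = p
        defined[chrom] = mask
    return BinDistribution(probs, defined, bin_width)


def proportion_tracks(
    dist: BinDistribution,
    layout: GenomeLayout,
    out_dir: str | Path,
    prefix: str = "proportion",
    scale_to_max: bool = False,
) -> dict[str, Path]:
    """Write one bedGraph of p_i per fraction; undefined bins are omitted.

    ``scale_to_max`` rescales all five tracks by the global maximum value —
    a display convenience only, never used in statistics.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    peak = 1.0
    if scale_to_max:
        peak = max(
            (np.nanmax(p) for p in dist.probs.values() if p.size and np.any(~np.isnan(p))),
            default=1.0,
        )
    paths: dict[str, Path] = {}
    for fi, label in enumerate(dist.fractions):
        rows = []
        for chrom in layout.chrom_names:
            if chrom not in dist.probs:
                continue
            p = dist.probs[chrom][:, fi]
            mask = dist.defined[chrom]
            for b in np.flatnonzero(mask):
                s, e = bin_bounds(int(b), dist.bin_width, layout.length(chrom))
                rows.append((chrom, s, e, p[b] / peak))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
        paths[label] = io.write_bedgraph(df, out_dir / f"{prefix}_{label}.bedgraph")
    return paths


def distributions_table(dist: BinDistribution, layout: GenomeLayout) -> pd.DataFrame:
    """Per-bin TSV-ready table: chrom, start, end, p1..p5, defined."""
    rows = []
    for chrom in layout.chrom_names:
        if chrom not in dist.probs:
            continue
        p = dist.probs[chrom]
        mask = dist.defined[chrom]
        for b in range(p.shape[0]):
            s, e = bin_bounds(b, dist.bin_width, layout.length(chrom))
            rows.append((chrom, s, e, *p[b], bool(mask[b])))
    cols = ["chrom", "start", "end", *[f"p{i+1}" for i in range(5)], "defined"]
    return pd.DataFrame(rows, columns=cols)


def distributions_from_table(df: pd.DataFrame, layout: GenomeLayout, bin_width: int) -> BinDistribution:
    """Inverse of :func:`distributions_table` (round-trips the TSV output)."""
    probs: dict[str, np.ndarray] = {}
    defined: dict[str, np.ndarray] = {}
    pcols = [f"p{i+1}" for i in range(5)]
    for chrom in layout.chrom_names:
        nb = n_bins(layout, chrom, bin_width)
        p = np.full((nb, 5), np.nan)
        mask = np.zeros(nb, dtype=bool)
        sub = df[df["chrom"] == chrom]
        idx = (sub["start"].to_numpy() // bin_width).astype(int)
        p[idx] = sub[pcols].to_numpy(dtype=float)
        mask[idx] = sub["defined"].to_numpy(dtype=bool)
        p[~mask] = np.nan
        probs[chrom] = p
        defined[chrom] = mask
    return BinDistribution(probs, defined, bin_width)
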