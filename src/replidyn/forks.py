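"""forkSense downstream processing: fork speed, filtering, and group comparisons.

A nanopore read pulse-labelled with EdU (6 min) then BrdU (6 min) carries, per
active fork, a labelled track whose length divided by the total pulse time
gives the fork speed in kb/min.  forkSense emits one BED-like file per fork
direction (leftForks / rightForks) plus per-fork stall scores in [0, 1]; a
track that abuts a read end is incomplete (its true extent is censored) and is
excluded, as are forks without a stall score and forks on chrY.

Speed outliers are removed with the Tukey fence: values outside
[Q1 - 1.5*IQR, Q3 + 1.5*IQR], quartiles by linear interpolation of the sorted
sample.  Group comparisons use Welch's two-sided t-test for speeds and the
two-sided Wilcoxon rank-sum test for stall scores (exact permutation
distribution for small samples, tie-corrected normal approximation otherwise).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .layout import GenomeLayout

FORK_COLUMNS = [
    "chrom", "start", "end", "read_id", "direction", "stall",
    "complete", "sample", "replicate",
]

EXACT_RANKSUM_MAX_N = 12


@dataclass(frozen=True)
class PulseConfig:
    """Durations of the two analogue pulses, minutes."""

    edu_minutes: float = 6.0
    brdu_minutes: float = 6.0

    def __post_init__(self) -> None:
        if self.edu_minutes <= 0 or self.brdu_minutes <= 0:
            raise ValueError("pulse durations must be positive")

    @property
    def total_minutes(self) -> float:
        return self.edu_minutes + self.brdu_minutes


@dataclass(frozen=True)
class ForkDialect:
    """Column layout of a forkSense-style BED file (0-based column indices).

    forkSense column layouts vary between versions, so the mapping is config:
    ``read_start``/``read_end`` columns, when present, drive the completeness
    rule (a track whose boundary coincides with the read boundary is
    incomplete); otherwise an explicit ``complete`` flag column may be named.
    """

    chrom: int = 0
    start: int = 1
    end: int = 2
    read_id: int = 3
    read_start: int | None = 4
    read_end: int | None = 5
    stall: int | None = 6
    complete_flag: int | None = None

    def max_col(self) -> int:
        cols = [self.chrom, self.start, self.end, self.read_id,
                self.read_start, self.read_end, self.stall, self.complete_flag]
        return max(c for c in cols if c is not None)


def _parse_fork_file(
    path: str | Path,
    direction: str,
    dialect: ForkDialect,
    sample: str,
    replicate: str,
) -> pd.DataFrame:
    rows = []
    bad = 0
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith(("#", "track")):
            continue
        parts = line.split()
        if len(parts) <= dialect.max_col():
            bad += 1
            continue
        try:
            chrom = parts[dialect.chrom]
            start = int(parts[dialect.start])
            end = int(parts[dialect.end])
            read_id = parts[dialect.read_id]
            stall = np.nan
            if dialect.stall is not None:
                tok = parts[dialect.stall]
                if tok not in (".", "NA", "nan", ""):
                    stall = float(tok)
            if dialect.complete_flag is not None:
                complete = parts[dialect.complete_flag].lower() in ("1", "true", "t")
            elif dialect.read_start is not None and dialect.read_end is not None:
                rs = int(parts[dialect.read_start])
                re_ = int(parts[dialect.read_end])
                complete = start > rs and end < re_
            else:
                complete = True
        except (ValueError, IndexError):
            bad += 1
            continue
        if end <= start:
            bad += 1
            continue
        if not np.isnan(stall) and not (0.0 <= stall <= 1.0):
            raise ValueError(f"{path}: stall score {stall} outside [0, 1]")
        rows.append((chrom, start, end, read_id, direction, stall, complete, sample, replicate))
    if bad:
        import warnings

        warnings.warn(f"{path}: skipped {bad} malformed row(s)", stacklevel=2)
    return pd.DataFrame(rows, columns=FORK_COLUMNS)


def parse_forksense(
    left_files: Iterable[str | Path] = (),
    right_files: Iterable[str | Path] = (),
    origin_files: Iterable[str | Path] = (),
    dialect: ForkDialect | None = None,
    sample: str = "sample",
    replicate: str = "rep1",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse forkSense-dialect BEDs into fork and origin tables.

    Direction is taken from which list a file appears in (leftForks /
    rightForks).  Returns ``(forks, origins)``; origins carry chrom, start,
    end, read_id, sample, replicate.
    """
    dialect = dialect or ForkDialect()
    parts = [
        _parse_fork_file(p, "leftward", dialect, sample, replicate) for p in left_files
    ] + [
        _parse_fork_file(p, "rightward", dialect, sample, replicate) for p in right_files
    ]
    forks = (
        pd.concat(parts, ignore_index=True)
        if parts
        else pd.DataFrame(columns=FORK_COLUMNS)
    )
    origin_rows = []
    for path in origin_files:
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            p = line.split()
            if len(p) < 4:
                continue
            origin_rows.append((p[0], int(p[1]), int(p[2]), p[3], sample, replicate))
    origins = pd.DataFrame(
        origin_rows, columns=["chrom", "start", "end", "read_id", "sample", "replicate"]
    )
    return forks, origins


def fork_speed(
    forks: pd.DataFrame | pd.Series, pulse: PulseConfig = PulseConfig()
) -> pd.Series | float:
    """Fork speed in kb/min: track length / total pulse minutes.

    Incomplete (read-end truncated) forks have a censored track length and
    must be filtered out first; passing one is an error.
    """
    if isinstance(forks, pd.Series):
        if not forks["complete"]:
            raise ValueError("fork speed undefined for incomplete (truncated) track")
        return float((forks["end"] - forks["start"]) / 1000.0 / pulse.total_minutes)
    if not forks["complete"].all():
        raise ValueError("fork speed undefined for incomplete (truncated) tracks; filter first")
    return (forks["end"] - forks["start"]) / 1000.0 / pulse.total_minutes


def filter_forks(forks: pd.DataFrame, exclude_chroms: Sequence[str] = ("chrY",)) -> pd.DataFrame:
    """Keep complete forks with a stall score, off the excluded chromosomes."""
    mask = (
        forks["complete"].astype(bool)
        & forks["stall"].notna()
        & ~forks["chrom"].isin(exclude_chroms)
    )
    return forks[mask].reset_index(drop=True)


def iqr_filter(values: Sequence[float]) -> tuple[np.ndarray, float, float]:
    """Tukey-fence outlier mask: True where a value is retained.

    Q1/Q3 by linear interpolation of the sorted sample; bounds Q1 - 1.5*IQR
    and Q3 + 1.5*IQR; values strictly outside are removed.  Not idempotent:
    re-applying to the retained subset may remove further points.  Requires
    at least 4 values.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise ValueError(f"IQR filter needs at least 4 values, got {arr.size}")
    q1, q3 = np.percentile(arr, [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return (arr >= lo) & (arr <= hi), float(lo), float(hi)


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact permutation p-value of the rank-sum statistic."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = len(a)
    obs = ranks[:n1].sum()
    mean = ranks.sum() * n1 / len(pooled)
    obs_dev = abs(obs - mean)
    count = 0
    total = comb(len(pooled), n1)
    for combo in itertools.combinations(range(len(pooled)), n1):
        if abs(ranks[list(combo)].sum() - mean) >= obs_dev - 1e-12:
            count += 1
    return count / total


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Exact permutation distribution when n1 + n2 <= 12 (handles ties), else
    the tie-corrected normal approximation (Mann–Whitney U, asymptotic).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) + len(b) <= EXACT_RANKSUM_MAX_N:
        u = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").statistic
        return float(u), _exact_ranksum_p(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def group_compare(
    groups: Mapping[str, Sequence[float]], statistic: str = "speed"
) -> dict:
    """Compare two groups of per-fork values.

    ``statistic == "speed"`` uses Welch's two-sided t-test (unequal
    variances); ``"stall"`` uses the two-sided Wilcoxon rank-sum test.  The
    report carries n, mean and median per group plus the percent difference
    of means relative to the first group.
    """
    if len(groups) != 2:
        raise ValueError(f"group_compare expects exactly two groups, got {len(groups)}")
    (name_a, va), (name_b, vb) = groups.items()
    a = np.asarray(va, dtype=float)
    b = np.asarray(vb, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if statistic == "speed":
        res = stats.ttest_ind(a, b, equal_var=False)
        stat, p, test = float(res.statistic), float(res.pvalue), "welch_t"
        if np.isnan(stat):  # identical constant groups: zero variance
            stat, p = 0.0, 1.0
    elif statistic == "stall":
        stat, p = rank_sum_test(a, b)
        test = "wilcoxon_ranksum"
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    pct = (mean_a - mean_b) / mean_a * 100.0 if mean_a != 0 else np.nan
    return {
        "test": test,
        "statistic": stat,
        "pvalue": p,
        "groups": {
            name_a: {"n": len(a), "mean": mean_a, "median": float(np.median(a))},
            name_b: {"n": len(b), "mean": mean_b, "median": float(np.median(b))},
        },
        "percent_difference_of_means": float(pct),
    }


def assign_region(
    forks: pd.DataFrame, layout: GenomeLayout, region_name: str = "ecDNA"
) -> pd.Series:
    """Label forks by midpoint: ``ecDNA`` inside the named region,
    ``chr8-excluded`` elsewhere on that region's chromosome (dropped from
    two-group comparisons), ``chromosomal`` otherwise."""
    region = layout.region(region_name)
    mid = (forks["start"] + forks["end"]) / 2
    in_region = (forks["chrom"] == region.chrom) & (mid >= region.start) & (mid < region.end)
    on_chrom = forks["chrom"] == region.chrom
    labels = np.where(in_region, "ecDNA", np.where(on_chrom, "chr8-excluded", "chromosomal"))
    return pd.Series(labels, index=forks.index, name="region")


def per_chromosome_medians(
    forks: pd.DataFrame, pulse: PulseConfig = PulseConfig()
) -> pd.DataFrame:
    """Median fork speed per chromosome (filtered forks)."""
    speeds = fork_speed(forks, pulse)
    df = forks.assign(speed=speeds)
    out = (
        df.groupby("chrom", sort=False)["speed"]
        .agg(n="size", median="median", mean="mean")
        .reset_index()
    )
    return out


def segment_stats(
    forks: pd.DataFrame,
    layout: GenomeLayout,
    segment_width: int = 20_000,
    pulse: PulseConfig = PulseConfig(),
    region_name: str | None = None,
) -> pd.DataFrame:
    """Per-segment fork counts and mean speed / stall score.

    Forks are assigned to the segment containing their midpoint.  When
    ``region_name`` is given, segments tile that region from its start;
    otherwise they tile each chromosome from 0.  Empty segments are emitted
    with n = 0 and NaN means (flagged, no fabricated values).
    """
    speeds = fork_speed(forks, pulse)
    df = forks.assign(speed=speeds, mid=(forks["start"] + forks["end"]) // 2)
    rows = []
    if region_name is not None:
        region = layout.region(region_name)
        sub = df[
            (df["chrom"] == region.chrom)
            & (df["mid"] >= region.start)
            & (df["mid"] < region.end)
        ]
        edges = np.arange(region.start, region.end, segment_width)
        for s in edges:
            e = min(s + segment_width, region.end)
            seg = sub[(sub["mid"] >= s) & (sub["mid"] < e)]
            rows.append(_segment_row(region.chrom, s, e, seg))
    else:
        for chrom in layout.chrom_names:
            sub = df[df["chrom"] == chrom]
            L = layout.length(chrom)
            for s in range(0, L, segment_width):
                e = min(s + segment_width, L)
                seg = sub[(sub["mid"] >= s) & (sub["mid"] < e)]
                rows.append(_segment_row(chrom, s, e, seg))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n", "mean_speed", "mean_stall", "empty"]
    )


def _segment_row(chrom: str, s: int, e: int, seg: pd.DataFrame) -> tuple:
    n = len(seg)
    if n == 0:
        return (chrom, s, e, 0, np.nan, np.nan, True)
    return (
        chrom, s, e, n,
        float(seg["speed"].mean()),
        float(seg["stall"].mean()),
        False,
    )
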