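"""Readers and writers for the plain-text formats the pipeline exchanges.

bedGraph (4 columns), chrom.sizes, alignment-summary TSV and BED-like fork /
origin files are all whitespace tables; pandas does the heavy lifting here and
every writer emits a deterministic, header-commented text file.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

ALN_COLUMNS = ["read_id", "chrom", "start", "end", "mapq"]


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a 4-column bedGraph into (chrom, start, end, value)."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
        skip_blank_lines=True,
    )
    # tolerate a UCSC track line
    if len(df) and str(df.iloc[0]["chrom"]).startswith("track"):
        df = df.iloc[1:].reset_index(drop=True)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["value"] = df["value"].astype(float)
    return df


def write_bedgraph(
    df: pd.DataFrame, path: str | Path, header_comment: str | None = None
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(
            fh,
            sep="\t",
            header=False,
            index=False,
            columns=["chrom", "start", "end", "value"],
            float_format="%.10g",
        )
    return path


def read_alignment_summary(path: str | Path) -> pd.DataFrame:
    """Read an alignment-summary TSV (read_id, chrom, start, end, mapq)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = set(ALN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"alignment summary {path} missing columns: {sorted(missing)}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    return path


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_chrom_sizes(chromosomes: Mapping[str, int], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, length in chromosomes.items():
            fh.write(f"{name}\t{length}\n")
    return path
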