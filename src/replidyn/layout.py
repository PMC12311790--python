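"""Genome coordinate plumbing: chromosomes, named regions, and bin grids.

All coordinates are 0-based half-open (BED convention).  Figure-legend style
1-based coordinates must be converted before they enter a :class:`GenomeLayout`.
Chromosomes are tiled from position 0 by fixed-width half-open bins; a trailing
partial bin at the chromosome end is kept as a short bin rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Region",
    "GenomeLayout",
    "load_chrom_sizes",
    "bins_overlapping",
    "n_bins",
    "bin_bounds",
]


@dataclass(frozen=True)
class Region:
    """A named genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty or inverted region [{self.start}, {self.end})")
        if self.start < 0:
            raise ValueError(f"negative region start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def contains_point(self, chrom: str, pos: float) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass
class GenomeLayout:
    """Ordered chromosomes plus named regions (e.g. the ecDNA interval).

    Parameters
    ----------
    chromosomes
        Mapping of chromosome name to length in bp, in genome order.
    regions
        Named intervals; analyses that compare the ecDNA interval against the
        rest of the genome expect a region named ``"ecDNA"``.
    """

    chromosomes: dict[str, int]
    regions: dict[str, Region] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, length in self.chromosomes.items():
            if int(length) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self.chromosomes = {str(k): int(v) for k, v in self.chromosomes.items()}
        for rname, region in self.regions.items():
            self._check_region(rname, region)

    def _check_region(self, name: str, region: Region) -> None:
        if region.chrom not in self.chromosomes:
            raise ValueError(f"region {name!r} on unknown chromosome {region.chrom!r}")
        if region.end > self.chromosomes[region.chrom]:
            raise ValueError(
                f"region {name!r} [{region.start}, {region.end}) exceeds "
                f"{region.chrom} length {self.chromosomes[region.chrom]}"
            )

    def add_region(self, name: str, chrom: str, start: int, end: int) -> Region:
        region = Region(chrom, int(start), int(end))
        self._check_region(name, region)
        self.regions[name] = region
        return region

    def length(self, chrom: str) -> int:
        try:
            return self.chromosomes[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chromosomes)

    def region(self, name: str) -> Region:
        try:
            return self.regions[name]
        except KeyError:
            raise KeyError(f"no region named {name!r} in layout") from None


def load_chrom_sizes(source: str | Path | Iterable[str]) -> GenomeLayout:
    """Parse a two-column ``chrom.sizes`` table into a :class:`GenomeLayout`.

    ``source`` is a path or an iterable of lines.  Blank lines and ``#``
    comments are skipped; duplicate chromosome names and malformed rows are
    rejected with the offending line number.
    """
    if isinstance(source, (str, Path)):
        lines = Path(source).read_text().splitlines()
    else:
        lines = list(source)
    chroms: dict[str, int] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"chrom.sizes line {lineno}: expected 'name\\tlength', got {raw!r}")
        name = parts[0]
        try:
            length = int(parts[1])
        except ValueError:
            raise ValueError(f"chrom.sizes line {lineno}: length {parts[1]!r} is not an integer")
        if length <= 0:
            raise ValueError(f"chrom.sizes line {lineno}: non-positive length for {name!r}")
        if name in chroms:
            raise ValueError(f"chrom.sizes line {lineno}: duplicate chromosome {name!r}")
        chroms[name] = length
    if not chroms:
        raise ValueError("no chromosomes in chrom.sizes input")
    return GenomeLayout(chroms)


def n_bins(layout: GenomeLayout, chrom: str, width: int) -> int:
    """Number of ``width``-bp bins tiling ``chrom`` (last bin may be short)."""
    if width <= 0:
        raise ValueError("bin width must be positive")
    return -(-layout.length(chrom) // width)


def bin_bounds(index: int, width: int, chrom_length: int | None = None) -> tuple[int, int]:
    """Half-open coordinates of bin ``index`` on a grid of ``width`` bp."""
    start = index * width
    end = start + width
    if chrom_length is not None:
        end = min(end, chrom_length)
    return start, end


def bins_overlapping(
    layout: GenomeLayout, chrom: str, start: int, end: int, width: int
) -> np.ndarray:
    """Indices of all bins overlapping ``[start, end)`` on ``chrom``, in order.

    Raises a bounds error when the interval falls outside the chromosome.
    """
    length = layout.length(chrom)
    if start < 0 or end > length or end <= start:
        raise ValueError(
            f"interval [{start}, {end}) outside {chrom} bounds [0, {length})"
        )
    first = start // width
    last = (end - 1) // width
    return np.arange(first, last + 1, dtype=np.int64)
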