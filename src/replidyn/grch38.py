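"""GRCh38 (hg38, p14 primary assembly) autosome lengths.

Used to calibrate the genome-wide null-fragment sampler against the human
genome without shipping sequence data.
"""

from __future__ import annotations

from .layout import GenomeLayout

#: Autosome lengths in bp, chr1..chr22, GRCh38 primary assembly.
GRCH38_AUTOSOMES: dict[str, int] = {
    "chr1": 248_956_422,
    "chr2": 242_193_529,
    "chr3": 198_295_559,
    "chr4": 190_214_555,
    "chr5": 181_538_259,
    "chr6": 170_805_979,
    "chr7": 159_345_973,
    "chr8": 145_138_636,
    "chr9": 138_394_717,
    "chr10": 133_797_422,
    "chr11": 135_086_622,
    "chr12": 133_275_309,
    "chr13": 114_364_328,
    "chr14": 107_043_718,
    "chr15": 101_991_189,
    "chr16": 90_338_345,
    "chr17": 83_257_441,
    "chr18": 80_373_285,
    "chr19": 58_617_616,
    "chr20": 64_444_167,
    "chr21": 46_709_983,
    "chr22": 50_818_468,
}


def grch38_autosome_layout() -> GenomeLayout:
    """A :class:`GenomeLayout` of the 22 GRCh38 autosomes."""
    return GenomeLayout(dict(GRCH38_AUTOSOMES))
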