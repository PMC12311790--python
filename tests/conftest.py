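import numpy as np
import pandas as pd
import pytest

from replidyn.layout import GenomeLayout


@pytest.fixture
def toy_layout() -> GenomeLayout:
    """Two 30 Mb chromosomes with a 1.6 Mb ecDNA-like region on chr1."""
    layout = GenomeLayout({"chr1": 30_000_000, "chr2": 30_000_000})
    layout.add_region("ecDNA", "chr1", 20_000_000, 21_600_000)
    return layout


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251002)


def make_forks(rows) -> pd.DataFrame:
    """Fork table from (chrom, start, end, stall, complete) tuples."""
    return pd.DataFrame(
        [
            {
                "chrom": c,
                "start": s,
                "end": e,
                "read_id": f"r{i}",
                "direction": "rightward",
                "stall": stall,
                "complete": complete,
                "sample": "s",
                "replicate": "rep1",
            }
            for i, (c, s, e, stall, complete) in enumerate(rows)
        ]
    )
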