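"""Run configuration: one YAML file drives a full scenario.

Flags on the CLI mirror these keys and win over the file.  Widths are bp,
pulses minutes; regions are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    workdir: str = "replidyn_run"
    seed: int = 0

    # grids
    bin_width: int = 10_000
    fork_segment_width: int = 20_000
    origin_segment_width: int = 50_000

    # RQE null
    fragment_length: int = 1_600_000
    spacing: int = 10_000_000
    spacing_convention: str = "start"  # or "gap"
    end_exclusion: int = 5_000_000
    chromosome_whitelist: list[str] | None = None
    exclude_target_from_null: bool = True

    # thresholds
    min_aligned_length: int = 20_000
    min_mapq: int = 20

    # pulses, minutes
    edu_minutes: float = 6.0
    brdu_minutes: float = 6.0

    # regions: name -> [chrom, start, end]
    regions: dict = field(default_factory=dict)

    # synthetic scenario
    sim_n_chromosomes: int = 2
    sim_chrom_length: int = 30_000_000
    sim_depth: float = 500.0
    sim_kappa: float = 5.0
    sim_region_kappa: dict = field(default_factory=lambda: {"ecDNA": 0.0})
    sim_n_reads: int = 5_000
    sim_ecdna_read_weight: float = 1.0

    def __post_init__(self) -> None:
        for name in ("bin_width", "fork_segment_width", "origin_segment_width", "fragment_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fragment_length % self.bin_width:
            raise ValueError("fragment_length must be a multiple of bin_width")
        if self.spacing_convention not in ("start", "gap"):
            raise ValueError(f"unknown spacing convention {self.spacing_convention!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path
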