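"""Stage orchestration: simulate → bin → rqe → forks → origins → qc → report.

Each stage reads the previous stage's files from the work directory, writes
its outputs plus a machine-readable ``<stage>_summary.json``, and the report
stage only aggregates those summaries — it never computes statistics itself.
A missing dependency output raises :class:`StageDependencyError` naming the
stage to run first.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import binning, forks as forks_mod, io, origins as origins_mod, readqc, rqe, simulate
from .config import RunConfig
from .forks import ForkDialect, PulseConfig
from .layout import GenomeLayout, Region, load_chrom_sizes

STAGES = ("simulate", "bin", "rqe", "forks", "origins", "qc", "report")


class StageDependencyError(RuntimeError):
    """An input produced by an earlier stage is missing."""


def _need(path: Path, producer: str) -> Path:
    if not path.exists():
        raise StageDependencyError(
            f"missing {path.name}; run the {producer!r} stage first"
        )
    return path


def _write_summary(workdir: Path, stage: str, payload: dict) -> Path:
    path = workdir / f"{stage}_summary.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float))
    return path


def _load_layout(config: RunConfig, workdir: Path) -> GenomeLayout:
    layout = load_chrom_sizes(_need(workdir / "chrom.sizes", "simulate"))
    for name, (chrom, start, end) in config.regions.items():
        layout.add_region(name, chrom, int(start), int(end))
    return layout


def stage_simulate(config: RunConfig, workdir: Path) -> dict:
    ecdna = config.regions.get("ecDNA")
    if ecdna is None:
        # default scenario: asynchronous 1.6 Mb interval late on chr1
        ecdna = ["chr1", 20_000_000, 21_600_000]
        config.regions["ecDNA"] = ecdna
    layout = simulate.make_layout(
        config.sim_n_chromosomes, config.sim_chrom_length, tuple(ecdna), config.seed
    )
    field = simulate.make_timing_field(
        layout,
        config.bin_width,
        kappa=config.sim_kappa,
        region_kappa=config.sim_region_kappa,
        seed=config.seed,
    )
    _, _, paths = simulate.simulate_repliseq(
        layout, field, config.sim_depth, seed=config.seed + 1, out_dir=workdir
    )
    model = simulate.ForkSimModel(ecdna_read_weight=config.sim_ecdna_read_weight)
    simulate.simulate_fork_data(
        layout,
        model,
        n_reads=config.sim_n_reads,
        pulse=PulseConfig(config.edu_minutes, config.brdu_minutes),
        seed=config.seed + 2,
        out_dir=workdir,
    )
    payload = {
        "seed": config.seed,
        "n_chromosomes": config.sim_n_chromosomes,
        "n_reads": config.sim_n_reads,
        "depth": config.sim_depth,
        "kappa": config.sim_kappa,
        "region_kappa": config.sim_region_kappa,
    }
    _write_summary(workdir, "simulate", payload)
    return payload


def stage_bin(config: RunConfig, workdir: Path) -> dict:
    layout = _load_layout(config, workdir)
    sources = {
        label: _need(workdir / f"repliseq_{label}.bedgraph", "simulate")
        for label in binning.FRACTION_LABELS
    }
    coverage = binning.bin_counts(sources, layout, config.bin_width)
    values = binning.rpkm(coverage)
    dist = binning.fraction_distributions(values, config.bin_width)
    table = binning.distributions_table(dist, layout)
    io.write_tsv(table, workdir / "bin_distributions.tsv")
    binning.proportion_tracks(dist, layout, workdir)
    payload = {
        "n_bins": int(len(table)),
        "n_defined": dist.n_defined(),
        "totals": {l: float(t) for l, t in zip(coverage.fractions, coverage.totals)},
    }
    _write_summary(workdir, "bin", payload)
    return payload


def stage_rqe(config: RunConfig, workdir: Path) -> dict:
    layout = _load_layout(config, workdir)
    table = io.read_tsv(_need(workdir / "bin_distributions.tsv", "bin"))
    dist = binning.distributions_from_table(table, layout, config.bin_width)
    targets = {
        name: Region(chrom, int(s), int(e))
        for name, (chrom, s, e) in config.regions.items()
    }
    exclude = list(targets.values()) if config.exclude_target_from_null else []
    fragments = rqe.sample_null_fragments(
        layout,
        config.chromosome_whitelist,
        config.fragment_length,
        config.spacing,
        config.end_exclusion,
        config.spacing_convention,
        exclude_regions=exclude,
    )
    null = rqe.empirical_null(fragments, dist)
    io.write_tsv(
        pd.DataFrame(
            {
                "chrom": [f.chrom for f in null.fragments],
                "start": [f.start for f in null.fragments],
                "end": [f.end for f in null.fragments],
                "sigma": null.sigmas,
            }
        ),
        workdir / "null_sigmas.tsv",
    )
    report = {}
    rows = []
    for name, region in targets.items():
        frag = rqe.Fragment(region.chrom, region.start, region.end)
        result = rqe.fragment_sigma(frag, dist)
        p = rqe.tail_probability(null, result.sigma)
        report[name] = {
            "sigma": result.sigma,
            "tail_probability": p,
            "n_defined_bins": result.n_defined,
            "n_undefined_bins": result.n_undefined,
        }
        rows.append((name, region.chrom, region.start, region.end, result.sigma, p))
    io.write_tsv(
        pd.DataFrame(rows, columns=["region", "chrom", "start", "end", "sigma", "tail_p"]),
        workdir / "rqe_targets.tsv",
    )
    payload = {
        "n_sampled": null.n_sampled,
        "n_retained": null.n_retained,
        "null_sigma_mean": float(null.sigmas.mean()),
        "targets": report,
        "spacing_convention": config.spacing_convention,
    }
    _write_summary(workdir, "rqe", payload)
    return payload


def stage_forks(config: RunConfig, workdir: Path) -> dict:
    layout = _load_layout(config, workdir)
    pulse = PulseConfig(config.edu_minutes, config.brdu_minutes)
    fork_df, _ = forks_mod.parse_forksense(
        [_need(workdir / "leftForks.bed", "simulate")],
        [_need(workdir / "rightForks.bed", "simulate")],
        dialect=ForkDialect(),
    )
    io.write_tsv(fork_df, workdir / "forks_raw.tsv")
    kept = forks_mod.filter_forks(fork_df)
    speeds = forks_mod.fork_speed(kept, pulse)
    mask, lo, hi = forks_mod.iqr_filter(speeds)
    kept = kept[mask].reset_index(drop=True)
    speeds = speeds[mask].reset_index(drop=True)
    kept = kept.assign(speed=speeds, region=forks_mod.assign_region(kept, layout))
    io.write_tsv(kept, workdir / "forks_filtered.tsv")
    io.write_tsv(forks_mod.per_chromosome_medians(kept, pulse), workdir / "fork_chrom_medians.tsv")
    seg = forks_mod.segment_stats(kept, layout, config.fork_segment_width, pulse, "ecDNA")
    io.write_tsv(seg, workdir / "fork_segments_ecDNA.tsv")
    groups_speed = {
        "ecDNA": kept.loc[kept["region"] == "ecDNA", "speed"],
        "chromosomal": kept.loc[kept["region"] == "chromosomal", "speed"],
    }
    groups_stall = {
        "ecDNA": kept.loc[kept["region"] == "ecDNA", "stall"],
        "chromosomal": kept.loc[kept["region"] == "chromosomal", "stall"],
    }
    payload = {
        "n_raw": int(len(fork_df)),
        "n_filtered": int(len(kept)),
        "iqr_bounds": [lo, hi],
        "speed_comparison": forks_mod.group_compare(groups_speed, "speed"),
        "stall_comparison": forks_mod.group_compare(groups_stall, "stall"),
    }
    _write_summary(workdir, "forks", payload)
    return payload


def stage_origins(config: RunConfig, workdir: Path) -> dict:
    layout = _load_layout(config, workdir)
    _, origin_df = forks_mod.parse_forksense(
        origin_files=[_need(workdir / "origins.bed", "simulate")]
    )
    reads = io.read_alignment_summary(_need(workdir / "alignment_summary.tsv", "simulate"))
    qreads = readqc.qualifying_reads(reads, config.min_aligned_length, config.min_mapq)
    region = layout.region("ecDNA")
    density = origins_mod.normalized_origin_density(
        origin_df, qreads, layout, config.origin_segment_width, "ecDNA"
    )
    io.write_tsv(density, workdir / "origin_density_ecDNA.tsv")
    n_reads_genome, n_calls_genome = origins_mod.count_origin_reads(origin_df)
    n_reads_ec, n_calls_ec = origins_mod.count_origin_reads(origin_df, region)
    uniformity = origins_mod.ks_uniformity(
        origin_df, region, config.origin_segment_width, "counts"
    )
    payload = {
        "origin_reads_genome": n_reads_genome,
        "origin_calls_genome": n_calls_genome,
        "origin_reads_ecDNA": n_reads_ec,
        "origin_calls_ecDNA": n_calls_ec,
        "uniformity": uniformity,
    }
    _write_summary(workdir, "origins", payload)
    return payload


def stage_qc(config: RunConfig, workdir: Path) -> dict:
    reads = io.read_alignment_summary(_need(workdir / "alignment_summary.tsv", "simulate"))
    payload = readqc.qc_report(reads, config.min_aligned_length, config.min_mapq)
    sorted_path = workdir / "sorted" / "alignment_summary.tsv"
    if sorted_path.exists():
        layout = _load_layout(config, workdir)
        region = layout.region("ecDNA")
        sorted_reads = readqc.qualifying_reads(
            io.read_alignment_summary(sorted_path),
            config.min_aligned_length,
            config.min_mapq,
        )
        bulk = readqc.qualifying_reads(reads, config.min_aligned_length, config.min_mapq)
        payload["enrichment_factor"] = readqc.enrichment_factor(sorted_reads, bulk, region)
    _write_summary(workdir, "qc", payload)
    return payload


def stage_report(config: RunConfig, workdir: Path) -> dict:
    report = {}
    for stage in STAGES[:-1]:
        path = workdir / f"{stage}_summary.json"
        if path.exists():
            report[stage] = json.loads(path.read_text())
    (workdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "bin": stage_bin,
    "rqe": stage_rqe,
    "forks": stage_forks,
    "origins": stage_origins,
    "qc": stage_qc,
    "report": stage_report,
}


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Run the requested stages in dependency order; returns the summaries."""
    stages = list(stages) if stages else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    results = {}
    for stage in STAGES:
        if stage in stages:
            results[stage] = _STAGE_FUNCS[stage](config, workdir)
    return results
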