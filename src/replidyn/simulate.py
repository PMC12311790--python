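"""Synthetic data with the statistical structure the pipeline assumes.

Two generators cover the two data modalities:

* :func:`simulate_repliseq` — five-fraction Repli-seq coverage.  Each 10-kb
  bin has a preferred S-phase fraction μ_b (piecewise constant over timing
  domains) and a synchronicity concentration κ; reads per bin are Poisson and
  are allocated to fractions with probabilities ∝ exp(κ·cos(2π(f − μ_b)/5)),
  a wrapped kernel on the same circle the RQE metric uses.  κ = 0 gives
  uniform (fully asynchronous, σ → 1) emission; large κ approaches a point
  mass (fully synchronous, σ → 0).

* :func:`simulate_fork_data` — nanopore read alignments plus forkSense-style
  fork and origin calls.  Read lengths are lognormal, MAPQ has a sub-20 tail,
  fork track length = speed × total pulse minutes with region-specific speed
  means, stall scores are Beta, a configurable fraction of tracks is
  truncated at read ends, and origin calls cluster in hotspots inside the
  ecDNA-like region.

Ground truth (per-bin μ/κ; per-fork true speed and region) accompanies every
output so recovery tests can close the loop.  All randomness flows from one
seed; every file records the seed and a config hash in a header comment.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .binning import FRACTION_LABELS, FractionCoverage
from .forks import PulseConfig
from .layout import GenomeLayout, bin_bounds, n_bins


def _config_hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha1(payload).hexdigest()[:10]


def make_layout(
    n_chromosomes: int = 2,
    chrom_length: int = 30_000_000,
    ecdna: tuple[str, int, int] = ("chr1", 20_000_000, 21_600_000),
    seed: int = 0,
) -> GenomeLayout:
    """A toy genome with an ecDNA-like region.

    Deterministic given its arguments (``seed`` is accepted for interface
    symmetry with the stochastic generators).
    """
    chroms = {f"chr{i+1}": int(chrom_length) for i in range(n_chromosomes)}
    layout = GenomeLayout(chroms)
    chrom, start, end = ecdna
    layout.add_region("ecDNA", chrom, start, end)
    return layout


@dataclass
class TimingField:
    """Per-bin preferred fraction μ_b ∈ {0..4} and concentration κ ≥ 0."""

    mu: dict[str, np.ndarray]
    kappa: dict[str, np.ndarray]
    bin_width: int

    def emission_probs(self, chrom: str) -> np.ndarray:
        """(n_bins, 5) fraction-allocation probabilities for one chromosome."""
        mu = self.mu[chrom][:, None]
        kap = self.kappa[chrom][:, None]
        f = np.arange(5)[None, :]
        w = np.exp(kap * np.cos(2 * np.pi * (f - mu) / 5))
        return w / w.sum(axis=1, keepdims=True)


def make_timing_field(
    layout: GenomeLayout,
    bin_width: int = 10_000,
    kappa: float = 5.0,
    region_kappa: dict[str, float] | None = None,
    mean_domain_length: int = 2_000_000,
    seed: int = 0,
) -> TimingField:
    """Piecewise-constant timing domains with a per-region κ override.

    Domains of ``mean_domain_length`` step through the five S-phase fractions
    in circular order (a replication wave) with a random phase and direction
    per chromosome.  Cycling keeps the genome's timing composition balanced
    across fractions — as in a real genome, where every locus replicates
    exactly once per S phase — which the RPKM library-size normalization of
    the binning stage relies on.  ``region_kappa`` maps layout region names
    to κ values imposed on the bins inside them (e.g. κ = 0 for an
    asynchronous ecDNA-like interval).
    """
    rng = np.random.default_rng(seed)
    domain_bins = max(1, mean_domain_length // bin_width)
    mu: dict[str, np.ndarray] = {}
    kap: dict[str, np.ndarray] = {}
    for chrom in layout.chrom_names:
        nb = n_bins(layout, chrom, bin_width)
        phase = int(rng.integers(0, 5))
        direction = 1 if rng.random() < 0.5 else -1
        m = (phase + direction * (np.arange(nb) // domain_bins)) % 5
        mu[chrom] = m.astype(int)
        kap[chrom] = np.full(nb, float(kappa))
    for name, value in (region_kappa or {}).items():
        region = layout.region(name)
        first = region.start // bin_width
        last = -(-region.end // bin_width)
        kap[region.chrom][first:last] = float(value)
    return TimingField(mu, kap, bin_width)


def simulate_repliseq(
    layout: GenomeLayout,
    field: TimingField,
    depth: float = 500.0,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[FractionCoverage, pd.DataFrame, dict[str, Path]]:
    """Draw per-bin, per-fraction read counts and (optionally) write bedGraphs.

    Per bin: total reads ~ Poisson(depth), split multinomially by the timing
    field's emission probabilities.  Returns the coverage, a ground-truth
    table (chrom, bin start/end, μ_b, κ_b), and the written file paths
    (five count bedGraphs + truth TSV) when ``out_dir`` is given.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    counts: dict[str, np.ndarray] = {}
    truth_rows = []
    for chrom in layout.chrom_names:
        probs = field.emission_probs(chrom)
        nb = probs.shape[0]
        totals = rng.poisson(depth, size=nb)
        alloc = rng.multinomial(totals, probs)  # (nb, 5)
        counts[chrom] = alloc.T.astype(float)
        for b in range(nb):
            s, e = bin_bounds(b, field.bin_width, layout.length(chrom))
            truth_rows.append((chrom, s, e, int(field.mu[chrom][b]), float(field.kappa[chrom][b])))
    totals_per_fraction = np.array([sum(c[fi].sum() for c in counts.values()) for fi in range(5)])
    coverage = FractionCoverage(FRACTION_LABELS, counts, totals_per_fraction, field.bin_width)
    truth = pd.DataFrame(truth_rows, columns=["chrom", "start", "end", "mu", "kappa"])
    paths: dict[str, Path] = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        header = f"seed={seed} config={_config_hash({'depth': depth, 'bin_width': field.bin_width})}"
        for fi, label in enumerate(FRACTION_LABELS):
            rows = []
            for chrom in layout.chrom_names:
                arr = counts[chrom][fi]
                for b in np.flatnonzero(arr > 0):
                    s, e = bin_bounds(int(b), field.bin_width, layout.length(chrom))
                    rows.append((chrom, s, e, arr[b]))
            df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
            paths[label] = io.write_bedgraph(df, out_dir / f"repliseq_{label}.bedgraph", header)
        paths["truth"] = io.write_tsv(truth, out_dir / "repliseq_truth.tsv", header)
        paths["chrom_sizes"] = io.write_chrom_sizes(layout.chromosomes, out_dir / "chrom.sizes")
    return coverage, truth, paths


@dataclass
class ForkSimModel:
    """Generative model for reads, forks and origins on the toy genome.

    Speed means/SDs are in kb/min (defaults follow the contrast between
    chromosomal and ecDNA replication this pipeline is built to detect);
    stall scores are Beta-distributed with region-specific means.
    """

    speed_mean: dict[str, float] = field(
        default_factory=lambda: {"chromosomal": 1.25, "ecDNA": 1.18}
    )
    speed_sd: dict[str, float] = field(
        default_factory=lambda: {"chromosomal": 0.35, "ecDNA": 0.35}
    )
    stall_mean: dict[str, float] = field(
        default_factory=lambda: {"chromosomal": 0.38, "ecDNA": 0.41}
    )
    stall_concentration: float = 4.0
    truncation_prob: float = 0.1
    fork_prob: float = 0.7
    origin_prob: float = 0.15
    read_length_median: float = 50_000.0
    read_length_sigma: float = 0.55
    mapq_low_fraction: float = 0.08
    ecdna_read_weight: float = 1.0  # >1 up-weights reads landing in the ecDNA region
    origin_hotspots: int = 3
    origin_hotspot_sd: float = 40_000.0
    origin_hotspot_bias: float = 0.8


def _draw_read_positions(
    layout: GenomeLayout, n: int, model: ForkSimModel, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Read midpoint chromosome indices and positions, region-weighted."""
    names = layout.chrom_names
    lengths = np.array([layout.length(c) for c in names], dtype=float)
    region = layout.regions.get("ecDNA")
    genome = lengths.sum()
    if region is not None:
        f_region = region.length / genome
        w = model.ecdna_read_weight
        p_region = w * f_region / (1 - f_region + w * f_region)
        in_region = rng.random(n) < p_region
    else:
        in_region = np.zeros(n, dtype=bool)
    chrom_idx = rng.choice(len(names), size=n, p=lengths / genome)
    pos = rng.uniform(0, lengths[chrom_idx])
    if region is not None:
        ridx = names.index(region.chrom)
        # The model is a two-component mixture: with probability p_region a
        # read midpoint is uniform inside the region, otherwise uniform over
        # the rest of the genome.  Resample any background draw that lands in
        # the region so its read share is exactly p_region (for w = 1 this
        # reduces to a genome-wide uniform).
        out = ~in_region
        bad = out & (chrom_idx == ridx) & (pos >= region.start) & (pos < region.end)
        while bad.any():
            k = int(bad.sum())
            chrom_idx[bad] = rng.choice(len(names), size=k, p=lengths / genome)
            pos[bad] = rng.uniform(0, lengths[chrom_idx[bad]])
            bad = out & (chrom_idx == ridx) & (pos >= region.start) & (pos < region.end)
        chrom_idx[in_region] = ridx
        pos[in_region] = rng.uniform(region.start, region.end, size=int(in_region.sum()))
    return chrom_idx, pos


def simulate_fork_data(
    layout: GenomeLayout,
    model: ForkSimModel | None = None,
    n_reads: int = 5_000,
    pulse: PulseConfig = PulseConfig(),
    seed: int = 0,
    out_dir: str | Path | None = None,
    sample: str = "sim",
    replicate: str = "rep1",
) -> dict:
    """Simulate reads, forkSense-style fork calls, and origin calls.

    Returns a dict with ``reads`` (alignment summary), ``forks`` (forkSense
    dialect columns + hidden truth), ``origins``, ``truth`` (per-fork true
    speed and region) and, when ``out_dir`` is given, the written ``paths``
    (leftForks/rightForks/origins BED, alignment TSV, truth TSV, chrom.sizes).
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    model = model or ForkSimModel()
    rng = np.random.default_rng(seed)
    names = layout.chrom_names
    region = layout.regions.get("ecDNA")

    chrom_idx, mid = _draw_read_positions(layout, n_reads, model, rng)
    rlen = rng.lognormal(np.log(model.read_length_median), model.read_length_sigma, n_reads)
    rlen = np.maximum(rlen, 1_000).astype(int)
    lengths = np.array([layout.length(c) for c in names])
    rstart = np.clip((mid - rlen / 2).astype(int), 0, None)
    rend = np.minimum(rstart + rlen, lengths[chrom_idx])
    rstart = np.maximum(rend - rlen, 0)
    mapq = np.where(
        rng.random(n_reads) < model.mapq_low_fraction,
        rng.integers(0, 20, n_reads),
        60,
    )
    reads = pd.DataFrame(
        {
            "read_id": [f"read_{i:06d}" for i in range(n_reads)],
            "chrom": [names[i] for i in chrom_idx],
            "start": rstart,
            "end": rend,
            "mapq": mapq,
        }
    )

    # hotspot centres for origin placement inside the ecDNA-like region
    hotspots = (
        rng.uniform(region.start, region.end, model.origin_hotspots)
        if region is not None and model.origin_hotspots > 0
        else np.array([])
    )

    fork_rows, truth_rows, origin_rows = [], [], []
    total_min = pulse.total_minutes
    for i in range(n_reads):
        rid = reads["read_id"].iloc[i]
        chrom = reads["chrom"].iloc[i]
        rs, re_ = int(reads["start"].iloc[i]), int(reads["end"].iloc[i])
        if rng.random() < model.fork_prob:
            anchor = rng.uniform(rs, re_)
            reg = (
                "ecDNA"
                if region is not None and region.contains_point(chrom, anchor)
                else "chromosomal"
            )
            speed = max(rng.normal(model.speed_mean[reg], model.speed_sd[reg]), 0.05)
            track = int(round(speed * total_min * 1000))
            direction = "leftward" if rng.random() < 0.5 else "rightward"
            truncate = rng.random() < model.truncation_prob or track >= (re_ - rs) - 2
            if truncate:
                # censor the track at whichever read end the fork runs into
                if direction == "rightward":
                    start = max(rs, re_ - track)
                    end = re_
                else:
                    start = rs
                    end = min(re_, rs + track)
            else:
                start = int(rng.uniform(rs + 1, re_ - 1 - track))
                end = start + track
            stall_mu = model.stall_mean[reg]
            c = model.stall_concentration
            stall = float(rng.beta(stall_mu * c, (1 - stall_mu) * c))
            fork_rows.append((chrom, start, end, rid, rs, re_, round(stall, 4), direction))
            truth_rows.append((rid, reg, speed, bool(truncate)))
        if rng.random() < model.origin_prob:
            omid = rng.uniform(rs, re_)
            if (
                region is not None
                and region.contains_point(chrom, omid)
                and len(hotspots)
                and rng.random() < model.origin_hotspot_bias
            ):
                h = hotspots[rng.integers(len(hotspots))]
                cand = rng.normal(h, model.origin_hotspot_sd)
                if rs <= cand < re_ and region.start <= cand < region.end:
                    omid = cand
            s = int(max(rs, omid - 500))
            e = int(min(re_, omid + 500))
            if e > s:
                origin_rows.append((chrom, s, e, rid))

    fork_cols = ["chrom", "start", "end", "read_id", "read_start", "read_end", "stall", "direction"]
    forks = pd.DataFrame(fork_rows, columns=fork_cols)
    truth = pd.DataFrame(truth_rows, columns=["read_id", "region", "true_speed", "truncated"])
    origins = pd.DataFrame(origin_rows, columns=["chrom", "start", "end", "read_id"])

    out = {"reads": reads, "forks": forks, "origins": origins, "truth": truth}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        header = f"seed={seed} config={_config_hash(asdict(model))} sample={sample} rep={replicate}"
        paths: dict[str, Path] = {}
        for direction, fname in (("leftward", "leftForks.bed"), ("rightward", "rightForks.bed")):
            sub = forks[forks["direction"] == direction].drop(columns="direction")
            path = out_dir / fname
            with open(path, "w") as fh:
                fh.write(f"# {header}\n")
                sub.to_csv(fh, sep="\t", header=False, index=False)
            paths[fname] = path
        path = out_dir / "origins.bed"
        with open(path, "w") as fh:
            fh.write(f"# {header}\n")
            origins.to_csv(fh, sep="\t", header=False, index=False)
        paths["origins.bed"] = path
        paths["alignments"] = io.write_tsv(reads, out_dir / "alignment_summary.tsv", header)
        paths["truth"] = io.write_tsv(truth, out_dir / "fork_truth.tsv", header)
        paths["chrom_sizes"] = io.write_chrom_sizes(layout.chromosomes, out_dir / "chrom.sizes")
        out["paths"] = paths
    return out
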