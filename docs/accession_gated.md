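# Accession-gated targets

The headline numbers reported for the COLO 320DM / COLO 320HSR / PC-3 / RPE-1
analyses (DOI: 10.1093/nar/gkaf711) cannot be reproduced from this repository
alone: they require the raw sequencing deposits (Repli-seq at GEO accession
GSE186675; nanopore DNAscent runs at ENA project PRJEB83636), which are far
beyond desk scale. This page records each gated number together with the exact
command a user holding the deposits would run to attempt it. Nothing on this
page is computed or asserted by the test suite beyond the existence of these
instructions.

## Input layout expected by the pipeline

Every stage reads plain-text inputs from `--workdir`:

- `chrom.sizes` — two-column chromosome table (GRCh38).
- `repliseq_S1.bedgraph` … `repliseq_S5.bedgraph` — per-fraction 10-kb read
  counts from the aligned Repli-seq libraries.
- `leftForks.bed`, `rightForks.bed`, `origins.bed` — DNAscent forkSense
  output.
- `alignment_summary.tsv` — `read_id  chrom  start  end  mapq` per primary
  alignment; place the FACS-sorted library's table in `sorted/` to trigger
  the enrichment computation.

A YAML config (`replidyn run --config cfg.yaml`) sets the target region, e.g.

```yaml
workdir: colo320dm
regions:
  ecDNA: [chr8, 126425747, 127997820]
```

## Gated targets and commands

| # | Headline number | Quantity | Command |
|---|----------------|----------|---------|
| 1 | σ = 0.96 | Normalized RQE synchronicity score of the ecDNA interval (chr8:126425747–127997820) in COLO 320DM, with tail probability < 0.01 against the genome-wide null | `replidyn bin --config cfg.yaml && replidyn rqe --config cfg.yaml` → `rqe_targets.tsv` |
| 2 | 1312 / 81 | Reads with ≥ 1 origin call, and origin calls within the ecDNA interval, in the COLO 320DM nanopore run (1115 / 43 for the HU-treated run) | `replidyn origins --config cfg.yaml` → `origins_summary.json` |
| 3 | KS = 0.91 | One-sample KS statistic against uniformity of origin positions over the 50-kb segments of the ecDNA interval (0.76 and 0.92 for the companion samples) | `replidyn origins --config cfg.yaml` → `uniformity` block of `origins_summary.json` |
| 4 | 1.18 vs 1.27 kb/min | Median fork speed, ecDNA vs chromosomal forks, COLO 320DM (1.18 vs 1.25 for the matched contrast) | `replidyn forks --config cfg.yaml` → `forks_summary.json`, `fork_chrom_medians.tsv` |
| 5 | 0.99 and 0.91 kb/min; 20.7% | Fork speeds under hydroxyurea and the relative reduction of the mean (22.9% for the companion contrast); stall-score shifts 0.41 vs 0.38 and 0.31 vs 0.30 | run `replidyn forks` on the HU workdir and compare `speed_comparison.percent_difference_of_means` |
| 6 | 11–40× | FINE enrichment factor: ecDNA-mapped fraction of qualifying reads, FACS-sorted vs bulk | `replidyn qc --config cfg.yaml` with the sorted library in `workdir/sorted/` → `enrichment_factor` in `qc_summary.json` |
| 7 | N50 = 91.1 kb | Qualifying-read N50 of the COLO 320DM nanopore run | `replidyn qc --config cfg.yaml` → `n50` in `qc_summary.json` |

The synthetic scenarios bundled with this repository exercise every one of
these code paths at desk scale with known ground truth; only the specific
real-data values above are accession-gated.
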