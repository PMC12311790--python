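# Methods

This note records the statistical model, the numerical conventions, and the
design decisions behind `replidyn`. The pipeline quantifies how *synchronous*
DNA replication timing is along the genome (with extrachromosomal DNA, ecDNA,
as the motivating target), and processes nanopore fork-tracking output into
fork speeds, stall scores, and origin densities. The methods follow the
analyses of DOI 10.1093/nar/gkaf711.

## Replication-timing synchronicity (Rao quadratic entropy)

High-resolution Repli-seq sorts S phase into five fractions S1–S5 (early to
late). After binning each fraction's aligned reads into 10-kb bins and RPKM
normalization, each bin carries a categorical distribution
p = (p₁,…,p₅), pᵢ = RPKMᵢ / Σⱼ RPKMⱼ, over the fractions. Its disorder is
measured by the Rao quadratic entropy with a circular metric,

    RQE(p) = Σᵢ Σⱼ d(i,j) · pᵢ · pⱼ,   d(i,j) = min(|i−j|, K−|i−j|),  K = 5.

The circular metric reflects that S1 and S5 are temporal neighbours across
consecutive cell cycles. RQE is normalized by its value at the uniform
distribution, so σ = 1 means replication spread evenly over all five
fractions (maximal asynchrony) and σ = 0 means replication confined to one
fraction (full synchrony).

**Exactness of the anchors.** The uniform value of the unnormalized RQE for
K = 5 is (K²−1)/(4K) = 1.2, but dividing by the literal constant 1.2 leaves
the uniform score at 1 + 1 ulp in IEEE double precision. The normalizer is
therefore evaluated at the uniform vector *through the identical einsum code
path* used for the observed distribution, which makes σ(uniform) == 1.0 and
σ(single-fraction) == 0.0 bit-exact.

**Fragment scores.** A genomic fragment's σ is the mean of its defined bins'
σ values (bins with zero total signal are undefined and excluded; a fragment
with no defined bin is an error, not a silent zero).

**Genome-wide empirical null.** Null fragments of 1.6 Mb (the size of the
target amplicon) are tiled deterministically over the autosomes, excluding
5 Mb at each chromosome end. Two spacing conventions exist in the wild and
give materially different fragment counts on GRCh38 (bundled as a 22-line
constant table):

- `start` (default): fragment *starts* every 10 Mb → 272 fragments;
- `gap`: 10 Mb of clear space between fragments (11.6 Mb start-to-start)
  → 236 fragments.

Both are implemented; the run summary records which was used. Null fragments
containing any undefined bin are dropped, and fragments overlapping a named
target region can be excluded so the null is not contaminated by the signal
under test. The tail probability of an observed σ is the inclusive empirical
fraction P(σ_null ≥ σ_obs); with N retained fragments its resolution is 1/N,
so a reported 0.0 means "larger than every null fragment", bounded below by
1/(N+1) in rank terms. Two σ samples (e.g. ecDNA vs chromosomal nulls) are
compared with the two-sample two-sided Kolmogorov–Smirnov test (SciPy).

## Fork dynamics (forkSense downstream)

Input is DNAscent forkSense leftward/rightward fork tracks and origin calls,
BED-like with read coordinates and a stall score per track. Conventions:

- **Speed** = track length (bp) / 1000 / total pulse duration (min); the
  default pulse scheme is 6 min EdU + 6 min BrdU = 12 min, so a 21 480-bp
  track is 1.79 kb/min.
- **Completeness**: a track flush against either read end is censored
  (the fork ran off the read) and is excluded from speed statistics.
- **Filters**: complete tracks with a stall score only; chrY excluded;
  then a Tukey fence on speeds, retaining [Q1 − 1.5·IQR, Q3 + 1.5·IQR]
  with quartiles by NumPy's linear interpolation. The fence is applied
  once — it is not idempotent in general, and refiltering is deliberately
  not done.
- **Comparisons**: Welch's unequal-variance t-test for speeds
  (`scipy.stats.ttest_ind(equal_var=False)`); Wilcoxon rank-sum for stall
  scores, with the exact permutation distribution enumerated when
  n₁+n₂ ≤ 12 (SciPy's exact path refuses ties) and the tie-corrected
  normal approximation otherwise. Percent difference of means is reported
  relative to the first group.
- **Segment profiles**: per-20-kb-segment mean speed and stall score over a
  region, tracks assigned by midpoint; empty segments flagged, not zeroed.

## Origin density and uniformity

Origin calls are counted two ways: reads carrying ≥ 1 origin call, and total
calls. Per-50-kb-segment density is origin calls divided by *qualifying*
reads (alignment span ≥ 20 kb and MAPQ ≥ 20, both inclusive) whose midpoints
fall in the segment; segments with zero qualifying reads are flagged
depth-undefined. Departure from positional uniformity over a region is
tested with a one-sample KS test in two variants: `counts` (ECDF over the
ordered 50-kb segments vs the uniform CDF, p from the exact KS distribution)
and `positions` (raw midpoints vs Uniform(region)). The segment-level
`counts` variant is the default because the headline real-data statistic is
defined on segments.

## Read QC and enrichment

N50 follows the verbatim descending-cumulative procedure: sort read lengths
descending, accumulate, and report the first length at which the running sum
reaches half the total (N50 of {80,70,50,40,30,20} is 70). The FACS
enrichment factor is the ratio of region-mapped fractions of qualifying
reads (by midpoint), sorted library over bulk library.

## Synthetic data

The simulator provides ground truth at desk scale:

- **Repli-seq**: a per-bin timing field with preferred fraction μ_b and
  concentration κ_b; emission probabilities ∝ exp(κ cos(2π(f−μ)/5)). μ is a
  *cyclic replication wave* — fixed-length domains stepping through the five
  fractions in circular order with a random phase and direction per
  chromosome. Cycling keeps each fraction's genome share balanced, which the
  RPKM library-size normalization requires to recover per-bin emission
  probabilities (a uniformly random μ field does not; this failure mode was
  observed directly and is why the wave field is used). Per bin, total reads
  are Poisson(depth), split multinomially by the emission probabilities.
  κ = 0 yields σ ≈ 1 (asynchronous); large κ yields σ ≈ 0.
- **Forks/reads**: log-normal read lengths, region-dependent Gaussian speeds
  and Beta stall scores, censoring at read ends, a low-MAPQ tail, origin
  hotspots inside the region, and a two-component read-position mixture
  that places a read in the target region with probability
  p = w·f/(1−f+w·f) (f = region's genome fraction, w the enrichment
  weight), so the expected enrichment factor is p/f = w/(1−f+w·f) and is
  recoverable from the generated data.

The bundled two-chromosome scenario (2 × 30 Mb, 1.6 Mb ecDNA-like region)
scales the null-sampler spacing to 2 Mb with 2 Mb end exclusion; the
genome-scale 10 Mb / 5 Mb defaults would fit only four null fragments in a
60 Mb toy genome, making control-region tail probabilities too granular to
be meaningful. Genome-scale defaults are unchanged.

## Conventions and limitations

- Coordinates are 0-based half-open throughout; bin/segment assignment is by
  midpoint. For 10-kb Repli-seq bins the *left-median* midpoint
  (start+end−1)//2 is used so an even-length read straddling a boundary is
  assigned to the bin containing the left of its two central bases; fork and
  origin midpoints use (start+end)//2.
- The trailing short bin of each chromosome is kept; RPKM uses true bin
  widths when a layout is supplied.
- The simulator does not model copy-number structure within the amplicon,
  sequencing error, mappability, or replication-dependent coverage waves in
  the bulk library; it is a calibration instrument, not a genome emulator.
- The empirical-null tail probability is a one-sided rank statistic, not a
  parametric p-value; with few null fragments it is coarse by construction
  and the run summary reports the retained fragment count alongside it.
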