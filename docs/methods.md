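# Methods

## Coordinate and track conventions

All intervals are 0-based half-open; BED is read and written natively and
GTF converted on I/O. Signal lives in `SignalTrack` objects: dense per-base
float32 arrays keyed by (chromosome, strand), with `"."` for unstranded ChIP
coverage. Dense storage was chosen over run-length encoding because the
package targets genomes of tens of megabases (toy chromosomes, or per-locus
extracts of real data), where dense arrays are simpler and faster; bedGraph,
the canonical on-disk form, run-length encodes the same values, so nothing
is lost at the file boundary. PRO-seq tracks carry read 5′-end counts (one
unit at the strand-aware 5′ coordinate); ChIP tracks carry coverage of reads
extended 200 bp from their 5′ end.

## Gene regions

A TSS region (FANTOM-style interval) is anchored at its strand-aware
downstream boundary and extended ±250 bp into a promoter of width 501 bp
(half-open: `[a−250, a+251)` on plus, mirrored on minus). The source
convention is ambiguous between anchoring at the region end and at the TSS
point; the end is the default and `anchor="midpoint"` is available. Each
promoter is assigned to the nearest same-strand transcript (gap distance,
0 when overlapping); promoters more than 2 kb from any transcript are
dropped and reported. The gene body runs from the promoter end to the modal
annotated transcript 3′ end, computed by exact coordinate equality; ties are
broken by the longest supporting isoform. When a transcript overlaps several
TSS regions, the representative promoter is the one with the highest mean
track signal (leftmost on ties). Genes whose representative end falls
upstream of the promoter end are excluded as degenerate.

## Spike-in normalization

PRO-seq/RNA-seq size factors are proportional to 1 / spike-genome reads and
rescaled to geometric mean 1 (asserted to 1e-12): a sample in which more
exogenous material was recovered is scaled down. ChIP coverage is multiplied
by the target/spike unique-read ratio, the same orientation; an
`orientation="divide"` flag covers protocols documented the other way
around. RPKM used by the expression filters is computed against the raw
mapped target-genome library size, not the spike-normalized one, because
those filters compare signal within a sample.

## The leading-edge wave caller

Difference tracks are per-base max(0, s_t − s_0); censoring negatives is
required because covered-base counting needs non-negative signal, and
subtracting the t = 0 track removes both the promoter-proximal pause signal
and signal from neighboring genes in head-to-tail orientation. Tiles are
1 kb, fixed to genome coordinates; the last partial tile is kept and clipped.
Smoothing applies only to covered-base counts — `smoothed[n] =
max(raw[n−1], raw[n])` computed non-iteratively from the raw vector, with
"preceding" meaning lower genomic coordinate on both strands — and both raw
and smoothed counts are retained for audit. Retention requires smoothed
covered ≥ 25 % of the tile width and summed signal ≥ 0.1 (applied after the
geometric-mean-1 rescaling when tracks are spike-scaled). Thresholds are
inclusive: regions of exactly 3000 bp survive, gaps of exactly 4000 bp are
merged. The leading edge is the region boundary at tile resolution; no
sub-tile refinement is attempted, since the construction itself is
tile-grained.

Regions are annotated to the closest upstream TSS with a one-tile (1 kb)
slack: tile quantization floors the region start, so a wave launched at a
TSS routinely begins up to one tile upstream of it, and a verbatim
"largest TSS ≤ region start" would hand the region to the previous gene.
Slack 0 restores the verbatim rule. When several regions are assigned to a
gene at one timepoint, the region whose 5′ boundary lies closest to the TSS
carries the leading edge. Rates use the nominal washout time (10/25/40 min)
with no lag correction. Genes lacking a region, or with a non-positive edge
distance, at any condition × timepoint are excluded throughout, and median
summaries are computed over a caller-supplied subset (by default genes
≥ 100 kb, where a 1 kb edge error is small relative to the wave).

The processivity index is log₁₀(distal/proximal) over the first and last
10 % of the gene body in transcription direction; the window fraction is a
flag because no standard definition of "distal"/"proximal" exists. Zero
counts in either window yield NaN with a named flag rather than ±inf.

## Stalling, filters and profiles

The stalling index is promoter / gene-body 5′-end counts; it is
scale-invariant within a sample, so spike scaling does not change it. The
read-through filter window is `[promoter 5′ − 500, promoter 5′ − 250)`
strand-aware; genes exceeding RPKM 8 there in the WT track are removed, as
are genes with promoter RPKM < 2 in every sample. The two rules commute and
the audit log records which removed each gene.

Metagene profiles bin each strand-oriented region (bin 1 = 5′) into 100
equal-width bins by exact fractional overlap (a cumulative-sum integral, so
regions shorter than the bin count are handled without exclusion),
optionally min–max rescale each region to [0, 1] (constant regions are
skipped with a count), and summarize each bin across regions by a two-sided
trimmed mean dropping floor(trim·n) values from each tail, trim = 0.3 by
default. Trim 0 reduces exactly to the arithmetic mean.

## Half-life estimation

Conversion rates r(t) = r₀·2^(−t/T) are linearized as ln r = a − k·t
(natural log internally; any display shift is a plotting concern since k is
base-invariant) and fit by iteratively reweighted least squares with Huber
weights, tuning constant 1.345, MAD residual scale, tolerance 1e-8, at most
50 iterations, via statsmodels RLM. All replicates enter one fit as
independent points — the robust loss is what downweights an outlier
replicate — with a per-replicate mode available. Exactly log-linear input
short-circuits to the exact least-squares line, because a zero MAD scale
degenerates the Huber weights; slopes below 1e-12 h⁻¹ are reported as k = 0
with an undefined half-life rather than astronomically large T½, and k ≤ 0
is never clipped (clipping would bias medians).

Gene filters before fitting: ≥ 3 replicates with conversion > 0 at every
(condition, timepoint); median conversion at t = 0 positive; median
conversion non-increasing across ordered timepoints in every condition
(an equal consecutive median is tolerated; only increases disqualify).
Per-condition median summaries are restricted to genes with a defined
half-life in every condition, so conditions are compared on one shared gene
set.

The buffering statistic is Δ = l2fc(RNA) − l2fc(PRO) on matched genes;
fold changes are computed from spike-scaled mean counts with a pseudocount
of 1 (no shrinkage-based differential testing). Under a steady-state model
(abundance ∝ production × half-life), a pure stability change of factor c
gives Δ = log₂ c exactly, which the tests verify.

## The synthetic-data generator

The generator reproduces the study design the analyses assume: washout
timepoints 0/10/25/40 min; SLAM chase 0/6/12 h with six replicates;
a 10 % spike-in fraction; gene-specific elongation rates U(1.5, 4.5) kb/min;
log-normal half-lives with median 5 h and σ_ln = 0.35 (a typical 2–3-fold
spread); initial conversion rates U(0.005, 0.05); multiplicative log-normal
noise (σ = 0.1 default) on conversion rates. Genes (100–150 kb by default)
are placed non-overlapping on one chromosome with ≥ 10 kb gaps so
upstream-TSS annotation is unambiguous, strands drawn uniformly; each gene
has one transcript and one TSS region whose anchor coincides with the
transcript 5′ end.

Reads are per-base Poisson counts on the underlying density — no read
lengths, no alignment artifacts. The DRB wave at time t is uniform over
[TSS, TSS + v·t·1000), clipped at the gene end, on top of a background
(uniform gene-body noise at one tenth of the wave density plus a
promoter-proximal peak) whose realization is *identical* across timepoints,
so the t = 0 subtraction removes it exactly; the t = 0 track is pure
background. `depth` is the expected wave read count of the first
post-release track (default 20 000 per gene, ≈ 0.6 reads/bp); the per-base
density is held constant at later timepoints, since polymerases keep
initiating behind the front — a fixed per-track budget would dilute coverage
below the 25 % tile threshold by 40 min. Pausing tracks split a gene's reads
between the promoter window and the uniform body so the expected count ratio
equals the planted stalling index. Spike-in matrices sequence each sample to
depth / size-factor with a fixed spike fraction, so 1/spike scaling recovers
the planted factors. A fixed `SimConfig.seed` makes every output
byte-identical; independent named substreams keep the stages decoupled.

What passing recovery tests does and does not show: the generator has no
mappability gaps, no gene-dense overlapping loci, no variable pause-release
lag, no inter-gene expression heterogeneity by default, and Poisson (not
overdispersed) counts. Recovery under these conditions validates the
algorithmic chain — not robustness to every artifact of real libraries.

## Problem sizes and numerical checks

The test suite and `scripts/acceptance.py` use: 200 genes ≥ 100 kb for
elongation-rate recovery (median |relative error| of t = 10 estimates ≈ 1 %,
Spearman ≈ 0.999); 1000 random tile patterns against a loop-based reference
implementation of the filter/merge/length chain (identical output); 500
genes for half-life recovery (Spearman ≈ 0.99, median relative error ≈ 2 %
at σ = 0.1; exact to ≈ 1e-15 relative at σ = 0); exhaustive 3-timepoint
sign patterns for the monotonicity filter; planted spike factors (1, 2, 0.5)
at depth 10⁶ (recovered within 0.5 %); and planted stalling indices
0.5/1/2/5 (within 3 SE). These sizes were chosen as the smallest that
exercise each estimator in its intended regime.

## Known limitations

* The leading edge is tile-quantized: rate estimates carry an O(1 kb / v·t)
  relative error, largest at the earliest timepoint and for slow genes.
* No lag-time model for inhibitor washout; rates at t = 10 absorb any
  release delay.
* Waves clipped at gene ends bias late-timepoint rates downward for fast,
  short genes; median summaries should use long genes.
* Single-exponential decay only; bi-exponential turnover will be fit by a
  compromise slope.
* The buffering fold changes are simple normalized means, not a shrinkage
  estimator; at low counts they are noisy.
* No liftover: all inputs must share one genome assembly.
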