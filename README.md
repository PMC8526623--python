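# polkinetics

Pol II transcription kinetics from nascent- and metabolic-RNA sequencing:
DRB-release elongation rates, stalling and processivity indices, spike-in
normalized signal tracks, metagene profiles, SLAM-seq mRNA half-lives and a
transcript-buffering statistic — with a ground-truth synthetic-data generator
so every stage is verifiable by parameter recovery.

## Who this is for

Groups that measure transcription elongation with a DRB washout time course
(PRO-seq), promoter-proximal pausing (PRO-seq or Pol II ChIP-seq) or mRNA
turnover (SLAM-seq), and want the standard derived quantities computed with
explicit, tested conventions: how promoters and gene bodies are defined, how
spike-ins scale samples, how a transcription wave front becomes a rate in
kb/min, and how a T→C conversion time series becomes a half-life in hours.

## The quantities it computes

**Elongation rate.** After release from a DRB (CDK9 inhibitor) block,
polymerases advance from the TSS as a synchronized wave. On the background-
subtracted difference track (t − t₀, negatives censored), the genome is split
into 1 kb tiles; covered bases per tile are smoothed with a one-step running
maximum, max(cₙ₋₁, cₙ); tiles with < 25 % covered bases or summed normalized
signal < 0.1 are dropped; survivors within 4 kb are merged and regions
shorter than 3 kb discarded. Each region is annotated to the gene with the
closest upstream TSS, and for genes with a region at every condition ×
timepoint,

&nbsp;&nbsp;&nbsp;&nbsp; v = (leading edge − TSS) / t &nbsp; [kb/min],

where the leading edge is the strand-aware 3′ boundary of the region.

**Stalling index.** SI = promoter 5′-end reads / gene-body 5′-end reads, on
promoters of ±250 bp around the TSS-region anchor and gene bodies from the
promoter end to the modal annotated transcript end (ties to the longest
isoform). Expression filters remove read-through genes (upstream-window
RPKM > 8 in WT) and non-expressed genes (promoter RPKM < 2 in all samples).

**Processivity index.** log₁₀(distal / proximal gene-body reads), windows
being the first and last 10 % of the body in transcription direction.

**Spike-in normalization.** PRO-seq size factors ∝ 1 / spike reads, rescaled
to geometric mean 1; ChIP tracks are 200 bp-extended coverage scaled by the
target/spike unique-read ratio, with enrichment tracks
max(0, log₂((ChIP+1)/(Input+1))).

**mRNA half-life.** The SLAM-seq T→C conversion rate decays as
r(t) = r₀·2^(−t/T). After detectability and monotonic-decrease filters, the
linearized model ln r = a − k·t is fit per gene and condition by a robust
linear model (Huber M-estimator, c = 1.345, MAD scale) pooling all
replicates; T½ = ln 2 / k.

**Transcript buffering.** Δ = log₂FC(RNA-seq) − log₂FC(PRO-seq) per gene; a
positive skew means steady-state mRNA changed more than production, i.e. a
stability change.

## Worked example

Forty genes are simulated with known elongation rates drawn U(1.5, 4.5)
kb/min and log-normal half-lives (median 5 h), and both pipelines are run
end to end:

```python
import pandas as pd
from polkinetics.pipeline import RunConfig, run_drb_pipeline, run_slam_pipeline
from polkinetics.simulate import SimConfig

cfg = RunConfig(outdir="out", synthetic=True,
                sim=SimConfig(seed=1, n_genes=40), min_gene_length=100_000)
drb = run_drb_pipeline(cfg)
slam = run_slam_pipeline(cfg)
print(drb["rates"].head().to_string(index=False))
print(drb["medians"].to_string(index=False))
print(slam["summary"].to_string(index=False))
```

which prints

```
 gene_id condition  timepoint  leading_edge  distance_from_tss  rate_kb_per_min
gene0000 synthetic         10        107000              17962          1.79620
gene0000 synthetic         25         80000              44962          1.79848
gene0000 synthetic         40         53000              71962          1.79905
gene0001 synthetic         10        151000              16058          1.60580
gene0001 synthetic         25        175000              40058          1.60232

condition  timepoint  median_rate_kb_per_min
synthetic         10                 3.02685
synthetic         25                 3.02156
synthetic         40                 2.77410

condition  median_half_life_h  n_genes
       WT            5.401806       40
```

`gene0000` is a minus-strand gene — its wave front (`leading_edge`) moves to
smaller coordinates over time while the TSS distance grows as ≈1.8 kb/min,
the planted velocity. The per-condition median rate at t = 10 min (3.03
kb/min) recovers the median of the planted U(1.5, 4.5) distribution, and the
median recovered half-life (5.4 h) matches the planted log-normal median of
5 h. Comparing per-gene estimates against the planted truth for this run
gives a median absolute relative error of 1 % and Spearman ρ = 0.997. The
drop of the median rate at t = 40 min is real: fast waves reach the ends of
100–150 kb genes within 40 min, so their leading edge saturates.

The same stages are available from the shell:

```sh
polkinetics simulate --seed 1 --n-genes 40 --outdir study/
polkinetics slam --conversion-tsv study/conversion_rates.tsv --outdir slam_out/
polkinetics waves --tss study/tss.bed --chrom-sizes study/chrom_sizes.tsv \
    --outdir waves_out/ \
    --track wt:0:study/drb_t0.plus.bedGraph:study/drb_t0.minus.bedGraph \
    --track wt:10:study/drb_t10.plus.bedGraph:study/drb_t10.minus.bedGraph \
    --track wt:25:study/drb_t25.plus.bedGraph:study/drb_t25.minus.bedGraph \
    --track wt:40:study/drb_t40.plus.bedGraph:study/drb_t40.minus.bedGraph
```

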