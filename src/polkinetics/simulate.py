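"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the study design the analyses were built for:

* a DRB (CDK9 inhibitor) block released for 10, 25 and 40 minutes, producing
  strand-specific nascent-transcription waves whose front advances at a
  gene-specific velocity over a time-independent t = 0 background;
* promoter-proximal Pol II accumulation with a tunable TSS:body ratio;
* T->C conversion rates decaying exponentially with log-normal gene
  half-lives, six replicates chased for 0, 6 and 12 hours;
* a fixed-fraction exogenous spike-in genome for normalization.

Reads are modelled as per-base Poisson counts on the underlying density
(PRO-seq tracks carry 5'-end counts only); a fixed seed reproduces every
output byte-identically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracks import SignalTrack
from .decay import CONVERSION_COLUMNS

MIN_GENE_GAP = 10_000  # bp between genes; keeps upstream-TSS calls unambiguous


@dataclass
class SimConfig:
    """Experimental-design constants of the simulated study.

    ``depth`` is the expected number of wave 5'-end reads per track at the
    first post-release timepoint (None: 20,000 per gene); the per-base wave
    density derived from it is held constant at later timepoints, as
    polymerases keep initiating behind the front.
    """
    seed: int = 0
    n_genes: int = 20
    chrom: str = "chrS"
    chrom_length: int | None = None   # None: sized to fit the genes
    gene_length_range: tuple[int, int] = (100_000, 150_000)
    timepoints_min: tuple = (0, 10, 25, 40)
    slam_timepoints_h: tuple = (0, 6, 12)
    n_replicates: int = 6
    depth: float | None = None
    noise_sigma: float = 0.1
    spike_fraction: float = 0.1
    signal_to_background: float = 10.0
    tss_region_width: int = 10

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0 <= self.spike_fraction <= 1:
            raise ValueError("spike_fraction must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid gene_length_range")


@dataclass
class GroundTruth:
    """Planted per-gene parameters the pipeline must recover."""
    gene_ids: list[str]
    elongation_rate: np.ndarray      # kb/min
    stalling_index: np.ndarray       # dimensionless
    half_life: np.ndarray            # hours
    size_factors: pd.Series          # per sample, geometric mean 1
    expression_weight: np.ndarray = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene_id": self.gene_ids,
            "elongation_rate_kb_per_min": self.elongation_rate,
            "stalling_index": self.stalling_index,
            "half_life_h": self.half_life,
            "expression_weight": self.expression_weight,
        })


def _rng(cfg: SimConfig, stream: str) -> np.random.Generator:
    # zlib.crc32 is stable across processes (str hash is salted)
    return np.random.default_rng(
        np.random.SeedSequence([cfg.seed, zlib.crc32(stream.encode())]))


def default_ground_truth(cfg: SimConfig,
                         rate_range: tuple[float, float] = (1.5, 4.5),
                         stalling_choices=(0.5, 1.0, 2.0, 5.0),
                         half_life_median_h: float = 5.0,
                         half_life_sigma_ln: float = 0.35,
                         samples=("WT", "KO", "dSPOC")) -> GroundTruth:
    """Draw plausible per-gene ground truth from the configured seed."""
    rng = _rng(cfg, "truth")
    n = cfg.n_genes
    rates = rng.uniform(*rate_range, size=n)
    stalling = rng.choice(stalling_choices, size=n)
    half_life = np.exp(np.log(half_life_median_h) +
                       half_life_sigma_ln * rng.standard_normal(n))
    raw = rng.uniform(0.5, 2.0, size=len(samples))
    factors = pd.Series(np.exp(np.log(raw) - np.log(raw).mean()),
                        index=list(samples), name="size_factor")
    weights = np.ones(n)
    return GroundTruth(gene_ids=[f"gene{i:04d}" for i in range(n)],
                       elongation_rate=rates, stalling_index=stalling,
                       half_life=half_life, size_factors=factors,
                       expression_weight=weights)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def make_toy_annotation(cfg: SimConfig
                        ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Place non-overlapping genes on one chromosome, >= 10 kb apart.

    Returns ``(transcripts, tss_regions, chrom_sizes)``.  Strands are drawn
    uniformly; each gene gets one transcript and one TSS region at its
    5' end.  Raises if the configured chromosome cannot hold the genes.
    """
    rng = _rng(cfg, "annotation")
    lo, hi = cfg.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n_genes)
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    needed = int(lengths.sum() + (cfg.n_genes + 1) * MIN_GENE_GAP)
    if cfg.chrom_length is None:
        chrom_length = needed
    else:
        chrom_length = cfg.chrom_length
        if needed > chrom_length:
            raise ValueError(
                f"chromosome of {chrom_length} bp cannot hold {cfg.n_genes} "
                f"genes of {lo}-{hi} bp with {MIN_GENE_GAP} bp gaps "
                f"({needed} bp needed)")
    tx_rows, tss_rows = [], []
    cursor = MIN_GENE_GAP
    for i, (length, strand) in enumerate(zip(lengths, strands)):
        start = cursor
        end = start + int(length)
        cursor = end + MIN_GENE_GAP
        gid = f"gene{i:04d}"
        tx_rows.append((cfg.chrom, start, end, f"{gid}.t1", gid, strand))
        # the TSS region's strand-aware downstream boundary (the promoter
        # anchor) coincides with the transcript 5' end
        if strand == "+":
            tss_lo = start - cfg.tss_region_width
        else:
            tss_lo = end
        tss_rows.append((cfg.chrom, tss_lo, tss_lo + cfg.tss_region_width,
                         gid, strand))
    transcripts = pd.DataFrame(tx_rows, columns=[
        "chrom", "start", "end", "transcript_id", "gene_id", "strand"])
    tss = pd.DataFrame(tss_rows, columns=[
        "chrom", "start", "end", "tss_id", "strand"])
    tss["gene_id"] = tss["tss_id"]
    return transcripts, tss, {cfg.chrom: chrom_length}


def _tss_point(tx) -> int:
    return int(tx.start) if tx.strand == "+" else int(tx.end)


def _promoter_window(tss_point: int, strand: str, flank: int = 250
                     ) -> tuple[int, int]:
    """Promoter interval anchored at the transcript 5' end, using the same
    half-open arithmetic as :func:`polkinetics.regions.make_promoters`."""
    if strand == "+":
        return tss_point - flank, tss_point + flank + 1
    return tss_point - flank - 1, tss_point + flank


# ---------------------------------------------------------------------------
# DRB-release wave tracks
# ---------------------------------------------------------------------------

def _wave_density(cfg: SimConfig, truth: GroundTruth,
                  transcripts: pd.DataFrame) -> float:
    """Per-base wave read density implied by ``depth`` at the first
    post-release timepoint."""
    depth = cfg.depth if cfg.depth is not None else 20_000.0 * cfg.n_genes
    t1 = min(t for t in cfg.timepoints_min if t > 0)
    w = truth.expression_weight
    lengths = (transcripts["end"] - transcripts["start"]).to_numpy()
    extents = np.minimum(truth.elongation_rate * t1 * 1000.0, lengths)
    return float(depth / np.sum(w * extents))


def _background_lam(cfg: SimConfig, truth: GroundTruth,
                    transcripts: pd.DataFrame, density: float,
                    chrom_sizes: dict) -> SignalTrack:
    """Expected-value (lambda) track of the t-independent background: uniform
    low-rate gene-body noise plus a promoter-proximal peak."""
    lam = SignalTrack(chrom_sizes, stranded=True, dtype=np.float32)
    if np.isinf(cfg.signal_to_background):  # background-free mode
        return lam
    body_rate = density / cfg.signal_to_background
    for i, tx in enumerate(transcripts.itertuples(index=False)):
        arr = lam.array(tx.chrom, tx.strand)
        w = truth.expression_weight[i]
        arr[tx.start:tx.end] += body_rate * w
        lo, hi = _promoter_window(_tss_point(tx), tx.strand)
        lo = max(0, lo)
        hi = min(chrom_sizes[tx.chrom], hi)
        arr[lo:hi] += density * w
    return lam


def simulate_drb_timecourse(transcripts: pd.DataFrame, truth: GroundTruth,
                            cfg: SimConfig) -> dict[int, SignalTrack]:
    """Strand-specific 5'-end count tracks for each washout timepoint.

    At timepoint t, gene g receives Poisson reads uniform over
    ``[TSS, TSS + v_g * t * 1000)`` (clipped to the gene end) on top of a
    background component whose realization is identical across timepoints;
    the t = 0 track is exactly that background.
    """
    if (truth.elongation_rate <= 0).any():
        raise ValueError("elongation rates must be > 0")
    if any(t < 0 for t in cfg.timepoints_min):
        raise ValueError("timepoints must be >= 0")
    _, _, chrom_sizes = _annotation_extent(transcripts, cfg)
    density = _wave_density(cfg, truth, transcripts)
    lam_bg = _background_lam(cfg, truth, transcripts, density, chrom_sizes)
    rng = _rng(cfg, "drb")
    background = SignalTrack(chrom_sizes, stranded=True, dtype=np.float32)
    for key in background.keys():
        lam = lam_bg.array(*key)
        nz = np.flatnonzero(lam)
        if nz.size:
            arr = background.array(*key)
            arr[nz] = rng.poisson(lam[nz].astype(np.float64)).astype(np.float32)
    tracks: dict[int, SignalTrack] = {}
    for t in cfg.timepoints_min:
        track = background.copy()
        if t > 0:
            for i, tx in enumerate(transcripts.itertuples(index=False)):
                v = truth.elongation_rate[i]
                extent = int(round(v * t * 1000.0))
                tss = _tss_point(tx)
                if tx.strand == "+":
                    lo, hi = tss, min(tx.end, tss + extent)
                else:
                    lo, hi = max(tx.start, tss - extent), tss
                if hi <= lo:
                    continue
                lam_val = density * truth.expression_weight[i]
                counts = rng.poisson(lam_val, size=hi - lo)
                arr = track.array(tx.chrom, tx.strand)
                arr[lo:hi] += counts.astype(np.float32)
        tracks[int(t)] = track
    return tracks


def _annotation_extent(transcripts: pd.DataFrame, cfg: SimConfig) -> tuple:
    sizes = {}
    for chrom, sub in transcripts.groupby("chrom"):
        sizes[chrom] = int(sub["end"].max()) + MIN_GENE_GAP
    if cfg.chrom_length is not None:
        sizes = {c: max(s, cfg.chrom_length) for c, s in sizes.items()}
    return transcripts, None, sizes


# ---------------------------------------------------------------------------
# Paused-Pol II tracks
# ---------------------------------------------------------------------------

def simulate_pausing_tracks(transcripts: pd.DataFrame, truth: GroundTruth,
                            cfg: SimConfig,
                            reads_per_gene: float = 10_000.0) -> SignalTrack:
    """5'-end tracks with a planted TSS : gene-body read ratio per gene.

    Reads split between the promoter window (TSS +/- 250 bp) and the uniform
    gene body (promoter end to gene end) so that the expected
    promoter/body count ratio equals the gene's stalling index.  A stalling
    index of 0 puts all reads in the body.
    """
    if (truth.stalling_index < 0).any():
        raise ValueError("stalling indices must be >= 0")
    _, _, chrom_sizes = _annotation_extent(transcripts, cfg)
    rng = _rng(cfg, "pausing")
    track = SignalTrack(chrom_sizes, stranded=True, dtype=np.float32)
    for i, tx in enumerate(transcripts.itertuples(index=False)):
        si = truth.stalling_index[i]
        n = reads_per_gene * truth.expression_weight[i]
        prom_lo, prom_hi = _promoter_window(_tss_point(tx), tx.strand)
        prom_lo = max(0, prom_lo)
        prom_hi = min(chrom_sizes[tx.chrom], prom_hi)
        if tx.strand == "+":
            body_lo, body_hi = prom_hi, tx.end
        else:
            body_lo, body_hi = tx.start, prom_lo
        arr = track.array(tx.chrom, tx.strand)
        p_prom = si / (1.0 + si)
        lam_prom = n * p_prom / (prom_hi - prom_lo)
        lam_body = n * (1.0 - p_prom) / max(1, body_hi - body_lo)
        if lam_prom > 0:
            arr[prom_lo:prom_hi] += rng.poisson(
                lam_prom, size=prom_hi - prom_lo).astype(np.float32)
        if body_hi > body_lo:
            arr[body_lo:body_hi] += rng.poisson(
                lam_body, size=body_hi - body_lo).astype(np.float32)
    return track


# ---------------------------------------------------------------------------
# SLAM-seq conversion tables
# ---------------------------------------------------------------------------

def simulate_conversion_table(truth: GroundTruth, cfg: SimConfig,
                              conditions=("WT",),
                              r0_range: tuple[float, float] = (0.005, 0.05)
                              ) -> pd.DataFrame:
    """Tidy conversion-rate table with planted exponential decay.

    ``r = r0 * 2**(-t / T) * exp(eps)`` with ``eps ~ N(0, sigma^2)`` drawn
    independently per (gene, condition, replicate, timepoint); rates are
    clipped into (0, 1].
    """
    if (truth.half_life <= 0).any():
        raise ValueError("half-lives must be > 0")
    rng = _rng(cfg, "slam")
    n = len(truth.gene_ids)
    r0 = rng.uniform(*r0_range, size=n)
    rows = []
    for gi, gene in enumerate(truth.gene_ids):
        for cond in conditions:
            for rep in range(1, cfg.n_replicates + 1):
                for t in cfg.slam_timepoints_h:
                    r = r0[gi] * 2.0 ** (-t / truth.half_life[gi])
                    if cfg.noise_sigma > 0:
                        r *= np.exp(cfg.noise_sigma * rng.standard_normal())
                    rows.append((gene, cond, rep, float(t), min(r, 1.0)))
    return pd.DataFrame(rows, columns=CONVERSION_COLUMNS)


# ---------------------------------------------------------------------------
# Spike-in count matrices
# ---------------------------------------------------------------------------

def simulate_spikein_counts(truth: GroundTruth, cfg: SimConfig,
                            depth: float = 1_000_000.0
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Target and spike count matrices whose spike totals recover the planted
    size factors.

    Each sample's sequencing depth is ``depth / size_factor`` (a sample
    needing more scaling up was sequenced shallower); the configured
    ``spike_fraction`` of each sample's reads falls on the spike genome, so
    factors proportional to 1 / spike reads recover the planted values.
    """
    if (truth.size_factors <= 0).any():
        raise ValueError("size factors must be > 0")
    rng = _rng(cfg, "spike")
    n = len(truth.gene_ids)
    w = truth.expression_weight / truth.expression_weight.sum()
    n_spike = max(10, n)
    ws = np.full(n_spike, 1.0 / n_spike)
    target, spike = {}, {}
    for sample, f in truth.size_factors.items():
        d = depth / f
        target[sample] = rng.poisson(d * (1 - cfg.spike_fraction) * w)
        spike[sample] = rng.poisson(d * cfg.spike_fraction * ws)
    target_df = pd.DataFrame(target, index=truth.gene_ids)
    spike_df = pd.DataFrame(spike,
                            index=[f"spike{i:04d}" for i in range(n_spike)])
    return target_df, spike_df


# ---------------------------------------------------------------------------
# Convenience bundle
# ---------------------------------------------------------------------------

def simulate_study(cfg: SimConfig, truth: GroundTruth | None = None) -> dict:
    """Generate annotation, DRB tracks, pausing track, conversion table and
    spike-in counts in one shot."""
    transcripts, tss, chrom_sizes = make_toy_annotation(cfg)
    truth = truth or default_ground_truth(cfg)
    return {
        "config": cfg,
        "truth": truth,
        "transcripts": transcripts,
        "tss": tss,
        "chrom_sizes": chrom_sizes,
        "drb_tracks": simulate_drb_timecourse(transcripts, truth, cfg),
        "pausing_track": simulate_pausing_tracks(transcripts, truth, cfg),
        "conversion_table": simulate_conversion_table(truth, cfg),
        "spikein_counts": simulate_spikein_counts(truth, cfg),
    }
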