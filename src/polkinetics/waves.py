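"""DRB-washout leading-edge calling and elongation-rate estimation.

After release from a DRB (CDK9 inhibitor) block, polymerases advance from the
TSS as a synchronized wave; the strand-aware downstream boundary of the
contiguously expressed region on the (t - t0) difference track, divided by
the washout time, gives the gene's elongation rate in kb/min.

The caller works on 1 kb genome tiles: covered bases are counted per tile,
smoothed with a one-step non-iterative running maximum, tiles failing the
covered-fraction or signal thresholds are dropped, survivors within the merge
gap are joined into regions, and short regions are discarded.  Regions are
annotated to the gene with the closest upstream TSS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import SignalTrack


@dataclass
class WaveParams:
    """Tunable parameters of the wave caller (defaults per the method)."""
    tile: int = 1000                 # tile width, bp
    min_covered_frac: float = 0.25   # minimum covered fraction per tile
    min_tile_signal: float = 0.1     # minimum summed normalized signal per tile
    merge_gap: int = 4000            # max gap joined into one region, bp
    min_region_len: int = 3000       # minimum region length, bp
    tss_slack: int = 1000            # upstream-TSS tolerance for tile quantization
    timepoints: tuple = (10, 25, 40)  # minutes after washout

    def __post_init__(self):
        if self.tile <= 0 or self.merge_gap < 0 or self.min_region_len <= 0:
            raise ValueError("tile/merge/length parameters must be positive")
        if not 0 < self.min_covered_frac <= 1:
            raise ValueError("min_covered_frac must be in (0, 1]")


@dataclass
class TileVector:
    """Fixed-width tiles of one (chromosome, strand) lane."""
    chrom: str
    strand: str
    tile: int
    starts: np.ndarray
    covered: np.ndarray          # raw covered-base counts
    signal_sum: np.ndarray
    smoothed_covered: np.ndarray
    chrom_size: int = 0


def difference_track(track_t: SignalTrack, track_0: SignalTrack) -> SignalTrack:
    """Per-base max(0, s_t - s_0); negatives censored."""
    if track_t.chrom_sizes != track_0.chrom_sizes or \
            track_t.stranded != track_0.stranded:
        raise ValueError("tracks have mismatched chromosomes or strandedness")
    out = SignalTrack(track_t.chrom_sizes, track_t.stranded, track_t.dtype)
    for chrom in track_t.chrom_sizes:
        for strand in track_t.strands:
            d = track_t.array(chrom, strand) - track_0.array(chrom, strand)
            np.maximum(d, 0, out=d)
            out.array(chrom, strand)[:] = d
    return out


def smooth_covered(raw: np.ndarray) -> np.ndarray:
    """Non-iterative running maximum with the preceding tile:
    ``out[n] = max(raw[n-1], raw[n])``, ``out[0] = raw[0]``."""
    out = raw.copy()
    if out.size > 1:
        np.maximum(raw[1:], raw[:-1], out=out[1:])
    return out


def tile_and_smooth(track: SignalTrack, params: WaveParams | None = None
                    ) -> list[TileVector]:
    """Split each (chrom, strand) lane into fixed tiles; count covered bases
    and summed signal per tile, then smooth the covered counts."""
    params = params or WaveParams()
    width = params.tile
    out = []
    for chrom, size in track.chrom_sizes.items():
        n_tiles = -(-size // width)
        edges = np.arange(0, n_tiles * width, width)
        for strand in track.strands:
            arr = track.array(chrom, strand)
            covered = np.add.reduceat((arr > 0).astype(np.int64), edges)
            signal = np.add.reduceat(arr.astype(np.float64), edges)
            out.append(TileVector(chrom, strand, width, edges, covered,
                                  signal, smooth_covered(covered), size))
    return out


def call_expressed_regions(tiles: list[TileVector],
                           params: WaveParams | None = None) -> pd.DataFrame:
    """Filter, merge and length-select tiles into expressed regions.

    A tile is retained when its smoothed covered-base count is at least
    ``min_covered_frac * tile`` and its summed signal at least
    ``min_tile_signal``; retained tiles whose gap is at most ``merge_gap`` bp
    are merged; regions shorter than ``min_region_len`` bp are dropped
    (thresholds inclusive).
    """
    params = params or WaveParams()
    rows = []
    for tv in tiles:
        keep = (tv.smoothed_covered >= params.min_covered_frac * tv.tile) & \
               (tv.signal_sum >= params.min_tile_signal)
        idx = np.flatnonzero(keep)
        if idx.size == 0:
            continue
        starts = tv.starts[idx]
        ends = np.minimum(starts + tv.tile,
                          tv.chrom_size or starts[-1] + tv.tile)
        # merge retained tiles whose inter-tile gap <= merge_gap
        breaks = np.flatnonzero(starts[1:] - ends[:-1] > params.merge_gap) + 1
        for lo, hi in zip(np.concatenate(([0], breaks)),
                          np.concatenate((breaks, [idx.size]))):
            start, end = int(starts[lo]), int(ends[hi - 1])
            if end - start >= params.min_region_len:
                rows.append((tv.chrom, start, end, tv.strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])


def annotate_to_upstream_tss(regions: pd.DataFrame, tss: pd.DataFrame,
                             slack: int = 1000) -> pd.DataFrame:
    """Assign each region to the gene with the closest upstream TSS.

    The TSS site is the strand-aware 5' boundary of the TSS region.  ``slack``
    (default one tile) lets a TSS lying up to that many bp inside the region
    still count as upstream, absorbing tile quantization of region starts.
    Regions with no upstream TSS on their strand are dropped.

    ``tss`` needs columns chrom, start, end, strand and a gene identifier in
    ``gene_id`` (falling back to ``tss_id``).
    """
    if len(tss) == 0:
        raise ValueError("TSS set is empty")
    gene_col = "gene_id" if "gene_id" in tss.columns else "tss_id"
    rows = []
    for (chrom, strand), sub in tss.groupby(["chrom", "strand"]):
        pos = np.where(sub["strand"] == "+", sub["start"], sub["end"])
        order = np.argsort(pos)
        pos = pos[order]
        genes = sub[gene_col].to_numpy()[order]
        reg = regions[(regions["chrom"] == chrom) &
                      (regions["strand"] == strand)]
        for r in reg.itertuples(index=False):
            if strand == "+":
                j = int(np.searchsorted(pos, r.start + slack, side="right")) - 1
                if j < 0:
                    continue
            else:
                j = int(np.searchsorted(pos, r.end - slack, side="left"))
                if j >= pos.size:
                    continue
            rows.append((r.chrom, r.start, r.end, r.strand, genes[j],
                         int(pos[j])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                       "gene_id", "tss_pos"])


def elongation_rates(regions: pd.DataFrame,
                     params: WaveParams | None = None,
                     gene_subset=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene elongation rates from annotated expressed regions.

    ``regions`` must carry columns from :func:`annotate_to_upstream_tss` plus
    ``condition`` and ``timepoint`` (minutes, t > 0 only).  The leading edge
    is the strand-aware 3'-most boundary of the gene's region (when several
    regions are assigned, the one whose 5' boundary lies closest to the TSS);
    rate = distance / (t * 1000) kb/min.  Genes lacking a region (or with a
    non-positive edge distance) at any (condition, timepoint) are excluded.

    Returns ``(rates, medians)``; medians are per (condition, timepoint) over
    ``gene_subset`` when given (e.g. genes > 100 kb), else over all kept genes.
    """
    params = params or WaveParams()
    required = set(pd.MultiIndex.from_product(
        [regions["condition"].unique(), [t for t in params.timepoints if t > 0]]))
    rows = []
    for (gene, cond, t), grp in regions.groupby(
            ["gene_id", "condition", "timepoint"]):
        if t <= 0:
            continue
        strand = grp["strand"].iloc[0]
        tss_pos = grp["tss_pos"].iloc[0]
        if strand == "+":
            pick = grp.loc[(grp["start"] - tss_pos).abs().idxmin()]
            edge = int(pick["end"])
            dist = edge - tss_pos
        else:
            pick = grp.loc[(grp["end"] - tss_pos).abs().idxmin()]
            edge = int(pick["start"])
            dist = tss_pos - edge
        rows.append((gene, cond, t, edge, dist, dist / (t * 1000.0)))
    rates = pd.DataFrame(rows, columns=["gene_id", "condition", "timepoint",
                                        "leading_edge", "distance_from_tss",
                                        "rate_kb_per_min"])
    # keep genes defined with positive distance at every condition x timepoint
    ok = rates[rates["distance_from_tss"] > 0]
    if len(ok):
        complete = ok.groupby("gene_id").apply(
            lambda g: set(zip(g["condition"], g["timepoint"])) >= required,
            include_groups=False)
        kept = complete[complete].index
        rates = ok[ok["gene_id"].isin(kept)].reset_index(drop=True)
    else:
        rates = ok.reset_index(drop=True)
    med_src = rates if gene_subset is None else \
        rates[rates["gene_id"].isin(gene_subset)]
    medians = (med_src.groupby(["condition", "timepoint"])["rate_kb_per_min"]
               .median().reset_index(name="median_rate_kb_per_min"))
    return rates, medians


def processivity_index(track: SignalTrack, gene_body,
                       proximal_frac: float = 0.1, distal_frac: float = 0.1
                       ) -> tuple[float, str | None]:
    """log10 of distal over proximal gene-body reads.

    Windows are the first (proximal) and last (distal) fraction of the gene
    body in transcription direction.  Returns ``(index, flag)``; the index is
    NaN with a flag when either window has zero reads.
    """
    if not (0 < proximal_frac <= 0.5 and 0 < distal_frac <= 0.5):
        raise ValueError("window fractions must be in (0, 0.5]")
    gb = gene_body
    start, end, strand = int(gb["start"]), int(gb["end"]), gb["strand"]
    length = end - start
    pw = max(1, int(round(length * proximal_frac)))
    dw = max(1, int(round(length * distal_frac)))
    if strand == "+":
        prox = track.region_sum(gb["chrom"], start, start + pw, strand)
        dist = track.region_sum(gb["chrom"], end - dw, end, strand)
    else:
        prox = track.region_sum(gb["chrom"], end - pw, end, strand)
        dist = track.region_sum(gb["chrom"], start, start + dw, strand)
    if prox == 0:
        return float("nan"), "zero_proximal"
    if dist == 0:
        return float("nan"), "zero_distal"
    return float(np.log10(dist / prox)), None
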