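"""Pol II stalling index, expression/read-through gene filters, and metagene
signal profiles."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import SignalTrack, region_rpkm


def stalling_index(promoter_count: float, body_count: float
                   ) -> tuple[float, str | None]:
    """TSS-region reads over gene-body reads; NaN with a flag when the body
    has zero reads."""
    if body_count == 0:
        return float("nan"), "zero_body"
    return promoter_count / body_count, None


def gene_counts(track: SignalTrack, promoters: pd.DataFrame,
                bodies: pd.DataFrame) -> pd.DataFrame:
    """Per-gene promoter and gene-body 5'-end counts from one track."""
    bodies = bodies.set_index("gene_id")
    rows = []
    for p in promoters.itertuples(index=False):
        b = bodies.loc[p.gene_id]
        pc = track.region_sum(p.chrom, p.start, p.end, p.strand)
        bc = track.region_sum(b["chrom"], b["start"], b["end"], b["strand"])
        si, flag = stalling_index(pc, bc)
        rows.append((p.gene_id, pc, bc, si, flag))
    return pd.DataFrame(rows, columns=["gene_id", "promoter_count",
                                       "body_count", "stalling_index", "flag"])


def upstream_window(promoter) -> tuple[int, int]:
    """The read-through control window: 250 bp wide, starting 500 bp and
    ending 250 bp upstream of the promoter's 5' boundary, strand-aware."""
    if promoter["strand"] == "+":
        return int(promoter["start"]) - 500, int(promoter["start"]) - 250
    return int(promoter["end"]) + 250, int(promoter["end"]) + 500


def expression_filter_table(promoters: pd.DataFrame, wt_track: SignalTrack,
                            sample_tracks: dict[str, SignalTrack],
                            wt_library_size: float,
                            library_sizes: dict[str, float]) -> pd.DataFrame:
    """Assemble the per-gene RPKM table the expression filters operate on:
    WT upstream-window RPKM plus promoter RPKM per sample."""
    rows = []
    for p in promoters.itertuples(index=False):
        prom = {"chrom": p.chrom, "start": p.start, "end": p.end,
                "strand": p.strand}
        us, ue = upstream_window(prom)
        us, ue = max(0, us), min(wt_track.chrom_sizes[p.chrom], ue)
        up_count = wt_track.region_sum(p.chrom, us, ue, p.strand)
        row = {"gene_id": p.gene_id,
               "upstream_rpkm": region_rpkm(up_count, max(1, ue - us),
                                            wt_library_size)}
        for sample, track in sample_tracks.items():
            c = track.region_sum(p.chrom, p.start, p.end, p.strand)
            row[f"promoter_rpkm_{sample}"] = region_rpkm(
                c, p.end - p.start, library_sizes[sample])
        rows.append(row)
    return pd.DataFrame(rows)


def apply_expression_filters(table: pd.DataFrame,
                             readthrough_rpkm: float = 8.0,
                             expressed_rpkm: float = 2.0
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop read-through and non-expressed genes.

    Removes genes whose WT upstream-window RPKM exceeds ``readthrough_rpkm``
    and genes whose promoter RPKM is below ``expressed_rpkm`` in every sample.
    Returns ``(kept, audit)``; the audit log names the rule that removed each
    gene.  The two rules commute.
    """
    prom_cols = [c for c in table.columns if c.startswith("promoter_rpkm_")]
    if not prom_cols:
        raise ValueError("table has no promoter_rpkm_<sample> columns")
    readthrough = table["upstream_rpkm"] > readthrough_rpkm
    non_expressed = (table[prom_cols] < expressed_rpkm).all(axis=1)
    audit_rows = []
    for _, row in table[readthrough | non_expressed].iterrows():
        reasons = []
        if row["upstream_rpkm"] > readthrough_rpkm:
            reasons.append("readthrough")
        if all(row[c] < expressed_rpkm for c in prom_cols):
            reasons.append("non_expressed")
        audit_rows.append((row["gene_id"], "+".join(reasons)))
    kept = table[~(readthrough | non_expressed)].reset_index(drop=True)
    audit = pd.DataFrame(audit_rows, columns=["gene_id", "removed_by"])
    return kept, audit


@dataclass
class Profile:
    """A metagene profile: one trimmed-mean value per bin."""
    values: np.ndarray
    nbins: int
    trim: float
    per_region_minmax: bool
    n_regions: int
    n_skipped: int = 0


def _bin_means(values: np.ndarray, nbins: int) -> np.ndarray:
    """Mean signal in ``nbins`` equal-width bins with fractional-overlap
    weighting (exact for regions shorter than ``nbins`` bp)."""
    n = values.size
    cum = np.concatenate(([0.0], np.cumsum(values, dtype=np.float64)))
    edges = np.linspace(0.0, float(n), nbins + 1)
    integral = np.interp(edges, np.arange(n + 1), cum)
    widths = np.diff(edges)
    return np.diff(integral) / widths


def metaprofile(track: SignalTrack, regions: pd.DataFrame, nbins: int = 100,
                trim: float = 0.3, per_region_minmax: bool = False) -> Profile:
    """Average signal over a region class into ``nbins`` bins.

    Each region is strand-oriented (bin 1 = 5' end), binned by fractional
    overlap, optionally min-max rescaled to [0, 1], and the per-bin summary
    across regions is the two-sided trimmed mean (``trim`` cut from each
    tail).  Regions that are constant under min-max rescaling are skipped.
    """
    if len(regions) == 0:
        raise ValueError("no regions given")
    mat_rows, skipped = [], 0
    for r in regions.itertuples(index=False):
        arr = track.array(r.chrom, r.strand if track.stranded else ".")
        vals = np.asarray(arr[r.start:r.end], dtype=np.float64)
        if r.strand == "-":
            vals = vals[::-1]
        binned = _bin_means(vals, nbins)
        if per_region_minmax:
            lo, hi = binned.min(), binned.max()
            if hi == lo:
                skipped += 1
                continue
            binned = (binned - lo) / (hi - lo)
        mat_rows.append(binned)
    if not mat_rows:
        raise ValueError("all regions skipped (constant under min-max)")
    mat = np.vstack(mat_rows)
    values = stats.trim_mean(mat, proportiontocut=trim, axis=0) if trim > 0 \
        else mat.mean(axis=0)
    return Profile(values=np.asarray(values), nbins=nbins, trim=trim,
                   per_region_minmax=per_region_minmax,
                   n_regions=len(mat_rows), n_skipped=skipped)
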