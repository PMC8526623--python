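"""Promoter and gene-body definitions from TSS regions and transcript models.

Coordinates are 0-based half-open throughout (BED convention; GTF is
converted on I/O).  A FANTOM-style TSS region is anchored at its strand-aware
downstream ("end") boundary and extended by +/- ``flank`` bp into a promoter;
the gene body runs from the promoter end to the modal annotated transcript
end, ties broken by the longest isoform.

Interval tables are plain pandas DataFrames:

* TSS regions: columns ``chrom, start, end, tss_id, strand``
* transcripts: columns ``chrom, start, end, transcript_id, gene_id, strand``
* promoters / gene bodies: ``chrom, start, end, <id>, strand``
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd


class DegenerateGeneError(ValueError):
    """The representative transcript end lies upstream of the promoter end."""


def _tss_anchor(row, anchor: str) -> int:
    """Strand-aware anchor coordinate of a TSS region.

    ``anchor="end"``: the downstream boundary in transcription direction
    (``end`` for +, ``start`` for -).  ``anchor="midpoint"``: the midpoint.
    """
    if anchor == "midpoint":
        return int((row.start + row.end) // 2)
    if anchor != "end":
        raise ValueError("anchor must be 'end' or 'midpoint'")
    return int(row.end) if row.strand == "+" else int(row.start)


def make_promoters(tss: pd.DataFrame, flank: int = 250,
                   chrom_sizes: Mapping[str, int] | None = None,
                   anchor: str = "end") -> pd.DataFrame:
    """Extend each TSS region into a promoter of width ``2*flank + 1``.

    Plus strand: ``[a - flank, a + flank + 1)`` with ``a`` the anchor; minus
    strand is the exact mirror, ``[a - flank - 1, a + flank)``.  Promoters are
    clipped at chromosome bounds when ``chrom_sizes`` is given.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    rows = []
    for row in tss.itertuples(index=False):
        if chrom_sizes is not None:
            size = chrom_sizes[row.chrom]
            if row.start < 0 or row.end > size:
                raise ValueError(
                    f"TSS region {row.tss_id} outside chromosome {row.chrom}")
        a = _tss_anchor(row, anchor)
        if row.strand == "+":
            start, end = a - flank, a + flank + 1
        else:
            start, end = a - flank - 1, a + flank
        if chrom_sizes is not None:
            size = chrom_sizes[row.chrom]
            start, end = max(0, start), min(size, end)
        rows.append((row.chrom, start, end, row.tss_id, row.strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "tss_id",
                                       "strand"])


def assign_to_transcript(promoters: pd.DataFrame, transcripts: pd.DataFrame,
                         max_dist: int = 2000
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map each promoter to the nearest same-strand transcript.

    Returns ``(assigned, dropped)``.  ``assigned`` carries the promoter
    columns plus ``transcript_id, gene_id, distance``; promoters farther than
    ``max_dist`` bp from every same-strand transcript (or with none available)
    appear in ``dropped`` with the offending distance.
    """
    assigned_rows, dropped_rows = [], []
    tx_groups = {k: g.sort_values("start").reset_index(drop=True)
                 for k, g in transcripts.groupby(["chrom", "strand"])}
    for prom in promoters.itertuples(index=False):
        g = tx_groups.get((prom.chrom, prom.strand))
        if g is None or len(g) == 0:
            dropped_rows.append((*prom, np.inf))
            continue
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        prefix_max_end = np.maximum.accumulate(ends)
        j = int(np.searchsorted(starts, prom.end, side="left"))
        best_dist, best_idx = np.inf, -1
        if j < len(g):  # nearest transcript entirely downstream of promoter end
            best_dist, best_idx = starts[j] - prom.end, j
        if j > 0:
            pme = prefix_max_end[j - 1]
            if pme > prom.start:  # overlap
                # recover an overlapping index for reporting
                mask = (starts[:j] < prom.end) & (ends[:j] > prom.start)
                best_dist, best_idx = 0, int(np.flatnonzero(mask)[0])
            elif prom.start - pme < best_dist:
                best_dist = prom.start - pme
                best_idx = int(np.flatnonzero(ends[:j] == pme)[0])
        if best_dist > max_dist:
            dropped_rows.append((*prom, float(best_dist)))
            continue
        tx = g.iloc[best_idx]
        assigned_rows.append((*prom, tx["transcript_id"], tx["gene_id"],
                              int(best_dist)))
    prom_cols = list(promoters.columns)
    assigned = pd.DataFrame(assigned_rows, columns=prom_cols +
                            ["transcript_id", "gene_id", "distance"])
    dropped = pd.DataFrame(dropped_rows, columns=prom_cols + ["distance"])
    return assigned, dropped


def representative_gene_body(transcripts: pd.DataFrame, promoter) -> dict:
    """Gene body from the promoter end to the representative transcript end.

    The representative 3' end is the modal strand-aware transcript end; among
    tied modal ends the longest supporting isoform decides.  Raises
    :class:`DegenerateGeneError` when the body would be empty.
    """
    if len(transcripts) == 0:
        raise ValueError("at least one transcript required")
    strand = transcripts["strand"].iloc[0]
    ends3 = transcripts["end"] if strand == "+" else transcripts["start"]
    counts = ends3.value_counts()
    top = counts[counts == counts.max()].index
    if len(top) == 1:
        rep_end = int(top[0])
    else:
        cand = transcripts[ends3.isin(top)]
        lengths = cand["end"] - cand["start"]
        rep_end = int((cand["end"] if strand == "+" else cand["start"])
                      .loc[lengths.idxmax()])
    prom_end = promoter["end"] if isinstance(promoter, (dict, pd.Series)) \
        else promoter.end
    prom_start = promoter["start"] if isinstance(promoter, (dict, pd.Series)) \
        else promoter.start
    if strand == "+":
        start, end = int(prom_end), rep_end
    else:
        start, end = rep_end, int(prom_start)
    if end <= start:
        raise DegenerateGeneError(
            f"representative end {rep_end} upstream of promoter end")
    return {"chrom": transcripts["chrom"].iloc[0], "start": start, "end": end,
            "strand": strand}


def select_representative_promoter(candidates: pd.DataFrame, track) -> pd.Series:
    """Among candidate promoters of one gene, pick the one with the highest
    mean signal on its own strand; ties broken by leftmost start."""
    if len(candidates) == 0:
        raise ValueError("at least one candidate promoter required")
    means = np.array([
        track.region_mean(p.chrom, p.start, p.end, p.strand)
        for p in candidates.itertuples(index=False)])
    best = means.max()
    tied = candidates.reset_index(drop=True)[means == best]
    return tied.sort_values("start").iloc[0]


def build_gene_regions(tss: pd.DataFrame, transcripts: pd.DataFrame,
                       flank: int = 250, max_dist: int = 2000,
                       chrom_sizes: Mapping[str, int] | None = None,
                       track=None, anchor: str = "end"
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end region definition: promoters and gene bodies per gene.

    TSS regions are extended to promoters, assigned to their nearest
    same-strand transcript (dropping those > ``max_dist`` away), one promoter
    per gene is selected (by mean track signal when ``track`` is given,
    otherwise the leftmost), and the representative gene body is derived.
    Genes whose body would be degenerate are skipped.
    """
    promoters = make_promoters(tss, flank=flank, chrom_sizes=chrom_sizes,
                               anchor=anchor)
    assigned, _ = assign_to_transcript(promoters, transcripts, max_dist)
    prom_rows, body_rows = [], []
    for gene_id, group in assigned.groupby("gene_id", sort=True):
        if track is not None and len(group) > 1:
            prom = select_representative_promoter(group, track)
        else:
            prom = group.sort_values("start").iloc[0]
        gene_tx = transcripts[transcripts["gene_id"] == gene_id]
        try:
            body = representative_gene_body(gene_tx, prom)
        except DegenerateGeneError:
            continue
        prom_rows.append((prom["chrom"], prom["start"], prom["end"], gene_id,
                          prom["strand"]))
        body_rows.append((body["chrom"], body["start"], body["end"], gene_id,
                          body["strand"]))
    cols = ["chrom", "start", "end", "gene_id", "strand"]
    return (pd.DataFrame(prom_rows, columns=cols),
            pd.DataFrame(body_rows, columns=cols))
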