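"""Readers and writers for the plain-text interchange formats: BED6, GTF,
bedGraph (via :mod:`.tracks`) and tab-separated tables."""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_bed6(df: pd.DataFrame, path, name_col: str | None = None) -> Path:
    """Write an interval table as BED6; ``name_col`` picks the id column
    (default: ``gene_id``/``tss_id``/``name``, whichever exists)."""
    if name_col is None:
        name_col = next(c for c in ("gene_id", "tss_id", "name", "transcript_id")
                        if c in df.columns)
    out = pd.DataFrame({
        "chrom": df["chrom"], "start": df["start"], "end": df["end"],
        "name": df[name_col], "score": 0, "strand": df["strand"]})
    out.to_csv(path, sep="\t", header=False, index=False)
    return Path(path)


def read_bed6(path, name_col: str = "name") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS,
                     dtype={"chrom": str})
    return df.rename(columns={"name": name_col})


def write_gtf(transcripts: pd.DataFrame, path,
              source: str = "polkinetics") -> Path:
    """Write transcripts (0-based half-open) as GTF transcript+exon features
    (1-based closed on disk)."""
    with open(path, "w") as fh:
        for tx in transcripts.itertuples(index=False):
            attrs = (f'gene_id "{tx.gene_id}"; '
                     f'transcript_id "{tx.transcript_id}";')
            for feature in ("transcript", "exon"):
                fh.write("\t".join([
                    tx.chrom, source, feature, str(tx.start + 1), str(tx.end),
                    ".", tx.strand, ".", attrs]) + "\n")
    return Path(path)


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gtf_transcripts(path) -> pd.DataFrame:
    """Read transcript features from a GTF into the internal 0-based
    half-open transcript table."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"malformed GTF line {i}: expected 9 fields")
            if parts[2] != "transcript":
                continue
            attrs = dict(_GTF_ATTR.findall(parts[8]))
            rows.append((parts[0], int(parts[3]) - 1, int(parts[4]),
                         attrs.get("transcript_id", ""),
                         attrs.get("gene_id", ""), parts[6]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                       "transcript_id", "gene_id", "strand"])


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet TSV: sample, condition, timepoint, plus/minus bedGraph
    paths, and read-count columns used for normalization."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "condition", "timepoint"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return df
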