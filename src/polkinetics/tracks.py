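"""Strand-specific genomic signal tracks and spike-in normalization.

A :class:`SignalTrack` holds per-base, per-strand signal on named chromosomes
as dense arrays (bedGraph, the canonical on-disk form, run-length encodes the
same values).  PRO-seq tracks carry read 5'-end counts; ChIP tracks carry
extended-read coverage and are unstranded (strand key ``"."``).

Spike-in conventions:

* PRO-seq / RNA-seq (exogenous Drosophila material): per-sample scaling
  factors proportional to 1 / spike reads, rescaled to geometric mean 1, so
  that a sample in which more spike-in was recovered is scaled *down*.
* ChIP-seq (mouse chromatin spike-in): a single scalar, target-genome reads
  divided by spike-genome reads, multiplied onto the coverage track.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

STRANDS = ("+", "-")
UNSTRANDED = "."


class SignalTrack:
    """Per-base non-negative signal, keyed by (chromosome, strand).

    Parameters
    ----------
    chrom_sizes
        Mapping chromosome name -> length in bp.
    stranded
        If True the track has separate "+" and "-" lanes, otherwise a single
        "." lane (ChIP coverage).
    dtype
        Storage dtype; float32 keeps whole-genome tracks desk-sized.
    """

    def __init__(self, chrom_sizes: Mapping[str, int], stranded: bool = True,
                 dtype=np.float32):
        self.chrom_sizes = dict(chrom_sizes)
        self.stranded = stranded
        self.dtype = np.dtype(dtype)
        self.scale_applied = 1.0
        self.units = "counts"
        self._data: dict[tuple[str, str], np.ndarray] = {}

    # -- storage ---------------------------------------------------------
    @property
    def strands(self) -> tuple[str, ...]:
        return STRANDS if self.stranded else (UNSTRANDED,)

    def _check(self, chrom: str, strand: str) -> None:
        if chrom not in self.chrom_sizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if strand not in self.strands:
            raise KeyError(f"strand {strand!r} not valid for this track")

    def array(self, chrom: str, strand: str = UNSTRANDED) -> np.ndarray:
        """Dense per-base array for one (chrom, strand); created on demand."""
        self._check(chrom, strand)
        key = (chrom, strand)
        if key not in self._data:
            self._data[key] = np.zeros(self.chrom_sizes[chrom], dtype=self.dtype)
        return self._data[key]

    def keys(self):
        return [(c, s) for c in self.chrom_sizes for s in self.strands]

    # -- queries ---------------------------------------------------------
    def total(self) -> float:
        return float(sum(a.sum(dtype=np.float64) for a in self._data.values()))

    def region_sum(self, chrom: str, start: int, end: int,
                   strand: str | None = None) -> float:
        """Sum of signal over [start, end); both strands if strand is None."""
        start = max(0, int(start))
        end = min(self.chrom_sizes[chrom], int(end))
        if end <= start:
            return 0.0
        lanes = self.strands if strand is None else (strand,)
        out = 0.0
        for s in lanes:
            key = (chrom, s)
            if key in self._data:
                out += float(self._data[key][start:end].sum(dtype=np.float64))
        return out

    def region_mean(self, chrom: str, start: int, end: int,
                    strand: str | None = None) -> float:
        start = max(0, int(start))
        end = min(self.chrom_sizes[chrom], int(end))
        if end <= start:
            return 0.0
        return self.region_sum(chrom, start, end, strand) / (end - start)

    # -- transforms ------------------------------------------------------
    def scale(self, factor: float) -> "SignalTrack":
        """Multiply every value by ``factor`` in place; records the factor."""
        if factor <= 0 or not math.isfinite(factor):
            raise ValueError(f"scale factor must be positive finite, got {factor}")
        for a in self._data.values():
            a *= self.dtype.type(factor)
        self.scale_applied *= factor
        return self

    def copy(self) -> "SignalTrack":
        out = SignalTrack(self.chrom_sizes, self.stranded, self.dtype)
        out.scale_applied = self.scale_applied
        out.units = self.units
        out._data = {k: v.copy() for k, v in self._data.items()}
        return out

    # -- I/O -------------------------------------------------------------
    def to_bedgraph(self, prefix: str | Path) -> list[Path]:
        """Write one 4-column bedGraph per strand.

        Stranded tracks get ``<prefix>.plus.bedGraph`` / ``.minus.bedGraph``;
        unstranded tracks a single ``<prefix>.bedGraph``.  Zero runs are
        omitted, as is conventional.
        """
        prefix = Path(prefix)
        names = {"+": ".plus", "-": ".minus", UNSTRANDED: ""}
        written = []
        for strand in self.strands:
            path = prefix.with_name(prefix.name + names[strand] + ".bedGraph")
            with open(path, "w") as fh:
                for chrom in self.chrom_sizes:
                    key = (chrom, strand)
                    if key not in self._data:
                        continue
                    for start, end, value in _runs(self._data[key]):
                        fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")
            written.append(path)
        return written

    @classmethod
    def from_bedgraph(cls, chrom_sizes: Mapping[str, int],
                      plus: str | Path | None = None,
                      minus: str | Path | None = None,
                      unstranded: str | Path | None = None,
                      dtype=np.float32) -> "SignalTrack":
        if unstranded is not None:
            track = cls(chrom_sizes, stranded=False, dtype=dtype)
            _read_bedgraph_into(track, unstranded, UNSTRANDED)
            return track
        track = cls(chrom_sizes, stranded=True, dtype=dtype)
        if plus is not None:
            _read_bedgraph_into(track, plus, "+")
        if minus is not None:
            _read_bedgraph_into(track, minus, "-")
        return track


def _runs(values: np.ndarray):
    """Yield (start, end, value) runs of equal non-zero value."""
    n = values.size
    if n == 0:
        return
    change = np.flatnonzero(values[1:] != values[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    for s, e in zip(starts, ends):
        v = float(values[s])
        if v != 0.0:
            yield int(s), int(e), v


def _read_bedgraph_into(track: SignalTrack, path: str | Path, strand: str) -> None:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str})
    for chrom, sub in df.groupby("chrom", sort=False):
        arr = track.array(chrom, strand)
        for start, end, value in zip(sub["start"], sub["end"], sub["value"]):
            if end > arr.size or start < 0:
                raise ValueError(f"interval {chrom}:{start}-{end} beyond chromosome")
            arr[start:end] = value


# ---------------------------------------------------------------------------
# Track construction
# ---------------------------------------------------------------------------

def five_prime_track(reads: pd.DataFrame, chrom_sizes: Mapping[str, int],
                     flip_strand: bool = False) -> SignalTrack:
    """Count read 5' ends per base, strand-specifically.

    ``reads`` needs columns chrom, start, end, strand (0-based half-open).
    A plus-strand read contributes +1 at ``start``, a minus-strand read at
    ``end - 1``.  ``flip_strand`` covers adaptor schemes where the alignment
    strand is the reverse of the transcription strand.
    """
    track = SignalTrack(chrom_sizes, stranded=True)
    if len(reads) == 0:
        return track
    if (reads["start"] < 0).any():
        raise ValueError("read interval with negative start")
    for (chrom, strand), sub in reads.groupby(["chrom", "strand"], sort=False):
        if (sub["end"] > chrom_sizes[chrom]).any():
            raise ValueError(f"read interval beyond chromosome {chrom}")
        pos = np.where(sub["strand"].to_numpy() == "+",
                       sub["start"].to_numpy(), sub["end"].to_numpy() - 1)
        out_strand = strand
        if flip_strand:
            out_strand = "-" if strand == "+" else "+"
        np.add.at(track.array(chrom, out_strand), pos, 1.0)
    return track


def chip_coverage_track(reads: pd.DataFrame, chrom_sizes: Mapping[str, int],
                        extend: int = 200) -> SignalTrack:
    """Extend each read to ``extend`` bp from its 5' end (strand-aware) and sum
    per-base coverage across strands into an unstranded track."""
    track = SignalTrack(chrom_sizes, stranded=False)
    for chrom, sub in reads.groupby("chrom", sort=False):
        arr = track.array(chrom, UNSTRANDED)
        strands = sub["strand"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        five = np.where(strands == "+", starts, ends - 1)
        lo = np.where(strands == "+", five, five - extend + 1)
        hi = lo + extend
        if (lo < 0).any() or (hi > arr.size).any():
            raise ValueError(f"extended read beyond chromosome {chrom}")
        # per-base increment via difference array
        delta = np.zeros(arr.size + 1, dtype=np.float64)
        np.add.at(delta, lo, 1.0)
        np.add.at(delta, hi, -1.0)
        arr += np.cumsum(delta[:-1]).astype(arr.dtype)
    return track


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def compute_spikein_factors(spike_totals: Mapping[str, float] | Iterable[float]
                            ) -> pd.Series:
    """Per-sample size factors from spike-in read totals.

    Raw factors are 1 / spike reads (more spike recovered => sample scaled
    down), then rescaled to geometric mean 1.
    """
    if isinstance(spike_totals, pd.Series):
        ser = spike_totals.astype(float)
    elif isinstance(spike_totals, Mapping):
        ser = pd.Series(spike_totals, dtype=float)
    else:
        ser = pd.Series({str(i): v for i, v in enumerate(spike_totals)},
                        dtype=float)
    ser = ser.copy()
    zero = ser[ser <= 0]
    if len(zero):
        raise ValueError(f"non-positive spike count for sample(s): "
                         f"{', '.join(map(str, zero.index))}")
    raw = 1.0 / ser
    log = np.log(raw)
    factors = np.exp(log - log.mean())
    factors.name = "size_factor"
    return factors


def chip_scale_factor(human_unique: float, mouse_unique: float) -> float:
    """Ratio of uniquely mapped target-genome (human) reads to spike-genome
    (mouse) reads; multiplied onto the ChIP coverage track."""
    if mouse_unique <= 0:
        raise ValueError("mouse (spike) unique read count must be > 0")
    return human_unique / mouse_unique


def apply_chip_scaling(track: SignalTrack, human_unique: float,
                       mouse_unique: float, orientation: str = "multiply"
                       ) -> SignalTrack:
    """Scale a ChIP coverage track by the human/mouse read ratio.

    ``orientation="multiply"`` (default) multiplies by human/mouse so that a
    sample in which more spike chromatin was recovered is scaled down;
    ``"divide"`` applies the inverse.
    """
    factor = chip_scale_factor(human_unique, mouse_unique)
    if orientation == "divide":
        factor = 1.0 / factor
    elif orientation != "multiply":
        raise ValueError("orientation must be 'multiply' or 'divide'")
    return track.scale(factor)


def log_enrichment_track(chip: SignalTrack, input_: SignalTrack) -> SignalTrack:
    """Per-base max(0, log2((chip + 1) / (input + 1)))."""
    if chip.chrom_sizes != input_.chrom_sizes:
        raise ValueError("ChIP and input tracks cover different genomes")
    out = SignalTrack(chip.chrom_sizes, stranded=False, dtype=chip.dtype)
    for chrom in chip.chrom_sizes:
        c = chip.array(chrom, UNSTRANDED).astype(np.float64)
        i = input_.array(chrom, UNSTRANDED).astype(np.float64)
        v = np.log2((c + 1.0) / (i + 1.0))
        np.maximum(v, 0.0, out=v)
        out.array(chrom, UNSTRANDED)[:] = v
    out.units = "log2_enrichment"
    return out


def region_rpkm(count: float, length_bp: float, library_size: float) -> float:
    """Reads per kilobase of region per million mapped reads."""
    if length_bp <= 0:
        raise ValueError("region length must be > 0")
    if library_size <= 0:
        raise ValueError("library size must be > 0")
    return count * 1e9 / (length_bp * library_size)
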