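"""Promoter-centred binned histone/Pol II signal features.

ChIP-style coverage around each gene's TSS (+/- 3 kb) is summarised into 20
bins of 300 bp, in gene-strand orientation: bin 1 is always the most
upstream bin (-3000..-2700) relative to the direction of transcription, so
bins 10 and 11 straddle the TSS.  Bin sums are normalised to FPKM-style
units: fragments per kilobase of bin per million mapped fragments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genes import GeneModel

logger = logging.getLogger(__name__)

N_BINS = 20
BIN_WIDTH = 300
WINDOW = N_BINS * BIN_WIDTH // 2  # 3000 bp each side of the TSS


@dataclass
class SignalTrack:
    """Sparse base-level signal: per-chromosome (start, end, value) intervals.

    Intervals are 0-based half-open (bedGraph convention); uncovered bases
    carry signal 0.
    """

    intervals: dict[str, np.ndarray]  # chrom -> (n, 3) float array [start, end, value]

    @classmethod
    def from_bedgraph(cls, path) -> "SignalTrack":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
        )
        out: dict[str, np.ndarray] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            arr = sub[["start", "end", "value"]].to_numpy(dtype=float)
            out[str(chrom)] = arr[np.argsort(arr[:, 0], kind="stable")]
        return cls(intervals=out)

    def to_bedgraph(self, path) -> None:
        # %.17g keeps float64 exact through a parse round-trip
        with open(path, "w") as fh:
            for chrom in self.intervals:
                for start, end, value in self.intervals[chrom]:
                    fh.write(f"{chrom}\t{int(start)}\t{int(end)}\t{value:.17g}\n")

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Total base-level signal over [start, end)."""
        arr = self.intervals.get(chrom)
        if arr is None or not len(arr):
            return 0.0
        ov = np.minimum(arr[:, 1], end) - np.maximum(arr[:, 0], start)
        ov = np.clip(ov, 0, None)
        return float(np.dot(ov, arr[:, 2]))


def bin_signal(gene: GeneModel, track: SignalTrack, n_bins: int = N_BINS, bin_width: int = BIN_WIDTH) -> np.ndarray:
    """Per-bin sums of base-level signal over TSS +/- (n_bins*bin_width/2).

    Reference-coordinate bins cover ``[tss - W + j*bin_width, ...)`` for
    ``j = 0..n_bins-1`` with ``W = n_bins*bin_width/2``; for minus-strand
    genes the bin order is reversed so bin 1 is most upstream of
    transcription.  Intervals missing from the track count as 0.
    """
    half = n_bins * bin_width // 2
    lo = gene.tss - half
    arr = track.intervals.get(gene.chrom)
    sums = np.zeros(n_bins, dtype=float)
    if arr is not None and len(arr):
        starts = lo + bin_width * np.arange(n_bins)
        # overlap of every interval with every bin
        ov = (
            np.minimum(arr[:, 1][:, None], (starts + bin_width)[None, :])
            - np.maximum(arr[:, 0][:, None], starts[None, :])
        )
        np.clip(ov, 0, None, out=ov)
        sums = ov.T @ arr[:, 2]
    if gene.strand == "-":
        sums = sums[::-1].copy()
    return sums


def fpkm_normalize(bin_sums: np.ndarray, bin_width: int = BIN_WIDTH, library_size: float = 1e6) -> np.ndarray:
    """FPKM: bin_sum / ((bin_width/1000) * (library_size/1e6))."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return np.asarray(bin_sums, dtype=float) / ((bin_width / 1000.0) * (library_size / 1e6))


@dataclass
class EpiFeatureMatrix:
    """Gene x (mark x 20 bins) FPKM matrix; columns named ``mark_i``, i=1..20."""

    marks: tuple[str, ...]
    values: pd.DataFrame
    bin_width: int = BIN_WIDTH
    flagged: tuple[str, ...] = ()

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path) -> "EpiFeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        marks = tuple(dict.fromkeys(c.rsplit("_", 1)[0] for c in df.columns))
        return cls(marks=marks, values=df)


def assemble_epi_matrix(
    genes,
    tracks: dict[str, SignalTrack],
    library_sizes: dict[str, float],
    n_bins: int = N_BINS,
    bin_width: int = BIN_WIDTH,
) -> EpiFeatureMatrix:
    """Bin and FPKM-normalise every mark's track around every gene's TSS.

    ``tracks`` maps mark label -> track (or list of replicate tracks, whose
    per-replicate FPKM values are averaged); ``library_sizes`` maps mark
    label -> mapped-fragment total (or list matching the replicates).
    """
    genes = list(genes)
    marks = list(tracks)
    if not marks:
        raise ValueError("no marks supplied")
    if len(set(marks)) != len(marks):
        raise ValueError("duplicated mark label")
    columns = [f"{m}_{i}" for m in marks for i in range(1, n_bins + 1)]
    rows = np.zeros((len(genes), len(columns)), dtype=float)
    flagged = []
    for gi, gene in enumerate(genes):
        if gene.tss - n_bins * bin_width // 2 < 0:
            flagged.append(gene.id)
            logger.warning("gene %s: TSS window extends past chromosome start", gene.id)
        for mi, mark in enumerate(marks):
            trk, lib = tracks[mark], library_sizes[mark]
            reps = trk if isinstance(trk, (list, tuple)) else [trk]
            libs = lib if isinstance(lib, (list, tuple)) else [lib]
            if len(reps) != len(libs):
                raise ValueError(f"mark {mark}: {len(reps)} replicates but {len(libs)} library sizes")
            fpkm = np.mean(
                [fpkm_normalize(bin_signal(gene, r, n_bins, bin_width), bin_width, l) for r, l in zip(reps, libs)],
                axis=0,
            )
            rows[gi, mi * n_bins : (mi + 1) * n_bins] = fpkm
    df = pd.DataFrame(rows, index=pd.Index([g.id for g in genes], name="gene"), columns=columns)
    return EpiFeatureMatrix(marks=tuple(marks), values=df, bin_width=bin_width, flagged=tuple(flagged))
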