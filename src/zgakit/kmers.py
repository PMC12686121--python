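"""Strand-aware flank extraction and k-mer spectrum featurization.

Positive and negative gene sets are represented by the sequence of their
regulatory flanks: TSS(-2 kb, +1 kb) and TES(-1 kb, +2 kb) in gene-strand
orientation.  Each gene becomes a vector of 4**k k-mer frequencies (counts
over both flanks divided by the number of valid sliding windows), with the
4**k words fixed in lexicographic order so that any word such as "TATATA"
is addressable by name.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genes import GeneModel, gene_strand_window

logger = logging.getLogger(__name__)

TSS_UPSTREAM, TSS_DOWNSTREAM = 2000, 1000
TES_UPSTREAM, TES_DOWNSTREAM = 1000, 2000

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# base -> 2-bit code; anything else is invalid
_CODE = np.full(256, -1, dtype=np.int64)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[b + 32] = i  # lowercase


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def kmer_names(k: int) -> list[str]:
    """All 4**k words over ACGT in lexicographic order."""
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


def _chrom_len(genome, chrom: str) -> int:
    seq = genome[chrom]
    return len(seq)


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Fetch [start, end) from a dict of strings or a pyfaidx.Fasta."""
    piece = genome[chrom][start:end]
    return str(piece).upper()


def _clipped_window(genome, gene: GeneModel, pos: int, up: int, down: int) -> str:
    start, end = gene_strand_window(pos, gene.strand, up, down)
    n = _chrom_len(genome, gene.chrom)
    cstart, cend = max(0, start), min(n, end)
    if cstart > cend:
        cstart = cend = 0
    if (cstart, cend) != (start, end):
        logger.warning(
            "gene %s: window [%d,%d) clipped to [%d,%d) at chromosome bounds",
            gene.id, start, end, cstart, cend,
        )
    seq = _fetch(genome, gene.chrom, cstart, cend)
    if gene.strand == "-":
        seq = reverse_complement(seq)
    return seq


def extract_flanks(gene: GeneModel, genome, orient_by_strand: bool = True) -> tuple[str, str]:
    """Return (tss_seq, tes_seq): TSS(-2,+1 kb) and TES(-1,+2 kb) flanks.

    Windows are gene-strand oriented (minus-strand genes return the reverse
    complement) unless ``orient_by_strand`` is False, in which case the
    reference-strand slice covering the same bases is returned.  Windows
    extending past chromosome bounds are clipped with a logged warning.
    """
    if gene.chrom not in (genome.keys() if hasattr(genome, "keys") else genome):
        raise KeyError(f"chromosome {gene.chrom!r} not in genome")
    tss_seq = _clipped_window(genome, gene, gene.tss, TSS_UPSTREAM, TSS_DOWNSTREAM)
    tes_seq = _clipped_window(genome, gene, gene.tes, TES_UPSTREAM, TES_DOWNSTREAM)
    if not orient_by_strand and gene.strand == "-":
        tss_seq, tes_seq = reverse_complement(tss_seq), reverse_complement(tes_seq)
    return tss_seq, tes_seq


def count_kmers(seq: str, k: int) -> np.ndarray:
    """Sliding-window (step 1) k-mer counts over all 4**k patterns.

    Windows containing non-ACGT characters are skipped; the returned counts
    sum to the number of valid windows.  Sequences shorter than k yield a
    zero vector with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = np.zeros(4**k, dtype=np.int64)
    if len(seq) < k:
        logger.warning("sequence length %d < k=%d; zero counts", len(seq), k)
        return counts
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    valid = codes >= 0
    # rolling 2k-bit codes via cumulative scheme: window is valid iff all k
    # positions are valid
    n_win = len(seq) - k + 1
    window_codes = np.zeros(n_win, dtype=np.int64)
    window_valid = np.ones(n_win, dtype=bool)
    for j in range(k):
        c = codes[j : j + n_win]
        window_codes = window_codes * 4 + np.where(c >= 0, c, 0)
        window_valid &= valid[j : j + n_win]
    counts = np.bincount(window_codes[window_valid], minlength=4**k).astype(np.int64)
    return counts


@dataclass
class KmerFeatureMatrix:
    """Gene x 4**k k-mer frequency matrix (lexicographic feature order)."""

    k: int
    values: pd.DataFrame  # index = gene id, columns = kmer_names(k)
    flagged: tuple[str, ...] = ()  # genes whose windows were fully clipped

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path, k: int | None = None) -> "KmerFeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if k is None:
            k = len(df.columns[0])
        return cls(k=k, values=df)


def featurize(genes, genome, k: int = 6, orient_by_strand: bool = True) -> KmerFeatureMatrix:
    """k-mer frequency features for a set of genes.

    TSS- and TES-flank counts are summed into one vector per gene, then
    normalised by the total number of valid windows across both flanks.
    A gene whose windows are entirely clipped away gets a zero row and is
    flagged.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("no genes supplied")
    names = kmer_names(k)
    rows = np.zeros((len(genes), 4**k), dtype=float)
    flagged = []
    for i, gene in enumerate(genes):
        tss_seq, tes_seq = extract_flanks(gene, genome, orient_by_strand=orient_by_strand)
        counts = count_kmers(tss_seq, k) + count_kmers(tes_seq, k)
        total = counts.sum()
        if total == 0:
            flagged.append(gene.id)
            logger.warning("gene %s: no valid k-mer windows; zero feature row", gene.id)
        else:
            rows[i] = counts / total
    df = pd.DataFrame(rows, index=pd.Index([g.id for g in genes], name="gene"), columns=names)
    return KmerFeatureMatrix(k=k, values=df, flagged=tuple(flagged))


class KmerFeaturizer:
    """sklearn-style transformer: gene models -> k-mer frequency matrix.

    Stateless apart from its parameters; ``transform`` accepts an iterable
    of :class:`GeneModel` and returns the feature DataFrame.
    """

    def __init__(self, genome, k: int = 6, orient_by_strand: bool = True):
        self.genome = genome
        self.k = k
        self.orient_by_strand = orient_by_strand

    def get_params(self, deep: bool = True) -> dict:
        return {"genome": self.genome, "k": self.k, "orient_by_strand": self.orient_by_strand}

    def set_params(self, **params) -> "KmerFeaturizer":
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def fit(self, X, y=None) -> "KmerFeaturizer":
        return self

    def transform(self, X) -> pd.DataFrame:
        return featurize(X, self.genome, k=self.k, orient_by_strand=self.orient_by_strand).values
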