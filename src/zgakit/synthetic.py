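"""Synthetic genome / expression / ChIP fixtures with planted class structure.

The generator builds a coupled set of inputs in which the ground truth is
known by construction: a random genome with non-overlapping gene slots, ZGA
and non-ZGA labels, staged TPM trajectories that reproduce those labels
under the ruleset caller, flank sequences with class-differential planted
6-mers, and TSS-centred histone-mark signal with active bumps on positives
and repressive bumps on negatives.  Every stage of the analysis pipeline can
therefore be tested for parameter recovery without any external download.

All randomness flows through ``numpy.random.default_rng`` seeds carried by
:class:`SyntheticTruth`; identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epigenome import BIN_WIDTH, N_BINS, EpiFeatureMatrix, SignalTrack, fpkm_normalize
from .expression import RULESETS, SpeciesRuleset, StageExpressionTable
from .genes import GeneModel, gene_strand_window
from .kmers import reverse_complement

logger = logging.getLogger(__name__)

CHROM = "chrS"
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: default planted words: TA-rich and CTGCAG-like motifs of the kind
#: over-represented in ZGA gene flanks
DEFAULT_PLANTED = ("TATATA", "ATTAAT", "CTGCAG")

#: mark -> (responding class, peak offset bp from TSS, peak FWHM bp, amplitude)
DEFAULT_MARK_PROFILES = {
    "H3K9ac": ("active", -150, 600, 5.0),
    "H3K4me3": ("active", -150, 600, 5.0),
    "H3K27me3": ("repressive", -150, 600, 5.0),
}


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator."""

    planted_kmers: tuple[str, ...] = DEFAULT_PLANTED
    enrich_pos: float = 8.0
    enrich_neg: float = 1.0
    labels: dict[str, str] = field(default_factory=dict)  # gene id -> ZGA / nonZGA
    mark_profiles: dict[str, tuple] = field(default_factory=lambda: dict(DEFAULT_MARK_PROFILES))
    seed: int = 0

    def __post_init__(self) -> None:
        for w in self.planted_kmers:
            if set(w) - set("ACGT"):
                raise ValueError(f"planted k-mer {w!r} must be over ACGT")
        if self.enrich_pos < 0 or self.enrich_neg < 0:
            raise ValueError("enrichments must be non-negative")
        for mark, (cls, *_rest) in self.mark_profiles.items():
            if cls not in {"active", "repressive"}:
                raise ValueError(f"mark {mark}: class must be active/repressive, got {cls!r}")

    @property
    def positives(self) -> list[str]:
        return [g for g, l in self.labels.items() if l == "ZGA"]

    @property
    def negatives(self) -> list[str]:
        return [g for g, l in self.labels.items() if l == "nonZGA"]


# window layout (gene-strand offsets) used for planting: TSS(-2,+1kb), TES(-1,+2kb)
_PLANT_WINDOWS = (("tss", -2000, 1000), ("tes", -1000, 2000))


def generate_genome(
    n_genes: int,
    flank_margin: int = 3000,
    gc: float = 0.5,
    seed: int = 0,
    frac_positive: float = 0.5,
) -> tuple[dict[str, str], list[GeneModel], SyntheticTruth]:
    """Random genome with one gene per fixed-size slot on a single chromosome.

    Gene bodies are 4--9 kb, strands random; slots are sized so that the
    TSS +/- 3 kb window and the TSS(-2,+1 kb)/TES(-1,+2 kb) flanks of
    different genes can never overlap.  Bases are i.i.d. with expected GC
    fraction ``gc``.  Returns (sequences, genes, truth) where ``truth``
    carries default planting parameters and the ZGA/nonZGA labels.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    if flank_margin < 3000:
        raise ValueError("flank_margin must be >= 3000 so all windows fit")
    rng = np.random.default_rng(seed)
    gene_len_range = (4000, 9000)
    offset = flank_margin + 2000  # distance from slot edge to TSS/TES
    slot = int(np.ceil((2 * offset + gene_len_range[1]) / 1000.0)) * 1000
    length = slot * n_genes
    # P(A)=P(T)=(1-gc)/2, P(C)=P(G)=gc/2 over the ACGT alphabet
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = _BASES[rng.choice(4, size=length, p=probs)]
    genes: list[GeneModel] = []
    n_pos = int(round(n_genes * frac_positive))
    is_pos = np.zeros(n_genes, dtype=bool)
    is_pos[rng.choice(n_genes, size=n_pos, replace=False)] = True
    labels: dict[str, str] = {}
    for i in range(n_genes):
        s = i * slot
        L = int(rng.integers(gene_len_range[0], gene_len_range[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            tss = s + offset
            tes = tss + L
        else:
            tss = s + offset + L
            tes = s + offset
        gid = f"g{i:04d}"
        genes.append(GeneModel(id=gid, chrom=CHROM, strand=strand, tss=tss, tes=tes))
        labels[gid] = "ZGA" if is_pos[i] else "nonZGA"
    truth = SyntheticTruth(labels=labels, seed=seed)
    return {CHROM: seq.tobytes().decode("ascii")}, genes, truth


def plant_motifs(
    sequences: dict[str, str],
    genes,
    truth: SyntheticTruth,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Write Poisson-distributed copies of each planted k-mer into gene flanks.

    Positive genes draw Poisson(enrich_pos) copies per k-mer, negatives
    Poisson(enrich_neg); copies are placed uniformly and non-overlappingly
    (rejection sampling) inside the TSS(-2,+1 kb) and TES(-1,+2 kb) windows,
    written in gene-strand orientation (reverse complement on the reference
    strand for minus-strand genes).

    Returns the modified sequences and a gene x k-mer table of the planted
    copy counts (so total planted copies can be audited exactly).
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed + 1)
    buffers = {c: bytearray(s.encode("ascii")) for c, s in sequences.items()}
    genes = list(genes)
    counts = pd.DataFrame(
        0, index=pd.Index([g.id for g in genes], name="gene"), columns=list(truth.planted_kmers), dtype=int
    )
    for gene in genes:
        lam = truth.enrich_pos if truth.labels.get(gene.id) == "ZGA" else truth.enrich_neg
        # candidate start offsets in a unified gene-coordinate frame
        # (offset along transcription direction, TSS = 0 for the TSS window,
        # TES anchored separately); occupancy tracked per (anchor, offset)
        occupied: list[tuple[str, int, int]] = []
        for kmer in truth.planted_kmers:
            klen = len(kmer)
            for win_name, lo, hi in _PLANT_WINDOWS:
                if hi - lo <= klen:
                    raise ValueError(f"planted k-mer {kmer} does not fit window {win_name}")
            n_copies = int(rng.poisson(lam))
            counts.loc[gene.id, kmer] = n_copies
            placed = 0
            attempts = 0
            while placed < n_copies:
                attempts += 1
                if attempts > 10000:
                    raise RuntimeError(f"gene {gene.id}: could not place {n_copies} copies of {kmer}")
                win_name, lo, hi = _PLANT_WINDOWS[int(rng.integers(len(_PLANT_WINDOWS)))]
                o = int(rng.integers(lo, hi - klen + 1))
                if any(w == win_name and not (o + klen <= a or b <= o) for w, a, b in occupied):
                    continue
                occupied.append((win_name, o, o + klen))
                anchor_pos = gene.tss if win_name == "tss" else gene.tes
                buf = buffers[gene.chrom]
                if gene.strand == "+":
                    start = anchor_pos + o
                    buf[start : start + klen] = kmer.encode("ascii")
                else:
                    # gene-strand offset o..o+klen maps to reference
                    # positions anchor-o-klen+1 .. anchor-o+1, reverse strand
                    start = anchor_pos - o - klen + 1
                    buf[start : start + klen] = reverse_complement(kmer).encode("ascii")
                placed += 1
    return {c: b.decode("ascii") for c, b in buffers.items()}, counts


def simulate_expression(
    genes,
    truth: SyntheticTruth,
    ruleset: SpeciesRuleset | str = "mouse",
    noise_sd: float = 0.1,
    seed: int | None = None,
    maternal_tpm: float = 0.1,
    zga_tpm: float = 20.0,
    max_resample: int = 100,
) -> StageExpressionTable:
    """Staged TPM table whose ruleset calls reproduce ``truth.labels`` exactly.

    Positives follow a step template (maternal stages ~0.1 TPM, stages from
    the first activation stage onward ~20 TPM); negatives sit at ~0.1 TPM
    throughout (summed TPM < 2).  Multiplicative lognormal noise with
    log-sd ``noise_sd`` is applied; any gene whose noisy profile would flip
    its label under the caller is re-sampled rather than silently emitted.
    """
    if isinstance(ruleset, str):
        ruleset = RULESETS[ruleset]
    rng = np.random.default_rng(truth.seed + 2 if seed is None else seed)
    genes = list(genes)
    stages = list(ruleset.stages)
    first_zga = min(stages.index(s) for s in ruleset.zga_stages)
    tmpl_pos = np.array([zga_tpm if i >= first_zga else maternal_tpm for i in range(len(stages))])
    tmpl_neg = np.full(len(stages), maternal_tpm)

    rows = np.empty((len(genes), len(stages)))
    for i, gene in enumerate(genes):
        tmpl = tmpl_pos if truth.labels.get(gene.id) == "ZGA" else tmpl_neg
        for _ in range(max_resample):
            noisy = tmpl * np.exp(rng.normal(0.0, noise_sd, size=len(stages))) if noise_sd > 0 else tmpl.copy()
            if _label_of(noisy, stages, ruleset) == truth.labels.get(gene.id):
                rows[i] = noisy
                break
        else:
            raise RuntimeError(
                f"gene {gene.id}: noise_sd={noise_sd} keeps flipping the label; "
                "lower the noise or widen the templates"
            )
    df = pd.DataFrame(rows, index=pd.Index([g.id for g in genes], name="gene"), columns=stages)
    table = StageExpressionTable(species=ruleset.species, values=df)
    return table


def _label_of(row: np.ndarray, stages: list[str], ruleset: SpeciesRuleset) -> str:
    s = dict(zip(stages, row))
    fired = any(
        s[c.numerator] / max(s[c.denominator], ruleset.maternal_floor) > c.threshold for c in ruleset.conditions
    )
    if ruleset.maternal_mode == "gate":
        fired = fired and any(s[m] < ruleset.maternal_floor for m in ruleset.maternal_stages)
    if fired:
        return "ZGA"
    total = sum(v for st, v in s.items() if st != "MII")
    return "nonZGA" if total < ruleset.non_zga_sum_max else "unassigned"


def simulate_chip_signal(
    genes,
    truth: SyntheticTruth,
    background: float = 0.5,
    library_size: float = 1e6,
    seed: int | None = None,
    make_tracks: bool = False,
    noise: bool = True,
    n_bins: int = N_BINS,
    bin_width: int = BIN_WIDTH,
) -> tuple[EpiFeatureMatrix, dict[str, SignalTrack]]:
    """TSS-centred per-mark signal with class-dependent Gaussian bumps.

    Active marks get a bump (amplitude, FWHM and offset from
    ``truth.mark_profiles``) on ZGA genes, repressive marks on non-ZGA
    genes; everyone gets positive background noise around ``background``.
    Returns the binned, FPKM-normalised matrix and (if ``make_tracks``)
    base-resolution :class:`SignalTrack` objects that re-bin to the same
    matrix.
    """
    if n_bins != N_BINS or bin_width != BIN_WIDTH:
        logger.info("non-default bin scheme: %d bins x %d bp", n_bins, bin_width)
    rng = np.random.default_rng(truth.seed + 3 if seed is None else seed)
    genes = list(genes)
    marks = list(truth.mark_profiles)
    half = n_bins * bin_width // 2
    columns = [f"{m}_{i}" for m in marks for i in range(1, n_bins + 1)]
    rows = np.zeros((len(genes), len(columns)))
    track_chunks: dict[str, list[tuple[int, np.ndarray]]] = {m: [] for m in marks}

    for gi, gene in enumerate(genes):
        lo = gene.tss - half
        ref_pos = np.arange(lo, lo + n_bins * bin_width)
        off = ref_pos - gene.tss if gene.strand == "+" else gene.tss - ref_pos
        gene_class = "active" if truth.labels.get(gene.id) == "ZGA" else "repressive"
        for mi, mark in enumerate(marks):
            cls, peak_offset, fwhm, amplitude = truth.mark_profiles[mark]
            sigma = fwhm / 2.3548200450309493  # FWHM -> Gaussian sd
            base = background * rng.uniform(0.5, 1.5, size=len(off)) if noise else np.full(len(off), background)
            signal = base
            if cls == gene_class and amplitude > 0:
                signal = signal + amplitude * np.exp(-0.5 * ((off - peak_offset) / sigma) ** 2)
            sums = signal.reshape(n_bins, bin_width).sum(axis=1)
            if gene.strand == "-":
                sums = sums[::-1]
            rows[gi, mi * n_bins : (mi + 1) * n_bins] = fpkm_normalize(sums, bin_width, library_size)
            if make_tracks:
                track_chunks[mark].append((lo, signal))

    matrix = EpiFeatureMatrix(
        marks=tuple(marks),
        values=pd.DataFrame(rows, index=pd.Index([g.id for g in genes], name="gene"), columns=columns),
        bin_width=bin_width,
    )
    tracks: dict[str, SignalTrack] = {}
    if make_tracks:
        chrom = genes[0].chrom if genes else CHROM
        for mark in marks:
            ivals = []
            for lo, signal in sorted(track_chunks[mark]):
                starts = lo + np.arange(len(signal))
                ivals.append(np.column_stack([starts, starts + 1, signal]))
            tracks[mark] = SignalTrack(intervals={chrom: np.concatenate(ivals)})
    return matrix, tracks


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_labels(truth: SyntheticTruth, path) -> None:
    pd.Series(truth.labels, name="label").rename_axis("gene").to_csv(path, sep="\t")
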