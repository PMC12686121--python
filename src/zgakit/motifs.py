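"""Salient k-mers as PWMs, MEME minimal format I/O, and motif matching.

Model features are plain DNA words; to connect them to transcription
factors they are encoded as near-deterministic position weight matrices,
exported in MEME minimal format (so external comparison tools can consume
them directly) and matched against a motif database with an internal
comparator: every offset and both orientations are scored by the mean
per-column Pearson correlation over the aligned overlap, with an empirical
p-value from shuffled-query-column permutations.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"


@dataclass
class PWM:
    """Position weight matrix: columns of (A, C, G, T) probabilities."""

    name: str
    columns: np.ndarray  # (w, 4), rows sum to 1
    nsites: int = 20

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.ndim != 2 or self.columns.shape[1] != 4:
            raise ValueError("PWM columns must be (w, 4)")
        if not np.allclose(self.columns.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.name}: columns must each sum to 1")

    @property
    def width(self) -> int:
        return self.columns.shape[0]

    def reverse_complement(self) -> "PWM":
        return PWM(name=self.name, columns=self.columns[::-1, ::-1].copy(), nsites=self.nsites)


@dataclass
class MotifMatch:
    query: str
    target: str
    offset: int
    orientation: str  # forward / revcomp
    score: float
    empirical_p: float


def kmer_to_pwm(kmer: str, match_prob: float = 0.997) -> PWM:
    """Consensus encoding: match_prob at the k-mer base, rest spread evenly."""
    kmer = kmer.upper()
    bad = set(kmer) - set(ALPHABET)
    if bad:
        raise ValueError(f"ambiguous bases {sorted(bad)} in k-mer {kmer!r}")
    cols = np.full((len(kmer), 4), (1.0 - match_prob) / 3.0)
    for i, b in enumerate(kmer):
        cols[i, ALPHABET.index(b)] = match_prob
    return PWM(name=kmer, columns=cols)


def export_meme(pwms, handle=None) -> str:
    """Write motifs in MEME minimal format (version 4 layout)."""
    pwms = list(pwms)
    if not pwms:
        raise ValueError("no motifs to export")
    buf = io.StringIO()
    buf.write("MEME version 4\n\n")
    buf.write("ALPHABET= ACGT\n\n")
    buf.write("strands: + -\n\n")
    buf.write("Background letter frequencies\n")
    buf.write("A 0.25 C 0.25 G 0.25 T 0.25\n\n")
    for p in pwms:
        buf.write(f"MOTIF {p.name}\n")
        buf.write(
            f"letter-probability matrix: alength= 4 w= {p.width} nsites= {p.nsites} E= 0\n"
        )
        for row in p.columns:
            buf.write(" ".join(f"{v:.6f}" for v in row) + "\n")
        buf.write("\n")
    text = buf.getvalue()
    if handle is not None:
        if hasattr(handle, "write"):
            handle.write(text)
        else:
            with open(handle, "w") as fh:
                fh.write(text)
    return text


def read_meme(source) -> list[PWM]:
    """Read motifs from MEME minimal format (text, file path, or handle)."""
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and "\n" in source:
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    motifs: list[PWM] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            name = parts[1] if len(parts) > 1 else f"motif{len(motifs)}"
            i += 1
            while i < len(lines) and "letter-probability matrix" not in lines[i]:
                i += 1
            if i >= len(lines):
                raise ValueError(f"motif {name}: no letter-probability matrix")
            header = lines[i]
            m = re.search(r"w=\s*(\d+)", header)
            if not m:
                raise ValueError(f"motif {name}: matrix header lacks w=")
            w = int(m.group(1))
            ns = re.search(r"nsites=\s*(\d+)", header)
            nsites = int(ns.group(1)) if ns else 20
            rows = []
            i += 1
            while len(rows) < w:
                vals = lines[i].split()
                if len(vals) != 4:
                    raise ValueError(f"motif {name}: expected 4 probabilities per row")
                rows.append([float(v) for v in vals])
                i += 1
            cols = np.array(rows)
            cols = cols / cols.sum(axis=1, keepdims=True)  # renormalise rounding
            motifs.append(PWM(name=name, columns=cols, nsites=nsites))
        else:
            i += 1
    if not motifs:
        raise ValueError("no MOTIF blocks found")
    return motifs


def _standardize(cols: np.ndarray) -> np.ndarray:
    """Per-column z-scores scaled so that a row dot product is the Pearson
    correlation of two columns; zero-variance columns become zero rows
    (contributing correlation 0)."""
    m = cols.mean(axis=1, keepdims=True)
    s = cols.std(axis=1, keepdims=True)
    z = np.where(s > 0, (cols - m) / np.where(s > 0, s, 1.0), 0.0)
    return z / 2.0  # 4 elements: corr = sum((a-ā)(b-b̄)) / (4 σa σb)


def _column_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Mean per-column Pearson correlation over aligned (standardized) columns."""
    return float(np.einsum("ij,ij->", a, b) / len(a))


def _best_alignment(qz: np.ndarray, tz_fwd: np.ndarray, tz_rev: np.ndarray, min_overlap: int) -> tuple[float, int, str]:
    """Best (score, offset, orientation) of standardized query columns."""
    best = (-np.inf, 0, "forward")
    for orientation, tz in (("forward", tz_fwd), ("revcomp", tz_rev)):
        wq, wt = len(qz), len(tz)
        for offset in range(-(wq - min_overlap), wt - min_overlap + 1):
            q_lo, q_hi = max(0, -offset), min(wq, wt - offset)
            if q_hi - q_lo < min_overlap:
                continue
            score = _column_corr(qz[q_lo:q_hi], tz[q_lo + offset : q_hi + offset])
            if score > best[0]:
                best = (score, offset, orientation)
    return best


def match_pwm(
    query: PWM,
    database: list[PWM],
    min_overlap: int = 5,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> list[MotifMatch]:
    """Rank database motifs against a query PWM.

    Every target is scanned in both orientations over all offsets keeping at
    least ``min_overlap`` aligned columns; the score is the mean per-column
    Pearson correlation.  The empirical p-value for each target is the
    fraction of column-shuffled queries whose best score reaches the
    observed one (add-one corrected).

    Results are ranked by score, then p: the shuffled null preserves the
    query's column multiset, so a repetitive query (e.g. GGGTTT) can
    reproduce its own self-match under shuffling and would get a large p
    despite a perfect score -- score-first ranking keeps an exact match on
    top, where it belongs.
    """
    if not database:
        raise ValueError("database must be non-empty")
    rng = np.random.default_rng(seed)
    qz = _standardize(query.columns)
    shuffles = [qz[rng.permutation(query.width)] for _ in range(n_shuffles)]
    matches: list[MotifMatch] = []
    for target in database:
        if target.width < min_overlap:
            logger.warning("target %s shorter than min_overlap=%d; skipped", target.name, min_overlap)
            continue
        tz_fwd = _standardize(target.columns)
        tz_rev = _standardize(target.reverse_complement().columns)
        score, offset, orientation = _best_alignment(qz, tz_fwd, tz_rev, min_overlap)
        null = np.array([_best_alignment(s, tz_fwd, tz_rev, min_overlap)[0] for s in shuffles])
        p = (1.0 + np.sum(null >= score - 1e-12)) / (n_shuffles + 1.0)
        matches.append(
            MotifMatch(
                query=query.name, target=target.name, offset=offset,
                orientation=orientation, score=score, empirical_p=float(p),
            )
        )
    matches.sort(key=lambda m: (-m.score, m.empirical_p, m.target))
    return matches


def matches_to_tsv(matches: list[MotifMatch], path) -> None:
    with open(path, "w") as fh:
        fh.write("query\ttarget\toffset\torientation\tscore\tempirical_p\n")
        for m in matches:
            fh.write(
                f"{m.query}\t{m.target}\t{m.offset}\t{m.orientation}\t{m.score:.6f}\t{m.empirical_p:.6g}\n"
            )
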