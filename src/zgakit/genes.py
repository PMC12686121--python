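"""Gene models and annotation I/O.

A :class:`GeneModel` anchors every coordinate operation in the package: flank
extraction around the transcription start site (TSS) and transcription end
site (TES), and signal binning around the TSS.  Positions are 0-based
genomic coordinates of single bases; for a plus-strand gene ``tss < tes``,
for a minus-strand gene ``tss > tes``.

Annotation is read from BED6 (0-based half-open intervals) or GFF3 (1-based
closed); in both cases the TSS is the 5' end of the feature on its own
strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModel:
    """A single gene anchored by TSS/TES positions on a chromosome."""

    id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss == self.tes:
            raise ValueError(f"gene {self.id}: tss == tes ({self.tss})")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"gene {self.id}: plus strand requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"gene {self.id}: minus strand requires tss > tes")

    # BED half-open interval of the gene body on the reference strand
    @property
    def start(self) -> int:
        return self.tss if self.strand == "+" else self.tes

    @property
    def end(self) -> int:
        return (self.tes if self.strand == "+" else self.tss) + 1


def gene_strand_window(pos: int, strand: str, upstream: int, downstream: int) -> tuple[int, int]:
    """Reference-strand half-open interval of gene-strand offsets
    ``[-upstream, +downstream)`` around ``pos`` (offset 0 = ``pos`` itself).

    For a minus-strand gene, gene-strand offset ``o`` maps to reference
    position ``pos - o``, so the window is ``[pos - downstream + 1,
    pos + upstream + 1)``.
    """
    if strand == "+":
        return pos - upstream, pos + downstream
    return pos - downstream + 1, pos + upstream + 1


def read_bed6(path) -> list[GeneModel]:
    """Read gene models from a BED6 file (chrom, start, end, name, score, strand)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: BED6 needs 6 columns, got {len(parts)}")
            chrom, start, end, name, _score, strand = parts[:6]
            start_i, end_i = int(start), int(end)
            if strand == "+":
                tss, tes = start_i, end_i - 1
            else:
                tss, tes = end_i - 1, start_i
            genes.append(GeneModel(id=name, chrom=chrom, strand=strand, tss=tss, tes=tes))
    return genes


def write_bed6(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.id}\t0\t{g.strand}\n")


def read_gff3(path, feature_type: str = "gene") -> list[GeneModel]:
    """Read gene models from GFF3, taking TSS/TES from ``feature_type`` rows.

    GFF3 is 1-based closed; the gene id is taken from the ``ID`` attribute
    (falling back to ``gene_id`` / ``Name``).
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{ln}: GFF3 needs 9 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts[:9]
            if ftype != feature_type:
                continue
            attr_map = {}
            for item in attrs.split(";"):
                item = item.strip()
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr_map[k] = v
            gid = attr_map.get("ID") or attr_map.get("gene_id") or attr_map.get("Name")
            if gid is None:
                raise ValueError(f"{path}:{ln}: no ID/gene_id/Name attribute")
            start0, end0 = int(start) - 1, int(end) - 1  # to 0-based closed
            biotype = attr_map.get("biotype", attr_map.get("gene_biotype", "protein_coding"))
            if strand == "+":
                tss, tes = start0, end0
            else:
                tss, tes = end0, start0
            genes.append(GeneModel(id=gid, chrom=chrom, strand=strand, tss=tss, tes=tes, biotype=biotype))
    return genes
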