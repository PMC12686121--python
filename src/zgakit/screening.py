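"""Genome-wide confidence reporting and the high-confidence ZGA-gene rule.

A gene's confidence report combines the sequence-model score, the
epigenetic-model score (which may be absent, e.g. for species without mark
data) and per-dataset expression fold changes.  The high-confidence rule:

* default: sequence score >= 0.6 AND fold change >= 2 in at least two
  datasets;
* mouse: additionally epigenetic score >= 0.6 (an absent epigenetic score
  fails the clause and is recorded in the trace).

All thresholds are configurable; raising any score or fold change can never
revoke the flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class HighConfidenceRule:
    name: str = "default"  # "default" or "mouse"
    seq_min: float = 0.6
    epi_min: float = 0.6
    fc_min: float = 2.0
    min_datasets: int = 2

    @property
    def requires_epi(self) -> bool:
        return self.name == "mouse"


@dataclass
class ConfidenceReport:
    """Per-gene table: seq_score, epi_score (NaN = absent), per-dataset FC,
    high_confidence flag and the clause trace."""

    table: pd.DataFrame
    fc_datasets: tuple[str, ...]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")


def build_report(
    seq_scores: pd.Series,
    epi_scores: pd.Series | None = None,
    fold_change_tables: dict[str, pd.Series] | None = None,
) -> ConfidenceReport:
    """Merge model scores and fold changes by gene id.

    Every reported gene must carry a sequence score; genes absent from the
    epigenetic input get NaN (absent), never 0.  Fold-change tables are a
    mapping dataset label -> gene series.
    """
    if seq_scores.index.duplicated().any():
        raise ValueError("duplicated gene ids in seq_scores")
    df = pd.DataFrame({"seq_score": seq_scores.astype(float)})
    if epi_scores is not None:
        if epi_scores.index.duplicated().any():
            raise ValueError("duplicated gene ids in epi_scores")
        df["epi_score"] = epi_scores.reindex(df.index)
    else:
        df["epi_score"] = np.nan
    fc_datasets = tuple(fold_change_tables or ())
    for label in fc_datasets:
        df[f"fc_{label}"] = fold_change_tables[label].reindex(df.index)
    df.index.name = "gene"
    return ConfidenceReport(table=df, fc_datasets=fc_datasets)


def apply_high_confidence_rule(report: ConfidenceReport, rule: HighConfidenceRule | str = "default") -> ConfidenceReport:
    """Evaluate the combined screening rule, adding ``high_confidence`` and a
    human-readable ``criteria_trace`` column."""
    if isinstance(rule, str):
        rule = HighConfidenceRule(name=rule)
    df = report.table.copy()
    fc_cols = [f"fc_{d}" for d in report.fc_datasets]
    flags, traces = [], []
    for gene, row in df.iterrows():
        trace = []
        ok_seq = row["seq_score"] >= rule.seq_min
        trace.append(f"seq>={rule.seq_min:g}:{'pass' if ok_seq else 'fail'}")
        n_fc = int(sum(row[c] >= rule.fc_min for c in fc_cols if pd.notna(row[c])))
        ok_fc = n_fc >= rule.min_datasets
        trace.append(f"fc>={rule.fc_min:g} in {n_fc}/{len(fc_cols)} datasets:{'pass' if ok_fc else 'fail'}")
        ok = ok_seq and ok_fc
        if rule.requires_epi:
            if pd.isna(row["epi_score"]):
                trace.append("epi score absent:fail")
                ok = False
            else:
                ok_epi = row["epi_score"] >= rule.epi_min
                trace.append(f"epi>={rule.epi_min:g}:{'pass' if ok_epi else 'fail'}")
                ok = ok and ok_epi
        flags.append(bool(ok))
        traces.append(";".join(trace))
    df["high_confidence"] = flags
    df["criteria_trace"] = traces
    return ConfidenceReport(table=df, fc_datasets=report.fc_datasets)


def shared_high_confidence(reports: dict[str, ConfidenceReport]) -> set[str]:
    """Gene ids flagged high-confidence in every per-species report.

    A cross-species set intersection utility; meaningful only when the
    reports share a common gene namespace (e.g. homology-mapped symbols).
    """
    sets = [
        set(rep.table.index[rep.table["high_confidence"]])
        for rep in reports.values()
        if "high_confidence" in rep.table
    ]
    if not sets:
        return set()
    out = sets[0]
    for s in sets[1:]:
        out &= s
    return out
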