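"""ZGA gene calling from staged expression tables.

The onset of transcription from the embryonic genome (zygotic genome
activation, ZGA) is detected from TPM ratios between an activation stage and
a maternal reference stage.  A gene is called ZGA when ANY condition of a
species ruleset fires; the maternal "< 0.5 TPM" clause is realised either as
a denominator floor (default) or as a gate requiring at least one maternal
stage below the floor.  Non-ZGA genes are genes whose summed TPM over the
preimplantation stages (MII oocyte excluded) stays below a small cap.

Rulesets are data, not code.  Three presets ship: mouse (major ZGA at the
2-cell stage), human/pig (4--8-cell) and bovine/goat (8--16-cell), each with
five ratio conditions and thresholds {2.5, 3, 3, 3, 3}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

ZGA = "ZGA"
NON_ZGA = "nonZGA"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class Condition:
    """One ratio rule: TPM(numerator)/TPM(denominator) > threshold."""

    numerator: str
    denominator: str
    threshold: float

    @property
    def name(self) -> str:
        return f"{self.numerator}/{self.denominator}>{self.threshold:g}"


@dataclass(frozen=True)
class SpeciesRuleset:
    species: str
    stages: tuple[str, ...]
    conditions: tuple[Condition, ...]
    maternal_stages: tuple[str, ...]
    maternal_floor: float = 0.5
    non_zga_sum_max: float = 2.0
    # "floor": ratios use max(denominator, maternal_floor)
    # "gate":  conditions only count when some maternal stage TPM < floor
    maternal_mode: str = "floor"

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("ruleset needs at least one condition")
        for c in self.conditions:
            if c.threshold <= 1:
                raise ValueError(f"threshold must exceed 1: {c.name}")
        if self.maternal_mode not in {"floor", "gate"}:
            raise ValueError(f"unknown maternal_mode {self.maternal_mode!r}")

    @property
    def zga_stages(self) -> tuple[str, ...]:
        seen: list[str] = []
        for c in self.conditions:
            if c.numerator not in seen:
                seen.append(c.numerator)
        return tuple(seen)


def _preset(species, stages, conds, maternal):
    return SpeciesRuleset(
        species=species,
        stages=tuple(stages),
        conditions=tuple(Condition(*c) for c in conds),
        maternal_stages=tuple(maternal),
    )


#: Published per-species rulesets; stage labels follow the convention
#: MII oocyte, then cleavage stages in developmental order.
RULESETS: dict[str, SpeciesRuleset] = {
    "mouse": _preset(
        "mouse",
        ["MII", "1C", "early2C", "late2C", "4C", "8C", "morula", "blastocyst"],
        [
            ("early2C", "1C", 2.5),
            ("late2C", "1C", 3.0),
            ("early2C", "MII", 3.0),
            ("late2C", "MII", 3.0),
            ("late2C", "early2C", 3.0),
        ],
        ["MII", "1C"],
    ),
    "human": _preset(
        "human",
        ["MII", "1C", "2C", "4C", "8C", "morula", "blastocyst"],
        [
            ("4C", "1C", 2.5),
            ("8C", "1C", 3.0),
            ("4C", "MII", 3.0),
            ("8C", "MII", 3.0),
            ("8C", "4C", 3.0),
        ],
        ["MII", "1C"],
    ),
    "bovine": _preset(
        "bovine",
        ["MII", "1C", "2C", "4C", "8C", "16C", "morula", "blastocyst"],
        [
            ("8C", "4C", 2.5),
            ("16C", "4C", 3.0),
            ("8C", "MII", 3.0),
            ("16C", "MII", 3.0),
            ("16C", "8C", 3.0),
        ],
        ["MII", "4C"],
    ),
}
RULESETS["pig"] = replace(RULESETS["human"], species="pig")
RULESETS["goat"] = replace(RULESETS["bovine"], species="goat")


def load_ruleset(path) -> SpeciesRuleset:
    """Load a ruleset from YAML/JSON (keys mirror :class:`SpeciesRuleset`)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return SpeciesRuleset(
        species=cfg["species"],
        stages=tuple(cfg["stages"]),
        conditions=tuple(Condition(c["numerator"], c["denominator"], float(c["threshold"])) for c in cfg["conditions"]),
        maternal_stages=tuple(cfg["maternal_stages"]),
        maternal_floor=float(cfg.get("maternal_floor", 0.5)),
        non_zga_sum_max=float(cfg.get("non_zga_sum_max", 2.0)),
        maternal_mode=cfg.get("maternal_mode", "floor"),
    )


@dataclass
class StageExpressionTable:
    """Gene x ordered-stage TPM matrix."""

    species: str
    values: pd.DataFrame  # index = gene id, columns = stage labels in order

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate stage labels")
        if (self.values.values < 0).any():
            raise ValueError("TPM values must be non-negative")

    @property
    def stages(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path, species: str = "unknown") -> "StageExpressionTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(species=species, values=df)


@dataclass
class CallResult:
    labels: dict[str, str]  # gene -> ZGA / nonZGA / unassigned
    fired_rules: dict[str, tuple[str, ...]]  # gene -> condition names satisfied
    provenance: dict[str, str]  # gene -> ratio_rule / external_list

    @property
    def zga_genes(self) -> set[str]:
        return {g for g, l in self.labels.items() if l == ZGA}

    @property
    def non_zga_genes(self) -> set[str]:
        return {g for g, l in self.labels.items() if l == NON_ZGA}

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.labels)
        return pd.DataFrame(
            {
                "label": [self.labels[g] for g in genes],
                "fired_rules": [";".join(self.fired_rules.get(g, ())) for g in genes],
                "provenance": [self.provenance.get(g, "") for g in genes],
            },
            index=pd.Index(genes, name="gene"),
        )


def floored_ratio(numerator: float, denominator: float, floor: float) -> float:
    """``numerator / max(denominator, floor)`` -- finite for all valid inputs."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    if numerator < 0 or denominator < 0:
        raise ValueError("TPM inputs must be non-negative")
    return numerator / max(denominator, floor)


def _require_stages(table: StageExpressionTable, ruleset: SpeciesRuleset) -> None:
    needed = {c.numerator for c in ruleset.conditions} | {c.denominator for c in ruleset.conditions}
    needed |= set(ruleset.maternal_stages)
    missing = needed - set(table.stages)
    if missing:
        raise KeyError(f"stages missing from expression table: {sorted(missing)}")


def call_zga(table: StageExpressionTable, ruleset: SpeciesRuleset) -> CallResult:
    """Label every gene ZGA / nonZGA / unassigned under the ruleset.

    ZGA iff any condition fires; nonZGA iff the preimplantation TPM sum is
    below ``non_zga_sum_max`` (ZGA takes precedence -- the sets are disjoint
    by construction because a firing ratio requires a numerator TPM above
    ``floor * threshold`` > sum cap contribution only in pathological
    tables, so precedence is made explicit here).
    """
    _require_stages(table, ruleset)
    df = table.values
    labels: dict[str, str] = {}
    fired: dict[str, tuple[str, ...]] = {}
    prov: dict[str, str] = {}

    gate_open = None
    if ruleset.maternal_mode == "gate":
        gate_open = (df[list(ruleset.maternal_stages)] < ruleset.maternal_floor).any(axis=1)

    non_zga = call_non_zga(table, ruleset)
    for gene in df.index:
        row = df.loc[gene]
        hits = []
        if gate_open is None or bool(gate_open.loc[gene]):
            for c in ruleset.conditions:
                r = floored_ratio(float(row[c.numerator]), float(row[c.denominator]), ruleset.maternal_floor)
                if r > c.threshold:
                    hits.append(c.name)
        if hits:
            labels[gene] = ZGA
            fired[gene] = tuple(hits)
            prov[gene] = "ratio_rule"
        elif gene in non_zga:
            labels[gene] = NON_ZGA
        else:
            labels[gene] = UNASSIGNED
    return CallResult(labels=labels, fired_rules=fired, provenance=prov)


def call_non_zga(table: StageExpressionTable, ruleset: SpeciesRuleset) -> set[str]:
    """Genes with summed TPM below the cap across preimplantation stages.

    The MII oocyte is a maternal sample, not a preimplantation embryo stage,
    so it is excluded from the sum.
    """
    stages = [s for s in table.stages if s != "MII"]
    if not len(table.values):
        return set()
    sums = table.values[stages].sum(axis=1)
    return set(sums.index[sums < ruleset.non_zga_sum_max])


def fold_change(table: StageExpressionTable, stage_a: str, stage_b: str, pseudo: float = 0.01) -> pd.Series:
    """Pseudocounted expression fold change (TPM_a + pseudo)/(TPM_b + pseudo)."""
    for s in (stage_a, stage_b):
        if s not in table.stages:
            raise KeyError(f"stage {s!r} not in table")
    return (table.values[stage_a] + pseudo) / (table.values[stage_b] + pseudo)


def merge_candidates(result: CallResult, external: list[str]) -> CallResult:
    """Union external candidate ZGA genes into a call result.

    Never removes a ratio-rule call; genes added (or confirmed) from the
    external list carry ``external_list`` provenance notes.
    """
    labels = dict(result.labels)
    fired = dict(result.fired_rules)
    prov = dict(result.provenance)
    for gene in external:
        if gene not in labels:
            logger.warning("external candidate %s absent from expression table; included anyway", gene)
        if labels.get(gene) == ZGA:
            prov[gene] = prov.get(gene, "ratio_rule") + "+external_list"
        else:
            labels[gene] = ZGA
            prov[gene] = "external_list"
    return CallResult(labels=labels, fired_rules=fired, provenance=prov)
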