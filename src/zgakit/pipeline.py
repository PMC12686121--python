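"""End-to-end pipelines on synthetic data with planted structure.

These drive the full chain -- genome simulation, motif planting, staged
expression, rule-based calling, featurization, balanced training, grid
search, evaluation and Shapley attribution -- and return the measurements
used to verify parameter recovery: can the sequence model find planted
6-mers, and does the epigenetic model recover the planted mark directions?

Default problem sizes (400 genes for the sequence benchmark, 300 for the
epigenetic one) are chosen to give stable recovery statistics at desk
scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import synthetic
from .expression import RULESETS, call_non_zga, call_zga
from .kmers import featurize
from .models import balance_and_split, evaluate, grid_search_train, score_genes
from .shapley import compute_shap, summarize
from .synthetic import SyntheticTruth, generate_genome, plant_motifs, simulate_expression

logger = logging.getLogger(__name__)

NEAR_TSS_BINS = (9, 10, 11, 12)  # the four 300-bp bins straddling the TSS


@dataclass
class BenchmarkResult:
    test_auc: float
    test_accuracy: float
    selected_features: list
    summary_table: pd.DataFrame  # attribution summary on the test split
    shap_local_error: float = float("nan")  # max |base + sum(phi) - prediction|
    planted_ranks: dict | None = None
    direction_calls: dict | None = None


def make_sequence_dataset(
    n_genes: int = 400,
    seed: int = 0,
    enrich_pos: float = 8.0,
    enrich_neg: float = 1.0,
    planted_kmers: tuple[str, ...] = synthetic.DEFAULT_PLANTED,
    species: str = "mouse",
    k: int = 6,
    noise_sd: float = 0.1,
):
    """Synthetic genome + expression -> called labels -> k-mer features.

    Returns (dataset, truth, genes, sequences); labels in the dataset come
    from the ruleset caller applied to the simulated expression table, not
    from the truth directly, so the whole chain is exercised.
    """
    sequences, genes, truth = generate_genome(n_genes, seed=seed)
    truth = SyntheticTruth(
        planted_kmers=tuple(planted_kmers),
        enrich_pos=enrich_pos,
        enrich_neg=enrich_neg,
        labels=truth.labels,
        seed=seed,
    )
    sequences, _counts = plant_motifs(sequences, genes, truth)
    table = simulate_expression(genes, truth, ruleset=species, noise_sd=noise_sd)
    ruleset = RULESETS[species]
    calls = call_zga(table, ruleset)
    pos = sorted(calls.zga_genes)
    neg_pool = sorted(call_non_zga(table, ruleset) - calls.zga_genes)
    dataset = balance_and_split(pos, neg_pool, seed=seed)
    X = featurize(genes, sequences, k=k).values
    return dataset.with_features(X), truth, genes, sequences


def run_sequence_benchmark(
    seed: int = 0,
    n_genes: int = 400,
    algorithm: str = "rf",
    k: int = 6,
    enrich_pos: float = 8.0,
    enrich_neg: float = 1.0,
    max_features: int = 20,
) -> BenchmarkResult:
    """Train an RF-6mer-style model on planted-motif data; measure recovery.

    ``planted_ranks`` maps each planted k-mer to its rank by mean |SHAP|
    over the test split (features the selector dropped rank after every
    selected feature).
    """
    dataset, truth, _genes, _seqs = make_sequence_dataset(
        n_genes=n_genes, seed=seed, enrich_pos=enrich_pos, enrich_neg=enrich_neg, k=k
    )
    model = grid_search_train(algorithm, dataset, seed=seed, max_features=max_features)
    report = evaluate(model, dataset)
    X_test, _ = dataset.test_arrays()
    attr = compute_shap(model, X_test, seed=seed)
    summary = summarize(attr, X_test[list(model.selected_features)])
    n_sel = len(model.selected_features)
    ranks = {}
    for kmer in truth.planted_kmers:
        if kmer in summary.table.index:
            ranks[kmer] = int(summary.table.loc[kmer, "rank"])
        else:
            ranks[kmer] = n_sel + 1  # not selected at all
    return BenchmarkResult(
        test_auc=report.auc,
        test_accuracy=report.accuracy,
        selected_features=list(model.selected_features),
        summary_table=summary.table,
        shap_local_error=attr.local_accuracy_error(),
        planted_ranks=ranks,
    )


def run_epigenome_benchmark(
    seed: int = 0,
    n_genes: int = 300,
    algorithm: str = "rf",
    max_features: int = 20,
) -> BenchmarkResult:
    """Train on planted active/repressive mark bumps; check direction calls.

    The epigenetic model keeps the full mark x bin matrix (interpretation
    reads the top-ranked features, so selection would only hide them).
    ``direction_calls`` records, for the near-TSS bins of each mark class
    that reach the top ``max_features`` attribution ranks, whether every
    one was called with the planted direction (favourable for active marks
    on positives, unfavourable for repressive marks on negatives).
    """
    _sequences, genes, truth = generate_genome(n_genes, seed=seed)
    matrix, _tracks = synthetic.simulate_chip_signal(genes, truth, seed=seed + 7)
    pos = sorted(truth.positives)
    neg = sorted(truth.negatives)
    dataset = balance_and_split(pos, neg, seed=seed).with_features(matrix.values)
    model = grid_search_train(algorithm, dataset, seed=seed, select=False)
    report = evaluate(model, dataset)
    X_test, _ = dataset.test_arrays()
    attr = compute_shap(model, X_test, seed=seed)
    summary = summarize(attr, X_test[list(model.selected_features)])

    active_marks = [m for m, p in truth.mark_profiles.items() if p[0] == "active"]
    repressive_marks = [m for m, p in truth.mark_profiles.items() if p[0] == "repressive"]
    near = {f"{m}_{i}" for m in truth.mark_profiles for i in NEAR_TSS_BINS}
    top = set(summary.table.index[summary.table["rank"] <= max_features])
    calls = {}
    for cls, marks, want in (
        ("active", active_marks, "favourable"),
        ("repressive", repressive_marks, "unfavourable"),
    ):
        feats = [
            f for f in summary.table.index
            if f in near and f in top and f.rsplit("_", 1)[0] in marks
        ]
        calls[cls] = {
            "features": feats,
            "directions": [summary.table.loc[f, "direction"] for f in feats],
            "all_correct": bool(feats) and all(summary.table.loc[f, "direction"] == want for f in feats),
        }
    return BenchmarkResult(
        test_auc=report.auc,
        test_accuracy=report.accuracy,
        selected_features=list(model.selected_features),
        summary_table=summary.table,
        shap_local_error=attr.local_accuracy_error(),
        direction_calls=calls,
    )


def genome_wide_scores(model, feature_matrix: pd.DataFrame) -> pd.Series:
    """Score every gene of a feature matrix with a trained model."""
    return score_genes(model, feature_matrix)
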