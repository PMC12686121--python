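"""Shapley attribution: oracle equivalence, axioms, directions, interactions."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from zgakit.shapley import (
    _extract_tree,
    compute_shap,
    explain_sample,
    forest_shap,
    interaction_summary,
    permutation_shap,
    summarize,
)


def tree_value_fn(arrays, x, S):
    """Path-dependent coalition value: follow x on S-features, cover-weight others."""
    cl, cr, feat, thr, leaf, wt = arrays

    def rec(n):
        f = feat[n]
        if f < 0:
            return leaf[n]
        if f in S:
            return rec(cl[n] if x[f] <= thr[n] else cr[n])
        l, r = cl[n], cr[n]
        return (wt[l] * rec(l) + wt[r] * rec(r)) / wt[n]

    return rec(0)


def brute_shapley(arrays, x, m):
    phi = np.zeros(m)
    for i in range(m):
        others = [j for j in range(m) if j != i]
        for k in range(m):
            for S in itertools.combinations(others, k):
                w = math.factorial(k) * math.factorial(m - k - 1) / math.factorial(m)
                phi[i] += w * (tree_value_fn(arrays, x, set(S) | {i}) - tree_value_fn(arrays, x, set(S)))
    return phi


class TestTreeShapExactness:
    def test_matches_subset_enumeration_oracle(self, small_forest_data):
        rf, Xdf, _ = small_forest_data
        X = Xdf.to_numpy()[:5]
        phi, base = forest_shap(rf, X)
        brute = np.zeros_like(phi)
        for t in rf.estimators_:
            arrays = _extract_tree(t)
            for r in range(len(X)):
                brute[r] += brute_shapley(arrays, X[r], X.shape[1])
        brute /= len(rf.estimators_)
        assert np.abs(phi - brute).max() < 1e-12

    def test_local_accuracy_every_row(self, small_forest_data):
        rf, Xdf, _ = small_forest_data
        attr = compute_shap(rf, Xdf)
        assert attr.local_accuracy_error() < 1e-6

    def test_single_feature_model_one_player_game(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 1))
        y = (X[:, 0] > 0).astype(int)
        rf = RandomForestClassifier(n_estimators=5, max_depth=3, random_state=0).fit(X, y)
        phi, base = forest_shap(rf, X[:10])
        pred = rf.predict_proba(X[:10])[:, 1]
        assert np.allclose(phi[:, 0], pred - base, atol=1e-12)

    def test_duplicate_columns_share_attribution(self):
        """Symmetry axiom: statistically identical twin features earn equal
        mean absolute attribution."""
        rng = np.random.default_rng(1)
        a = rng.normal(size=400)
        X = np.column_stack([a, a, rng.normal(size=400)])
        y = (a > 0).astype(int)
        rf = RandomForestClassifier(n_estimators=200, random_state=1).fit(X, y)
        phi, _ = forest_shap(rf, X[:100])
        m0, m1 = np.abs(phi[:, 0]).mean(), np.abs(phi[:, 1]).mean()
        assert m0 == pytest.approx(m1, rel=0.25)
        assert m0 > 5 * np.abs(phi[:, 2]).mean()


class TestPermutationShap:
    def test_exact_additivity_and_agreement_with_linear_model(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(150, 4))
        y = (X @ np.array([2.0, -1.0, 0.5, 0.0]) > 0).astype(int)
        lr = LogisticRegression(max_iter=1000).fit(X, y)
        bg = X.mean(axis=0, keepdims=True)
        phi, base = permutation_shap(lambda A: lr.predict_proba(A)[:, 1], X[:5], bg, n_permutations=500, seed=0)
        pred = lr.predict_proba(X[:5])[:, 1]
        assert np.abs(base + phi.sum(axis=1) - pred).max() < 1e-10
        # the dead feature earns far less attribution than the strong one
        assert np.abs(phi[:, 3]).mean() < 0.2 * np.abs(phi[:, 0]).mean()

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            permutation_shap(lambda A: A[:, 0], np.ones((2, 2)), np.empty((0, 2)))

    def test_compute_shap_dispatch_for_logistic(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        y = (X["a"] > 0).astype(int)
        lr = LogisticRegression(max_iter=1000).fit(X.values, y)
        attr = compute_shap(lr, X, n_permutations=100, seed=1)
        assert attr.local_accuracy_error() < 1e-10
        assert attr.output_space == "probability"


class TestSummarize:
    def test_directions_recover_planted_signs(self):
        rng = np.random.default_rng(4)
        n = 400
        y = rng.integers(0, 2, n)
        fav = np.where(y == 1, rng.normal(3, 1, n), rng.normal(0, 1, n))
        unfav = np.where(y == 0, rng.normal(3, 1, n), rng.normal(0, 1, n))
        noise = rng.normal(size=n)
        X = pd.DataFrame({"fav": fav, "unfav": unfav, "noise": noise})
        rf = RandomForestClassifier(n_estimators=100, random_state=4).fit(X.values, y)
        attr = compute_shap(rf, X)
        summary = summarize(attr, X)
        t = summary.table
        assert t.loc["fav", "direction"] == "favourable"
        assert t.loc["unfav", "direction"] == "unfavourable"
        assert list(t.sort_values("rank").index[:2]) in (["fav", "unfav"], ["unfav", "fav"])

    def test_rank_is_permutation_and_monotone(self, small_forest_data):
        rf, Xdf, _ = small_forest_data
        attr = compute_shap(rf, Xdf)
        t = summarize(attr, Xdf).table
        assert sorted(t["rank"]) == list(range(1, len(t) + 1))
        ordered = t.sort_values("rank")["mean_abs_shap"].to_numpy()
        assert np.all(np.diff(ordered) <= 1e-12)

    def test_constant_feature_indeterminate(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"a": rng.normal(size=100), "c": np.ones(100)})
        y = (X["a"] > 0).astype(int)
        rf = RandomForestClassifier(n_estimators=20, random_state=5).fit(X.values, y)
        t = summarize(compute_shap(rf, X), X).table
        assert t.loc["c", "direction"] == "indeterminate"


class TestExplainSample:
    def test_base_plus_contributions_is_prediction(self, small_forest_data):
        rf, Xdf, _ = small_forest_data
        exp = explain_sample(rf, Xdf.iloc[0])
        assert exp.base_value + exp.contributions.sum() == pytest.approx(exp.prediction, abs=1e-9)
        assert len(exp.top(3)) == 3

    def test_mean_input_contributes_little(self, small_forest_data):
        rf, Xdf, _ = small_forest_data
        mean_row = pd.Series(Xdf.mean(), name="mean_gene")
        exp = explain_sample(rf, mean_row)
        assert abs(exp.contributions.sum()) == pytest.approx(abs(exp.prediction - exp.base_value), abs=1e-9)


class TestInteractions:
    @staticmethod
    def _interaction_ratio(y_fn, seed):
        """Mean |interaction| relative to mean |main attribution| for an RF
        fitted to labels y_fn(a, b)."""
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(600, 2)), columns=["a", "b"])
        y = y_fn(X["a"].to_numpy(), X["b"].to_numpy()).astype(int)
        rf = RandomForestClassifier(n_estimators=100, max_depth=6, random_state=seed).fit(X.values, y)
        res = interaction_summary(rf, X.iloc[:60], "a", "b")
        phi, _ = forest_shap(rf, X.iloc[:60].to_numpy())
        return res["mean_abs"] / np.abs(phi).mean()

    def test_xor_interaction_dwarfs_additive_interaction(self):
        # a tree ensemble fitted to an additive rule still carries some
        # tree-structure interaction, so the discriminating check is the
        # contrast against a planted XOR rule, where the pair interaction
        # must dominate
        additive = self._interaction_ratio(lambda a, b: (a + b) > 0, seed=6)
        xor = self._interaction_ratio(lambda a, b: (a > 0) ^ (b > 0), seed=7)
        assert xor > 0.5
        assert xor > 2 * additive

    def test_symmetry_in_feature_order(self, small_forest_data):
        rf, Xdf, _ = small_forest_data
        r1 = interaction_summary(rf, Xdf.iloc[:20], "f0", "f2")
        r2 = interaction_summary(rf, Xdf.iloc[:20], "f2", "f0")
        assert np.allclose(r1["values"].to_numpy(), r2["values"].to_numpy(), atol=1e-10)

    def test_non_tree_model_unsupported(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
        y = (X["a"] > 0).astype(int)
        lr = LogisticRegression().fit(X.values, y)
        with pytest.raises(TypeError):
            interaction_summary(lr, X, "a", "b")
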