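"""Dataset balancing, incremental feature selection and model training."""

import numpy as np
import pandas as pd
import pytest

from zgakit.models import (
    LabeledDataset,
    ZGAClassifier,
    balance_and_split,
    evaluate,
    grid_search_train,
    score_genes,
)
from zgakit.selection import MICSelector, incremental_feature_selection


def planted_frame(n=200, n_feats=30, n_signal=3, seed=0, sep=2.5):
    """Feature frame where only the first n_signal columns carry signal."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.normal(size=(n, n_feats))
    for j in range(n_signal):
        X[:, j] += sep * y
    cols = [f"f{j}" for j in range(n_feats)]
    idx = pd.Index([f"g{i}" for i in range(n)], name="gene")
    return pd.DataFrame(X, index=idx, columns=cols), pd.Series(y, index=idx)


class TestBalanceAndSplit:
    def test_counts_and_split_sizes(self):
        pos = [f"p{i}" for i in range(100)]
        neg = [f"n{i}" for i in range(500)]
        ds = balance_and_split(pos, neg, seed=0)
        assert int(ds.y.sum()) == 100
        assert len(ds.y) == 200
        assert (ds.split == "train").sum() == 160
        assert (ds.split == "test").sum() == 40
        # stratified: test split is half positive
        assert ds.y.loc[ds.test_genes].sum() == 20

    def test_seed_reproducibility(self):
        pos = [f"p{i}" for i in range(30)]
        neg = [f"n{i}" for i in range(90)]
        a = balance_and_split(pos, neg, seed=5)
        b = balance_and_split(pos, neg, seed=5)
        assert a.y.equals(b.y) and a.split.equals(b.split)

    def test_pool_equal_to_pos_uses_all(self):
        pos = [f"p{i}" for i in range(20)]
        neg = [f"n{i}" for i in range(20)]
        ds = balance_and_split(pos, neg, seed=1)
        assert set(ds.y.index[ds.y == 0]) == set(neg)

    def test_insufficient_negatives(self):
        with pytest.raises(ValueError):
            balance_and_split(["a", "b"], ["c"], seed=0)


class TestIncrementalSelection:
    def test_recovers_planted_columns(self):
        X, y = planted_frame(seed=1)
        ranking = ["f0", "f1", "f2"] + [f"f{j}" for j in range(3, 30)]
        sel = incremental_feature_selection(X, y, ranking, cv_folds=5, max_features=10, seed=1)
        assert set(["f0", "f1", "f2"]) <= set(sel)
        assert len(sel) <= 10

    def test_max_features_one_returns_top(self):
        X, y = planted_frame(seed=2)
        ranking = list(X.columns)
        sel = incremental_feature_selection(X, y, ranking, cv_folds=5, max_features=1, seed=2)
        assert sel == ["f0"]

    def test_all_noise_accuracy_near_chance(self):
        X, y = planted_frame(n_signal=0, seed=3)
        sel = MICSelector(max_features=5, cv=5, random_state=3).fit(X, y)
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.model_selection import cross_val_score

        acc = cross_val_score(
            RandomForestClassifier(n_estimators=100, random_state=3),
            X[sel.selected_features_], y, cv=5, scoring="accuracy",
        ).mean()
        assert 0.35 <= acc <= 0.65

    def test_ranking_must_cover_columns(self):
        X, y = planted_frame()
        with pytest.raises(ValueError):
            incremental_feature_selection(X, y, ["f0"], cv_folds=5)


class TestMICSelector:
    def test_ranks_signal_columns_first(self):
        X, y = planted_frame(seed=4)
        sel = MICSelector(max_features=8, cv=5, random_state=4).fit(X, y)
        assert set(sel.ranking_[:3]) == {"f0", "f1", "f2"}
        out = sel.transform(X)
        assert list(out.columns) == list(sel.selected_features_)

    def test_transform_missing_column_raises(self):
        X, y = planted_frame(seed=5)
        sel = MICSelector(max_features=3, cv=5, random_state=5).fit(X, y)
        with pytest.raises(KeyError):
            sel.transform(X.drop(columns=[sel.selected_features_[0]]))

    def test_sklearn_param_interface(self):
        sel = MICSelector(max_features=7)
        assert sel.get_params()["max_features"] == 7
        sel.set_params(max_features=9)
        assert sel.max_features == 9


class TestZGAClassifier:
    def test_grid_choice_deterministic(self):
        X, y = planted_frame(seed=6, n_feats=10)
        grid = {"n_estimators": [50, 100], "max_depth": [None, 5]}
        a = ZGAClassifier("rf", grid=grid, cv=5, random_state=6).fit(X, y)
        b = ZGAClassifier("rf", grid=grid, cv=5, random_state=6).fit(X, y)
        assert a.best_params_ == b.best_params_
        assert a.best_score_ == b.best_score_

    def test_all_four_algorithms_fit_and_score(self):
        X, y = planted_frame(n=120, n_feats=6, seed=7)
        for algo, grid in [
            ("rf", {"n_estimators": [50]}),
            ("svm", {"C": [1.0]}),
            ("lr", {"C": [1.0]}),
            ("gbm", {"n_estimators": [50], "max_depth": [3]}),
        ]:
            clf = ZGAClassifier(algo, grid=grid, cv=5, random_state=7).fit(X, y)
            proba = clf.predict_proba(X)
            assert proba.shape == (len(X), 2)
            assert np.all((proba >= 0) & (proba <= 1))

    def test_empty_grid_rejected(self):
        X, y = planted_frame(n=60, seed=8)
        with pytest.raises(ValueError):
            ZGAClassifier("rf", grid={}, cv=5).fit(X, y)


class TestTrainEvaluate:
    def make_dataset(self, seed=9, n=200):
        X, y = planted_frame(n=n, seed=seed)
        pos = sorted(y.index[y == 1])
        neg = sorted(y.index[y == 0])
        k = min(len(pos), len(neg))
        return balance_and_split(pos[:k], neg, seed=seed).with_features(X)

    def test_train_and_evaluate_recovers_signal(self):
        ds = self.make_dataset()
        model = grid_search_train(
            "rf", ds, grid={"n_estimators": [100]}, folds=5, seed=9, max_features=8
        )
        rep = evaluate(model, ds)
        assert rep.auc > 0.85
        assert set(["f0", "f1", "f2"]) & set(model.selected_features)

    def test_no_test_set_leakage_in_selection_and_grid(self):
        """Permuting test labels must not change what training produced."""
        ds = self.make_dataset(seed=10)
        rng = np.random.default_rng(0)
        y_perm = ds.y.copy()
        test_idx = ds.test_genes
        y_perm.loc[test_idx] = rng.permutation(y_perm.loc[test_idx].to_numpy())
        ds_perm = LabeledDataset(y=y_perm, split=ds.split, seed=ds.seed, X=ds.X)
        kw = dict(grid={"n_estimators": [50, 100]}, folds=5, seed=10, max_features=6)
        m1 = grid_search_train("rf", ds, **kw)
        m2 = grid_search_train("rf", ds_perm, **kw)
        assert m1.selected_features == m2.selected_features
        assert m1.hyperparameters == m2.hyperparameters

    def test_score_genes_missing_feature_names_column(self):
        ds = self.make_dataset(seed=11)
        model = grid_search_train("rf", ds, grid={"n_estimators": [50]}, folds=5, seed=11, max_features=4)
        bad = ds.X.drop(columns=[model.selected_features[0]])
        with pytest.raises(KeyError, match=model.selected_features[0]):
            score_genes(model, bad)

    def test_score_genes_ignores_extra_columns_and_handles_zero_row(self):
        ds = self.make_dataset(seed=12)
        model = grid_search_train("rf", ds, grid={"n_estimators": [50]}, folds=5, seed=12, max_features=4)
        X = ds.X.copy()
        X["extra"] = 1.0
        X.iloc[0] = 0.0
        s = score_genes(model, X)
        assert len(s) == len(X)
        assert ((s >= 0) & (s <= 1)).all()

    def test_save_load_round_trip(self, tmp_path):
        ds = self.make_dataset(seed=13)
        model = grid_search_train("rf", ds, grid={"n_estimators": [50]}, folds=5, seed=13, max_features=4)
        path = tmp_path / "model.joblib"
        model.save(path)
        from zgakit.models import TrainedClassifier

        loaded = TrainedClassifier.load(path)
        assert loaded.selected_features == model.selected_features
        a = score_genes(model, ds.X)
        b = score_genes(loaded, ds.X)
        assert np.allclose(a.to_numpy(), b.to_numpy())
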