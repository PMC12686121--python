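"""Classifier training: balanced datasets, grid-searched CV models, scoring.

The four supported algorithms are an RBF-kernel SVM, a random forest,
L2-regularised logistic regression and gradient boosting (XGBoost).
Hyperparameters come from a grid search with stratified 10-fold
cross-validation on the training split only, model selection by mean CV
accuracy; the test split is never touched before final evaluation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .metrics import EvalReport, evaluate_scores
from .selection import MICSelector

logger = logging.getLogger(__name__)

ALGORITHMS = ("svm", "rf", "lr", "gbm")

#: conventional, config-overridable hyperparameter grids
DEFAULT_GRIDS: dict[str, dict] = {
    "rf": {"n_estimators": [100, 300, 500], "max_depth": [None, 10, 20]},
    "svm": {"C": [0.1, 1, 10], "gamma": ["scale", 0.01]},
    "lr": {"C": [0.01, 0.1, 1, 10]},
    "gbm": {"n_estimators": [100, 300], "learning_rate": [0.1, 0.05], "max_depth": [3, 6]},
}


def base_estimator(algorithm: str, seed: int = 0):
    if algorithm == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if algorithm == "svm":
        return SVC(kernel="rbf", probability=True, random_state=seed)
    if algorithm == "lr":
        return LogisticRegression(max_iter=5000, random_state=seed)
    if algorithm == "gbm":
        return XGBClassifier(random_state=seed, n_jobs=1, eval_metric="logloss", verbosity=0)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


@dataclass
class LabeledDataset:
    """Balanced, split dataset: features X, labels y (1=ZGA), train/test split."""

    y: pd.Series  # gene id -> 0/1
    split: pd.Series  # gene id -> "train"/"test"
    seed: int
    X: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if set(self.y.index) != set(self.split.index):
            raise ValueError("y and split must cover the same genes")
        if self.X is not None:
            missing = set(self.y.index) - set(self.X.index)
            if missing:
                raise ValueError(f"feature matrix missing genes: {sorted(missing)[:5]}...")
            self.X = self.X.loc[self.y.index]

    @property
    def train_genes(self) -> pd.Index:
        return self.split.index[self.split == "train"]

    @property
    def test_genes(self) -> pd.Index:
        return self.split.index[self.split == "test"]

    def with_features(self, X: pd.DataFrame) -> "LabeledDataset":
        return LabeledDataset(y=self.y, split=self.split, seed=self.seed, X=X)

    def train_arrays(self) -> tuple[pd.DataFrame, np.ndarray]:
        g = self.train_genes
        return self.X.loc[g], self.y.loc[g].to_numpy()

    def test_arrays(self) -> tuple[pd.DataFrame, np.ndarray]:
        g = self.test_genes
        return self.X.loc[g], self.y.loc[g].to_numpy()


def balance_and_split(pos, neg_pool, seed: int = 0, test_size: float = 0.2) -> LabeledDataset:
    """Sample |pos| negatives from the pool and make a stratified 80/20 split."""
    pos = sorted(pos)
    neg_pool = sorted(set(neg_pool) - set(pos))
    if len(neg_pool) < len(pos):
        raise ValueError(f"need >= {len(pos)} negatives, pool has {len(neg_pool)}")
    rng = np.random.default_rng(seed)
    neg = [neg_pool[i] for i in rng.choice(len(neg_pool), size=len(pos), replace=False)]
    genes = pos + neg
    labels = np.array([1] * len(pos) + [0] * len(neg))
    train_g, test_g = train_test_split(
        genes, test_size=test_size, stratify=labels, random_state=seed
    )
    y = pd.Series(labels, index=pd.Index(genes, name="gene"), name="label")
    split = pd.Series("train", index=y.index, name="split")
    split.loc[test_g] = "test"
    return LabeledDataset(y=y, split=split, seed=seed)


class ZGAClassifier(BaseEstimator, ClassifierMixin):
    """Grid-searched classifier for ZGA vs non-ZGA feature vectors.

    A thin sklearn estimator: ``fit`` runs GridSearchCV (stratified k-fold,
    accuracy) over ``grid`` (default: the conventional grid for the chosen
    algorithm) and refits the best model on the full training data.

    Fitted attributes: ``best_params_``, ``best_score_``, ``estimator_``,
    ``classes_``, ``feature_names_in_`` (DataFrame input).
    """

    def __init__(self, algorithm: str = "rf", grid: dict | None = None, cv: int = 10, random_state: int = 0):
        self.algorithm = algorithm
        self.grid = grid
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        grid = self.grid if self.grid is not None else DEFAULT_GRIDS[self.algorithm]
        if not grid:
            raise ValueError("hyperparameter grid must be non-empty")
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if counts.min() < self.cv:
            raise ValueError(
                f"smallest class has {counts.min()} members; cannot stratify {self.cv} folds"
            )
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.values
        cv = StratifiedKFold(n_splits=self.cv, shuffle=True, random_state=self.random_state)
        search = GridSearchCV(
            base_estimator(self.algorithm, self.random_state),
            grid,
            scoring="accuracy",
            cv=cv,
            refit=True,
            n_jobs=1,
        )
        search.fit(X, y)
        self.best_params_ = search.best_params_
        self.best_score_ = float(search.best_score_)
        self.estimator_ = search.best_estimator_
        self.classes_ = search.classes_
        logger.info(
            "%s: best CV accuracy %.3f with %s", self.algorithm, self.best_score_, self.best_params_
        )
        return self

    def _as_array(self, X):
        if isinstance(X, pd.DataFrame) and hasattr(self, "feature_names_in_"):
            missing = [f for f in self.feature_names_in_ if f not in X.columns]
            if missing:
                raise KeyError(f"feature columns missing: {missing}")
            X = X[list(self.feature_names_in_)]
        return np.asarray(X)

    def predict_proba(self, X):
        return self.estimator_.predict_proba(self._as_array(X))

    def predict(self, X):
        return self.estimator_.predict(self._as_array(X))


@dataclass
class TrainedClassifier:
    """A fitted selector+classifier pair with its provenance."""

    algorithm: str
    hyperparameters: dict
    selected_features: list
    classifier: ZGAClassifier
    selector: MICSelector | None
    training_seed: int
    training_hash: str = ""

    def sidecar(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "hyperparameters": {k: (None if v is None else v) for k, v in self.hyperparameters.items()},
            "selected_features": [str(f) for f in self.selected_features],
            "training_seed": self.training_seed,
            "training_hash": self.training_hash,
        }

    def save(self, path) -> None:
        """Persist the fitted state (joblib) plus a JSON sidecar."""
        import joblib

        joblib.dump({"classifier": self.classifier, "selector": self.selector}, path)
        with open(str(path) + ".json", "w") as fh:
            json.dump(self.sidecar(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "TrainedClassifier":
        import joblib

        state = joblib.load(path)
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        return cls(
            algorithm=meta["algorithm"],
            hyperparameters=meta["hyperparameters"],
            selected_features=meta["selected_features"],
            classifier=state["classifier"],
            selector=state["selector"],
            training_seed=meta["training_seed"],
            training_hash=meta["training_hash"],
        )


def _hash_frame(X: pd.DataFrame, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X.values).tobytes())
    h.update(np.asarray(y).tobytes())
    return h.hexdigest()[:16]


def grid_search_train(
    algorithm: str,
    dataset: LabeledDataset,
    grid: dict | None = None,
    folds: int = 10,
    seed: int = 0,
    select: bool = True,
    max_features: int = 20,
) -> TrainedClassifier:
    """Feature-select (MIC + IFS) and grid-search a classifier on the
    training split; the test split is untouched."""
    if dataset.X is None:
        raise ValueError("dataset has no feature matrix attached")
    X_train, y_train = dataset.train_arrays()
    selector = None
    if select:
        selector = MICSelector(max_features=max_features, cv=folds, random_state=seed)
        selector.fit(X_train, y_train)
        X_sel = selector.transform(X_train)
        features = list(selector.selected_features_)
    else:
        X_sel = X_train
        features = list(X_train.columns)
    clf = ZGAClassifier(algorithm=algorithm, grid=grid, cv=folds, random_state=seed)
    clf.fit(X_sel, y_train)
    return TrainedClassifier(
        algorithm=algorithm,
        hyperparameters=dict(clf.best_params_),
        selected_features=features,
        classifier=clf,
        selector=selector,
        training_seed=seed,
        training_hash=_hash_frame(X_train, y_train),
    )


def score_genes(model: TrainedClassifier, X: pd.DataFrame) -> pd.Series:
    """Probability of the ZGA class for every row of ``X``.

    Extra columns are ignored; a missing selected feature raises a KeyError
    naming the column.
    """
    missing = [f for f in model.selected_features if f not in X.columns]
    if missing:
        raise KeyError(f"feature columns missing: {missing}")
    Xs = X[list(model.selected_features)]
    proba = model.classifier.predict_proba(Xs)
    pos_col = int(np.flatnonzero(model.classifier.classes_ == 1)[0])
    return pd.Series(proba[:, pos_col], index=X.index, name="score")


def evaluate(model: TrainedClassifier, dataset: LabeledDataset, threshold: float = 0.5) -> EvalReport:
    """Confusion counts at ``threshold`` plus ROC/AUC on the test split."""
    X_test, y_test = dataset.test_arrays()
    if not len(X_test):
        raise ValueError("test split is empty")
    scores = score_genes(model, X_test)
    return evaluate_scores(y_test, scores.to_numpy(), threshold=threshold)
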