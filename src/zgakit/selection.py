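"""MIC-ranked incremental feature selection (IFS).

Features are ranked by MIC against the class labels; nested prefixes of the
ranking (sizes 1..max_features) are then scored by stratified k-fold
cross-validated accuracy and the best prefix wins, with ties broken toward
fewer features.  The whole procedure runs inside the training split only.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .mic import mic_scores

logger = logging.getLogger(__name__)


def _default_evaluator(seed: int):
    # a modest forest is a stable judge for comparing nested prefixes
    return RandomForestClassifier(n_estimators=50, random_state=seed, n_jobs=1)


def incremental_feature_selection(
    X,
    y,
    ranking,
    cv_folds: int = 10,
    max_features: int = 20,
    estimator=None,
    seed: int = 0,
) -> list:
    """Best prefix of ``ranking`` by mean CV accuracy (ties -> fewer features).

    ``ranking`` lists column names (DataFrame input) or indices, best first,
    and must cover all columns of X.
    """
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
    y = np.asarray(y)
    ranking = list(ranking)
    if set(ranking) != set(Xdf.columns):
        raise ValueError("ranking must cover exactly the columns of X")
    if max_features > Xdf.shape[1]:
        logger.warning("max_features=%d exceeds %d columns; clipped", max_features, Xdf.shape[1])
        max_features = Xdf.shape[1]
    est = estimator if estimator is not None else _default_evaluator(seed)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    best_acc, best_m = -np.inf, 1
    for m in range(1, max_features + 1):
        acc = cross_val_score(clone(est), Xdf[ranking[:m]].values, y, cv=cv, scoring="accuracy").mean()
        if acc > best_acc + 1e-12:
            best_acc, best_m = acc, m
    logger.info("IFS: selected %d features (CV accuracy %.3f)", best_m, best_acc)
    return ranking[:best_m]


class MICSelector(BaseEstimator, TransformerMixin):
    """sklearn transformer: MIC ranking + incremental selection.

    Fitted attributes: ``mic_scores_`` (per input column), ``ranking_``
    (column names, best first) and ``selected_features_``.
    """

    def __init__(
        self,
        max_features: int = 20,
        cv: int = 10,
        estimator=None,
        n_superclumps: int = 50,
        random_state: int = 0,
    ):
        self.max_features = max_features
        self.cv = cv
        self.estimator = estimator
        self.n_superclumps = n_superclumps
        self.random_state = random_state

    def fit(self, X, y):
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        y = np.asarray(y)
        scores = mic_scores(
            Xdf.values, y, n_superclumps=self.n_superclumps, seed=self.random_state
        )
        self.mic_scores_ = pd.Series(scores, index=Xdf.columns)
        order = np.argsort(-scores, kind="stable")
        self.ranking_ = [Xdf.columns[i] for i in order]
        self.selected_features_ = incremental_feature_selection(
            Xdf,
            y,
            self.ranking_,
            cv_folds=self.cv,
            max_features=self.max_features,
            estimator=self.estimator,
            seed=self.random_state,
        )
        return self

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.selected_features_ if f not in X.columns]
            if missing:
                raise KeyError(f"feature columns missing: {missing}")
            return X[self.selected_features_]
        return np.asarray(X)[:, [int(f) for f in self.selected_features_]]
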