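"""Shapley-value attribution for trained ZGA classifiers.

Tree ensembles (random forest) get exact path-dependent tree attributions:
the coalition value of a feature subset S is the tree expectation obtained
by following the sample's branch at splits on features in S and
cover-weighting both branches elsewhere, and the per-feature Shapley values
of that game are computed in polynomial time with the extend/unwind path
recursion of tree-ensemble SHAP.  XGBoost models use the library's native
``pred_contribs`` (the same algorithm, in margin space).  SVM and logistic
models fall back to permutation-sampling Shapley against a background
reference, exact-in-expectation and exactly additive to the prediction by
construction.

Local accuracy -- base value plus summed contributions equals the model
output -- holds to float precision for tree models and exactly w.r.t. the
sampled base for permutation estimates.

The per-node recursion is jit-compiled with numba when available; the same
code runs uncompiled otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
import xgboost
from xgboost import XGBClassifier

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# path-dependent TreeSHAP kernel
# ---------------------------------------------------------------------------

@njit(cache=False)
def _unwound_sum(z, o, w, u, i):
    one, zero = o[i], z[i]
    nxt = w[u]
    total = 0.0
    for j in range(u - 1, -1, -1):
        if one != 0.0:
            tmp = nxt * (u + 1) / ((j + 1) * one)
            total += tmp
            nxt = w[j] - tmp * zero * (u - j) / (u + 1)
        else:
            total += w[j] * (u + 1) / (zero * (u - j))
    return total


@njit(cache=False)
def _unwind(d, z, o, w, u, i):
    one, zero = o[i], z[i]
    nxt = w[u]
    for j in range(u - 1, -1, -1):
        if one != 0.0:
            t = w[j]
            w[j] = nxt * (u + 1) / ((j + 1) * one)
            nxt = t - w[j] * zero * (u - j) / (u + 1)
        else:
            w[j] = w[j] * (u + 1) / (zero * (u - j))
    for j in range(i, u):
        d[j] = d[j + 1]
        z[j] = z[j + 1]
        o[j] = o[j + 1]


@njit(cache=False)
def _recurse(cl, cr, feat, thr, leaf_val, wt, x, phi,
             node, depth, pd_, pz_, po_, pw_,
             pzf, pof, pif, scale, skip_feature, skip_mode):
    f = feat[node]
    if f >= 0 and f == skip_feature:
        # conditioned feature: never a player; prune (present) or
        # cover-weight (absent) without touching the path
        hot = cl[node] if x[f] <= thr[node] else cr[node]
        cold = cr[node] if hot == cl[node] else cl[node]
        if skip_mode == 1:
            _recurse(cl, cr, feat, thr, leaf_val, wt, x, phi, hot, depth,
                     pd_, pz_, po_, pw_, pzf, pof, pif, scale, skip_feature, skip_mode)
        else:
            _recurse(cl, cr, feat, thr, leaf_val, wt, x, phi, hot, depth,
                     pd_, pz_, po_, pw_, pzf, pof, pif,
                     scale * wt[hot] / wt[node], skip_feature, skip_mode)
            _recurse(cl, cr, feat, thr, leaf_val, wt, x, phi, cold, depth,
                     pd_, pz_, po_, pw_, pzf, pof, pif,
                     scale * wt[cold] / wt[node], skip_feature, skip_mode)
        return

    # extend the unique path with the incoming (pzf, pof, pif)
    nd = np.empty(depth + 1, dtype=np.int64)
    nz = np.empty(depth + 1, dtype=np.float64)
    no = np.empty(depth + 1, dtype=np.float64)
    nw = np.empty(depth + 1, dtype=np.float64)
    for j in range(depth):
        nd[j] = pd_[j]
        nz[j] = pz_[j]
        no[j] = po_[j]
        nw[j] = pw_[j]
    nd[depth] = pif
    nz[depth] = pzf
    no[depth] = pof
    nw[depth] = 1.0 if depth == 0 else 0.0
    for i in range(depth - 1, -1, -1):
        nw[i + 1] += pof * nw[i] * (i + 1) / (depth + 1)
        nw[i] = pzf * nw[i] * (depth - i) / (depth + 1)
    L = depth + 1  # elements now on the path

    if f < 0:  # leaf
        v = leaf_val[node] * scale
        for i in range(1, L):
            w = _unwound_sum(nz, no, nw, L - 1, i)
            phi[nd[i]] += w * (no[i] - nz[i]) * v
        return

    hot = cl[node] if x[f] <= thr[node] else cr[node]
    cold = cr[node] if hot == cl[node] else cl[node]
    iz = 1.0
    io = 1.0
    k = -1
    for j in range(1, L):
        if nd[j] == f:
            k = j
            break
    if k >= 0:
        iz = nz[k]
        io = no[k]
        _unwind(nd, nz, no, nw, L - 1, k)
        L -= 1
    _recurse(cl, cr, feat, thr, leaf_val, wt, x, phi, hot, L,
             nd, nz, no, nw, iz * wt[hot] / wt[node], io, f, scale, skip_feature, skip_mode)
    _recurse(cl, cr, feat, thr, leaf_val, wt, x, phi, cold, L,
             nd, nz, no, nw, iz * wt[cold] / wt[node], 0.0, f, scale, skip_feature, skip_mode)


@njit(cache=False)
def _tree_shap_matrix(cl, cr, feat, thr, leaf_val, wt, X, phi_out, skip_feature, skip_mode):
    d0 = np.empty(0, dtype=np.int64)
    f0 = np.empty(0, dtype=np.float64)
    for r in range(X.shape[0]):
        _recurse(cl, cr, feat, thr, leaf_val, wt, X[r], phi_out[r],
                 0, 0, d0, f0, f0, f0, 1.0, 1.0, -1, 1.0, skip_feature, skip_mode)


@njit(cache=False)
def _tree_expected(cl, cr, feat, thr, leaf_val, wt, x, node, skip_feature, skip_mode):
    f = feat[node]
    if f < 0:
        return leaf_val[node]
    if f == skip_feature and skip_mode == 1:
        hot = cl[node] if x[f] <= thr[node] else cr[node]
        return _tree_expected(cl, cr, feat, thr, leaf_val, wt, x, hot, skip_feature, skip_mode)
    l, r = cl[node], cr[node]
    el = _tree_expected(cl, cr, feat, thr, leaf_val, wt, x, l, skip_feature, skip_mode)
    er = _tree_expected(cl, cr, feat, thr, leaf_val, wt, x, r, skip_feature, skip_mode)
    return (wt[l] * el + wt[r] * er) / wt[node]


def _extract_tree(tree, class_index: int = 1):
    """Flatten a fitted sklearn DecisionTreeClassifier into plain arrays.

    Leaf values are class probabilities (value row normalised), matching
    what ``predict_proba`` averages over the forest.
    """
    t = tree.tree_
    value = t.value.reshape(t.node_count, -1)
    probs = value / value.sum(axis=1, keepdims=True)
    leaf_val = probs[:, class_index].astype(np.float64)
    return (
        t.children_left.astype(np.int64),
        t.children_right.astype(np.int64),
        t.feature.astype(np.int64),
        t.threshold.astype(np.float64),
        leaf_val,
        t.weighted_n_node_samples.astype(np.float64),
    )


def forest_shap(forest, X: np.ndarray, skip_feature: int = -1, skip_mode: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Path-dependent SHAP values for a RandomForestClassifier (class 1
    probability space).  Returns (phi, base) with phi of shape (n, m) and
    per-sample base values (conditioning on ``skip_feature`` can make the
    base sample-dependent)."""
    # sklearn compares float32-cast samples against float64 thresholds;
    # mirror that cast so split decisions match predict_proba exactly
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float32).astype(np.float64))
    n, m = X.shape
    trees = forest.estimators_ if hasattr(forest, "estimators_") else [forest]
    phi = np.zeros((n, m))
    base = np.zeros(n)
    for tree in trees:
        arrays = _extract_tree(tree)
        phi_t = np.zeros((n, m))
        _tree_shap_matrix(*arrays, X, phi_t, skip_feature, skip_mode)
        phi += phi_t
        if skip_feature < 0:
            base += _tree_expected(*arrays, X[0], 0, skip_feature, skip_mode)
        else:
            for r in range(n):
                base[r] += _tree_expected(*arrays, X[r], 0, skip_feature, skip_mode)
    phi /= len(trees)
    base /= len(trees)
    return phi, base


# ---------------------------------------------------------------------------
# permutation-sampling Shapley (model-agnostic)
# ---------------------------------------------------------------------------

def permutation_shap(
    predict_fn,
    X: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 2048,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo Shapley values by sampling feature permutations.

    For each permutation the background row is morphed into the sample one
    feature at a time; the output deltas are the contributions.  Every
    permutation's contributions sum exactly to f(x) - f(z), so the averaged
    attribution is exactly additive to the prediction around the averaged
    base.  Returns (phi, base) with one base value per sample.
    """
    X = np.asarray(X, dtype=float)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.size == 0:
        raise ValueError("background set must be non-empty")
    n, m = X.shape
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(m) for _ in range(n_permutations)])
    bg_idx = np.arange(n_permutations) % len(background)
    phi = np.zeros((n, m))
    base = np.zeros(n)
    for r in range(n):
        x = X[r]
        # configs[p, step] = background row morphed through perm p up to step
        rows = np.empty((n_permutations, m + 1, m))
        rows[:, 0, :] = background[bg_idx]
        for step in range(m):
            rows[:, step + 1, :] = rows[:, step, :]
            rows[np.arange(n_permutations), step + 1, perms[:, step]] = x[perms[:, step]]
        out = predict_fn(rows.reshape(-1, m)).reshape(n_permutations, m + 1)
        deltas = np.diff(out, axis=1)  # (P, m) contribution of perms[:, step]
        contrib = np.zeros(m)
        np.add.at(contrib, perms.ravel(), deltas.ravel())
        phi[r] = contrib / n_permutations
        base[r] = out[:, 0].mean()
    return phi, base


# ---------------------------------------------------------------------------
# public API over trained models
# ---------------------------------------------------------------------------

@dataclass
class Attribution:
    """Per-sample, per-feature Shapley attributions in model-output space."""

    values: pd.DataFrame  # gene x feature signed attributions
    base_values: pd.Series  # gene -> base (expected model output)
    predictions: pd.Series  # gene -> model output explained
    output_space: str  # "probability" (RF, SVM, LR) or "margin" (XGBoost)

    def local_accuracy_error(self) -> float:
        recon = self.base_values + self.values.sum(axis=1)
        return float(np.abs(recon - self.predictions).max())


@dataclass
class AttributionSummary:
    table: pd.DataFrame  # per feature: mean_abs_shap, rank, direction, direction_stat

    def top(self, n: int = 20) -> pd.DataFrame:
        return self.table.sort_values("rank").head(n)


@dataclass
class SampleExplanation:
    gene_id: str
    base_value: float
    contributions: pd.Series
    prediction: float

    def top(self, n: int = 10) -> pd.Series:
        return self.contributions.reindex(self.contributions.abs().sort_values(ascending=False).index).head(n)


def _resolve(model, X: pd.DataFrame):
    """Unwrap TrainedClassifier / ZGAClassifier to (raw estimator, X frame)."""
    from .models import TrainedClassifier, ZGAClassifier

    if isinstance(model, TrainedClassifier):
        missing = [f for f in model.selected_features if f not in X.columns]
        if missing:
            raise KeyError(f"feature columns missing: {missing}")
        return model.classifier.estimator_, X[list(model.selected_features)]
    if isinstance(model, ZGAClassifier):
        if hasattr(model, "feature_names_in_"):
            X = X[list(model.feature_names_in_)]
        return model.estimator_, X
    return model, X


def compute_shap(
    model,
    X: pd.DataFrame,
    background: np.ndarray | None = None,
    n_permutations: int = 2048,
    seed: int = 0,
) -> Attribution:
    """Shapley attribution matrix for every row of X.

    Tree models (random forest / single tree) are exact in class-1
    probability space; XGBoost uses its native tree attributions in margin
    space; SVM / logistic regression use permutation sampling against
    ``background`` (default: column means of X, the conventional
    training-mean reference).
    """
    est, Xs = _resolve(model, X)
    arr = Xs.to_numpy(dtype=float)
    if isinstance(est, (RandomForestClassifier, DecisionTreeClassifier)):
        phi, base = forest_shap(est, arr)
        pred = est.predict_proba(arr)[:, 1]
        space = "probability"
    elif isinstance(est, XGBClassifier):
        dmat = xgboost.DMatrix(arr)
        contrib = est.get_booster().predict(dmat, pred_contribs=True)
        phi, base = contrib[:, :-1], contrib[:, -1].astype(float)
        pred = est.get_booster().predict(dmat, output_margin=True)
        space = "margin"
    elif isinstance(est, (SVC, LogisticRegression)):
        if background is None:
            background = arr.mean(axis=0, keepdims=True)
        phi, base = permutation_shap(
            lambda A: est.predict_proba(A)[:, 1], arr, background,
            n_permutations=n_permutations, seed=seed,
        )
        pred = est.predict_proba(arr)[:, 1]
        space = "probability"
    else:
        raise TypeError(f"unsupported model type {type(est).__name__}")
    return Attribution(
        values=pd.DataFrame(phi, index=Xs.index, columns=Xs.columns),
        base_values=pd.Series(np.broadcast_to(base, (len(arr),)).copy(), index=Xs.index),
        predictions=pd.Series(pred, index=Xs.index),
        output_space=space,
    )


def summarize(
    attr: Attribution,
    X: pd.DataFrame,
    direction_threshold: float = 0.2,
) -> AttributionSummary:
    """Global ranking by mean |SHAP| plus favourable/unfavourable direction.

    Direction is the sign of the Pearson correlation between feature value
    and attribution across samples: above +threshold -> favourable, below
    -threshold -> unfavourable, else indeterminate (constant features are
    always indeterminate).
    """
    feats = list(attr.values.columns)
    Xs = X[feats].loc[attr.values.index]
    mean_abs = attr.values.abs().mean(axis=0)
    order = np.argsort(-mean_abs.to_numpy(), kind="stable")
    rank = pd.Series(0, index=mean_abs.index, dtype=int)
    rank.iloc[order] = np.arange(1, len(feats) + 1)
    stats, directions = [], []
    for f in feats:
        xv = Xs[f].to_numpy(dtype=float)
        pv = attr.values[f].to_numpy()
        if np.std(xv) == 0 or np.std(pv) == 0:
            stats.append(np.nan)
            directions.append("indeterminate")
            continue
        r = float(np.corrcoef(xv, pv)[0, 1])
        stats.append(r)
        if r > direction_threshold:
            directions.append("favourable")
        elif r < -direction_threshold:
            directions.append("unfavourable")
        else:
            directions.append("indeterminate")
    table = pd.DataFrame(
        {
            "mean_abs_shap": mean_abs,
            "rank": rank,
            "direction": directions,
            "direction_stat": stats,
        }
    )
    return AttributionSummary(table=table)


def explain_sample(model, x: pd.Series | pd.DataFrame, **kwargs) -> SampleExplanation:
    """Signed per-feature contributions for one gene."""
    X = x.to_frame().T if isinstance(x, pd.Series) else x
    if len(X) != 1:
        raise ValueError("explain_sample expects exactly one row")
    attr = compute_shap(model, X, **kwargs)
    return SampleExplanation(
        gene_id=str(X.index[0]),
        base_value=float(attr.base_values.iloc[0]),
        contributions=attr.values.iloc[0],
        prediction=float(attr.predictions.iloc[0]),
    )


def interaction_summary(model, X: pd.DataFrame, feature_a: str, feature_b: str) -> dict:
    """Pairwise SHAP interaction values between two features (tree models).

    Interaction(a, b) = (phi_b | a present) - (phi_b | a absent) halved,
    computed per sample; symmetric in (a, b).  Raises for non-tree models,
    whose exact interaction values are not available.
    """
    est, Xs = _resolve(model, X)
    feats = list(Xs.columns)
    for f in (feature_a, feature_b):
        if f not in feats:
            raise KeyError(f"feature {f!r} not among model features")
    arr = Xs.to_numpy(dtype=float)
    if isinstance(est, (RandomForestClassifier, DecisionTreeClassifier)):
        ia = feats.index(feature_a)
        phi_on, _ = forest_shap(est, arr, skip_feature=ia, skip_mode=1)
        phi_off, _ = forest_shap(est, arr, skip_feature=ia, skip_mode=-1)
        inter = (phi_on[:, feats.index(feature_b)] - phi_off[:, feats.index(feature_b)]) / 2.0
    elif isinstance(est, XGBClassifier):
        import xgboost

        tensor = est.get_booster().predict(xgboost.DMatrix(arr), pred_interactions=True)
        inter = tensor[:, feats.index(feature_a), feats.index(feature_b)]
    else:
        raise TypeError(
            f"exact interaction values require a tree model, got {type(est).__name__}"
        )
    values = pd.Series(inter, index=Xs.index, name=f"interaction[{feature_a},{feature_b}]")
    return {
        "feature_a": feature_a,
        "feature_b": feature_b,
        "values": values,
        "mean_abs": float(values.abs().mean()),
    }


def dependence_table(attr: Attribution, X: pd.DataFrame, feature: str, interacting: str | None = None) -> pd.DataFrame:
    """Plot-ready table: feature value, its attribution, optional colour-by."""
    out = pd.DataFrame(
        {
            "feature_value": X.loc[attr.values.index, feature],
            "shap_value": attr.values[feature],
        }
    )
    if interacting is not None:
        out["interacting_value"] = X.loc[attr.values.index, interacting]
    return out
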