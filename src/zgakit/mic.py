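"""Maximal information coefficient (MIC) for class-labelled features.

For a continuous feature x and a discrete label y, the MINE search over
grids reduces to a one-dimensional problem: the y-axis partition is fixed by
the label classes, so MIC is the maximum over x-axis partitions P (with the
grid bound ``|P| * n_classes <= B = n**0.6``) of

    I(P(x); y) / log2(min(|P|, n_classes))

Mutual information is additive over the bins of P, so the optimal partition
for each bin count is found exactly by dynamic programming over "clumps"
(maximal runs of tied x values, optionally pre-merged into equal-frequency
superclumps for speed, as in the MINE approximation).

``mic_score`` handles a single feature with exact tie clumping;
``mic_scores`` ranks whole feature matrices with a vectorised DP shared
across columns (random tie-breaking, seeded).
"""

from __future__ import annotations

import numpy as np

__all__ = ["mic_score", "mic_scores"]


def _grid_bound(n: int, alpha: float = 0.6) -> float:
    return float(n) ** alpha


def _bin_contrib(n0: np.ndarray, n1: np.ndarray, n: int, ny0: int, ny1: int) -> np.ndarray:
    """Additive MI contribution (bits) of bins with per-class counts n0, n1."""
    nb = n0 + n1
    with np.errstate(divide="ignore", invalid="ignore"):
        t0 = np.where(n0 > 0, n0 / n * np.log2(np.maximum(n0, 1) * n / np.maximum(nb * ny0, 1)), 0.0)
        t1 = np.where(n1 > 0, n1 / n * np.log2(np.maximum(n1, 1) * n / np.maximum(nb * ny1, 1)), 0.0)
    return t0 + t1


def _encode_labels(y) -> tuple[np.ndarray, int]:
    y = np.asarray(y)
    classes, codes = np.unique(y, return_inverse=True)
    if len(classes) != 2:
        raise ValueError(f"mic_score expects binary labels, got {len(classes)} classes")
    return codes.astype(np.int64), 2


def mic_score(x, y, alpha: float = 0.6, max_clumps: int = 200) -> float:
    """MIC of one feature column against binary labels.

    Symmetric in the label coding; 0 for a constant column; requires at
    least 10 samples.  ``max_clumps`` caps the DP size by merging adjacent
    tie-clumps into equal-frequency superclumps (never splitting a tie run),
    mirroring the MINE superclump approximation.
    """
    x = np.asarray(x, dtype=float)
    codes, _ = _encode_labels(y)
    n = len(x)
    if n < 10:
        raise ValueError("mic_score needs at least 10 samples")
    if len(codes) != n:
        raise ValueError("x and y length mismatch")
    if np.all(x == x[0]):
        return 0.0
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], codes[order]
    # clump boundaries: indices where a new distinct x value starts
    new_val = np.flatnonzero(np.diff(xs) != 0) + 1
    bounds = np.concatenate([[0], new_val, [n]])
    if len(bounds) - 1 > max_clumps:
        # merge into ~max_clumps superclumps along equal-frequency targets
        targets = np.linspace(0, n, max_clumps + 1)[1:-1]
        keep = np.unique(np.searchsorted(bounds, targets, side="left").clip(1, len(bounds) - 2))
        bounds = np.concatenate([[0], bounds[keep], [n]])
    k = len(bounds) - 1  # number of clumps
    c1 = np.concatenate([[0], np.cumsum(ys)])[bounds]  # class-1 counts up to each boundary
    c0 = bounds - c1
    ny1 = int(c1[-1])
    ny0 = n - ny1
    cmax = max(2, int(_grid_bound(n, alpha) / 2))
    cmax = min(cmax, k)
    if cmax < 2:
        return 0.0
    # contrib[j, i]: MI contribution of a bin spanning clumps j..i-1
    contrib = _bin_contrib(
        c0[None, 1:] - c0[:-1, None], c1[None, 1:] - c1[:-1, None], n, ny0, ny1
    )  # shape (k, k): rows j = start boundary, cols i-1 = end boundary
    NEG = -np.inf
    # F1[i] = contribution of a single bin covering clumps 0..i-1
    f_prev = np.full(k + 1, NEG)
    f_prev[1:] = contrib[0, :]
    out = 0.0
    for c in range(2, cmax + 1):
        f_cur = np.full(k + 1, NEG)
        for i in range(c, k + 1):
            # last bin spans clumps j..i-1 for j in [c-1, i-1]
            cand = f_prev[c - 1 : i] + contrib[c - 1 : i, i - 1]
            f_cur[i] = cand.max()
        f_prev = f_cur
        out = max(out, f_cur[k] / np.log2(min(c, 2)))
    return float(min(max(out, 0.0), 1.0))


def mic_scores(
    X,
    y,
    alpha: float = 0.6,
    n_superclumps: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """MIC of every column of X against binary labels (vectorised DP).

    Columns are pre-binned into ``n_superclumps`` equal-frequency
    superclumps with random (seeded) tie-breaking, then the same
    dynamic program as :func:`mic_score` runs across all columns at once.
    Exactly constant columns score 0.
    """
    X = np.asarray(X, dtype=float)
    codes, _ = _encode_labels(y)
    n, nf = X.shape
    if n < 10:
        raise ValueError("mic_scores needs at least 10 samples")
    rng = np.random.default_rng(seed)
    # random tie-break: jitter far below any meaningful value gap
    scale = np.maximum(np.nanstd(X, axis=0), 1.0)
    Xj = X + rng.uniform(-1e-9, 1e-9, size=X.shape) * scale
    order = np.argsort(Xj, axis=0, kind="stable")
    ys = codes[order]  # (n, nf) labels sorted by each column
    G = min(n_superclumps, n)
    bounds = np.floor(np.linspace(0, n, G + 1)).astype(np.int64)
    csum = np.concatenate([np.zeros((1, nf), dtype=np.int64), np.cumsum(ys, axis=0)])
    c1 = csum[bounds]  # (G+1, nf)
    c0 = bounds[:, None] - c1
    ny1 = int(codes.sum())
    ny0 = n - ny1
    cmax = max(2, int(_grid_bound(n, alpha) / 2))
    cmax = min(cmax, G)
    NEG = -np.inf
    # contrib[j, i]: MI contribution of a bin spanning boundaries j..i, all columns
    contrib = np.full((G + 1, G + 1, nf), NEG)
    for i in range(1, G + 1):
        j = np.arange(0, i)
        contrib[j, i] = _bin_contrib(c0[i][None, :] - c0[j], c1[i][None, :] - c1[j], n, ny0, ny1)
    f_prev = contrib[0].copy()  # one bin covering boundaries 0..i
    out = np.zeros(nf)
    for c in range(2, cmax + 1):
        f_cur = np.full((G + 1, nf), NEG)
        for i in range(c, G + 1):
            # candidates over last-bin start boundary j in [c-1, i-1]
            f_cur[i] = (f_prev[c - 1 : i] + contrib[c - 1 : i, i]).max(axis=0)
        f_prev = f_cur
        out = np.maximum(out, f_cur[G] / np.log2(min(c, 2)))
    out = np.clip(out, 0.0, 1.0)
    out[np.ptp(X, axis=0) == 0] = 0.0
    return out
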