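"""Random-forest Gini importance engine.

Implements the standard mean-decrease-in-impurity importance: an ensemble
of CART trees, each grown on a bootstrap sample with Gini impurity as the
split criterion and a random subset of sqrt(p) candidate features per node
(constant features at a node do not count against the budget, matching the
common splitter semantics).  Per-tree importances — impurity decreases
weighted by node size — are normalized to sum to one and averaged across
trees, then renormalized.

The trees exist only to score features; no predictions are made with them.
The hot loops are numba-compiled because the surrounding ensemble fits
hundreds of thousands of forests on very small training sets, where a
general-purpose implementation spends nearly all its time on per-call
overhead.  Agreement with scikit-learn's RandomForestClassifier
importances is checked in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _gini(n0: int, n1: int) -> float:
    n = n0 + n1
    if n == 0:
        return 0.0
    p0 = n0 / n
    p1 = n1 / n
    return 1.0 - p0 * p0 - p1 * p1


@njit(cache=True)
def _grow_tree(X, y, idx, max_features, importances):
    """Grow one CART tree in place; accumulate impurity decreases.

    ``idx`` holds the bootstrap sample row indices and is partitioned in
    place as the tree grows (iterative depth-first, explicit stack).
    Importance contribution of a split on feature f at a node with n of N
    samples: (n*gini_parent - n_left*gini_left - n_right*gini_right) / N.
    """
    n_total = idx.shape[0]
    n_feat = X.shape[1]
    stack_start = np.empty(2 * n_total + 2, np.int64)
    stack_end = np.empty(2 * n_total + 2, np.int64)
    stack_start[0] = 0
    stack_end[0] = n_total
    top = 1
    feat_order = np.empty(n_feat, np.int64)
    while top > 0:
        top -= 1
        s = stack_start[top]
        e = stack_end[top]
        n = e - s
        n1 = 0
        for i in range(s, e):
            n1 += y[idx[i]]
        n0 = n - n1
        if n < 2 or n0 == 0 or n1 == 0:
            continue
        parent_gini = _gini(n0, n1)

        for f in range(n_feat):
            feat_order[f] = f
        best_gain = 0.0
        best_feat = -1
        best_thr = 0.0
        visited = 0
        f_i = 0
        while f_i < n_feat and visited < max_features:
            j = f_i + np.random.randint(n_feat - f_i)
            tmp = feat_order[f_i]
            feat_order[f_i] = feat_order[j]
            feat_order[j] = tmp
            feat = feat_order[f_i]
            f_i += 1

            vals = np.empty(n, np.float64)
            for i in range(n):
                vals[i] = X[idx[s + i], feat]
            order = np.argsort(vals, kind="mergesort")
            if vals[order[n - 1]] <= vals[order[0]]:
                continue  # constant at this node: not counted as visited
            visited += 1
            c1 = 0
            for i in range(n - 1):
                c1 += y[idx[s + order[i]]]
                v = vals[order[i]]
                v_next = vals[order[i + 1]]
                if v_next <= v:
                    continue
                nl = i + 1
                nr = n - nl
                gl = _gini(nl - c1, c1)
                gr = _gini(n0 - (nl - c1), n1 - c1)
                gain = parent_gini - (nl * gl + nr * gr) / n
                if gain > best_gain + 1e-12:
                    best_gain = gain
                    best_feat = feat
                    best_thr = 0.5 * (v + v_next)
        if best_feat < 0:
            continue

        # child class counts for the importance bookkeeping
        nl = 0
        c1l = 0
        for i in range(s, e):
            if X[idx[i], best_feat] <= best_thr:
                nl += 1
                c1l += y[idx[i]]
        gl = _gini(nl - c1l, c1l)
        gr = _gini((n - nl) - (n1 - c1l), n1 - c1l)
        importances[best_feat] += (n * parent_gini - nl * gl - (n - nl) * gr) / n_total

        # in-place partition of idx[s:e] around the split
        i = s
        j = e - 1
        while i <= j:
            if X[idx[i], best_feat] <= best_thr:
                i += 1
            else:
                tmp = idx[i]
                idx[i] = idx[j]
                idx[j] = tmp
                j -= 1
        stack_start[top] = s
        stack_end[top] = i
        top += 1
        stack_start[top] = i
        stack_end[top] = e
        top += 1


@njit(cache=True)
def _gini_importances(X, y, n_trees, max_features, seed):
    n, p = X.shape
    total = np.zeros(p, np.float64)
    np.random.seed(seed)
    imp = np.empty(p, np.float64)
    for _ in range(n_trees):
        idx = np.empty(n, np.int64)
        for i in range(n):
            idx[i] = np.random.randint(n)
        imp[:] = 0.0
        _grow_tree(X, y, idx, max_features, imp)
        s = imp.sum()
        if s > 0.0:
            total += imp / s
    s = total.sum()
    if s > 0.0:
        total /= s
    else:
        total[:] = 1.0 / p  # no tree found any split: all features equal
    return total


def gini_importances(
    X: np.ndarray, y: np.ndarray, n_trees: int = 100, seed: int = 0
) -> np.ndarray:
    """Normalized mean-decrease-in-impurity importances (sum to 1).

    ``max_features`` is sqrt(p) rounded, the classification default.
    Deterministic given ``seed``.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.int64)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y shapes disagree")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    max_features = max(1, int(round(np.sqrt(X.shape[1]))))
    return _gini_importances(X, y, int(n_trees), max_features, int(seed) % (2**32))
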