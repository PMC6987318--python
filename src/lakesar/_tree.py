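"""Low-level CART kernels (numba) used by :mod:`lakesar.forest`.

Trees are stored as flat arrays: ``feature[k] >= 0`` marks an internal node
with split ``x[feature[k]] <= threshold[k]`` sending a row to ``left[k]``,
else ``right[k]``; ``feature[k] == -1`` marks a leaf predicting ``value[k]``
(the mean response of its training rows).

Split search: among the ``mtry`` candidate predictors, the (variable,
threshold) pair minimising total within-child sum of squared residuals,
thresholds at midpoints of consecutive distinct observed values.  Ties are
broken deterministically toward the lowest variable index and smallest
threshold (candidates are scanned in that order and only strict improvements
are accepted).  Splitting stops when children would fall below ``min_leaf``
or no split reduces the SSE (tolerance 1e-12, guarding float noise on
constant responses).
"""
from __future__ import annotations

import numpy as np
from numba import njit

# gain below this is treated as "no reduction in SSE"
_GAIN_TOL = 1e-12


@njit(cache=True)
def grow_tree(X, y, sample_idx, mtry, min_leaf, seed):  # pragma: no cover - numba
    np.random.seed(seed)
    n = sample_idx.shape[0]
    p = X.shape[1]
    max_nodes = 2 * n + 1

    feature = np.full(max_nodes, -1, np.int64)
    threshold = np.zeros(max_nodes)
    left = np.full(max_nodes, -1, np.int64)
    right = np.full(max_nodes, -1, np.int64)
    value = np.zeros(max_nodes)
    count = np.zeros(max_nodes, np.int64)

    samples = sample_idx.copy()
    feats = np.empty(p, np.int64)

    stack_node = np.empty(max_nodes, np.int64)
    stack_lo = np.empty(max_nodes, np.int64)
    stack_hi = np.empty(max_nodes, np.int64)
    stack_node[0] = 0
    stack_lo[0] = 0
    stack_hi[0] = n
    top = 1
    n_nodes = 1

    while top > 0:
        top -= 1
        node = stack_node[top]
        lo = stack_lo[top]
        hi = stack_hi[top]
        nn = hi - lo

        s1 = 0.0
        s2 = 0.0
        for k in range(lo, hi):
            yv = y[samples[k]]
            s1 += yv
            s2 += yv * yv
        value[node] = s1 / nn
        count[node] = nn
        sse_parent = s2 - s1 * s1 / nn

        if nn < 2 * min_leaf or sse_parent <= _GAIN_TOL:
            continue

        # sample mtry distinct predictors (partial Fisher-Yates), then sort
        # ascending so the lowest-index tie-break falls out of the scan order
        for f in range(p):
            feats[f] = f
        for i in range(mtry):
            j = i + np.random.randint(p - i)
            tmp = feats[i]
            feats[i] = feats[j]
            feats[j] = tmp
        chosen = np.sort(feats[:mtry])

        best_f = -1
        best_thr = 0.0
        best_sse = np.inf

        xv = np.empty(nn)
        ys = np.empty(nn)
        for ci in range(mtry):
            f = chosen[ci]
            for k in range(nn):
                xv[k] = X[samples[lo + k], f]
            order = np.argsort(xv)
            for k in range(nn):
                ys[k] = y[samples[lo + order[k]]]
            sl1 = 0.0
            sl2 = 0.0
            for k in range(nn - 1):
                yv = ys[k]
                sl1 += yv
                sl2 += yv * yv
                nl = k + 1
                nr = nn - nl
                if nl < min_leaf or nr < min_leaf:
                    continue
                xa = xv[order[k]]
                xb = xv[order[k + 1]]
                if xb <= xa:
                    continue
                sr1 = s1 - sl1
                sr2 = s2 - sl2
                sse = (sl2 - sl1 * sl1 / nl) + (sr2 - sr1 * sr1 / nr)
                if sse < best_sse:
                    best_sse = sse
                    best_f = f
                    best_thr = 0.5 * (xa + xb)

        if best_f < 0 or sse_parent - best_sse <= _GAIN_TOL:
            continue

        # in-place partition of samples[lo:hi] around the chosen split
        i = lo
        j = hi - 1
        while i <= j:
            if X[samples[i], best_f] <= best_thr:
                i += 1
            else:
                tmp = samples[i]
                samples[i] = samples[j]
                samples[j] = tmp
                j -= 1
        mid = i

        feature[node] = best_f
        threshold[node] = best_thr
        lchild = n_nodes
        rchild = n_nodes + 1
        n_nodes += 2
        left[node] = lchild
        right[node] = rchild
        stack_node[top] = lchild
        stack_lo[top] = lo
        stack_hi[top] = mid
        top += 1
        stack_node[top] = rchild
        stack_lo[top] = mid
        stack_hi[top] = hi
        top += 1

    return (feature[:n_nodes], threshold[:n_nodes], left[:n_nodes],
            right[:n_nodes], value[:n_nodes], count[:n_nodes])


@njit(cache=True)
def apply_forest(offsets, feature, threshold, left, right, X):  # pragma: no cover - numba
    """Leaf index (local to each tree) for every row under every tree."""
    n_trees = offsets.shape[0] - 1
    n = X.shape[0]
    leaves = np.empty((n_trees, n), np.int64)
    for t in range(n_trees):
        base = offsets[t]
        for i in range(n):
            node = 0
            while feature[base + node] >= 0:
                if X[i, feature[base + node]] <= threshold[base + node]:
                    node = left[base + node]
                else:
                    node = right[base + node]
            leaves[t, i] = node
    return leaves


@njit(cache=True)
def predict_per_tree(offsets, feature, threshold, left, right, value, X):  # pragma: no cover
    n_trees = offsets.shape[0] - 1
    n = X.shape[0]
    out = np.empty((n_trees, n))
    for t in range(n_trees):
        base = offsets[t]
        for i in range(n):
            node = 0
            while feature[base + node] >= 0:
                if X[i, feature[base + node]] <= threshold[base + node]:
                    node = left[base + node]
                else:
                    node = right[base + node]
            out[t, i] = value[base + node]
    return out


@njit(cache=True)
def proximity_from_leaves(leaves):  # pragma: no cover - numba
    """Fraction of trees in which rows i and j share a terminal node."""
    n_trees, n = leaves.shape
    P = np.zeros((n, n))
    for t in range(n_trees):
        for i in range(n):
            li = leaves[t, i]
            for j in range(i + 1, n):
                if leaves[t, j] == li:
                    P[i, j] += 1.0
    P /= n_trees
    out = P + P.T
    for i in range(n):
        out[i, i] = 1.0
    return out


@njit(cache=True)
def cross_proximity(leaves_a, leaves_b):  # pragma: no cover - numba
    """Proximity between two row sets evaluated on the same forest."""
    n_trees, na = leaves_a.shape
    nb = leaves_b.shape[1]
    P = np.zeros((na, nb))
    for t in range(n_trees):
        for i in range(na):
            li = leaves_a[t, i]
            for j in range(nb):
                if leaves_b[t, j] == li:
                    P[i, j] += 1.0
    return P / n_trees
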