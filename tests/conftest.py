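import numpy as np
import pandas as pd
import pytest

from lakesar import synth


@pytest.fixture(scope="session")
def small_dataset():
    """Two lakes, five years monthly, 80 taxa, no missingness."""
    cfg = synth.GeneratorConfig(n_lakes=2, start="1992-01-15",
                                end="1996-12-15", n_taxa=80, seed=5)
    return synth.generate_dataset(cfg)


@pytest.fixture(scope="session")
def taxon_pool():
    return synth.generate_taxon_pool(100, (0, 6), seed=3)


def brute_force_cart(X, y, min_leaf=5, gain_tol=1e-12):
    """Exhaustive best-split CART: every (variable, midpoint) candidate.

    Independent reference for the tree grower: direct SSE computation per
    candidate, lowest-variable-index / smallest-threshold tie-break, split
    accepted only on a strict SSE reduction.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    node = {"value": y.mean(), "n": n}
    sse_parent = float(((y - y.mean()) ** 2).sum())
    if n < 2 * min_leaf or sse_parent <= gain_tol:
        return node
    best = None
    for f in range(X.shape[1]):
        vals = np.unique(X[:, f])
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = 0.5 * (lo + hi)
            mask = X[:, f] <= thr
            nl = int(mask.sum())
            nr = n - nl
            if nl < min_leaf or nr < min_leaf:
                continue
            yl, yr = y[mask], y[~mask]
            sse = float(((yl - yl.mean()) ** 2).sum()
                        + ((yr - yr.mean()) ** 2).sum())
            if best is None or sse < best[0]:
                best = (sse, f, thr, mask)
    if best is None or sse_parent - best[0] <= gain_tol:
        return node
    sse, f, thr, mask = best
    node["feature"] = f
    node["threshold"] = thr
    node["left"] = brute_force_cart(X[mask], y[mask], min_leaf, gain_tol)
    node["right"] = brute_force_cart(X[~mask], y[~mask], min_leaf, gain_tol)
    return node


def assert_same_tree(forest, ref, node=0):
    """Compare a 1-tree no-bootstrap forest against the reference dict."""
    feat = forest.tree_feature_
    if "feature" not in ref:
        assert feat[node] == -1, f"expected leaf at node {node}"
        assert forest.tree_value_[node] == pytest.approx(ref["value"],
                                                         abs=1e-12)
        return
    assert feat[node] == ref["feature"], f"split variable differs at {node}"
    assert forest.tree_threshold_[node] == pytest.approx(ref["threshold"],
                                                         abs=1e-12)
    assert_same_tree(forest, ref["left"], forest.tree_left_[node])
    assert_same_tree(forest, ref["right"], forest.tree_right_[node])
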