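"""Exact Shapley attributions for scikit-learn gradient-boosted trees.

For each tree the conditional expectation of the tree output given a feature
subset is evaluated with cover-weighted traversal (splits on out-of-subset
features average their children by training cover).  Because individual
trees are shallow, the Shapley value over the tree's own feature set is
computed exactly by subset enumeration; trees are summed, which preserves
exact additivity: base value + sum of attributions = model prediction.
"""

from __future__ import annotations

from math import factorial

import numpy as np

__all__ = ["tree_shapley_values", "single_tree_shapley", "expected_value"]


def expected_value(tree, X: np.ndarray, in_subset: frozenset) -> np.ndarray:
    """Cover-weighted conditional expectation of a sklearn Tree per row.

    Features inside ``in_subset`` follow the split; features outside are
    marginalized using the training-cover fractions of the children.
    """
    cl, cr = tree.children_left, tree.children_right
    feat, thr = tree.feature, tree.threshold
    cover = tree.weighted_n_node_samples
    value = tree.value[:, 0, 0]

    def rec(node: int) -> np.ndarray:
        if cl[node] == -1:
            return np.full(X.shape[0], value[node])
        left = rec(cl[node])
        right = rec(cr[node])
        f = feat[node]
        if f in in_subset:
            return np.where(X[:, f] <= thr[node], left, right)
        wl = cover[cl[node]] / cover[node]
        return wl * left + (1.0 - wl) * right

    return rec(0)


def single_tree_shapley(tree, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact Shapley values of one tree for every row of X.

    Returns (phi, base) where phi has shape (n_rows, n_features) and base is
    the per-row empty-subset expectation (constant vector).
    """
    n_rows, n_features = X.shape
    used = sorted(set(int(f) for f in tree.feature if f >= 0))
    phi = np.zeros((n_rows, n_features))
    base = expected_value(tree, X, frozenset())
    d = len(used)
    if d == 0:
        return phi, base
    # v[mask] = E[f | features with bit set in mask are known]
    v = {}
    for mask in range(1 << d):
        subset = frozenset(used[b] for b in range(d) if mask >> b & 1)
        v[mask] = expected_value(tree, X, subset)
    fact = [factorial(k) for k in range(d + 1)]
    for b, f in enumerate(used):
        bit = 1 << b
        for mask in range(1 << d):
            if mask & bit:
                continue
            s = bin(mask).count("1")
            weight = fact[s] * fact[d - s - 1] / fact[d]
            phi[:, f] += weight * (v[mask | bit] - v[mask])
    return phi, base


def tree_shapley_values(model, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Shapley attributions for a GradientBoostingRegressor/Classifier.

    Returns (phi, base_value) on the raw-prediction scale; for the regressor
    base_value + phi.sum(axis=1) equals model.predict(X) exactly.
    """
    X = np.asarray(X, dtype=np.float64)
    phi = np.zeros_like(X, dtype=np.float64)
    lr = model.learning_rate
    base = 0.0
    for stage in model.estimators_:
        est = stage[0]
        p, b = single_tree_shapley(est.tree_, X)
        phi += lr * p
        base += lr * float(b[0])
    # initial raw prediction (constant for the default init estimators)
    init_raw = model._raw_predict_init(X[:1]).ravel()[0]
    return phi, float(init_raw + base)
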