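"""Exact SHAP values for scikit-learn tree ensembles.

Implements the path-dependent TreeSHAP recursion: for a single decision
tree the Shapley value of each feature is computed against the value
function v(S) = E[f(x) | x_S], where the expectation follows the tree's
own training cover (``weighted_n_node_samples``) whenever a split feature
is outside S.  For a random forest the per-tree attributions are averaged,
which preserves local accuracy because ``predict_proba`` is itself the
tree average.

Local accuracy: for every sample x and class c,

    base_value[c] + sum_j phi[x, j, c] == predict_proba(x)[c]

to numerical precision.  This identity is asserted in the test suite and
re-checked for every resampling iteration of the modelling protocol.
"""

from __future__ import annotations

import numpy as np

__all__ = ["tree_shap_values", "forest_shap_values", "expected_value"]


def _leaf_values(tree) -> np.ndarray:
    """Per-node class-probability vectors, shape (n_nodes, n_classes)."""
    value = tree.value.copy()            # (n_nodes, 1, n_classes)
    value = value[:, 0, :]
    totals = value.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return value / totals


def expected_value(tree) -> np.ndarray:
    """Cover-weighted mean prediction of one fitted sklearn tree."""
    t = tree.tree_
    values = _leaf_values(t)
    leaves = t.children_left == -1
    cover = t.weighted_n_node_samples
    w = cover[leaves] / cover[0]
    return w @ values[leaves]


def _extend(path, zero_fraction, one_fraction, feature_index):
    depth = len(path)
    path.append([feature_index, zero_fraction, one_fraction,
                 1.0 if depth == 0 else 0.0])
    for i in range(depth - 1, -1, -1):
        path[i + 1][3] += one_fraction * path[i][3] * (i + 1) / (depth + 1)
        path[i][3] = zero_fraction * path[i][3] * (depth - i) / (depth + 1)


def _unwind(path, index):
    depth = len(path) - 1
    one_fraction = path[index][1:3][1]
    zero_fraction = path[index][1]
    next_one = path[depth][3]
    for i in range(depth - 1, -1, -1):
        if one_fraction != 0.0:
            tmp = path[i][3]
            path[i][3] = next_one * (depth + 1) / ((i + 1) * one_fraction)
            next_one = tmp - path[i][3] * zero_fraction * (depth - i) / (depth + 1)
        else:
            path[i][3] = path[i][3] * (depth + 1) / (zero_fraction * (depth - i))
    for i in range(index, depth):
        path[i][0:3] = path[i + 1][0:3]
    path.pop()


def _unwound_sum(path, index):
    depth = len(path) - 1
    one_fraction = path[index][2]
    zero_fraction = path[index][1]
    next_one = path[depth][3]
    total = 0.0
    if one_fraction != 0.0:
        for i in range(depth - 1, -1, -1):
            tmp = next_one * (depth + 1) / ((i + 1) * one_fraction)
            total += tmp
            next_one = path[i][3] - tmp * zero_fraction * (depth - i) / (depth + 1)
    else:
        for i in range(depth - 1, -1, -1):
            total += path[i][3] * (depth + 1) / (zero_fraction * (depth - i))
    return total


def _recurse(node, x, phi, arrays, path, parent_zero, parent_one, parent_feature):
    left, right, feature, threshold, cover, values = arrays
    path = [row[:] for row in path]
    _extend(path, parent_zero, parent_one, parent_feature)
    if left[node] == -1:
        leaf = values[node]
        for i in range(1, len(path)):
            w = _unwound_sum(path, i)
            phi[path[i][0]] += w * (path[i][2] - path[i][1]) * leaf
        return
    xj = x[feature[node]]
    hot, cold = ((left[node], right[node]) if xj <= threshold[node]
                 else (right[node], left[node]))
    incoming_zero = 1.0
    incoming_one = 1.0
    for k in range(1, len(path)):
        if path[k][0] == feature[node]:
            incoming_zero = path[k][1]
            incoming_one = path[k][2]
            _unwind(path, k)
            break
    node_cover = cover[node]
    _recurse(hot, x, phi, arrays, path,
             incoming_zero * cover[hot] / node_cover, incoming_one, feature[node])
    _recurse(cold, x, phi, arrays, path,
             incoming_zero * cover[cold] / node_cover, 0.0, feature[node])


def tree_shap_values(tree, X: np.ndarray) -> np.ndarray:
    """SHAP values for one fitted sklearn decision tree.

    Parameters
    ----------
    tree : fitted ``DecisionTreeClassifier`` (or an element of
        ``RandomForestClassifier.estimators_``).
    X : array of shape (n_samples, n_features).

    Returns
    -------
    array of shape (n_samples, n_features, n_classes).
    """
    t = tree.tree_
    values = _leaf_values(t)
    arrays = (t.children_left, t.children_right, t.feature, t.threshold,
              t.weighted_n_node_samples, values)
    X = np.asarray(X, dtype=float)
    phi = np.zeros((X.shape[0], X.shape[1], values.shape[1]))
    for s in range(X.shape[0]):
        _recurse(0, X[s], phi[s], arrays, [], 1.0, 1.0, -1)
    return phi


def forest_shap_values(forest, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """SHAP values and base values for a fitted random forest.

    Returns ``(phi, base)`` where ``phi`` has shape
    (n_samples, n_features, n_classes) and ``base`` shape (n_classes,);
    ``base + phi.sum(axis=1)`` equals ``forest.predict_proba(X)``.
    """
    X = np.asarray(X, dtype=float)
    phi = np.zeros((X.shape[0], X.shape[1], len(forest.classes_)))
    base = np.zeros(len(forest.classes_))
    for est in forest.estimators_:
        phi += tree_shap_values(est, X)
        base += expected_value(est)
    n = len(forest.estimators_)
    return phi / n, base / n
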