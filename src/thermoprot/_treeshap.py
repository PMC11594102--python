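"""Exact path-dependent SHAP values for scikit-learn decision trees.

Implements the polynomial-time tree-traversal algorithm for Shapley
value computation on a single decision tree, where the value of a
feature coalition is the tree's cover-weighted expected output with the
out-of-coalition split decisions averaged over the training cover.
Ensemble attributions are sums (gradient boosting, in logit space) or
means (forests / bagging, in probability space) over member trees.

The test suite checks this implementation against a brute-force
subset-enumeration Shapley oracle on small trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import (
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor


@dataclass
class _Tree:
    """Flat view of one sklearn tree with scalar leaf values."""

    left: np.ndarray
    right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    value: np.ndarray  # scalar per node
    cover: np.ndarray  # weighted training samples per node


def _flatten(tree, classifier_leaf: bool) -> _Tree:
    t = tree.tree_
    if classifier_leaf:
        counts = t.value[:, 0, :]
        # sklearn >= 1.4 stores normalized class fractions already
        totals = counts.sum(axis=1)
        value = np.where(totals > 0, counts[:, -1] / np.where(totals > 0, totals, 1), 0.0)
    else:
        value = t.value[:, 0, 0]
    return _Tree(
        left=t.children_left,
        right=t.children_right,
        feature=t.feature,
        threshold=t.threshold,
        value=np.asarray(value, dtype=float),
        cover=np.asarray(t.weighted_n_node_samples, dtype=float),
    )


def _tree_shap_single(t: _Tree, x: np.ndarray, phi: np.ndarray) -> None:
    """Add the SHAP values of one tree for one sample into ``phi``.

    Direct transcription of the EXTEND/UNWIND path algorithm, with the
    path kept 1-indexed to mirror the recurrence weights.
    """

    # path entries: d (feature), z (zero fraction), o (one fraction), w;
    # index 0 is a dummy so real entries run 1..l as in the recurrences
    def extend(m, pz, po, pi):
        l = len(m) - 1
        m = [e.copy() for e in m] + [[pi, pz, po, 1.0 if l == 0 else 0.0]]
        for i in range(l, 0, -1):
            m[i + 1][3] += po * m[i][3] * i / (l + 1.0)
            m[i][3] = pz * m[i][3] * (l + 1.0 - i) / (l + 1.0)
        return m

    def unwind(m, i):
        # removes path entry i (1-indexed among entries 1..l)
        l = len(m) - 1
        o_i, z_i = m[i][2], m[i][1]
        n = m[l][3]
        m = [e.copy() for e in m]
        for j in range(l - 1, 0, -1):
            if o_i != 0:
                t_ = m[j][3]
                m[j][3] = n * l / (j * o_i)
                n = t_ - m[j][3] * z_i * (l - j) / l
            else:
                m[j][3] = m[j][3] * l / (z_i * (l - j))
        for j in range(i, l):
            m[j][0], m[j][1], m[j][2] = m[j + 1][0], m[j + 1][1], m[j + 1][2]
        return m[:-1]

    def unwound_sum(m, i):
        l = len(m) - 1
        o_i, z_i = m[i][2], m[i][1]
        total = 0.0
        n = m[l][3]
        for j in range(l - 1, 0, -1):
            if o_i != 0:
                tmp = n * l / (j * o_i)
            else:
                tmp = m[j][3] * l / (z_i * (l - j))
            total += tmp
            if o_i != 0:
                n = m[j][3] - tmp * z_i * (l - j) / l
        return total

    def recurse(j, m, pz, po, pi):
        m = extend(m, pz, po, pi)
        if t.left[j] < 0:  # leaf
            for i in range(1, len(m)):
                w = unwound_sum(m, i)
                phi[m[i][0]] += w * (m[i][2] - m[i][1]) * t.value[j]
            return
        f = int(t.feature[j])
        hot, cold = (
            (t.left[j], t.right[j])
            if x[f] <= t.threshold[j]
            else (t.right[j], t.left[j])
        )
        iz, io = 1.0, 1.0
        k = next((i for i in range(1, len(m)) if m[i][0] == f), 0)
        if k != 0:
            iz, io = m[k][1], m[k][2]
            m = unwind(m, k)
        recurse(int(hot), m, iz * t.cover[hot] / t.cover[j], io, f)
        recurse(int(cold), m, iz * t.cover[cold] / t.cover[j], 0.0, f)

    recurse(0, [[-1, 0.0, 0.0, 0.0]], 1.0, 1.0, -1)


def tree_expected_value(t: _Tree, x: np.ndarray, coalition: frozenset) -> float:
    """Cover-weighted expectation with only ``coalition`` features fixed.

    The independent brute-force oracle uses this to enumerate Shapley
    values; exposed for testing.
    """

    def rec(j) -> float:
        if t.left[j] < 0:
            return float(t.value[j])
        f = int(t.feature[j])
        if f in coalition:
            child = t.left[j] if x[f] <= t.threshold[j] else t.right[j]
            return rec(int(child))
        cl, cr = int(t.left[j]), int(t.right[j])
        return (t.cover[cl] * rec(cl) + t.cover[cr] * rec(cr)) / t.cover[j]

    return rec(0)


def brute_force_tree_shap(t: _Tree, x: np.ndarray, n_features: int) -> np.ndarray:
    """Exponential-time Shapley enumeration over the tree's own features."""
    feats = sorted({int(f) for f in t.feature if f >= 0})
    phi = np.zeros(n_features)
    M = len(feats)
    for i in feats:
        others = [f for f in feats if f != i]
        for mask in range(2 ** len(others)):
            S = frozenset(f for b, f in enumerate(others) if mask >> b & 1)
            w = math.factorial(len(S)) * math.factorial(M - len(S) - 1) / math.factorial(M)
            phi[i] += w * (
                tree_expected_value(t, x, S | {i}) - tree_expected_value(t, x, S)
            )
    return phi


def _model_trees(model) -> tuple[list[_Tree], str]:
    """Flatten a supported tree model into (trees, combine mode)."""
    if isinstance(model, GradientBoostingClassifier):
        trees = [_flatten(est, classifier_leaf=False) for est in model.estimators_[:, 0]]
        return trees, "sum"
    if isinstance(model, (RandomForestClassifier,)):
        return [_flatten(est, classifier_leaf=True) for est in model.estimators_], "mean"
    if isinstance(model, BaggingClassifier):
        if not all(isinstance(e, DecisionTreeClassifier) for e in model.estimators_):
            raise TypeError("bagging ensemble does not consist of decision trees")
        return [_flatten(est, classifier_leaf=True) for est in model.estimators_], "mean"
    if isinstance(model, DecisionTreeClassifier):
        return [_flatten(model, classifier_leaf=True)], "mean"
    if isinstance(model, DecisionTreeRegressor):
        return [_flatten(model, classifier_leaf=False)], "mean"
    raise TypeError(
        f"{type(model).__name__} is not a supported tree model; "
        "use permutation_importance for non-tree models"
    )


def shap_values(model, X: np.ndarray) -> np.ndarray:
    """Per-sample, per-feature SHAP attributions for a tree model.

    Gradient boosting: attributions in logit space scaled by the
    learning rate, summing (with the model's prior) to the decision
    function.  Forest/bagging/tree classifiers: attributions in
    probability space of the positive class.
    """
    X = np.asarray(X, dtype=float)
    trees, mode = _model_trees(model)
    out = np.zeros((X.shape[0], X.shape[1]))
    for t in trees:
        for r in range(X.shape[0]):
            phi = np.zeros(X.shape[1])
            _tree_shap_single(t, X[r], phi)
            out[r] += phi
    if mode == "mean":
        out /= len(trees)
    elif isinstance(model, GradientBoostingClassifier):
        out *= model.learning_rate
    return out
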