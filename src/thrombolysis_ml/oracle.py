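"""Brute-force Shapley oracle for small tree ensembles.

Independent verification harness for the fast TreeSHAP path: Shapley
values and pairwise interaction indices are computed by explicit
enumeration of all feature coalitions. The coalition value v(S) is the
expected raw margin when the features outside S are integrated out by
recursive tree descent — at a split on a present feature the walk follows
the patient's value; at a split on an absent feature both children are
averaged, weighted by their share of the training mass recorded in the
tree (or of a user-supplied background table).

Cost is O(2^M) coalition evaluations per tree, so the oracle refuses
more than a small number of encoded features; it exists to certify the
fast implementation on toy models, not to explain real ones.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import xgboost as xgb
from scipy.special import logit

__all__ = [
    "ParsedTree",
    "parse_booster",
    "coalition_value",
    "exact_shap_values",
    "exact_shap_interactions",
    "MAX_ORACLE_FEATURES",
]

MAX_ORACLE_FEATURES = 12


@dataclass
class ParsedTree:
    """One regression tree from the booster's JSON dump.

    ``weights[node]`` is the training mass (sum of hessians) at the node;
    leaf values live in ``values`` with ``children_left == -1`` marking
    leaves. Split conditions use xgboost's convention: go left when
    ``x[feature] < threshold``.
    """

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    values: np.ndarray
    weights: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.values)

    def reweight(self, background: np.ndarray) -> "ParsedTree":
        """Replace node weights by background-row counts (tree descent)."""
        counts = np.zeros(self.n_nodes)
        for row in background:
            node = 0
            while True:
                counts[node] += 1.0
                if self.children_left[node] == -1:
                    break
                node = (self.children_left[node]
                        if row[self.feature[node]] < self.threshold[node]
                        else self.children_right[node])
        return ParsedTree(self.children_left, self.children_right,
                          self.feature, self.threshold, self.values, counts)


def parse_booster(booster: xgb.Booster) -> tuple[list[ParsedTree], float]:
    """Parse a booster's JSON model dump into trees plus the margin offset.

    Returns the trees and the global bias on the margin scale (for the
    logistic objective, logit of the stored base score).
    """
    raw = json.loads(bytes(booster.save_raw(raw_format="json")))
    learner = raw["learner"]
    base_score = float(learner["learner_model_param"]["base_score"])
    objective = learner["objective"]["name"]
    offset = float(logit(base_score)) if objective.startswith("binary:") \
        else base_score
    trees = []
    for t in learner["gradient_booster"]["model"]["trees"]:
        # JSON prints float32 node values as shortest round-trip decimals;
        # cast back to float32 so threshold comparisons match the booster's.
        conditions = np.asarray(t["split_conditions"],
                                dtype=np.float32).astype(float)
        trees.append(ParsedTree(
            children_left=np.asarray(t["left_children"], dtype=int),
            children_right=np.asarray(t["right_children"], dtype=int),
            feature=np.asarray(t["split_indices"], dtype=int),
            threshold=conditions,
            values=conditions,
            weights=np.asarray(t["sum_hessian"], dtype=float),
        ))
    return trees, offset


def _tree_values_all_masks(tree: ParsedTree, x: np.ndarray,
                           n_features: int) -> np.ndarray:
    """v(S) for one tree and one row, for every coalition bitmask at once.

    Bottom-up over nodes: for masks containing the split feature, descend
    to the child the row falls into; otherwise average the children with
    training-mass weights.
    """
    n_masks = 1 << n_features
    masks = np.arange(n_masks)
    vals = np.empty((tree.n_nodes, n_masks))
    # process nodes in reverse index order: children always have larger ids
    for node in range(tree.n_nodes - 1, -1, -1):
        left = tree.children_left[node]
        if left == -1:
            vals[node, :] = tree.values[node]
            continue
        right = tree.children_right[node]
        f = tree.feature[node]
        goes_left = x[f] < tree.threshold[node]
        follow = vals[left] if goes_left else vals[right]
        w = tree.weights
        denom = w[left] + w[right]
        avg = (w[left] * vals[left] + w[right] * vals[right]) / denom
        present = (masks >> f) & 1 == 1
        vals[node] = np.where(present, follow, avg)
    return vals[0]


def coalition_value(trees: list[ParsedTree], offset: float, x: np.ndarray,
                    mask: int, n_features: int) -> float:
    """v(S) for coalition ``mask`` (bit i set = feature i present)."""
    total = offset
    for tree in trees:
        total += _tree_values_all_masks(tree, x, n_features)[mask]
    return float(total)


def _prepare(model, X, background):
    if hasattr(model, "booster_"):
        booster = model.booster_
    elif isinstance(model, xgb.Booster):
        booster = model
    else:
        raise TypeError("expected an xgboost Booster or a fitted classifier")
    # the booster sees float32 inputs; mirror that for identical branching
    X = np.asarray(X, dtype=np.float32).astype(float)
    if X.ndim == 1:
        X = X[None, :]
    m = X.shape[1]
    if m > MAX_ORACLE_FEATURES:
        raise ValueError(
            f"oracle refuses {m} features (> {MAX_ORACLE_FEATURES}): "
            "coalition enumeration is exponential")
    trees, offset = parse_booster(booster)
    if background is not None:
        bg = np.asarray(background, dtype=float)
        trees = [t.reweight(bg) for t in trees]
    return trees, offset, X, m


def _shapley_weights(m: int) -> np.ndarray:
    """w[s] = s!(m-s-1)!/m! for coalition sizes s = 0..m-1."""
    return np.array([math.factorial(s) * math.factorial(m - s - 1)
                     / math.factorial(m) for s in range(m)])


def exact_shap_values(model, X, background=None
                      ) -> tuple[np.ndarray, float]:
    """Exact Shapley values by coalition enumeration.

    Parameters
    ----------
    model
        A fitted :class:`~thrombolysis_ml.model.ThrombolysisClassifier`
        or a raw booster with few features.
    X
        Encoded rows (n, m), matching the booster's feature order.
    background
        Optional background table; when given, node weights are recomputed
        as background-row counts instead of the stored training hessians.

    Returns
    -------
    values : (n, m) array of per-feature Shapley values (log-odds).
    base : float, v(empty coalition) — the expected margin.
    """
    trees, offset, X, m = _prepare(model, X, background)
    w = _shapley_weights(m)
    popcount = np.array([bin(s).count("1") for s in range(1 << m)])
    out = np.zeros((X.shape[0], m))
    base = None
    for r, x in enumerate(X):
        v = np.full(1 << m, offset)
        for tree in trees:
            v += _tree_values_all_masks(tree, x, m)
        if base is None:
            base = float(v[0])
        for i in range(m):
            bit = 1 << i
            without = np.nonzero(np.arange(1 << m) & bit == 0)[0]
            gains = v[without | bit] - v[without]
            out[r, i] = float(np.sum(w[popcount[without]] * gains))
    return out, base


def exact_shap_interactions(model, X, background=None) -> np.ndarray:
    """Exact pairwise Shapley interaction tensor by coalition enumeration.

    Off-diagonal (i, j): half the pairwise interaction index
    (discrete second difference of v over coalitions, Shapley-weighted
    over subsets excluding both features). Diagonal: the feature's
    Shapley value minus its off-diagonal row, i.e. the main effect. Row
    sums therefore equal the Shapley values exactly — the same halved
    symmetric convention as the fast implementation.
    """
    trees, offset, X, m = _prepare(model, X, background)
    if m < 2:
        raise ValueError("interactions need at least 2 features")
    popcount = np.array([bin(s).count("1") for s in range(1 << m)])
    # weights over subsets of the m-1 remaining features (j held out)
    w_pair = np.array([math.factorial(s) * math.factorial(m - s - 2)
                       / math.factorial(m - 1) for s in range(m - 1)])
    phi, _ = exact_shap_values(model, X, background)
    out = np.zeros((X.shape[0], m, m))
    for r, x in enumerate(X):
        v = np.full(1 << m, offset)
        for tree in trees:
            v += _tree_values_all_masks(tree, x, m)
        for i in range(m):
            bi = 1 << i
            for j in range(i + 1, m):
                bj = 1 << j
                sel = np.nonzero((np.arange(1 << m) & (bi | bj)) == 0)[0]
                second_diff = (v[sel | bi | bj] - v[sel | bi]
                               - v[sel | bj] + v[sel])
                inter = float(np.sum(w_pair[popcount[sel]] * second_diff))
                out[r, i, j] = out[r, j, i] = inter / 2.0
        for i in range(m):
            out[r, i, i] = phi[r, i] - out[r, i].sum()
    return out
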