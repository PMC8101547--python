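"""Recursive tree growth, leaf prototypes, prediction and serialization.

At every node the features are re-standardized over the node's rows (targets
over its labeled rows), the clustering weights are scaled by the supervision
degree omega, and one oblique split is learned with the configured variant.
The split is kept only if each child receives at least ``min_leaf_labeled``
labeled examples and the size-weighted mean of the child impurities drops
below ``(1 - imp_reduction)`` times the parent impurity (all measured in the
node's standardized space with hard membership weights); otherwise the node
becomes a leaf whose prediction is the column-wise mean of its labeled
targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .core import (
    ClusteringWeights,
    HierarchySpec,
    SemiDataset,
    SplitConfig,
    Standardization,
    Task,
    apply_standardization,
    decode_class,
    default_raw_weights,
    scale_clustering_weights,
    standardize,
)
from .split_grad import group_impurity, learn_split_grad
from .split_svm import learn_split_svm

__all__ = ["SplitNode", "LeafNode", "Tree", "grow_tree", "leaf_prototype",
           "predict_tree"]


@dataclass
class LeafNode:
    prototype: np.ndarray  # column means of the raw labeled targets
    n_labeled: int

    def to_dict(self) -> dict:
        return {"kind": "leaf", "prototype": self.prototype.tolist(),
                "n_labeled": self.n_labeled}


@dataclass
class SplitNode:
    w: np.ndarray
    b: float
    feat_standardization: Standardization
    left: "SplitNode | LeafNode"   # negative side, z < 0
    right: "SplitNode | LeafNode"  # positive side, z >= 0
    n_examples: int

    def to_dict(self) -> dict:
        return {
            "kind": "split", "w": self.w.tolist(), "b": self.b,
            "standardization": self.feat_standardization.to_dict(),
            "n_examples": self.n_examples,
            "left": self.left.to_dict(), "right": self.right.to_dict(),
        }


def _node_from_dict(d: dict):
    if d["kind"] == "leaf":
        return LeafNode(np.array(d["prototype"], dtype=float), d["n_labeled"])
    return SplitNode(
        np.array(d["w"], dtype=float), float(d["b"]),
        Standardization.from_dict(d["standardization"]),
        _node_from_dict(d["left"]), _node_from_dict(d["right"]),
        d["n_examples"],
    )


class Tree:
    """A fitted semi-supervised oblique predictive clustering tree."""

    def __init__(self, root, task: Task, config: SplitConfig,
                 label_order: Sequence[str], n_features: int,
                 hierarchy: HierarchySpec | None = None) -> None:
        self.root = root
        self.task = Task(task)
        self.config = config
        self.label_order = list(label_order)
        self.n_features = n_features
        self.hierarchy = hierarchy

    # -- prediction ---------------------------------------------------------

    def predict_scores(self, X_new) -> np.ndarray:
        return predict_tree(self, X_new)

    def predict(self, X_new, threshold: float = 0.5):
        scores = predict_tree(self, X_new)
        return decode_class(scores, self.task, self.label_order, threshold)

    # -- introspection ------------------------------------------------------

    def depth(self) -> int:
        def rec(node):
            if isinstance(node, LeafNode):
                return 0
            return 1 + max(rec(node.left), rec(node.right))

        return rec(self.root)

    def n_splits(self) -> int:
        def rec(node):
            if isinstance(node, LeafNode):
                return 0
            return 1 + rec(node.left) + rec(node.right)

        return rec(self.root)

    def iter_splits(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            if isinstance(node, SplitNode):
                yield node
                stack.append(node.left)
                stack.append(node.right)

    # -- persistence --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "model": "tree",
            "task": self.task.value,
            "label_order": self.label_order,
            "n_features": self.n_features,
            "config": self.config.to_dict(),
            "hierarchy": None if self.hierarchy is None else self.hierarchy.to_dict(),
            "root": self.root.to_dict(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "Tree":
        hier = d.get("hierarchy")
        return cls(
            _node_from_dict(d["root"]), Task(d["task"]),
            SplitConfig.from_dict(d["config"]), d["label_order"],
            d["n_features"],
            None if hier is None else HierarchySpec.from_dict(hier),
        )

    @classmethod
    def from_json(cls, s: str) -> "Tree":
        return cls.from_dict(json.loads(s))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "Tree":
        with open(path) as fh:
            return cls.from_json(fh.read())


def leaf_prototype(Y_leaf: np.ndarray) -> np.ndarray:
    """Column means of the raw (unstandardized) labeled targets in a leaf."""
    Y_leaf = np.asarray(Y_leaf, dtype=float)
    if Y_leaf.ndim == 1:
        Y_leaf = Y_leaf[:, None]
    assert Y_leaf.shape[0] >= 1, "a leaf must contain a labeled example"
    return Y_leaf.mean(axis=0)


def _hard_impurity(Xs, Ys, rows, p: ClusteringWeights) -> float:
    """Total p-weighted impurity of a row subset with all-ones weights."""
    weights = np.zeros(Xs.shape[0])
    weights[rows] = 1.0
    # group_impurity masks targets to the first L entries by construction
    return group_impurity(Xs, Ys, weights, p)


def grow_tree(data: SemiDataset, config: SplitConfig,
              rng: np.random.Generator | None = None,
              label_order: Sequence[str] | None = None) -> Tree:
    """Grow one tree on a labeled+unlabeled dataset.

    With ``omega = 1`` the unlabeled rows are discarded up front: feature
    impurity carries no weight, so they cannot affect split selection, and
    dropping them makes the fit identical to a purely supervised one.
    """
    if config.omega == "auto":
        raise ValueError("omega must be resolved to a number before growth "
                         "(see evaluation.select_omega_cv)")
    omega = float(config.omega)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if omega == 1.0 and data.U > 0:
        data = data.labeled_only()
    if label_order is None:
        label_order = (data.hierarchy.labels if data.hierarchy is not None
                       else [f"target_{j}" for j in range(data.T)])
    X, Y, L = data.X, data.Y, data.L
    p_raw = default_raw_weights(data.D, data.T, data.hierarchy)
    min_lab = max(config.min_leaf_labeled, 1)

    def build(rows: np.ndarray, depth: int):
        lab_rows = rows[rows < L]
        n_lab = lab_rows.size

        def leaf():
            return LeafNode(leaf_prototype(Y[lab_rows]), int(n_lab))

        if n_lab < 2 * min_lab or rows.size < 2:
            return leaf()
        if config.max_depth is not None and depth >= config.max_depth:
            return leaf()
        # rows stays sorted ascending, so with labeled-first dataset ordering
        # the node's labeled rows occupy positions 0..n_lab-1 of Xn
        Xn = X[rows]
        Yn = Y[lab_rows]
        Xs, st = standardize(Xn)
        Ys, _ = standardize(Yn)
        p = scale_clustering_weights(p_raw, omega, data.D)
        if config.variant == "svm":
            res = learn_split_svm(Xs, Ys, p, config, rng)
        else:
            res = learn_split_grad(Xs, Ys, p, config, rng)
        if res is None:
            return leaf()
        w, b = res
        z = np.asarray(Xs @ w).ravel() + b
        pos = z >= 0
        lab_pos = pos[:n_lab]
        if lab_pos.sum() < min_lab or (~lab_pos).sum() < min_lab:
            return leaf()
        all_rows = np.arange(rows.size)
        parent_imp = _hard_impurity(Xs, Ys, all_rows, p)
        imp_left = _hard_impurity(Xs, Ys, all_rows[~pos], p)
        imp_right = _hard_impurity(Xs, Ys, all_rows[pos], p)
        n_l, n_r = int((~pos).sum()), int(pos.sum())
        # law of total variance: the split must remove >= imp_reduction of
        # the node's impurity (size-weighted mean of child impurities)
        child_imp = (n_l * imp_left + n_r * imp_right) / rows.size
        if child_imp > (1.0 - config.imp_reduction) * parent_imp:
            return leaf()
        left = build(rows[~pos], depth + 1)
        right = build(rows[pos], depth + 1)
        return SplitNode(w, float(b), st, left, right, int(rows.size))

    root = build(np.arange(X.shape[0]), 0)
    return Tree(root, data.task, config, label_order, data.D, data.hierarchy)


def predict_tree(tree: Tree, X_new) -> np.ndarray:
    """Route rows through the tree and return their leaf prototypes."""
    if sp.issparse(X_new):
        X_new = sp.csr_matrix(X_new, dtype=float)
    else:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != tree.n_features:
        raise ValueError(
            f"expected {tree.n_features} feature columns, got {X_new.shape[1]}"
        )
    n = X_new.shape[0]
    T = len(tree.label_order)
    out = np.empty((n, T))

    def rec(node, rows: np.ndarray) -> None:
        if rows.size == 0:
            return
        if isinstance(node, LeafNode):
            out[rows] = node.prototype
            return
        Xs = apply_standardization(X_new[rows], node.feat_standardization)
        z = np.asarray(Xs @ node.w).ravel() + node.b
        pos = z >= 0
        rec(node.left, rows[~pos])
        rec(node.right, rows[pos])

    rec(tree.root, np.arange(n))
    return out
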