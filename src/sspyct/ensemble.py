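"""Bagging ensembles of oblique predictive clustering trees.

Each tree is grown on a stratified bootstrap: L draws with replacement from
the labeled rows and U draws from the unlabeled rows, so every bootstrap
keeps at least one labeled example and the labeled/unlabeled proportions of
the training set.  Predictions are score averages over the member trees;
feature importances are averages of per-tree hyperplane-weight importances.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .core import SemiDataset, SplitConfig, decode_class
from .tree import LeafNode, Tree, grow_tree, predict_tree

__all__ = ["Ensemble", "fit_bagging", "predict_ensemble", "feature_importance"]


class Ensemble:
    """A bag of trees sharing task, feature count and label order."""

    def __init__(self, trees: Sequence[Tree]) -> None:
        if not trees:
            raise ValueError("an ensemble needs at least one tree")
        first = trees[0]
        for t in trees:
            if (t.task, t.n_features, tuple(t.label_order)) != (
                first.task, first.n_features, tuple(first.label_order)
            ):
                raise ValueError("ensemble members disagree on task shape")
        self.trees = list(trees)
        self.task = first.task
        self.label_order = first.label_order
        self.n_features = first.n_features

    def predict_scores(self, X_new) -> np.ndarray:
        return predict_ensemble(self, X_new)[0]

    def predict(self, X_new, threshold: float = 0.5):
        return predict_ensemble(self, X_new, threshold)[1]

    def to_dict(self) -> dict:
        return {"model": "ensemble", "trees": [t.to_dict() for t in self.trees]}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "Ensemble":
        return cls([Tree.from_dict(td) for td in d["trees"]])

    @classmethod
    def from_json(cls, s: str) -> "Ensemble":
        return cls.from_dict(json.loads(s))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "Ensemble":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _bootstrap(data: SemiDataset, rng: np.random.Generator) -> SemiDataset:
    lab = rng.integers(0, data.L, size=data.L)
    if data.U > 0:
        unlab = data.L + rng.integers(0, data.U, size=data.U)
        idx = np.concatenate([lab, unlab])
    else:
        idx = lab
    X = data.X[idx]
    return SemiDataset(X, data.Y[lab], data.task, data.hierarchy)


def fit_bagging(data: SemiDataset, config: SplitConfig, n_trees: int = 50,
                rng: np.random.Generator | None = None,
                bootstrap: bool = True) -> Ensemble:
    """Fit a bagging ensemble of ``n_trees`` trees.

    Per-tree randomness is drawn from independent spawned streams; within a
    tree, the bootstrap and the growth use separate streams, so the labeled
    part of a bootstrap does not depend on how many unlabeled rows exist.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    label_order = (data.hierarchy.labels if data.hierarchy is not None
                   else [f"target_{j}" for j in range(data.T)])
    trees = []
    for tree_rng in rng.spawn(n_trees):
        boot_rng, grow_rng = tree_rng.spawn(2)
        sample = _bootstrap(data, boot_rng) if bootstrap else data
        trees.append(grow_tree(sample, config, grow_rng, label_order))
    return Ensemble(trees)


def predict_ensemble(ens: Ensemble, X_new, threshold: float = 0.5):
    """Mean of member score matrices, plus the task-decoded predictions."""
    scores = np.mean([predict_tree(t, X_new) for t in ens.trees], axis=0)
    return scores, decode_class(scores, ens.task, ens.label_order, threshold)


def feature_importance(model: Tree | Ensemble) -> np.ndarray:
    """Hyperplane-weight importances.

    For one tree: sum over split nodes of (s_n / N) * |s_w| / ||s_w||_1,
    where s_n is the number of training examples reaching the node and N the
    number reaching the root.  Ensembles average the per-tree vectors.
    A leaf-only tree scores all zeros.
    """
    if isinstance(model, Ensemble):
        return np.mean([feature_importance(t) for t in model.trees], axis=0)
    imp = np.zeros(model.n_features)
    if isinstance(model.root, LeafNode):
        return imp
    N = model.root.n_examples
    for node in model.iter_splits():
        aw = np.abs(node.w)
        norm = aw.sum()
        if norm > 0:
            imp += (node.n_examples / N) * (aw / norm)
    return imp
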