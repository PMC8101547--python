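"""Evaluation metrics, internal omega selection, and the label-masking protocol.

Metrics follow the structured-output conventions: coefficient of
determination R^2 (averaged over targets for multi-target regression), F1
(macro-averaged for multi-class), and weighted label ranking average
precision (LRAP) for (hierarchical) multi-label tasks, where hierarchy labels
are weighted 0.75^depth.  The supervision degree omega is selected from
{0, 0.25, 0.5, 0.75, 1} by 3-fold cross-validation over the labeled examples
only; unlabeled examples join every internal training fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.metrics import f1_score

from .core import SemiDataset, SplitConfig, Task, decode_class

__all__ = [
    "MetricResult",
    "r2",
    "mean_r2",
    "macro_f1",
    "lrap_weighted",
    "score_task",
    "select_omega_cv",
    "mask_labels_protocol",
    "OMEGA_GRID",
]

OMEGA_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass
class MetricResult:
    name: str
    value: float
    per_target: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "metric": self.name,
            "value": self.value,
            "per_target": None if self.per_target is None
            else list(map(float, self.per_target)),
        }


def r2(y, yhat) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size < 2:
        raise ValueError("R^2 needs at least two observations")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("R^2 undefined for a constant target")
    return 1.0 - float(((y - yhat) ** 2).sum()) / ss_tot


def mean_r2(Y, Yhat) -> MetricResult:
    """Unweighted mean of per-target R^2 scores."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    Yhat = np.atleast_2d(np.asarray(Yhat, dtype=float))
    per = np.array([r2(Y[:, j], Yhat[:, j]) for j in range(Y.shape[1])])
    return MetricResult("mean_r2", float(per.mean()), per)


def macro_f1(y_true, y_pred, average: str = "macro") -> float:
    """F1 score; ``average='binary'`` gives the positive-class F1.

    A class with neither predictions nor positives contributes 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    return float(f1_score(y_true, y_pred, average=average, zero_division=0))


def lrap_weighted(Y, S, label_weights=None) -> float:
    """Weighted label ranking average precision.

    For every example i and every true label j,
    ``L_ij / R_ij`` is the precision of the score ranking at label j's rank
    (ties count on both sides, comparisons use >=); the terms are combined
    with label weights w_j normalized per example by the total weight W_i of
    its true labels.  Rows without any positive label are skipped with a
    warning.
    """
    Y = np.asarray(Y, dtype=float)
    S = np.asarray(S, dtype=float)
    if Y.shape != S.shape:
        raise ValueError("score matrix shape mismatch")
    n, T = Y.shape
    if label_weights is None:
        label_weights = np.ones(T)
    w = np.asarray(label_weights, dtype=float)
    if (w < 0).any():
        raise ValueError("label weights must be nonnegative")
    total = 0.0
    used = 0
    for i in range(n):
        pos = Y[i] > 0
        if not pos.any():
            warnings.warn(f"row {i} has no positive labels; skipped")
            continue
        W_i = w[pos].sum()
        acc = 0.0
        for j in np.flatnonzero(pos):
            higher = S[i] >= S[i, j]
            R_ij = int(higher.sum())
            L_ij = int((higher & pos).sum())
            acc += (w[j] / W_i) * (L_ij / R_ij)
        total += acc
        used += 1
    if used == 0:
        raise ValueError("no rows with positive labels")
    return total / used


def score_task(task: Task, Y_true: np.ndarray, scores: np.ndarray,
               label_order, hierarchy=None) -> float:
    """The task's headline metric from raw prototype scores.

    STR/MTR: mean R^2; BC: positive-class F1; MCC: macro F1;
    MLC: uniform-weight LRAP; HMLC: LRAP with 0.75^depth label weights.
    """
    task = Task(task)
    if task in (Task.STR, Task.MTR):
        return mean_r2(Y_true, scores).value
    if task is Task.BC:
        pred = decode_class(scores, task, label_order)
        return macro_f1(Y_true.ravel().astype(int), pred, average="binary")
    if task is Task.MCC:
        true_cls = np.argmax(Y_true, axis=1)
        pred_cls = np.argmax(scores, axis=1)
        return macro_f1(true_cls, pred_cls, average="macro")
    weights = hierarchy.weight_vector() if hierarchy is not None else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return lrap_weighted(Y_true, scores, weights)


def select_omega_cv(data: SemiDataset, config: SplitConfig,
                    grid=OMEGA_GRID, folds: int = 3,
                    rng: np.random.Generator | None = None,
                    n_trees: int = 1) -> float:
    """Pick omega from ``grid`` by cross-validation over the labeled rows.

    The labeled rows are partitioned into ``folds`` folds; every unlabeled
    row joins each training fold.  Each candidate omega is scored with the
    task metric averaged over folds (folds where the metric is undefined,
    e.g. a constant regression target, are dropped for all candidates alike);
    ties prefer the largest omega.  With a single-value grid CV is skipped.
    """
    grid = sorted(float(g) for g in grid)
    if len(grid) == 1:
        return grid[0]
    if data.L < folds:
        raise ValueError(
            f"only {data.L} labeled examples; use at most {data.L} folds"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    from .ensemble import fit_bagging  # local import to avoid a cycle
    from .tree import grow_tree, predict_tree

    perm = rng.permutation(data.L)
    fold_ids = np.arange(data.L) % folds
    fold_of = np.empty(data.L, dtype=int)
    fold_of[perm] = fold_ids
    fold_seeds = [int(rng.integers(0, 2 ** 31 - 1)) for _ in range(folds)]
    X_lab = data.X[: data.L]
    X_unlab = data.X[data.L:]
    scores = {om: [] for om in grid}
    for f in range(folds):
        val = fold_of == f
        tr = ~val
        if sp.issparse(data.X):
            X_tr = sp.vstack([X_lab[tr], X_unlab], format="csr")
        else:
            X_tr = np.vstack([X_lab[tr], X_unlab])
        ds = SemiDataset(X_tr, data.Y[tr], data.task, data.hierarchy)
        for om in grid:
            cfg_dict = config.to_dict()
            cfg_dict["omega"] = om
            cfg = SplitConfig.from_dict(cfg_dict)
            frng = np.random.default_rng(fold_seeds[f])
            if n_trees == 1:
                model = grow_tree(ds, cfg, frng)
                pred = predict_tree(model, X_lab[val])
            else:
                model = fit_bagging(ds, cfg, n_trees=n_trees, rng=frng)
                pred = model.predict_scores(X_lab[val])
            try:
                sc = score_task(data.task, data.Y[val], pred,
                                model.label_order, data.hierarchy)
            except ValueError:
                sc = None
            scores[om].append(sc)
    best_om, best_sc = grid[0], -np.inf
    for om in grid:  # ascending: >= keeps the largest omega on ties
        vals = [s for s in scores[om] if s is not None]
        mean = float(np.mean(vals)) if vals else -np.inf
        if mean >= best_sc:
            best_om, best_sc = om, mean
    return best_om


def mask_labels_protocol(X_full, Y_full, L: int, folds: int = 10,
                         rng: np.random.Generator | None = None,
                         task: Task = Task.STR, hierarchy=None):
    """Inductive cross-validation with label masking.

    The examples are split into ``folds`` test folds.  For each fold, the
    remaining rows form the training set, of which ``L`` random rows keep
    their labels and the rest become unlabeled.  Returns a list of
    ``(train SemiDataset, X_test, Y_test)`` tuples; each example is tested
    exactly once.
    """
    n = X_full.shape[0]
    Y_full = np.atleast_2d(np.asarray(Y_full, dtype=float))
    if Y_full.shape[0] != n:
        raise ValueError("X and Y row counts differ")
    if rng is None:
        rng = np.random.default_rng(0)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[perm] = np.arange(n) % folds
    out = []
    for f in range(folds):
        test = np.flatnonzero(fold_of == f)
        train = np.flatnonzero(fold_of != f)
        if L > train.size:
            raise ValueError(f"L={L} exceeds {train.size} training rows")
        lab = rng.choice(train, size=L, replace=False)
        lab_set = np.zeros(n, dtype=bool)
        lab_set[lab] = True
        lab_idx = train[lab_set[train]]
        unlab_idx = train[~lab_set[train]]
        order = np.concatenate([lab_idx, unlab_idx])
        if sp.issparse(X_full):
            X_tr = sp.csr_matrix(X_full)[order]
        else:
            X_tr = np.asarray(X_full)[order]
        ds = SemiDataset(X_tr, Y_full[lab_idx], task, hierarchy,
                         orig_index=order)
        out.append((ds, X_full[test], Y_full[test]))
    return out
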