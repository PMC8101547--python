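"""Shared domain types for semi-supervised oblique predictive clustering trees.

A predictive clustering tree minimizes impurity over *clustering attributes*;
here those are the features and the targets jointly, which is what lets
unlabeled examples (rows with features but no targets) inform split selection.
This module holds the dataset container, target encodings, per-split
standardization, the clustering-weight vector with its supervision degree
``omega``, and hierarchy-derived label weights for hierarchical multi-label
classification (HMLC).
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Task",
    "SemiDataset",
    "HierarchySpec",
    "ClusteringWeights",
    "SplitConfig",
    "Standardization",
    "encode_targets",
    "standardize",
    "apply_standardization",
    "destandardize",
    "scale_clustering_weights",
    "hierarchy_weights",
]


class Task(str, Enum):
    """Structured output prediction task kinds."""

    STR = "STR"  # single-target regression
    MTR = "MTR"  # multi-target regression
    BC = "BC"  # binary classification
    MCC = "MCC"  # multi-class classification
    MLC = "MLC"  # multi-label classification
    HMLC = "HMLC"  # hierarchical multi-label classification

    @property
    def is_classification(self) -> bool:
        return self in (Task.BC, Task.MCC, Task.MLC, Task.HMLC)


# ---------------------------------------------------------------------------
# Hierarchy
# ---------------------------------------------------------------------------


class HierarchySpec:
    """A rooted label DAG with per-label depths and weights.

    Top-level labels (those without parents) have depth 1; every other label's
    depth is the mean of its parents' depths plus one.  Label weights are
    ``w0 ** depth`` with ``w0 = 0.75`` by default, so deeper labels weigh less
    both in the clustering objective and in the ranking metric.
    """

    def __init__(
        self,
        labels: Sequence[str],
        edges: Sequence[tuple[str, str]] = (),
        w0: float = 0.75,
    ) -> None:
        self.labels = list(labels)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate label names in hierarchy")
        known = set(self.labels)
        seen: set[tuple[str, str]] = set()
        self.edges: list[tuple[str, str]] = []
        for parent, child in edges:
            if parent not in known or child not in known:
                missing = parent if parent not in known else child
                raise ValueError(f"edge references unknown label {missing!r}")
            if (parent, child) not in seen:  # collapse duplicates
                seen.add((parent, child))
                self.edges.append((parent, child))
        self.w0 = float(w0)
        self._parents: dict[str, list[str]] = {lab: [] for lab in self.labels}
        self._children: dict[str, list[str]] = {lab: [] for lab in self.labels}
        for parent, child in self.edges:
            self._parents[child].append(parent)
            self._children[parent].append(child)
        self.depth = self._compute_depths()
        self.label_weight = {lab: self.w0 ** d for lab, d in self.depth.items()}

    def _compute_depths(self) -> dict[str, float]:
        ts = graphlib.TopologicalSorter(
            {lab: self._parents[lab] for lab in self.labels}
        )
        try:
            order = list(ts.static_order())
        except graphlib.CycleError as err:
            raise ValueError(f"hierarchy contains a cycle: {err.args[1]}") from err
        depth: dict[str, float] = {}
        for lab in order:
            parents = self._parents[lab]
            if not parents:
                depth[lab] = 1.0
            else:
                depth[lab] = float(np.mean([depth[p] for p in parents])) + 1.0
        return depth

    def parents(self, label: str) -> list[str]:
        return list(self._parents[label])

    def ancestors(self, label: str) -> set[str]:
        out: set[str] = set()
        stack = list(self._parents[label])
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(self._parents[p])
        return out

    def weight_vector(self) -> np.ndarray:
        return np.array([self.label_weight[lab] for lab in self.labels])

    def depth_vector(self) -> np.ndarray:
        return np.array([self.depth[lab] for lab in self.labels])

    def check_consistent(self, Y: np.ndarray) -> None:
        """Raise if any row has a label whose parent is absent."""
        idx = {lab: j for j, lab in enumerate(self.labels)}
        for parent, child in self.edges:
            bad = (Y[:, idx[child]] > 0) & (Y[:, idx[parent]] == 0)
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"row {row}: label {child!r} present without parent {parent!r}"
                )

    def to_dict(self) -> dict:
        return {"labels": self.labels, "edges": [list(e) for e in self.edges],
                "w0": self.w0}

    @classmethod
    def from_dict(cls, d: Mapping) -> "HierarchySpec":
        return cls(d["labels"], [tuple(e) for e in d["edges"]], d.get("w0", 0.75))


def hierarchy_weights(hier: HierarchySpec, w0: float = 0.75) -> np.ndarray:
    """Per-label weights ``w0 ** depth`` in the hierarchy's label order."""
    depths = hier.depth_vector()
    return w0 ** depths


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------


@dataclass
class SemiDataset:
    """Features of L labeled + U unlabeled examples, targets of the labeled.

    Rows ``0..L-1`` of ``X`` correspond one-to-one to the rows of ``Y``
    (labeled-first ordering).  ``orig_index`` optionally records the
    permutation back to an external row ordering.
    """

    X: np.ndarray | sp.spmatrix
    Y: np.ndarray
    task: Task
    hierarchy: HierarchySpec | None = None
    orig_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim == 1:
            self.Y = self.Y[:, None]
        if not sp.issparse(self.X):
            self.X = np.asarray(self.X, dtype=float)
        else:
            self.X = sp.csr_matrix(self.X, dtype=float)
        if self.X.ndim != 2 or self.Y.ndim != 2:
            raise ValueError("X and Y must be 2-D")
        if self.L < 1:
            raise ValueError("at least one labeled example is required")
        if self.Y.shape[0] > self.X.shape[0]:
            raise ValueError("more target rows than feature rows")
        self._validate_targets()
        if self.task is Task.HMLC:
            if self.hierarchy is None:
                raise ValueError("HMLC task requires a hierarchy")
            if len(self.hierarchy.labels) != self.T:
                raise ValueError("hierarchy label count does not match T")
            self.hierarchy.check_consistent(self.Y)

    def _validate_targets(self) -> None:
        if self.task is Task.BC:
            if self.T != 1 or not np.isin(self.Y, (0.0, 1.0)).all():
                raise ValueError("BC targets must be a single {0,1} column")
        elif self.task is Task.MCC:
            ok = np.isin(self.Y, (0.0, 1.0)).all() and np.allclose(
                self.Y.sum(axis=1), 1.0
            )
            if not ok:
                raise ValueError("MCC targets must be one-hot rows")
        elif self.task in (Task.MLC, Task.HMLC):
            if not np.isin(self.Y, (0.0, 1.0)).all():
                raise ValueError("MLC/HMLC targets must be binary")

    @property
    def L(self) -> int:
        return self.Y.shape[0]

    @property
    def U(self) -> int:
        return self.X.shape[0] - self.Y.shape[0]

    @property
    def D(self) -> int:
        return self.X.shape[1]

    @property
    def T(self) -> int:
        return self.Y.shape[1]

    @property
    def is_sparse(self) -> bool:
        return sp.issparse(self.X)

    def labeled_only(self) -> "SemiDataset":
        """The same dataset with the unlabeled rows dropped."""
        return SemiDataset(
            self.X[: self.L], self.Y, self.task, self.hierarchy,
            None if self.orig_index is None else self.orig_index[: self.L],
        )


# ---------------------------------------------------------------------------
# Target encoding
# ---------------------------------------------------------------------------


def encode_targets(
    raw_targets,
    task: Task,
    hierarchy: HierarchySpec | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Encode raw targets into the real matrix used for tree learning.

    Returns ``(Y, label_order)`` where label order is deterministic: sorted
    class/label names, or the hierarchy's label order for HMLC.

    - STR/MTR: values pass through unchanged (one column per target).
    - BC: two classes mapped to a single {0,1} column (sorted; larger is 1).
    - MCC: one-hot over the sorted observed classes.
    - MLC: binary indicators over the sorted union of observed labels.
    - HMLC: binary indicators over the hierarchy's labels; every row must be
      hierarchy-consistent (a label implies all its ancestors).
    """
    task = Task(task)
    if task in (Task.STR, Task.MTR):
        Y = np.asarray(raw_targets, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        names = [f"target_{j}" for j in range(Y.shape[1])]
        return Y, names
    if task is Task.BC:
        raw = np.asarray(raw_targets).ravel()
        classes = sorted({str(v) for v in raw})
        if len(classes) > 2:
            raise ValueError(f"binary task with {len(classes)} classes")
        pos = classes[-1]
        return (np.array([str(v) == pos for v in raw], dtype=float)[:, None],
                [pos])
    if task is Task.MCC:
        raw = np.asarray(raw_targets).ravel()
        classes = sorted({str(v) for v in raw})
        col = {c: j for j, c in enumerate(classes)}
        Y = np.zeros((raw.shape[0], len(classes)))
        for i, v in enumerate(raw):
            Y[i, col[str(v)]] = 1.0
        return Y, classes
    # MLC / HMLC: raw is a sequence of label collections
    rows = [set(map(str, labs)) for labs in raw_targets]
    if task is Task.HMLC:
        if hierarchy is None:
            raise ValueError("HMLC encoding requires a hierarchy")
        labels = hierarchy.labels
        known = set(labels)
        for i, labs in enumerate(rows):
            unknown = labs - known
            if unknown:
                raise ValueError(f"row {i}: unknown label {sorted(unknown)[0]!r}")
            for lab in labs:
                missing = hierarchy.ancestors(lab) - labs
                if missing:
                    raise ValueError(
                        f"row {i}: label {lab!r} present without its "
                        f"ancestor {sorted(missing)[0]!r}"
                    )
    else:
        labels = sorted(set().union(*rows)) if rows else []
    col = {lab: j for j, lab in enumerate(labels)}
    Y = np.zeros((len(rows), len(labels)))
    for i, labs in enumerate(rows):
        for lab in labs:
            Y[i, col[lab]] = 1.0
    return Y, list(labels)


def decode_class(scores: np.ndarray, task: Task, label_order: Sequence[str],
                 threshold: float = 0.5):
    """Turn raw prototype scores into task-level predictions.

    BC thresholds at 0.5; MCC takes the argmax (ties go to the lowest column
    index); MLC/HMLC threshold each label score.  Regression is the identity.
    """
    task = Task(task)
    if task in (Task.STR, Task.MTR):
        return scores
    if task is Task.BC:
        return (scores[:, 0] >= threshold).astype(int)
    if task is Task.MCC:
        idx = np.argmax(scores, axis=1)  # np.argmax breaks ties low
        return np.array([label_order[i] for i in idx])
    return (scores >= threshold).astype(int)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


@dataclass
class Standardization:
    """Column means and standard deviations fitted on a row subset.

    Population standard deviation is used; zero-variance columns record
    ``sigma = 1`` so the transform is always well defined.  For sparse inputs
    only scaling is applied (``mu`` is stored as zeros) to preserve sparsity.
    """

    mu: np.ndarray
    sigma: np.ndarray

    def to_dict(self) -> dict:
        return {"mu": self.mu.tolist(), "sigma": self.sigma.tolist()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Standardization":
        return cls(np.array(d["mu"], dtype=float), np.array(d["sigma"], dtype=float))


def standardize(M, fit_rows=None):
    """Standardize columns of ``M`` to mean 0 / sd 1 fitted on ``fit_rows``.

    Returns ``(Ms, Standardization)``.  ``fit_rows`` defaults to all rows.
    Dense matrices are centered and scaled; sparse matrices are scaled only.
    """
    if fit_rows is None:
        fit = M
    else:
        fit_rows = np.asarray(fit_rows)
        if fit_rows.size == 0:
            raise ValueError("fit_rows must be non-empty")
        fit = M[fit_rows]
    if sp.issparse(M):
        fit = sp.csr_matrix(fit)
        n = fit.shape[0]
        mean = np.asarray(fit.mean(axis=0)).ravel()
        mean_sq = np.asarray(fit.multiply(fit).mean(axis=0)).ravel()
        var = np.maximum(mean_sq - mean ** 2, 0.0)
        sigma = np.sqrt(var)
        sigma[sigma == 0] = 1.0
        st = Standardization(np.zeros(M.shape[1]), sigma)
        return apply_standardization(M, st), st
    fit = np.asarray(fit, dtype=float)
    mu = fit.mean(axis=0)
    sigma = fit.std(axis=0)  # population convention
    sigma = np.where(sigma == 0, 1.0, sigma)
    st = Standardization(mu, sigma)
    return apply_standardization(M, st), st


def apply_standardization(M, st: Standardization):
    if sp.issparse(M):
        return sp.csr_matrix(M.multiply(1.0 / st.sigma))
    return (np.asarray(M, dtype=float) - st.mu) / st.sigma


def destandardize(Ms, st: Standardization):
    if sp.issparse(Ms):
        return sp.csr_matrix(Ms.multiply(st.sigma))
    return np.asarray(Ms) * st.sigma + st.mu


# ---------------------------------------------------------------------------
# Clustering weights
# ---------------------------------------------------------------------------


@dataclass
class ClusteringWeights:
    """Nonnegative per-attribute priorities over D features + T targets.

    After scaling, the feature block sums to ``1 - omega`` and the target
    block to ``omega``; ``omega = 0`` grows the tree unsupervised, ``omega = 1``
    fully supervised.
    """

    p: np.ndarray
    omega: float
    D: int

    @property
    def p_feat(self) -> np.ndarray:
        return self.p[: self.D]

    @property
    def p_targ(self) -> np.ndarray:
        return self.p[self.D:]


def scale_clustering_weights(p_raw, omega: float, D: int) -> ClusteringWeights:
    """Scale raw priorities so features sum to ``1-omega``, targets to ``omega``."""
    p_raw = np.asarray(p_raw, dtype=float)
    if (p_raw < 0).any():
        raise ValueError("clustering weights must be nonnegative")
    if not 0.0 <= omega <= 1.0:
        raise ValueError("omega must lie in [0, 1]")
    feat, targ = p_raw[:D], p_raw[D:]
    p = np.empty_like(p_raw)
    for block, mass, sl in ((feat, 1.0 - omega, slice(0, D)),
                            (targ, omega, slice(D, None))):
        s = block.sum()
        if mass == 0.0:
            p[sl] = 0.0
        elif s == 0.0:
            raise ValueError("cannot place nonzero mass on an all-zero block")
        else:
            p[sl] = block * (mass / s)
    return ClusteringWeights(p, float(omega), D)


def default_raw_weights(D: int, T: int,
                        hierarchy: HierarchySpec | None) -> np.ndarray:
    """Uniform feature priorities; target priorities uniform, or the 0.75^d
    hierarchy weights for HMLC."""
    p = np.ones(D + T)
    if hierarchy is not None:
        p[D:] = hierarchy.weight_vector()
    return p


# ---------------------------------------------------------------------------
# Split configuration
# ---------------------------------------------------------------------------


@dataclass
class SplitConfig:
    """Hyperparameters shared by tree growth and both split variants.

    Defaults follow common practice for these trees: regularization ``C=10``,
    at most 100 hyperplane-optimization iterations, at most 10 clustering
    iterations for the SVM variant, Adam constants (0.9, 0.999, 1e-8), leaves
    requiring one labeled example, unlimited depth, and a split accepted only
    if it lowers impurity by at least 5% in at least one child.
    """

    variant: str = "grad"  # "svm" | "grad"
    omega: float | str = 0.5  # numeric, or "auto" for internal-CV selection
    C: float = 10.0
    opt_iters: int = 100
    clust_iters: int = 10
    adam_lr: float = 0.1
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    min_leaf_labeled: int = 1
    max_depth: int | None = None
    imp_reduction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("svm", "grad"):
            raise ValueError(f"unknown split variant {self.variant!r}")
        if self.omega != "auto" and not 0.0 <= float(self.omega) <= 1.0:
            raise ValueError("omega must be in [0, 1] or 'auto'")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if not 0.0 <= self.imp_reduction < 1.0:
            raise ValueError("imp_reduction must be in [0, 1)")

    def to_dict(self) -> dict:
        return {
            "variant": self.variant, "omega": self.omega, "C": self.C,
            "opt_iters": self.opt_iters, "clust_iters": self.clust_iters,
            "adam_lr": self.adam_lr, "adam_beta1": self.adam_beta1,
            "adam_beta2": self.adam_beta2, "adam_eps": self.adam_eps,
            "min_leaf_labeled": self.min_leaf_labeled,
            "max_depth": self.max_depth, "imp_reduction": self.imp_reduction,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SplitConfig":
        return cls(**dict(d))
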