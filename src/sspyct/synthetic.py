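"""Seeded generators for cluster-structured semi-supervised datasets.

The semi-supervised method rests on the cluster assumption: examples that
fall in the same feature-space cluster share target values, so unlabeled
examples can sharpen split placement.  The generator draws Gaussian clusters
whose centers sit on a regular simplex with a controllable pairwise
separation (in units of the unit within-cluster standard deviation) and ties
the targets deterministically to the cluster identity; label masking and the
noise-feature-doubling protocol used for importance studies are provided
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .core import HierarchySpec, SemiDataset, Task

__all__ = ["GenSpec", "gen_clustered", "add_noise_features", "mask_labels",
           "gen_hierarchy"]


@dataclass
class GenSpec:
    """Conditions for one synthetic dataset.

    ``separation`` is the pairwise distance between cluster centers in units
    of the within-cluster standard deviation (identity covariance).
    ``noise_frac`` reserves that fraction of the D feature columns as pure
    noise carrying no cluster signal; ``sparsity`` zeroes that fraction of
    feature entries and returns a CSR matrix.
    """

    task: Task = Task.BC
    n: int = 500
    D: int = 10
    T: int = 1
    n_clusters: int = 2
    separation: float = 4.0
    noise_frac: float = 0.0
    sparsity: float = 0.0
    hierarchy_depth: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        if min(self.n, self.D, self.T, self.n_clusters) < 1:
            raise ValueError("all counts must be positive")
        if self.n_clusters > self.n:
            raise ValueError("more clusters than examples")
        if self.separation < 0:
            raise ValueError("separation must be nonnegative")
        if not 0 <= self.noise_frac <= 1 or not 0 <= self.sparsity < 1:
            raise ValueError("noise_frac in [0,1], sparsity in [0,1)")


def _simplex_centers(k: int, dim: int, separation: float) -> np.ndarray:
    """k centers with all pairwise distances exactly ``separation``."""
    if dim < k:
        raise ValueError(f"need at least {k} informative dimensions for "
                         f"{k} clusters (got {dim})")
    E = np.zeros((k, dim))
    E[np.arange(k), np.arange(k)] = 1.0  # pairwise distance sqrt(2)
    E -= E.mean(axis=0)
    return E * (separation / np.sqrt(2.0))


def _cluster_targets(task: Task, ids: np.ndarray, X: np.ndarray,
                     centers: np.ndarray, spec: GenSpec,
                     rng: np.random.Generator):
    k = spec.n_clusters
    if task is Task.BC:
        Y = (ids % 2).astype(float)[:, None]
        return Y, None
    if task is Task.MCC:
        T = max(spec.T, k)
        Y = np.zeros((spec.n, T))
        Y[np.arange(spec.n), ids % T] = 1.0
        return Y, None
    if task in (Task.STR, Task.MTR):
        T = 1 if task is Task.STR else spec.T
        offs = rng.normal(0.0, max(spec.separation, 1.0), size=(k, T))
        slopes = rng.normal(0.0, 1.0, size=(spec.D, T)) / np.sqrt(spec.D)
        Y = offs[ids] + (X - centers[ids]) @ slopes
        Y += 0.1 * rng.normal(size=Y.shape)
        return Y, None
    # MLC / HMLC: deterministic per-cluster label subsets
    if task is Task.MLC:
        T = spec.T
        n_active = max(1, int(np.ceil(T / 2)))
        Y = np.zeros((spec.n, T))
        subsets = [rng.choice(T, size=n_active, replace=False)
                   for _ in range(k)]
        for c in range(k):
            Y[np.ix_(ids == c, subsets[c])] = 1.0
        return Y, None
    # HMLC: each cluster activates one label plus all its ancestors
    hier = gen_hierarchy(spec.T, spec.hierarchy_depth,
                         seed=int(rng.integers(0, 2 ** 31 - 1)))
    idx = {lab: j for j, lab in enumerate(hier.labels)}
    Y = np.zeros((spec.n, spec.T))
    anchors = rng.choice(spec.T, size=k, replace=spec.T < k)
    for c in range(k):
        lab = hier.labels[anchors[c]]
        active = {lab} | hier.ancestors(lab)
        cols = [idx[a] for a in active]
        Y[np.ix_(ids == c, cols)] = 1.0
    return Y, hier


def gen_clustered(spec: GenSpec) -> tuple[SemiDataset, np.ndarray]:
    """Generate a fully labeled cluster-structured dataset.

    Returns ``(dataset, cluster_ids)``; the dataset has U = 0 (apply
    :func:`mask_labels` to hide targets).  Cluster signal lives in the first
    ``ceil((1 - noise_frac) * D)`` feature columns; the remainder is pure
    standard-normal noise.
    """
    rng = np.random.default_rng(spec.seed)
    d_info = max(1, int(np.ceil((1.0 - spec.noise_frac) * spec.D)))
    centers_info = _simplex_centers(spec.n_clusters, d_info, spec.separation)
    centers = np.zeros((spec.n_clusters, spec.D))
    centers[:, :d_info] = centers_info
    ids = rng.integers(0, spec.n_clusters, size=spec.n)
    X = centers[ids] + rng.normal(size=(spec.n, spec.D))
    Y, hier = _cluster_targets(spec.task, ids, X, centers, spec, rng)
    if spec.sparsity > 0:
        keep = rng.random(X.shape) >= spec.sparsity
        X = sp.csr_matrix(X * keep)
    return SemiDataset(X, Y, spec.task, hier), ids


def add_noise_features(X, rng: np.random.Generator):
    """Double the feature count with independent standard-normal columns.

    Returns ``(X_aug, is_noise)`` where ``is_noise`` flags the appended
    columns; the original columns are untouched.
    """
    D = X.shape[1]
    noise = rng.standard_normal((X.shape[0], D))
    if sp.issparse(X):
        X_aug = sp.hstack([sp.csr_matrix(X), sp.csr_matrix(noise)],
                          format="csr")
    else:
        X_aug = np.hstack([np.asarray(X, dtype=float), noise])
    is_noise = np.zeros(2 * D, dtype=bool)
    is_noise[D:] = True
    return X_aug, is_noise


def mask_labels(dataset_full: SemiDataset, L: int,
                rng: np.random.Generator) -> SemiDataset:
    """Keep the labels of ``L`` uniformly chosen rows; hide the rest.

    The result is reordered labeled-first; ``orig_index`` maps its rows back
    to the input ordering.
    """
    n = dataset_full.X.shape[0]
    if not 1 <= L <= n:
        raise ValueError(f"L must be in [1, {n}], got {L}")
    if dataset_full.U > 0:
        raise ValueError("input must be fully labeled")
    lab = np.sort(rng.choice(n, size=L, replace=False))
    mask = np.zeros(n, dtype=bool)
    mask[lab] = True
    order = np.concatenate([lab, np.flatnonzero(~mask)])
    return SemiDataset(dataset_full.X[order], dataset_full.Y[lab],
                       dataset_full.task, dataset_full.hierarchy,
                       orig_index=order)


def gen_hierarchy(T: int, depth: int, branching: int = 2,
                  seed: int = 0, n_dag_edges: int = 0) -> HierarchySpec:
    """A random rooted label tree of the given maximum depth over T labels.

    A chain of ``depth`` labels guarantees the depth is attained; remaining
    labels attach uniformly to parents of lesser depth, preferring parents
    with fewer than ``branching`` children.  ``n_dag_edges`` extra cross
    edges turn the tree into a DAG.  Deterministic per seed.
    """
    if not 1 <= depth <= T:
        raise ValueError("need T >= depth >= 1")
    rng = np.random.default_rng(seed)
    labels = [f"l{j}" for j in range(T)]
    level = {}
    edges: list[tuple[str, str]] = []
    for j in range(depth):  # guaranteed chain
        level[labels[j]] = j + 1
        if j > 0:
            edges.append((labels[j - 1], labels[j]))
    n_children: dict[str, int] = {lab: 0 for lab in labels}
    for p, _ in edges:
        n_children[p] += 1
    for j in range(depth, T):
        if depth == 1:
            level[labels[j]] = 1  # all top-level
            continue
        candidates = [lab for lab in labels[:j] if level[lab] < depth]
        open_slots = [lab for lab in candidates if n_children[lab] < branching]
        pool = open_slots or candidates
        parent = pool[int(rng.integers(0, len(pool)))]
        edges.append((parent, labels[j]))
        n_children[parent] += 1
        level[labels[j]] = level[parent] + 1
    existing = set(edges)
    tries = 0
    added = 0
    while added < n_dag_edges and tries < 50 * max(1, n_dag_edges):
        tries += 1
        a, b = rng.choice(T, size=2, replace=False)
        pa, ch = labels[a], labels[b]
        if level[pa] < level[ch] and (pa, ch) not in existing:
            edges.append((pa, ch))
            existing.add((pa, ch))
            added += 1
    return HierarchySpec(labels, edges)
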