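"""SVM split variant: semi-supervised 2-means, then a sparse linear separator.

A split is found in two stages.  First the node's examples are grouped into
two clusters by k-means over the joint (feature, target) space, where
unlabeled examples contribute only through their features (the target term of
the distance is masked for them) and centroid target parts are averaged over
labeled members only.  Second, an L1-regularized squared-hinge linear SVM on
the features alone approximates the cluster partition, yielding the oblique
hyperplane (w, b) used by the tree.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC

from .core import ClusteringWeights, SplitConfig

__all__ = [
    "Unsplittable",
    "ss_distance",
    "kmeans_semisupervised",
    "svm_objective",
    "learn_split_svm",
]


class Unsplittable(Exception):
    """The node's labeled examples cannot seed two distinct clusters."""


def _row(M, j):
    r = M[j]
    return r.toarray().ravel() if sp.issparse(r) else np.asarray(r).ravel()


def ss_distance(x_j, y_j, centroid: tuple[np.ndarray, np.ndarray],
                p: ClusteringWeights, labeled: bool) -> float:
    """Weighted squared distance of one example to a centroid.

    The target term is counted only for labeled examples (``alpha = 1`` iff
    labeled); unlabeled examples see the feature part of the centroid alone.
    """
    cx, cy = centroid
    x_j = np.asarray(x_j, dtype=float).ravel()
    if x_j.shape[0] != cx.shape[0]:
        raise ValueError("feature dimension mismatch")
    d = float(p.p_feat @ (x_j - cx) ** 2)
    if labeled:
        y_j = np.asarray(y_j, dtype=float).ravel()
        if y_j.shape[0] != cy.shape[0]:
            raise ValueError("target dimension mismatch")
        d += float(p.p_targ @ (y_j - cy) ** 2)
    return d


def _dists(Xs, Ys, cx, cy, p: ClusteringWeights) -> np.ndarray:
    """Vectorized masked distances of every row to one centroid."""
    n, L = Xs.shape[0], Ys.shape[0]
    if sp.issparse(Xs):
        # sum_k p_k (x-c)^2 = sum p x^2 - 2 sum p x c + sum p c^2
        x2 = Xs.multiply(Xs) @ p.p_feat
        xc = Xs @ (p.p_feat * cx)
        d = np.asarray(x2).ravel() - 2 * np.asarray(xc).ravel() + p.p_feat @ cx ** 2
    else:
        d = ((Xs - cx) ** 2) @ p.p_feat
    d = np.maximum(d, 0.0)
    d[:L] += ((Ys - cy) ** 2) @ p.p_targ
    return d


def kmeans_objective(Xs, Ys, s: np.ndarray, centroids, p: ClusteringWeights) -> float:
    """Within-cluster masked weighted distance, summed over all examples."""
    d0 = _dists(Xs, Ys, *centroids[0], p=p)
    d1 = _dists(Xs, Ys, *centroids[1], p=p)
    return float(np.where(s == 0, d0, d1).sum())


def _seed_centroids(Xs, Ys, rng: np.random.Generator):
    """Two distinct labeled rows in the joint space (random, then scan)."""
    L = Ys.shape[0]
    if L < 2:
        raise Unsplittable("need at least 2 labeled examples")

    def joint(j):
        return np.concatenate([_row(Xs, j), Ys[j]])

    for _ in range(10):
        i, j = rng.choice(L, size=2, replace=False)
        if not np.array_equal(joint(i), joint(j)):
            return int(i), int(j)
    ref = joint(0)
    for j in range(1, L):
        if not np.array_equal(joint(j), ref):
            return 0, j
    raise Unsplittable("all labeled examples identical in joint space")


def kmeans_semisupervised(Xs, Ys, p: ClusteringWeights, iters: int,
                          rng: np.random.Generator,
                          trace: list | None = None) -> np.ndarray:
    """Two-cluster semi-supervised k-means over standardized (Xs, Ys).

    Initial centroids are two distinct labeled rows.  Each round assigns every
    example to its nearer centroid under the masked distance (ties broken
    uniformly at random), then recomputes centroids: feature parts over all
    members, target parts over labeled members only.  A fully empty cluster
    is re-seeded from a random labeled row; a cluster left without labeled
    members keeps its previous target part.  Stops early when the assignment
    stabilizes.  Returns the {0,1} membership
    vector; ``trace`` (if given) collects the objective after each assignment.
    """
    n, L = Xs.shape[0], Ys.shape[0]
    i0, i1 = _seed_centroids(Xs, Ys, rng)
    cents = [(_row(Xs, i0), Ys[i0].copy()), (_row(Xs, i1), Ys[i1].copy())]
    s_prev = None
    s = np.zeros(n, dtype=int)
    for it in range(iters):
        d0 = _dists(Xs, Ys, *cents[0], p=p)
        d1 = _dists(Xs, Ys, *cents[1], p=p)
        s = (d1 < d0).astype(int)
        ties = d0 == d1
        if ties.any():
            s[ties] = rng.integers(0, 2, size=int(ties.sum()))
        if trace is not None:
            trace.append(float(np.where(s == 0, d0, d1).sum()))
        if s_prev is not None and np.array_equal(s, s_prev):
            break
        s_prev = s.copy()
        for c in (0, 1):
            members = s == c
            lab_members = members[:L]
            if not members.any():
                # empty cluster: fresh labeled seed (cannot raise the
                # objective, since no example is assigned to it)
                j = int(rng.integers(0, L))
                cents[c] = (_row(Xs, j), Ys[j].copy())
                continue
            if sp.issparse(Xs):
                cx = np.asarray(Xs[members].mean(axis=0)).ravel()
            else:
                cx = Xs[members].mean(axis=0)
            # without labeled members the target part is irrelevant to the
            # objective this round; keep the previous one
            cy = Ys[lab_members].mean(axis=0) if lab_members.any() \
                else cents[c][1]
            cents[c] = (cx, cy)
    return s


def svm_objective(w: np.ndarray, b: float, Xs, y_pm: np.ndarray, C: float) -> float:
    """L1-regularized squared-hinge objective ||w||_1 + C * sum hinge^2."""
    w = np.asarray(w, dtype=float).ravel()
    if w.shape[0] != Xs.shape[1]:
        raise ValueError("weight dimension mismatch")
    z = Xs @ w + b
    z = np.asarray(z).ravel()
    hinge = np.maximum(0.0, 1.0 - y_pm * z)
    return float(np.abs(w).sum() + C * (hinge ** 2).sum())


def learn_split_svm(Xs, Ys, p: ClusteringWeights, config: SplitConfig,
                    rng: np.random.Generator):
    """Full SVM-variant split: cluster, then separate.

    Returns ``(w, b)`` in standardized-feature coordinates, or ``None`` when
    no usable split exists (degenerate node, one-sided clustering, or a
    hyperplane that leaves one side empty).
    """
    try:
        s = kmeans_semisupervised(Xs, Ys, p, config.clust_iters, rng)
    except Unsplittable:
        return None
    if s.min() == s.max():
        return None
    y_pm = 2 * s - 1
    svc = LinearSVC(
        penalty="l1", loss="squared_hinge", dual=False, C=config.C,
        max_iter=config.opt_iters, tol=1e-4, fit_intercept=True,
        random_state=int(rng.integers(0, 2 ** 31 - 1)),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        svc.fit(Xs, y_pm)
    w = svc.coef_.ravel().astype(float)
    # liblinear orders classes ascending; make positive scores mean cluster 1
    if svc.classes_[1] != 1:
        w = -w
        b = -float(svc.intercept_[0])
    else:
        b = float(svc.intercept_[0])
    z = np.asarray(Xs @ w).ravel() + b
    pos = z >= 0
    if pos.all() or not pos.any():
        return None
    return w, b
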