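"""Gradient split variant: differentiable fuzzy-membership impurity descent.

The hyperplane score ``z = Xs w + b`` is squashed through a sigmoid into a
fuzzy membership ``s`` in (0, 1); each example belongs to the "positive" group
with weight ``s_i`` and to the "negative" group with weight ``1 - s_i``.
Group impurity is the clustering-weighted sum of weighted variances of every
feature (all rows) and every target (labeled rows only), and the split
fitness is the group-size-weighted sum of the two impurities, which biases
the search toward balanced splits.  The objective adds a smoothed
l_{1/2}-type penalty on w and is minimized with Adam.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .core import ClusteringWeights, SplitConfig

__all__ = [
    "weighted_mean",
    "weighted_variance",
    "group_impurity",
    "split_fitness",
    "fitness_gradient",
    "learn_split_grad",
]

_SQRT_EPS = 1e-8  # smoothing inside sqrt(|w| + eps)


def weighted_mean(v, a) -> float:
    v = np.asarray(v, dtype=float)
    a = np.asarray(a, dtype=float)
    A = a.sum()
    if A <= 0:
        return 0.0
    return float((a @ v) / A)


def weighted_variance(v, a) -> float:
    """Weighted population variance mean(v^2, a) - mean(v, a)^2.

    Defined as 0 when the total weight is 0 (an empty fuzzy group).
    """
    v = np.asarray(v, dtype=float)
    a = np.asarray(a, dtype=float)
    A = a.sum()
    if A <= 0:
        return 0.0
    m = (a @ v) / A
    m2 = (a @ (v * v)) / A
    return float(max(m2 - m * m, 0.0))


def _column_moments(M, a, A):
    """Per-column weighted mean and variance under weights ``a`` (sum A > 0)."""
    if sp.issparse(M):
        m = np.asarray(M.T @ a).ravel() / A
        m2 = np.asarray(M.multiply(M).T @ a).ravel() / A
    else:
        m = (a @ M) / A
        m2 = (a @ (M * M)) / A
    return m, np.maximum(m2 - m * m, 0.0)


def group_impurity(Xs, Ys, weights, p: ClusteringWeights) -> float:
    """Clustering-weighted impurity of one fuzzy group.

    ``weights`` has length L+U; feature variances use all of it, target
    variances only its first L entries (the labeled rows).
    """
    weights = np.asarray(weights, dtype=float)
    n, L = Xs.shape[0], Ys.shape[0]
    if weights.shape[0] != n:
        raise ValueError("weight vector length mismatch")
    imp = 0.0
    A = weights.sum()
    if A > 0:
        _, var = _column_moments(Xs, weights, A)
        imp += float(p.p_feat @ var)
    a_lab = weights[:L]
    A_lab = a_lab.sum()
    if A_lab > 0 and p.p_targ.size:
        _, var_t = _column_moments(Ys, a_lab, A_lab)
        imp += float(p.p_targ @ var_t)
    return imp


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def split_fitness(w, b, Xs, Ys, p: ClusteringWeights) -> float:
    """Size-weighted two-group impurity f = S*imp(s) + (n-S)*imp(1-s)."""
    z = np.asarray(Xs @ np.asarray(w, dtype=float)).ravel() + b
    s = _sigmoid(z)
    n = Xs.shape[0]
    S = s.sum()
    return float(S * group_impurity(Xs, Ys, s, p)
                 + (n - S) * group_impurity(Xs, Ys, 1.0 - s, p))


def _group_terms(Xs, Ys, a, p: ClusteringWeights):
    """imp(a) and its per-example partial derivatives times the group size.

    For group weights ``a`` with feature mass A = sum(a) and labeled mass
    A_L = sum(a[:L]):

        d var(v, a) / d a_i = ((v_i - m)^2 - var) / A

    so  A * d imp / d a_i  separates into a feature term (all rows) and a
    target term scaled by A / A_L (labeled rows only).
    """
    n, L = Xs.shape[0], Ys.shape[0]
    imp = 0.0
    g = np.zeros(n)  # will hold A * d imp/d a_i pieces assembled below
    A = a.sum()
    feat_quad = np.zeros(n)
    imp_f = 0.0
    if A > 0:
        m, var = _column_moments(Xs, a, A)
        imp_f = float(p.p_feat @ var)
        pm = p.p_feat * m
        if sp.issparse(Xs):
            q = (np.asarray(Xs.multiply(Xs) @ p.p_feat).ravel()
                 - 2.0 * np.asarray(Xs @ pm).ravel() + pm @ m)
        else:
            q = (Xs * Xs) @ p.p_feat - 2.0 * (Xs @ pm) + pm @ m
        feat_quad = q - imp_f  # sum_k p_k ((x_ik - m_k)^2 - var_k)
    imp += imp_f
    targ_quad = np.zeros(L)
    imp_t = 0.0
    a_lab = a[:L]
    A_lab = a_lab.sum()
    if A_lab > 0 and p.p_targ.size:
        mt, vart = _column_moments(Ys, a_lab, A_lab)
        imp_t = float(p.p_targ @ vart)
        pmt = p.p_targ * mt
        qt = (Ys * Ys) @ p.p_targ - 2.0 * (Ys @ pmt) + pmt @ mt
        targ_quad = qt - imp_t
    imp += imp_t
    # A * d imp/d a_i = feat_quad_i + (A / A_L) * targ_quad_i  (i < L)
    if A > 0:
        g[:] = feat_quad
        if A_lab > 0 and p.p_targ.size:
            g[:L] += (A / A_lab) * targ_quad
    return imp, g


def fitness_gradient(w, b, Xs, Ys, p: ClusteringWeights):
    """Value and analytic gradient of the split fitness f(w, b)."""
    w = np.asarray(w, dtype=float)
    n = Xs.shape[0]
    z = np.asarray(Xs @ w).ravel() + b
    s = _sigmoid(z)
    S = s.sum()
    imp_pos, g_pos = _group_terms(Xs, Ys, s, p)
    imp_neg, g_neg = _group_terms(Xs, Ys, 1.0 - s, p)
    f = S * imp_pos + (n - S) * imp_neg
    # df/ds_i = imp_pos - imp_neg + S * d imp_pos/ds_i - (n-S) * d imp_neg/da_i
    # where the *_terms above already carry the group-size factor.
    df_ds = imp_pos - imp_neg + g_pos - g_neg
    dz = df_ds * s * (1.0 - s)
    if sp.issparse(Xs):
        grad_w = np.asarray(Xs.T @ dz).ravel()
    else:
        grad_w = Xs.T @ dz
    return float(f), grad_w, float(dz.sum())


def _reg_value(w):
    return float(np.sqrt(np.abs(w) + _SQRT_EPS).sum())


def _reg_grad(w):
    return np.sign(w) / (2.0 * np.sqrt(np.abs(w) + _SQRT_EPS))


def objective(w, b, Xs, Ys, p: ClusteringWeights, C: float) -> float:
    """Smoothed half-norm penalty plus C times the split fitness."""
    return _reg_value(w) + C * split_fitness(w, b, Xs, Ys, p)


def learn_split_grad(Xs, Ys, p: ClusteringWeights, config: SplitConfig,
                     rng: np.random.Generator):
    """Minimize ||w||_{1/2} + C f(w, b) with Adam from a random start.

    Weights start at N(0, 1/D), bias at 0.  Runs up to ``opt_iters`` Adam
    steps and keeps the best-objective iterate seen.  Returns ``(w, b)``, or
    ``None`` when the hard 0.5-threshold partition leaves one side empty.
    Raises on a non-finite objective, naming the offending step.
    """
    D = Xs.shape[1]
    n = Xs.shape[0]
    if n < 2:
        return None
    w = rng.standard_normal(D) / np.sqrt(D)
    b = 0.0
    lr = config.adam_lr
    b1, b2, eps = config.adam_beta1, config.adam_beta2, config.adam_eps
    m = np.zeros(D + 1)
    v = np.zeros(D + 1)
    f0, gw, gb = fitness_gradient(w, b, Xs, Ys, p)
    best_obj = _reg_value(w) + config.C * f0
    best = (w.copy(), b)
    for t in range(1, config.opt_iters + 1):
        grad = np.concatenate([config.C * gw + _reg_grad(w), [config.C * gb]])
        m = b1 * m + (1 - b1) * grad
        v = b2 * v + (1 - b2) * grad ** 2
        mhat = m / (1 - b1 ** t)
        vhat = v / (1 - b2 ** t)
        step = lr * mhat / (np.sqrt(vhat) + eps)
        w = w - step[:-1]
        b = b - step[-1]
        f, gw, gb = fitness_gradient(w, b, Xs, Ys, p)
        obj = _reg_value(w) + config.C * f
        if not np.isfinite(obj):
            raise FloatingPointError(f"non-finite objective at Adam step {t}")
        if obj < best_obj:
            best_obj = obj
            best = (w.copy(), b)
    w, b = best
    z = np.asarray(Xs @ w).ravel() + b
    pos = z >= 0  # membership >= 0.5 goes to the positive child
    if pos.all() or not pos.any():
        return None
    return w, float(b)
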