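import numpy as np
import pytest

from sspyct import (
    SplitConfig,
    group_impurity,
    learn_split_grad,
    split_fitness,
    weighted_mean,
    weighted_variance,
)
from sspyct.core import scale_clustering_weights, standardize
from sspyct.split_grad import _sigmoid, fitness_gradient, objective


def _weights(D, T, omega=0.5):
    return scale_clustering_weights(np.ones(D + T), omega, D)


def _two_pass_variance(v, a):
    A = a.sum()
    m = (a @ v) / A
    return float((a @ (v - m) ** 2) / A)


class TestWeightedVariance:
    def test_constant_vector(self):
        assert weighted_variance([1, 1, 1], [0.2, 0.5, 0.3]) == 0.0

    def test_symmetric_two_point(self):
        assert weighted_variance([0, 1], [1, 1]) == 0.25

    def test_zero_weight_drops_middle(self):
        assert weighted_mean([1, 2, 3], [1, 0, 1]) == 2.0
        assert weighted_variance([1, 2, 3], [1, 0, 1]) == 1.0

    def test_zero_total_weight_defined_as_zero(self):
        assert weighted_variance([1, 2], [0, 0]) == 0.0

    def test_shortcut_matches_two_pass_oracle(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(1000):
            n = int(rng.integers(2, 20))
            v = rng.normal(scale=rng.uniform(0.1, 10), size=n)
            a = rng.uniform(0.01, 1, size=n)
            ref = _two_pass_variance(v, a)
            got = weighted_variance(v, a)
            worst = max(worst, abs(got - ref) / max(abs(ref), 1e-30))
        assert worst <= 1e-10


class TestGroupImpurity:
    def test_constant_columns(self):
        Xs = np.ones((4, 2))
        Ys = np.full((2, 1), 3.0)
        assert group_impurity(Xs, Ys, np.ones(4), _weights(2, 1)) == 0.0

    def test_hand_evaluation(self):
        Xs = np.array([[-1.0], [1.0]])
        Ys = np.array([[-1.0], [1.0]])
        p = _weights(1, 1)
        assert group_impurity(Xs, Ys, np.array([1.0, 1.0]), p) == 1.0

    def test_omega_zero_ignores_targets(self):
        rng = np.random.default_rng(1)
        Xs = rng.normal(size=(8, 3))
        Ys = rng.normal(size=(5, 2))
        s = rng.uniform(0.1, 0.9, size=8)
        p = _weights(3, 2, omega=0.0)
        a = group_impurity(Xs, Ys, s, p)
        b = group_impurity(Xs, Ys[rng.permutation(5)], s, p)
        assert a == b

    def test_unlabeled_weights_do_not_touch_target_term(self):
        rng = np.random.default_rng(2)
        Xs = rng.normal(size=(6, 2))
        Ys = rng.normal(size=(3, 1))  # rows 3..5 are unlabeled
        s = rng.uniform(size=6)
        s2 = s.copy()
        s2[3:] = rng.uniform(size=3)  # perturb only unlabeled memberships
        p = _weights(2, 1, omega=1.0)  # target-only impurity
        assert group_impurity(Xs, Ys, s, p) == group_impurity(Xs, Ys, s2, p)


class TestSplitFitness:
    def test_zero_hyperplane_symmetric(self):
        rng = np.random.default_rng(3)
        Xs = rng.normal(size=(10, 2))
        Ys = rng.normal(size=(6, 1))
        p = _weights(2, 1)
        f = split_fitness(np.zeros(2), 0.0, Xs, Ys, p)
        half = 0.5 * np.ones(10)
        assert f == pytest.approx(10 * group_impurity(Xs, Ys, half, p))

    def test_saturation_limit(self):
        rng = np.random.default_rng(4)
        Xs = rng.normal(size=(8, 2))
        Ys = rng.normal(size=(5, 1))
        p = _weights(2, 1)
        f = split_fitness(np.zeros(2), 50.0, Xs, Ys, p)
        assert f == pytest.approx(8 * group_impurity(Xs, Ys, np.ones(8), p),
                                  rel=1e-6)

    def test_nonnegative(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            Xs = rng.normal(size=(7, 3))
            Ys = rng.normal(size=(4, 2))
            w = rng.normal(size=3)
            assert split_fitness(w, float(rng.normal()), Xs, Ys,
                                 _weights(3, 2)) >= 0.0

    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(50):
            n = int(rng.integers(5, 15))
            L = int(rng.integers(2, n + 1))
            D = int(rng.integers(2, 6))
            T = int(rng.integers(1, 4))
            Xs = rng.normal(size=(n, D))
            Ys = rng.normal(size=(L, T))
            p = scale_clustering_weights(rng.random(D + T) + 0.1,
                                         float(rng.random()), D)
            w = rng.normal(size=D)
            b = float(rng.normal())
            _, gw, gb = fitness_gradient(w, b, Xs, Ys, p)
            h = 1e-6
            num = np.empty(D + 1)
            for i in range(D):
                wp, wm = w.copy(), w.copy()
                wp[i] += h
                wm[i] -= h
                num[i] = (split_fitness(wp, b, Xs, Ys, p)
                          - split_fitness(wm, b, Xs, Ys, p)) / (2 * h)
            num[-1] = (split_fitness(w, b + h, Xs, Ys, p)
                       - split_fitness(w, b - h, Xs, Ys, p)) / (2 * h)
            ana = np.concatenate([gw, [gb]])
            rel = np.abs(ana - num) / np.maximum(np.abs(num) + np.abs(ana),
                                                 1e-8)
            worst = max(worst, float(rel.max()))
        assert worst <= 1e-5


class TestLearnSplitGrad:
    def test_separable_toy_partition(self, toy_1d):
        hits = 0
        for seed in range(20):
            Xs, _ = standardize(toy_1d.X)
            Ys, _ = standardize(toy_1d.Y)
            res = learn_split_grad(Xs, Ys, _weights(1, 1),
                                   SplitConfig(variant="grad"),
                                   np.random.default_rng(seed))
            assert res is not None
            w, b = res
            side = (Xs @ w + b >= 0).ravel()
            raw = toy_1d.X.ravel()
            if (len(np.unique(side[raw > 0])) == 1
                    and len(np.unique(side[raw < 0])) == 1
                    and side[raw > 0][0] != side[raw < 0][0]):
                hits += 1
        assert hits == 20

    def test_final_objective_not_worse_than_initial(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n, L, D, T = 20, 10, 3, 1
            Xs = rng.normal(size=(n, D))
            Ys = rng.normal(size=(L, T))
            p = _weights(D, T)
            cfg = SplitConfig(variant="grad", opt_iters=30)
            init_rng = np.random.default_rng(seed + 1)
            w0 = init_rng.standard_normal(D) / np.sqrt(D)
            obj0 = objective(w0, 0.0, Xs, Ys, p, cfg.C)
            res = learn_split_grad(Xs, Ys, p, cfg,
                                   np.random.default_rng(seed + 1))
            if res is None:
                continue
            w, b = res
            assert objective(w, b, Xs, Ys, p, cfg.C) <= obj0 + 1e-12

    def test_deterministic_given_seed(self, toy_1d):
        Xs, _ = standardize(toy_1d.X)
        Ys, _ = standardize(toy_1d.Y)
        p = _weights(1, 1)
        r1 = learn_split_grad(Xs, Ys, p, SplitConfig(variant="grad"),
                              np.random.default_rng(5))
        r2 = learn_split_grad(Xs, Ys, p, SplitConfig(variant="grad"),
                              np.random.default_rng(5))
        assert np.array_equal(r1[0], r2[0]) and r1[1] == r2[1]


def test_sigmoid_is_stable_at_extremes():
    z = np.array([-1000.0, 0.0, 1000.0])
    s = _sigmoid(z)
    assert np.isfinite(s).all() and s[0] == 0.0 and s[1] == 0.5 and s[2] == 1.0
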