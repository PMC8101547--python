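import numpy as np
import pytest
from sklearn.metrics import label_ranking_average_precision_score

from sspyct import (
    OMEGA_GRID,
    SemiDataset,
    SplitConfig,
    lrap_weighted,
    macro_f1,
    mask_labels_protocol,
    mean_r2,
    r2,
    select_omega_cv,
)


def _brute_force_lrap(Y, S, w):
    """Pairwise-counting definition, computed term by term."""
    n, T = Y.shape
    vals = []
    for i in range(n):
        pos = [j for j in range(T) if Y[i, j] == 1]
        if not pos:
            continue
        W = sum(w[j] for j in pos)
        acc = 0.0
        for j in pos:
            R = sum(1 for k in range(T) if S[i, k] >= S[i, j])
            L = sum(1 for k in pos if S[i, k] >= S[i, j])
            acc += (w[j] / W) * (L / R)
        vals.append(acc)
    return float(np.mean(vals))


class TestR2:
    def test_perfect(self):
        assert r2([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_mean_prediction_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r2(y, np.full(3, y.mean())) == 0.0

    def test_direct_formula(self):
        assert r2([0.0, 2.0], [0.0, 1.0]) == 0.5

    def test_constant_target_rejected(self):
        with pytest.raises(ValueError):
            r2([1.0, 1.0], [1.0, 2.0])

    def test_multi_target_mean(self):
        Y = np.array([[0.0, 1.0], [2.0, 3.0]])
        Yhat = np.array([[0.0, 1.0], [1.0, 3.0]])
        res = mean_r2(Y, Yhat)
        assert res.per_target.tolist() == [0.5, 1.0]
        assert res.value == 0.75


class TestMacroF1:
    def test_perfect(self):
        assert macro_f1([0, 1, 1], [0, 1, 1], average="binary") == 1.0

    def test_confusion_arithmetic(self):
        # TP=1, FP=1, FN=1 -> precision = recall = 0.5 -> F1 = 0.5
        assert macro_f1([1, 1, 0, 0], [1, 0, 1, 0], average="binary") == 0.5

    def test_all_wrong_single_class(self):
        assert macro_f1([1, 1, 1], [0, 0, 0], average="binary") == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            macro_f1([], [])


class TestLrap:
    def test_perfect_ranking(self):
        Y = np.array([[1, 0, 1], [0, 1, 0]])
        S = np.array([[0.9, 0.1, 0.8], [0.2, 0.9, 0.1]])
        assert lrap_weighted(Y, S) == 1.0

    def test_hand_enumeration(self):
        Y = np.array([[1, 0, 1]])
        S = np.array([[0.9, 0.8, 0.5]])
        assert lrap_weighted(Y, S) == pytest.approx(0.5 * (1 + 2 / 3))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(200):
            n = int(rng.integers(1, 6))
            T = int(rng.integers(2, 6))
            Y = (rng.random((n, T)) < 0.5).astype(float)
            Y[np.arange(n), rng.integers(0, T, n)] = 1.0  # ensure positives
            S = np.round(rng.random((n, T)), 1)  # coarse scores force ties
            w = rng.uniform(0.1, 1.0, T)
            worst = max(worst, abs(lrap_weighted(Y, S, w)
                                   - _brute_force_lrap(Y, S, w)))
        assert worst <= 1e-12

    def test_uniform_weights_match_sklearn(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            Y = (rng.random((6, 5)) < 0.4).astype(float)
            Y[np.arange(6), rng.integers(0, 5, 6)] = 1.0
            S = rng.random((6, 5))
            ref = label_ranking_average_precision_score(Y, S)
            assert lrap_weighted(Y, S) == pytest.approx(ref, abs=1e-12)

    def test_rows_without_positives_skipped(self):
        Y = np.array([[1, 0], [0, 0]])
        S = np.array([[0.9, 0.1], [0.5, 0.5]])
        with pytest.warns(UserWarning):
            assert lrap_weighted(Y, S) == 1.0

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            lrap_weighted(np.array([[1]]), np.array([[1.0]]), [-1.0])


class TestSelectOmega:
    def _data(self, seed=0):
        from sspyct import GenSpec, gen_clustered, mask_labels
        ds, _ = gen_clustered(GenSpec(task="BC", n=120, D=4, n_clusters=2,
                                      separation=5.0, seed=seed))
        return mask_labels(ds, 30, np.random.default_rng(seed))

    def test_single_value_grid_short_circuits(self):
        ds = self._data()
        cfg = SplitConfig(variant="grad", seed=0)
        assert select_omega_cv(ds, cfg, grid=[0.25]) == 0.25

    def test_result_in_grid_and_deterministic(self):
        ds = self._data(3)
        cfg = SplitConfig(variant="grad", seed=3)
        om1 = select_omega_cv(ds, cfg, rng=np.random.default_rng(3))
        om2 = select_omega_cv(ds, cfg, rng=np.random.default_rng(3))
        assert om1 == om2 and om1 in OMEGA_GRID

    def test_too_few_labeled_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        ds = SemiDataset(X, np.array([[1.0], [2.0]]), "STR")
        with pytest.raises(ValueError, match="folds"):
            select_omega_cv(ds, SplitConfig(), folds=3)


class TestMaskLabelsProtocol:
    def test_fold_arithmetic(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 3))
        Y = rng.normal(size=(100, 1))
        splits = mask_labels_protocol(X, Y, L=25, folds=10,
                                      rng=np.random.default_rng(1))
        assert len(splits) == 10
        for ds, X_test, Y_test in splits:
            assert ds.L == 25 and ds.U == 65 and X_test.shape[0] == 10

    def test_test_folds_disjoint_and_cover(self):
        rng = np.random.default_rng(2)
        X = np.arange(50, dtype=float)[:, None]
        Y = rng.normal(size=(50, 1))
        splits = mask_labels_protocol(X, Y, L=20, folds=5,
                                      rng=np.random.default_rng(3))
        seen = np.concatenate([X_test.ravel() for _, X_test, _ in splits])
        assert sorted(seen.tolist()) == list(range(50))

    def test_deterministic(self):
        X = np.random.default_rng(4).normal(size=(40, 2))
        Y = np.random.default_rng(5).normal(size=(40, 1))
        a = mask_labels_protocol(X, Y, L=10, folds=4,
                                 rng=np.random.default_rng(6))
        b = mask_labels_protocol(X, Y, L=10, folds=4,
                                 rng=np.random.default_rng(6))
        for (da, xa, _), (db, xb, _) in zip(a, b):
            assert np.array_equal(da.X, db.X) and np.array_equal(xa, xb)

    def test_oversized_L_rejected(self):
        X = np.zeros((20, 1))
        Y = np.zeros((20, 1))
        with pytest.raises(ValueError):
            mask_labels_protocol(X, Y, L=19, folds=10,
                                 rng=np.random.default_rng(0))
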