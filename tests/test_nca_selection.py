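"""NCA feature weighting: oracle agreement, invariances, selection, sweep."""

import numpy as np
import pytest

from brainnext.errors import ConfigurationError
from brainnext.evaluation import ClassifierConfig
from brainnext.nca_selection import (NCAConfig, NCAResult, iterative_sweep,
                                     nca_fit, select_top_k)


def loo_1nn_accuracy_per_feature(X, y):
    """Independent oracle: leave-one-out 1-NN accuracy using one feature at
    a time (brute force)."""
    n, d = X.shape
    acc = np.zeros(d)
    for r in range(d):
        correct = 0
        for i in range(n):
            dist = np.abs(X[:, r] - X[i, r])
            dist[i] = np.inf
            correct += y[int(np.argmin(dist))] == y[i]
        acc[r] = correct / n
    return acc


def test_separating_feature_ranks_first(rng):
    """Feature 1 equals the class label plus tiny noise; features 2-3 are
    pure noise.  The single-feature LOO-1NN oracle identifies feature 1 as
    the only informative one, and NCA must rank it first."""
    y = np.repeat([0, 1, 2], 7)[:20]
    X = np.column_stack([y + rng.normal(0, 0.01, 20),
                         rng.normal(size=20), rng.normal(size=20)])
    oracle = loo_1nn_accuracy_per_feature(X, y)
    assert np.argmax(oracle) == 0 and oracle[0] > 0.95
    res = nca_fit(X, y)
    assert res.index[0] == 0


def test_constant_features_tie_to_index_order():
    res = nca_fit(np.ones((10, 5)), np.repeat([0, 1], 5))
    assert np.allclose(res.weights, res.weights[0])
    assert res.index.tolist() == [0, 1, 2, 3, 4]


def test_row_permutation_leaves_ranking_unchanged(rng):
    X = rng.normal(size=(30, 6))
    y = rng.integers(0, 2, 30)
    X[:, 2] += 2 * y
    perm = rng.permutation(30)
    a = nca_fit(X, y)
    b = nca_fit(X[perm], y[perm])
    assert np.array_equal(a.index, b.index)


def test_weights_nonnegative_and_index_is_permutation(rng):
    X = rng.normal(size=(40, 12))
    y = rng.integers(0, 3, 40)
    res = nca_fit(X, y)
    assert (res.weights >= 0).all()
    assert sorted(res.index.tolist()) == list(range(12))


def test_objective_nondecreasing_full_batch(rng):
    X = rng.normal(size=(50, 8))
    y = rng.integers(0, 2, 50)
    X[:, 0] += 1.5 * y
    res = nca_fit(X, y, NCAConfig(epochs=40))
    diffs = np.diff(res.objective_trace)
    assert (diffs >= -1e-9).all()


def test_ranking_invariant_to_feature_rescaling(rng):
    """With standardization on, per-feature affine rescaling cannot change
    the ranking."""
    X = rng.normal(size=(40, 6))
    y = rng.integers(0, 2, 40)
    X[:, 3] += 2 * y
    scales = np.array([1.0, 100.0, 0.01, 5.0, 1e3, 0.5])
    a = nca_fit(X, y)
    b = nca_fit(X * scales + 7.0, y)
    assert np.array_equal(a.index, b.index)


def test_relevance_recovery_planted_features():
    """5 informative of 50 features (n=100): all informative in the top 10
    ranks in >= 18 of 20 seeds."""
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, 100)
        X = rng.normal(size=(100, 50))
        X[:, :5] += 1.5 * y[:, None]
        res = nca_fit(X, y, NCAConfig(seed=seed))
        hits += set(range(5)) <= set(res.index[:10].tolist())
    assert hits >= 18


def test_stochastic_mode_seeded(rng):
    X = rng.normal(size=(30, 5))
    y = rng.integers(0, 2, 30)
    X[:, 1] += 2 * y
    cfg = NCAConfig(batch_mode="stochastic", epochs=5, seed=3)
    a = nca_fit(X, y, cfg)
    b = nca_fit(X, y, NCAConfig(batch_mode="stochastic", epochs=5, seed=3))
    assert np.array_equal(a.weights, b.weights)
    assert (a.weights >= 0).all()


@pytest.mark.parametrize("bad_y", [np.zeros(10, int)])
def test_single_class_rejected(bad_y, rng):
    with pytest.raises(ConfigurationError):
        nca_fit(rng.normal(size=(10, 3)), bad_y)


def test_nonfinite_feature_names_column(rng):
    X = rng.normal(size=(10, 3))
    X[4, 1] = np.nan
    with pytest.raises(ConfigurationError, match="column 1"):
        nca_fit(X, np.repeat([0, 1], 5))


class TestSelectTopK:
    def test_forced_ordering(self):
        res = NCAResult(weights=np.array([0.9, 0.1, 0.5]),
                        index=np.array([0, 2, 1]))
        F = np.arange(12).reshape(4, 3).astype(float)
        s, idx = select_top_k(res, F, 2)
        assert idx.tolist() == [0, 2]
        assert np.array_equal(s, F[:, [0, 2]])

    def test_k_equals_d_is_permutation(self, rng):
        X = rng.normal(size=(8, 5))
        res = nca_fit(X, np.repeat([0, 1], 4))
        s, idx = select_top_k(res, X, 5)
        assert np.array_equal(s, X[:, idx])
        assert sorted(idx.tolist()) == list(range(5))

    def test_k_out_of_range(self, rng):
        res = NCAResult(weights=np.ones(3), index=np.arange(3))
        with pytest.raises(ConfigurationError):
            select_top_k(res, rng.normal(size=(4, 3)), 4)


@pytest.fixture(scope="module")
def sweep_data():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(40, 30))
    y = rng.integers(0, 2, 40)
    X[:, :3] += 2 * y[:, None]
    res = nca_fit(X, y, NCAConfig(epochs=10))
    return res, X, y


class TestSweep:
    def test_single_entry(self, sweep_data):
        res, X, y = sweep_data
        sw = iterative_sweep(res, X, y, 5, 5,
                             ClassifierConfig(folds=3, seed=0))
        assert len(sw.k_values) == 1 and sw.best_k == 5

    def test_best_k_at_least_as_good_as_kmin(self, sweep_data):
        res, X, y = sweep_data
        sw = iterative_sweep(res, X, y, 10, 20,
                             ClassifierConfig(folds=3, seed=0))
        assert len(sw.k_values) == 11
        best_acc = sw.accuracies[sw.k_values.tolist().index(sw.best_k)]
        assert best_acc >= sw.accuracies[0]
        assert best_acc == sw.accuracies.max()

    def test_invalid_range(self, sweep_data):
        res, X, y = sweep_data
        with pytest.raises(ConfigurationError):
            iterative_sweep(res, X, y, 20, 10)
        with pytest.raises(ConfigurationError):
            iterative_sweep(res, X, y, 10, 100)
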