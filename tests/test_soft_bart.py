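"""Soft BART: gating/leaf-weight algebra, prediction, fitting behaviour."""

import numpy as np
import pytest

from gfbart.ldart_prior import DartPrior
from gfbart.soft_bart import (
    BartHypers,
    McmcConfig,
    SoftForest,
    SoftTree,
    _Node,
    fit_gaussian,
    fit_probit,
    leaf_weights,
    predict,
    split_counts,
)

FAST = McmcConfig(n_warmup=100, n_save=100, thin=1, seed=5)


def make_split_tree(feature=0, threshold=0.5, bandwidth=0.1,
                    left=-1.0, right=1.0, hard=False):
    t = SoftTree(bandwidth=bandwidth, hard=hard)
    nd = t.root
    nd.feature, nd.threshold = feature, threshold
    nd.left, nd.right = _Node(1), _Node(1)
    nd.left.leaf_value, nd.right.leaf_value = left, right
    return t


def friedman(X):
    return (10 * np.sin(np.pi * X[:, 0] * X[:, 1]) + 20 * (X[:, 2] - 0.5) ** 2
            + 10 * X[:, 3] + 5 * X[:, 4])


class TestLeafWeights:
    def test_single_leaf(self):
        t = SoftTree()
        w = leaf_weights(t, np.array([0.3, 0.7]))
        np.testing.assert_allclose(w, [1.0])

    def test_split_point_gives_half_half(self):
        t = make_split_tree(threshold=0.4)
        w = leaf_weights(t, np.array([0.4, 0.0]))
        np.testing.assert_allclose(w, [0.5, 0.5])

    def test_weights_sum_to_one(self, rng):
        t = make_split_tree()
        t.root.left.feature, t.root.left.threshold = 1, 0.3
        t.root.left.left, t.root.left.right = _Node(2), _Node(2)
        X = rng.uniform(size=(50, 3))
        W = leaf_weights(t, X)
        np.testing.assert_allclose(W.sum(axis=1), 1.0)
        assert (W >= 0).all()

    def test_small_bandwidth_approaches_hard_partition(self, rng):
        """b -> 0 recovers the indicator split (hard-decision oracle)."""
        X = rng.uniform(size=(100, 2))
        soft = make_split_tree(bandwidth=1e-9)
        hard_oracle = (X[:, 0] > 0.5).astype(float)
        W = leaf_weights(soft, X)
        np.testing.assert_allclose(W[:, 1], hard_oracle, atol=1e-6)


class TestPredict:
    def test_zero_leaves_give_intercept(self):
        f = SoftForest([make_split_tree(left=0.0, right=0.0)], mu0=2.5, sigma=1.0)
        assert predict(f, np.array([0.3])) == pytest.approx(2.5)

    def test_single_leaf_additivity(self):
        t = SoftTree()
        t.root.leaf_value = 3.0
        f = SoftForest([t], mu0=1.0, sigma=1.0)
        assert predict(f, np.array([0.0])) == pytest.approx(4.0)

    def test_prediction_continuous_in_input(self):
        f = SoftForest([make_split_tree(bandwidth=0.05)], mu0=0.0, sigma=1.0)
        eps = 1e-6
        base = predict(f, np.array([0.5]))
        near = predict(f, np.array([0.5 + eps]))
        assert abs(near - base) < 1e-4  # no jump at the split point

    def test_json_round_trip(self, rng):
        t = make_split_tree()
        f = SoftForest([t], mu0=0.3, sigma=1.2, y_offset=1.0, y_scale=2.0,
                       x_lo=np.zeros(2), x_rng=np.ones(2))
        g = SoftForest.from_json(f.to_json())
        X = rng.uniform(size=(10, 2))
        np.testing.assert_allclose(g.predict(X), f.predict(X))


class TestSplitCounts:
    def test_stumps_are_zero(self):
        f = SoftForest([SoftTree(), SoftTree()], mu0=0, sigma=1)
        np.testing.assert_array_equal(split_counts(f, 4), np.zeros(4))

    def test_counts_and_conservation(self):
        t = make_split_tree(feature=3)
        t.root.left.feature, t.root.left.threshold = 3, 0.2
        t.root.left.left, t.root.left.right = _Node(2), _Node(2)
        f = SoftForest([t, make_split_tree(feature=1)], mu0=0, sigma=1)
        counts = split_counts(f, 5)
        assert counts[3] == 2
        assert counts[1] == 1
        n_internal = sum(len(tr.internal_nodes()) for tr in f.trees)
        assert counts.sum() == n_internal


class TestFitGaussian:
    def test_constant_outcome_returns_constant_forest(self, rng):
        X = rng.uniform(size=(30, 3))
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_gaussian(X, np.full(30, 7.0), cfg=FAST)
        np.testing.assert_allclose(fit.predict_mean(X), 7.0)
        assert np.all(fit.sigma_draws == 0.0)

    def test_friedman_recovery(self, rng):
        """Fit quality oracle: out-of-sample R^2 vs the true surface > 0.7."""
        X = rng.uniform(size=(500, 10))
        f = friedman(X)
        y = f + rng.normal(0, 1, 500)
        fit = fit_gaussian(X, y, cfg=FAST)
        Xt = rng.uniform(size=(300, 10))
        ft = friedman(Xt)
        resid = fit.predict_mean(Xt) - ft
        r2 = 1 - np.mean(resid ** 2) / ft.var()
        assert r2 > 0.7
        # residual scale is recovered too (true sigma = 1)
        assert 0.7 < fit.sigma_draws.mean() < 1.5

    def test_identical_seeds_identical_draws(self, rng):
        X = rng.uniform(size=(60, 4))
        y = X[:, 0] + rng.normal(0, 0.3, 60)
        cfg = McmcConfig(n_warmup=30, n_save=20, thin=1, seed=11)
        a = fit_gaussian(X, y, cfg=cfg)
        b = fit_gaussian(X, y, cfg=cfg)
        np.testing.assert_array_equal(a.sigma_draws, b.sigma_draws)
        np.testing.assert_array_equal(a.predict(X[:5]), b.predict(X[:5]))

    def test_stump_forest_reduces_to_intercept_model(self, rng):
        """With splitting disabled the fit is Bayesian intercept-plus-noise."""
        X = rng.uniform(size=(80, 3))
        y = rng.normal(5.0, 1.0, 80)
        fit = fit_gaussian(X, y, cfg=FAST,
                           hypers=BartHypers(n_trees=1, gamma=0.0))
        assert fit.predict_mean(X).mean() == pytest.approx(y.mean(), abs=0.3)

    def test_swapping_duplicate_predictors_is_symmetric(self, rng):
        """Two identical predictors share split mass under uniform q."""
        x = rng.uniform(size=(200, 1))
        X = np.hstack([x, x, rng.uniform(size=(200, 1))])
        y = 8 * x[:, 0] + rng.normal(0, 0.5, 200)
        fit = fit_gaussian(X, y, cfg=FAST)
        counts = fit.split_count_draws.sum(axis=0)
        share0 = counts[0] / counts[:2].sum()
        assert 0.3 < share0 < 0.7

    def test_missing_values_rejected(self, rng):
        X = rng.uniform(size=(20, 2))
        y = rng.normal(size=20)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_gaussian(X, y, cfg=FAST)


class TestFitProbit:
    def test_sharp_threshold(self, rng):
        X = rng.uniform(size=(500, 5))
        z = (X[:, 0] > 0.5).astype(float)
        fit = fit_probit(X, z, cfg=FAST)
        p = fit.predict_mean(X)
        assert p[X[:, 0] > 0.6].mean() > 0.8
        assert p[X[:, 0] < 0.4].mean() < 0.2
        assert np.all((p > 0) & (p < 1))

    def test_null_model_matches_rate(self, rng):
        X = rng.uniform(size=(300, 4))
        z = (rng.uniform(size=300) < 0.3).astype(float)
        fit = fit_probit(X, z, cfg=FAST)
        assert fit.predict_mean(X).mean() == pytest.approx(z.mean(), abs=0.07)

    def test_single_class_degenerates_with_warning(self, rng):
        X = rng.uniform(size=(30, 2))
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_probit(X, np.ones(30), cfg=FAST)
        p = fit.predict_mean(X)
        assert np.all((p > 0) & (p <= 1))


class TestDartIntegration:
    def test_sparse_truth_concentrates_splits(self, rng):
        """With 1 of 20 predictors active, DART beats uniform-q split shares."""
        X = rng.uniform(size=(300, 20))
        y = 10 * X[:, 0] + rng.normal(0, 1, 300)
        uni = fit_gaussian(X, y, cfg=FAST)
        dart = fit_gaussian(X, y, DartPrior(20), cfg=FAST)
        share = lambda f: f.split_count_draws.sum(0)[0] / f.split_count_draws.sum()
        assert share(dart) > share(uni)
        assert share(dart) > 0.3
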