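import numpy as np
import pytest

from circpred.classifier import (
    GRID_POWERS,
    balanced_accuracy,
    fit,
    grid_search,
    iterate_label_feature,
)
from circpred.kernels import KernelSpec


@pytest.fixture(scope="module")
def separable_2d():
    rng = np.random.default_rng(0)
    X = np.vstack(
        [rng.normal(loc=-3, size=(15, 2)), rng.normal(loc=3, size=(15, 2))]
    )
    y = np.array([-1] * 15 + [1] * 15)
    return X, y


class TestFit:
    def test_separable_training_accuracy_is_one(self, separable_2d):
        X, y = separable_2d
        model = fit(X, y, KernelSpec("linear"), C=1.0)
        labels, _ = model.predict(X)
        assert np.array_equal(labels, y)

    def test_label_flip_negates_decision(self, separable_2d):
        X, y = separable_2d
        d1 = fit(X, y, KernelSpec("linear"), C=1.0).decision_function(X)
        d2 = fit(X, -y, KernelSpec("linear"), C=1.0).decision_function(X)
        assert np.allclose(d1, -d2, atol=1e-6)

    def test_dual_constraints_hold(self, separable_2d):
        X, y = separable_2d
        rng = np.random.default_rng(1)
        X = X + rng.normal(scale=2.5, size=X.shape)  # force some bounded alphas
        C = 0.5
        model = fit(X, y, KernelSpec("laplace"), C=C)
        assert abs(model.dual_coefs.sum()) < 1e-6  # sum alpha_i y_i = 0
        assert np.all(np.abs(model.dual_coefs) <= C + 1e-9)  # 0 <= alpha <= C

    def test_single_class_input_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError, match="both classes"):
            fit(X, np.ones(5, dtype=int), KernelSpec("linear"))

    def test_non_positive_C_rejected(self, separable_2d):
        X, y = separable_2d
        with pytest.raises(ValueError, match="C must be positive"):
            fit(X, y, KernelSpec("linear"), C=0.0)


class TestPredict:
    def test_probability_monotone_in_decision(self, separable_2d):
        X, y = separable_2d
        model = fit(X, y, KernelSpec("rbf"), C=1.0)
        d = model.decision_function(X)
        p = model.calibrator(d)
        order = np.argsort(d)
        assert np.all(np.diff(p[order]) >= 0)

    def test_true_class_probability_above_half_when_separable(self, separable_2d):
        X, y = separable_2d
        model = fit(X, y, KernelSpec("linear"), C=1.0)
        _, p = model.predict(X)
        p_true = np.where(y == 1, p, 1 - p)
        assert np.all(p_true > 0.5)

    def test_class_probabilities_complement(self, separable_2d):
        X, y = separable_2d
        model = fit(X, y, KernelSpec("linear"), C=1.0)
        _, p_pos = model.predict(X)
        assert np.allclose(p_pos + (1 - p_pos), 1.0)

    def test_deterministic(self, separable_2d):
        X, y = separable_2d
        model = fit(X, y, KernelSpec("laplace"), C=1.0)
        l1, p1 = model.predict(X)
        l2, p2 = model.predict(X)
        assert np.array_equal(l1, l2) and np.array_equal(p1, p2)

    def test_dimension_mismatch_rejected(self, separable_2d):
        X, y = separable_2d
        model = fit(X, y, KernelSpec("linear"))
        with pytest.raises(ValueError, match="features"):
            model.predict(np.zeros((3, 5)))


class TestGridSearch:
    def test_grid_contains_13_powers_of_two(self):
        assert len(GRID_POWERS) == 13
        assert [2.0**p for p in GRID_POWERS][0] == 2.0**-6
        assert [2.0**p for p in GRID_POWERS][-1] == 2.0**6

    def test_single_point_grid_returns_it(self, separable_2d):
        X, y = separable_2d
        res = grid_search(X, y, "rbf", folds=3, seed=0, powers=[0])
        assert res.gamma == 1.0 and res.C == 1.0
        assert len(res.table) == 1

    def test_linear_kernel_searches_C_only(self, separable_2d):
        X, y = separable_2d
        res = grid_search(X, y, "linear", folds=3, seed=0, powers=[-1, 0, 1])
        assert res.gamma is None
        assert len(res.table) == 3

    def test_noisy_labels_do_not_select_maximal_C(self):
        # 15% label noise: the largest C in the grid overfits, CV should
        # prefer something below it (oracle = the exhaustive table itself)
        rng = np.random.default_rng(4)
        X = np.vstack(
            [rng.normal(loc=-1.2, size=(40, 2)), rng.normal(loc=1.2, size=(40, 2))]
        )
        y = np.array([-1] * 40 + [1] * 40)
        flip = rng.choice(80, size=12, replace=False)
        y[flip] = -y[flip]
        res = grid_search(X, y, "rbf", folds=5, seed=0, powers=[0, 2, 6])
        assert res.C < 2.0**6
        best_in_table = max(res.table, key=lambda t: t[2])[2]
        assert res.score == best_in_table

    def test_tie_breaks_toward_smaller_C(self, separable_2d):
        X, y = separable_2d  # perfectly separable: every grid point scores 1.0
        res = grid_search(X, y, "linear", folds=3, seed=0, powers=[-2, 0, 2])
        assert res.C == 2.0**-2


class TestIterateLabelFeature:
    def test_zero_iterations_equals_plain_fit(self, separable_dataset):
        X, y = separable_dataset
        result = iterate_label_feature(X, y, KernelSpec("rbf"), max_iter=0, seed=0)
        plain = fit(X, y, KernelSpec("rbf"))
        assert result.n_features_final == X.shape[1]
        assert np.allclose(
            result.model.decision_function(X), plain.decision_function(X)
        )

    def test_feature_count_grows_by_one_per_iteration(self, null_dataset):
        X, y = null_dataset
        keep = np.r_[0:40, 100:140]  # 40 per class
        X, y = X[keep], y[keep]
        result = iterate_label_feature(
            X, y, KernelSpec("rbf"), max_iter=3, patience=10, folds=3, seed=0
        )
        assert len(result.trace) == 4  # base + 3 augmentations
        assert result.n_features_final == X.shape[1] + result.best_iteration

    def test_returns_best_iteration_model(self, separable_dataset):
        X, y = separable_dataset
        result = iterate_label_feature(
            X, y, KernelSpec("rbf"), max_iter=2, patience=5, folds=3, seed=0
        )
        assert result.trace[result.best_iteration] == result.trace.max()

    def test_patience_stops_early_on_plateau(self, separable_dataset):
        X, y = separable_dataset  # already at ceiling: no improvement possible
        result = iterate_label_feature(
            X, y, KernelSpec("laplace"), max_iter=50, patience=2, folds=3, seed=0
        )
        assert len(result.trace) <= 4  # base + at most patience+1 stalls


class TestBalancedAccuracy:
    def test_matches_mean_of_rates(self):
        y = np.array([1, 1, 1, 1, 1, -1, -1, -1, -1, -1])
        pred = np.array([1, 1, 1, 1, -1, -1, -1, 1, 1, 1])
        assert balanced_accuracy(y, pred) == pytest.approx((0.8 + 0.4) / 2)

    def test_single_class_reduces_to_that_rate(self):
        y = np.ones(4, dtype=int)
        pred = np.array([1, 1, -1, -1])
        assert balanced_accuracy(y, pred) == pytest.approx(0.5)
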