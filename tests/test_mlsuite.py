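"""ML comparators: fixed hyperparameters, determinism, and sanity oracles."""

import numpy as np
import pandas as pd
import pytest

from gbmprog.mlsuite import (
    MLConfig,
    RF_DEFAULTS,
    cv_attribute_search,
    pca_scores,
    predict,
    rf_feature_scores,
    rff_map,
    train_model,
)
from gbmprog.survstats import SurvivalSample, spearman


def linear_problem(n=120, n_features=4, seed=0, noise=0.0):
    """Survival-free regression toy: OS = linear score (+ noise)."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.uniform(size=(n, n_features)),
        columns=[f"f{i}" for i in range(n_features)],
    )
    w = np.arange(1, n_features + 1, dtype=float)
    y = X.to_numpy() @ w + 5.0 + noise * rng.normal(size=n)
    return X, SurvivalSample(np.maximum(y, 0.1), np.ones(n, bool))


class TestANN:
    @pytest.mark.parametrize("n_features,expected", [(4, 2), (44, 22), (1, 1)])
    def test_hidden_layer_size_rule(self, n_features, expected):
        X, s = linear_problem(n=60, n_features=n_features)
        model = train_model(MLConfig(kind="ann", seed=0), X, s)
        assert model.inner.n_hidden == expected

    def test_loss_decreases_on_linear_toy(self):
        X, s = linear_problem(n=80, n_features=1, seed=3)
        model = train_model(MLConfig(kind="ann", seed=3), X, s)
        traj = model.inner.loss_trajectory
        assert len(traj) == 201  # 200 iterations + final evaluation
        assert traj[-1] < traj[0]

    def test_fixed_seed_bit_identical_weights(self):
        X, s = linear_problem(seed=5)
        a = train_model(MLConfig(kind="ann", seed=9), X, s)
        b = train_model(MLConfig(kind="ann", seed=9), X, s)
        assert np.array_equal(a.inner.w1, b.inner.w1)
        assert np.array_equal(a.inner.w2, b.inner.w2)


class TestSVRAndTree:
    def test_constant_target_predicted_within_epsilon(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"a": rng.uniform(size=50), "b": rng.uniform(size=50)})
        s = SurvivalSample(np.full(50, 12.0), np.ones(50, bool))
        for kind in ("svr_rbf", "regression_tree"):
            model = train_model(MLConfig(kind=kind, seed=0), X, s)
            pred = model.predict(X)
            assert np.allclose(pred, 12.0, atol=0.05), kind
        # the SGD-trained RFF head carries ridge shrinkage, so it only
        # approaches the constant
        rff = train_model(MLConfig(kind="svr_rff", seed=0), X, s)
        assert np.allclose(rff.predict(X), 12.0, rtol=0.05)
        tree = train_model(MLConfig(kind="regression_tree", seed=0), X, s)
        assert tree.inner.root.is_leaf

    def test_tree_depth_capped(self):
        X, s = linear_problem(n=300, seed=8, noise=0.5)
        model = train_model(MLConfig(kind="regression_tree", seed=1), X, s)

        def depth(node):
            if node.is_leaf:
                return 0
            return 1 + max(depth(node.left), depth(node.right))

        assert 1 <= depth(model.inner.root) <= 5

    def test_rff_predictions_track_truth_on_noise_free_problem(self):
        X, s = linear_problem(n=150, seed=4)
        model = train_model(MLConfig(kind="svr_rff", seed=4), X, s)
        rho, _ = spearman(model.predict(X), s.times)
        assert rho > 0.9


class TestRFFMap:
    def test_inner_products_approximate_gaussian_kernel(self):
        rng = np.random.default_rng(6)
        _, _, transform = rff_map(4, 200, 1.0, seed=6)
        A, B = rng.uniform(size=(2, 100, 4))
        approx = (transform(A) * transform(B)).sum(axis=1)
        exact = np.exp(-((A - B) ** 2).sum(axis=1))
        assert np.abs(approx - exact).mean() < 0.1

    def test_map_is_seed_deterministic(self):
        W1, b1, _ = rff_map(3, 50, 1.0, seed=1)
        W2, b2, _ = rff_map(3, 50, 1.0, seed=1)
        assert np.array_equal(W1, W2) and np.array_equal(b1, b2)


class TestTrainingContract:
    def test_censored_rows_never_enter_training(self):
        X, s = linear_problem(n=100, seed=7)
        events = s.events.copy()
        events[50:] = False
        s_cens = SurvivalSample(s.times, events)
        times_perturbed = s.times.copy()
        times_perturbed[50:] = 999.0  # censored times wildly different
        s_pert = SurvivalSample(times_perturbed, events)
        for kind in ("ann", "svr_rbf", "svr_rff", "regression_tree"):
            a = train_model(MLConfig(kind=kind, seed=0), X, s_cens)
            b = train_model(MLConfig(kind=kind, seed=0), X, s_pert)
            assert np.array_equal(a.predict(X), b.predict(X)), kind

    def test_schema_mismatch_rejected_by_name(self):
        X, s = linear_problem()
        model = train_model(MLConfig(kind="ann", seed=0), X, s)
        with pytest.raises(ValueError, match="f0"):
            predict(model, X.drop(columns=["f0"]))

    def test_empty_row_prediction(self):
        X, s = linear_problem()
        model = train_model(MLConfig(kind="svr_rbf", seed=0), X, s)
        assert predict(model, X.iloc[:0]).shape == (0,)

    def test_no_features_rejected(self):
        X, s = linear_problem()
        with pytest.raises(ValueError):
            train_model(MLConfig(kind="ann", seed=0), X.iloc[:, :0], s)


class TestRFFeatureScores:
    def test_pure_noise_rarely_qualifies(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(200, 6)),
                         columns=[f"n{i}" for i in range(6)])
        s = SurvivalSample(rng.exponential(12, 200) + 0.1, np.ones(200, bool))
        scores, q = rf_feature_scores(X, s, n_iterations=200, seed=0)
        assert q <= 10
        assert scores.sum() <= q  # importances sum to <= 1 per forest

    def test_informative_features_hold_top_scores(self):
        hits = 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            n = 400
            signal = pd.DataFrame(
                rng.uniform(size=(n, 4)), columns=list("abcd"))
            noise = pd.DataFrame(
                rng.normal(size=(n, 8)), columns=[f"z{i}" for i in range(8)])
            X = pd.concat([signal, noise], axis=1)
            y = 10 + 8 * signal.sum(axis=1) + 0.5 * rng.normal(size=n)
            s = SurvivalSample(y.to_numpy(), np.ones(n, bool))
            scores, q = rf_feature_scores(X, s, n_iterations=150, seed=seed)
            assert q > 0
            top4 = set(scores.sort_values(ascending=False).index[:4])
            hits += top4 == set("abcd")
        assert hits >= 2

    def test_printed_forest_defaults(self):
        assert RF_DEFAULTS == {
            "n_estimators": 10,
            "max_depth": 5,
            "min_samples_leaf": 20,
            "min_samples_split": 40,
            "min_impurity_decrease": 0.1,
        }


class TestCVAttributeSearch:
    def test_single_candidate_returned_with_stats(self):
        X, s = linear_problem(n=120, seed=2, noise=1.0)
        res = cv_attribute_search(
            [("f0", "f1")], X, s, n_folds=4, holdout_size=30, seed=0)
        assert res.best_subset == ("f0", "f1")
        assert 0 <= res.mean_cindex <= 1
        assert res.mean_rmse > 0

    def test_fold_bookkeeping(self):
        rng = np.random.default_rng(3)
        n = 311
        X = pd.DataFrame({"a": rng.uniform(size=n), "b": rng.uniform(size=n)})
        s = SurvivalSample(rng.exponential(12, n) + 0.1,
                           rng.uniform(size=n) > 0.1)
        res = cv_attribute_search([("a", "b")], X, s,
                                  n_folds=20, holdout_size=50, seed=1)
        assert len(res.folds) == 20
        for fold in res.folds:
            assert len(fold) == 50
            assert len(np.unique(fold)) == 50  # held-out disjoint from train

    def test_dominant_subset_wins_across_seeds(self):
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed + 50)
            n = 160
            X = pd.DataFrame({
                "good1": rng.uniform(size=n),
                "good2": rng.uniform(size=n),
                "junk1": rng.normal(size=n),
                "junk2": rng.normal(size=n),
            })
            y = 5 + 10 * X["good1"] + 10 * X["good2"] + 0.3 * rng.normal(size=n)
            s = SurvivalSample(y.to_numpy(), np.ones(n, bool))
            res = cv_attribute_search(
                [("good1", "good2"), ("junk1", "junk2")], X, s,
                n_folds=5, holdout_size=40, seed=seed)
            wins += res.best_subset == ("good1", "good2")
        assert wins >= 4

    def test_small_cohort_rejected(self):
        X, s = linear_problem(n=30)
        with pytest.raises(ValueError, match="holdout"):
            cv_attribute_search([("f0",)], X, s, n_folds=2, holdout_size=50)


class TestPCA:
    def test_components_orthonormal_and_reconstruction_exact(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(40, 5)),
                         columns=[f"v{i}" for i in range(5)])
        res = pca_scores(X)
        C = res["components"]
        assert np.allclose(C @ C.T, np.eye(C.shape[0]), atol=1e-10)
        Z = (X - X.mean()) / X.std(ddof=0)
        back = res["scores"] @ C
        assert np.allclose(back, Z.to_numpy(), atol=1e-10)

    def test_leading_axis_matches_analytic_eigenvector(self):
        rng = np.random.default_rng(12)
        z = rng.normal(size=4000)
        # correlated pair: leading standardized eigenvector is (1,1)/sqrt(2)
        X = pd.DataFrame({"x": z + 0.3 * rng.normal(size=4000),
                          "y": z + 0.3 * rng.normal(size=4000)})
        res = pca_scores(X)
        lead = res["components"][0]
        expected = np.array([1.0, 1.0]) / np.sqrt(2)
        assert np.allclose(np.abs(lead), expected, atol=0.02)

    def test_constant_column_dropped_with_warning(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="flat"):
            res = pca_scores(X)
        assert res["feature_names"] == ["a"]
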