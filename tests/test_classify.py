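"""Classifier stack: pruning, grid search, LOOCV, metrics, permutation."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import cohen_kappa_score, roc_auc_score
from sklearn.pipeline import Pipeline

from rehoflow import classify


def _corr_features(rng, n, cov):
    L = np.linalg.cholesky(cov)
    return rng.standard_normal((n, cov.shape[0])) @ L.T


class TestCollinearityPruner:
    def test_uncorrelated_table_untouched(self, rng):
        X = rng.standard_normal((200, 4))
        pruner = classify.CollinearityPruner(0.75).fit(X)
        assert list(pruner.kept_columns_) == [0, 1, 2, 3]

    def test_duplicate_feature_dropped_once(self, rng):
        x = rng.standard_normal(50)
        X = np.column_stack([x, x, rng.standard_normal(50)])
        pruner = classify.CollinearityPruner(0.75).fit(X)
        assert len(pruner.kept_columns_) == 2 and 2 in pruner.kept_columns_

    def test_hand_worked_three_feature_case(self, rng):
        # r(1,2)=0.9, r(1,3)=0.8, r(2,3)=0.5: the (1,2) pair exceeds the
        # threshold first and feature 1 has the larger mean absolute
        # correlation (0.85 vs 0.70), so it is dropped; the survivors (2,3)
        # correlate at 0.5 < 0.75 and the iteration stops
        cov = np.array([[1.0, 0.9, 0.8], [0.9, 1.0, 0.5], [0.8, 0.5, 1.0]])
        X = _corr_features(rng, 4000, cov)
        pruner = classify.CollinearityPruner(0.75).fit(X)
        assert list(pruner.kept_columns_) == [1, 2]

    def test_pruned_table_below_threshold(self, rng):
        for trial in range(10):
            r = np.random.default_rng(trial)
            A = r.standard_normal((60, 3))
            X = np.column_stack([A, A @ r.standard_normal((3, 4)) + 0.3 * r.standard_normal((60, 4))])
            out = classify.CollinearityPruner(0.75).fit(X).transform(X)
            if out.shape[1] >= 2:
                c = np.abs(np.corrcoef(out, rowvar=False))
                np.fill_diagonal(c, 0)
                assert c.max() <= 0.75 + 1e-12

    def test_functional_wrapper_keeps_names(self, rng):
        x = rng.standard_normal(50)
        df = pd.DataFrame({"a": x, "b": x * 2, "c": rng.standard_normal(50)})
        out = classify.prune_collinear(df)
        assert list(out.columns) == ["a", "c"]

    def test_sklearn_compatibility(self, rng):
        X = rng.standard_normal((40, 3))
        y = (rng.random(40) < 0.5).astype(int)
        pipe = Pipeline([("prune", classify.CollinearityPruner(0.9)),
                         ("lr", LogisticRegression())])
        clone(pipe).fit(X, y).predict(X)
        assert classify.CollinearityPruner().get_params() == {"threshold": 0.75}


class TestGridSearch:
    def test_single_point_grid_selected(self, rng):
        X = rng.standard_normal((20, 2))
        y = np.r_[np.ones(10), np.zeros(10)]
        best, _ = classify.grid_search_logistic(X, y, grid=(0.3,))
        assert best == 0.3

    def test_separable_data_perfect_loocv(self):
        X = np.r_[np.zeros((6, 1)), np.ones((6, 1)) + 3]
        y = np.r_[np.ones(6), np.zeros(6)]
        clf = classify.PrunedLogisticClassifier().fit(X, y)
        assert clf.cv_accuracy_ == 1.0

    def test_null_labels_near_chance(self, rng):
        X = rng.standard_normal((40, 2))
        y = np.r_[np.ones(20), np.zeros(20)]
        _, acc = classify.grid_search_logistic(X, y)
        assert 0.2 <= acc <= 0.8

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            classify.PrunedLogisticClassifier().fit(rng.standard_normal((10, 2)), np.ones(10))

    def test_estimator_api(self, rng):
        clf = classify.PrunedLogisticClassifier(threshold=0.8)
        assert clone(clf).get_params()["threshold"] == 0.8
        X = rng.standard_normal((30, 2))
        y = np.r_[np.ones(15), np.zeros(15)]
        clf.fit(X, y)
        assert hasattr(clf, "best_c_") and hasattr(clf, "model_")
        assert clf.predict(X).shape == (30,)
        assert clf.predict_proba(X).shape == (30, 2)


class TestIrlsCore:
    def test_matches_sklearn_solution(self, rng):
        X = rng.standard_normal((50, 3))
        y01 = (rng.random(50) < 0.5).astype(float)
        Xs = (X - X.mean(0)) / X.std(0)
        for C in (0.01, 1.0, 10.0):
            w = classify._logistic_irls(Xs, y01, C)
            sk = LogisticRegression(C=C, max_iter=5000, tol=1e-10).fit(Xs, y01)
            assert np.abs(np.r_[sk.coef_[0], sk.intercept_] - w).max() < 1e-6


class TestLoocv:
    def test_tiny_separable_all_correct(self):
        X = np.array([[0.0], [0.1], [5.0], [5.1]])
        y = np.array([1, 1, 2, 2])
        preds, scores = classify.loocv_evaluate(X, y, C=1.0)
        assert np.array_equal(preds, y)

    def test_null_accuracy_near_half(self, rng):
        X = rng.standard_normal((40, 2))
        y = np.r_[np.ones(20, int), np.full(20, 2)]
        preds, _ = classify.loocv_evaluate(X, y, C=1.0)
        acc = (preds == y).mean()
        assert 0.2 <= acc <= 0.8

    def test_subject_order_invariance(self, rng):
        X = rng.standard_normal((24, 3)) + np.r_[np.ones(12), np.zeros(12)][:, None]
        y = np.r_[np.ones(12, int), np.full(12, 2)]
        preds, scores = classify.loocv_evaluate(X, y, C=1.0)
        perm = rng.permutation(24)
        preds_p, scores_p = classify.loocv_evaluate(X[perm], y[perm], C=1.0)
        assert np.array_equal(preds_p, preds[perm])
        assert np.allclose(scores_p, scores[perm], atol=1e-9)

    def test_honest_mode_runs_nested_selection(self, rng):
        X = rng.standard_normal((16, 2)) + np.r_[np.ones(8), np.zeros(8)][:, None] * 2
        y = np.r_[np.ones(8, int), np.full(8, 2)]
        preds, _ = classify.loocv_evaluate(X, y, honest=True, c_grid=(0.1, 1.0))
        assert (preds == y).mean() > 0.7

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            classify.loocv_evaluate(np.zeros((2, 1)), np.array([1, 2]))


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1, 1, 2, 2])
        rep = classify.compute_metrics(y, np.array([0.9, 0.8, 0.1, 0.2]), y)
        assert (rep.auc, rep.accuracy, rep.sensitivity, rep.specificity, rep.kappa) == \
            (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_hand_worked_confusion(self):
        # TP=40 FN=10 TN=35 FP=15: acc .75, sens .8, spec .7, kappa .5
        y = np.array([1] * 50 + [2] * 50)
        preds = np.array([1] * 40 + [2] * 10 + [1] * 15 + [2] * 35)
        scores = (preds == 1).astype(float)
        rep = classify.compute_metrics(preds, scores, y)
        assert rep.accuracy == pytest.approx(0.75)
        assert rep.sensitivity == pytest.approx(0.8)
        assert rep.specificity == pytest.approx(0.7)
        assert rep.kappa == pytest.approx(0.5)
        assert rep.kappa == pytest.approx(
            cohen_kappa_score(y, preds), abs=1e-12)

    def test_constant_scores_give_half_auc(self, rng):
        y = np.r_[np.ones(10, int), np.full(10, 2)]
        rep = classify.compute_metrics(y, np.ones(20), y)
        assert rep.auc == pytest.approx(0.5)

    def test_auc_equals_mann_whitney_identity(self, rng):
        y = np.r_[np.ones(30, int), np.full(25, 2)]
        scores = rng.standard_normal(55) + (y == 1) * 0.8
        rep = classify.compute_metrics(np.where(scores > 0.4, 1, 2), scores, y)
        U = stats.mannwhitneyu(scores[y == 1], scores[y == 2]).statistic
        assert rep.auc == pytest.approx(U / (30 * 25), abs=1e-12)
        assert rep.auc == pytest.approx(roc_auc_score(y == 1, scores), abs=1e-12)

    def test_auc_with_tied_scores_matches_sklearn(self, rng):
        y = np.r_[np.ones(20, int), np.full(20, 2)]
        scores = rng.integers(0, 4, 40).astype(float)
        rep = classify.compute_metrics(np.where(scores > 1, 1, 2), scores, y)
        assert rep.auc == pytest.approx(roc_auc_score(y == 1, scores), abs=1e-12)


class TestPermutationTest:
    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((16, 2))
        y = np.r_[np.ones(8, int), np.full(8, 2)]
        p1 = classify.permutation_test(X, y, n_perm=49, seed=3, c_grid=(1.0,))
        p2 = classify.permutation_test(X, y, n_perm=49, seed=3, c_grid=(1.0,))
        assert p1 == p2

    def test_separable_signal_hits_floor(self):
        X = np.r_[np.zeros((8, 1)), np.ones((8, 1)) + 4]
        y = np.r_[np.ones(8, int), np.full(8, 2)]
        p = classify.permutation_test(X, y, n_perm=99, seed=0, c_grid=(1.0,))
        assert p == pytest.approx(1 / 100)

    def test_gaussian_class_separation_auc(self):
        """LOOCV AUC tracks the analytic two-Gaussian value Phi(d/sqrt(2)).

        At d=0 leave-one-out scores are anti-correlated with the left-out
        label (the well-known LOOCV pessimism), so the null check only
        asserts the AUC stays at or below chance.
        """
        from scipy.stats import norm

        def mean_auc(d):
            aucs = []
            for rep in range(6):
                r = np.random.default_rng(50 + rep)
                X = np.concatenate([r.standard_normal(48) + d, r.standard_normal(47)])[:, None]
                y = np.r_[np.ones(48, int), np.full(47, 2)]
                preds, scores = classify.loocv_evaluate(X, y, C=1.0)
                aucs.append(classify.compute_metrics(preds, scores, y).auc)
            return float(np.mean(aucs))

        assert mean_auc(2.0) == pytest.approx(norm.cdf(2 / np.sqrt(2)), abs=0.05)
        assert mean_auc(1.0) == pytest.approx(norm.cdf(1 / np.sqrt(2)), abs=0.06)
        assert mean_auc(0.0) <= 0.55


class TestAssembleFeatures:
    def test_constant_map_gives_constant_feature(self):
        cmask = np.zeros((3, 3, 3), bool)
        cmask[1, 1, 1] = True
        maps = [[np.full((3, 3, 3), 2.5)]]
        out = classify.assemble_features(maps, [cmask], ["c1"])
        assert out.loc[0, "c1"] == 2.5

    def test_matches_loop_oracle(self, rng):
        masks = [rng.random((4, 4, 4)) < 0.3 for _ in range(2)]
        masks = [m | ~m.any() for m in masks]
        subject_maps = [[rng.standard_normal((4, 4, 4)) for _ in range(2)] for _ in range(2)]
        out = classify.assemble_features(subject_maps, masks)
        for s in range(2):
            for j, m in enumerate(masks):
                assert out.iloc[s, j] == pytest.approx(subject_maps[s][j][m].mean())

    def test_empty_cluster_list_rejected(self):
        with pytest.raises(ValueError):
            classify.assemble_features([], [])
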