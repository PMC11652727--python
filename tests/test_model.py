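"""SMOTE, variance filter, standardization, nested CV and bootstrap CIs."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from mammoread.model import (ModelConfig, ModelResult, Standardizer,
                             accuracy_at_threshold, bootstrap_auc_ci,
                             compare_aucs, nested_cv, smote_oversample,
                             standardize, variance_filter)


class TestSMOTE:
    def test_balances_class_counts(self, rng):
        X = rng.normal(size=(13, 4))
        y = np.array([0] * 10 + [1] * 3)
        X2, y2 = smote_oversample(X, y, k=2, seed=0)
        assert (y2 == 0).sum() == 10 and (y2 == 1).sum() == 10
        # originals preserved verbatim
        assert np.array_equal(X2[:13], X)

    def test_synthetic_rows_inside_minority_coordinate_hull(self, rng):
        X = rng.normal(size=(20, 5))
        y = np.array([0] * 14 + [1] * 6)
        X2, y2 = smote_oversample(X, y, k=3, seed=1)
        minority = X[y == 1]
        new = X2[20:]
        lo, hi = minority.min(axis=0), minority.max(axis=0)
        assert (new >= lo - 1e-12).all() and (new <= hi + 1e-12).all()

    def test_deterministic_for_fixed_seed(self, rng):
        X = rng.normal(size=(12, 3))
        y = np.array([0] * 9 + [1] * 3)
        a, _ = smote_oversample(X, y, seed=7)
        b, _ = smote_oversample(X, y, seed=7)
        assert np.array_equal(a, b)

    def test_small_minority_reduces_neighbours_with_warning(self, rng):
        X = rng.normal(size=(12, 3))
        y = np.array([0] * 9 + [1] * 3)
        with pytest.warns(UserWarning, match="reducing SMOTE"):
            X2, y2 = smote_oversample(X, y, k=5, seed=0)
        assert (y2 == 1).sum() == 9

    def test_singleton_minority_duplicates_with_jitter(self, rng):
        X = rng.normal(size=(5, 3))
        y = np.array([0, 0, 0, 0, 1])
        with pytest.warns(UserWarning, match="singleton"):
            X2, y2 = smote_oversample(X, y, seed=0)
        assert (y2 == 1).sum() == 4
        assert np.allclose(X2[5:], X[4], atol=1e-3)

    def test_balanced_input_unchanged(self, rng):
        X = rng.normal(size=(6, 2))
        y = np.array([0, 0, 0, 1, 1, 1])
        X2, y2 = smote_oversample(X, y, seed=0)
        assert np.array_equal(X2, X) and np.array_equal(y2, y)


class TestVarianceFilter:
    def test_threshold_is_strict(self):
        X = np.array([[0.0, 0.0], [1.0, 4.0], [2.0, 8.0]])
        # variances: 2/3 and 32/3
        keep = variance_filter(X, threshold=1.0)
        assert list(keep) == [1]

    def test_zero_variance_feature_removed(self, rng):
        X = np.column_stack([np.full(10, 3.0), rng.normal(0, 5, 10)])
        assert list(variance_filter(X)) == [1]

    def test_empty_selection_falls_back_to_all(self, rng):
        X = rng.normal(0, 0.1, size=(10, 4))
        with pytest.warns(UserWarning, match="keeping all"):
            keep = variance_filter(X, threshold=1.0)
        assert list(keep) == [0, 1, 2, 3]


class TestStandardize:
    def test_train_statistics_and_roundtrip(self, rng):
        train = rng.normal(3, 2, size=(30, 5))
        test = rng.normal(3, 2, size=(10, 5))
        z_train, z_test, scaler = standardize(train, test)
        assert np.allclose(z_train.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z_train.std(axis=0), 1, atol=1e-12)
        assert np.allclose(scaler.inverse_transform(z_test), test, atol=1e-9)

    def test_zero_sd_feature_maps_to_zero(self):
        train = np.array([[1.0, 2.0], [1.0, 4.0]])
        z = Standardizer.fit(train).transform(np.array([[5.0, 3.0]]))
        assert z[0, 0] == 0.0


class TestNoLeakage:
    """Transforms fitted inside a split must ignore held-out rows."""

    def test_nan_poisoned_test_rows_change_nothing(self, rng):
        X = rng.normal(0, 2, size=(30, 8))
        y = np.array([0] * 20 + [1] * 10)
        train_idx = np.arange(0, 24)
        test_idx = np.arange(24, 30)
        Xp = X.copy()
        Xp[test_idx] = np.nan

        keep_a = variance_filter(X[train_idx])
        keep_b = variance_filter(Xp[train_idx])
        assert np.array_equal(keep_a, keep_b)

        sa = Standardizer.fit(X[train_idx][:, keep_a])
        sb = Standardizer.fit(Xp[train_idx][:, keep_b])
        assert np.array_equal(sa.mean, sb.mean)
        assert np.array_equal(sa.sd, sb.sd)

        Xa, ya = smote_oversample(X[train_idx], y[train_idx], seed=3)
        Xb, yb = smote_oversample(Xp[train_idx], y[train_idx], seed=3)
        assert np.array_equal(Xa, Xb) and np.array_equal(ya, yb)


class TestBootstrap:
    def test_perfect_scores_give_degenerate_ci(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        scores = np.array([0.1, 0.2, 0.3, 0.8, 0.9, 1.0])
        auc, lo, hi, _ = bootstrap_auc_ci(y, scores, reps=200, seed=0)
        assert auc == 1.0 and lo == 1.0 and hi == 1.0

    def test_point_estimate_equals_mann_whitney_statistic(self, rng):
        y = np.array([0] * 12 + [1] * 8)
        scores = rng.normal(size=20)
        auc, *_ = bootstrap_auc_ci(y, scores, reps=10, seed=0)
        u = mannwhitneyu(scores[y == 1], scores[y == 0],
                         alternative="two-sided").statistic
        assert auc == pytest.approx(u / (12 * 8))

    def test_interval_narrows_with_sample_size(self, rng):
        def width(n, seed):
            y = np.array([0] * n + [1] * n)
            scores = np.concatenate([rng.normal(0, 1, n),
                                     rng.normal(1.2, 1, n)])
            _, lo, hi, _ = bootstrap_auc_ci(y, scores, reps=400, seed=seed)
            return hi - lo

        assert width(200, 1) < width(20, 2)


class TestCompare:
    def make_result(self, auc, boots):
        return ModelResult(scores=np.zeros(4), y=np.zeros(4), auc=auc,
                           auc_ci=(0, 1), accuracy=0.5, chosen_trees=[],
                           top_features=[], feature_names=[],
                           bootstrap_aucs=np.asarray(boots))

    def test_identical_results_give_z0_p1(self, rng):
        boots = rng.normal(0.8, 0.02, 500)
        a = self.make_result(0.8, boots)
        z, p = compare_aucs(a, self.make_result(0.8, boots))
        assert z == 0.0 and p == 1.0

    def test_large_separation_is_significant(self, rng):
        a = self.make_result(0.9, rng.normal(0.9, 0.005, 500))
        b = self.make_result(0.5, rng.normal(0.5, 0.005, 500))
        z, p = compare_aucs(a, b)
        assert p < 0.001 and z > 0

    def test_antisymmetry(self, rng):
        a = self.make_result(0.85, rng.normal(0.85, 0.02, 300))
        b = self.make_result(0.70, rng.normal(0.70, 0.03, 300))
        z_ab, p_ab = compare_aucs(a, b)
        z_ba, p_ba = compare_aucs(b, a)
        assert z_ab == pytest.approx(-z_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_missing_bootstrap_rejected(self):
        a = self.make_result(0.8, np.array([0.8]))
        a.bootstrap_aucs = None
        with pytest.raises(ValueError):
            compare_aucs(a, a)


class TestAccuracy:
    def test_all_correct_and_all_wrong(self):
        y = np.array([0, 1, 0, 1])
        assert accuracy_at_threshold(y, [0.1, 0.9, 0.2, 0.8]) == 1.0
        assert accuracy_at_threshold(y, [0.9, 0.1, 0.8, 0.2]) == 0.0

    def test_hand_counted_six_sample_case(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        scores = np.array([0.2, 0.6, 0.4, 0.7, 0.3, 0.9])
        # predictions at 0.5: [0,1,0,1,0,1] -> 4 correct
        assert accuracy_at_threshold(y, scores) == pytest.approx(4 / 6)


class TestNestedCV:
    def test_perfectly_separable_data_scores_auc_one(self, rng):
        n = 14
        X = np.column_stack([
            np.concatenate([rng.normal(0, 1, n), rng.normal(12, 1, n)]),
            rng.normal(0, 3, 2 * n)])
        y = np.array([0] * n + [1] * n)
        cfg = ModelConfig(tree_grid=(10,), inner_repeats=1,
                          bootstrap_reps=50, seed=0)
        res = nested_cv(X, y, cfg)
        assert res.auc == 1.0
        assert len(res.scores) == 2 * n  # leave-one-out: one score each
        assert len(res.chosen_trees) == 2 * n
        assert all(t == 10 for t in res.chosen_trees)
        assert all(len(tf) <= 10 for tf in res.top_features)

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(16, 6))
        y = np.array([0] * 10 + [1] * 6)
        cfg = ModelConfig(tree_grid=(10, 25), inner_repeats=1,
                          bootstrap_reps=50, seed=5)
        a = nested_cv(X, y, cfg)
        b = nested_cv(X, y, cfg)
        assert np.array_equal(a.scores, b.scores)
        assert a.chosen_trees == b.chosen_trees

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            nested_cv(rng.normal(size=(8, 3)), np.zeros(8), ModelConfig())


def test_model_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(tree_grid=())
    with pytest.raises(ValueError):
        ModelConfig(inner_folds=1)
    with pytest.raises(ValueError):
        ModelConfig(bootstrap_reps=0)
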