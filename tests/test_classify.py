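"""Cross-validated classification: folds, scaling hygiene, metric identities."""

import numpy as np
import pytest

from mammofract.classify import (
    Metrics,
    confusion_metrics,
    evaluate_cv,
    standardize,
    stratified_kfold,
    train_predict,
)


def two_gaussians(n_per_class=200, sep=8.0, seed=0, d=4):
    """Well-separated binary fixture: abnormal at +sep/2, normal at -sep/2."""
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [
            rng.normal(+sep / 2, 1.0, size=(n_per_class, d)),
            rng.normal(-sep / 2, 1.0, size=(n_per_class, d)),
        ]
    )
    y = np.array(["abnormal"] * n_per_class + ["normal"] * n_per_class)
    return X, y


class TestStratifiedKFold:
    def test_balanced_folds(self):
        y = np.array(["abnormal"] * 5 + ["normal"] * 5)
        fa = stratified_kfold(y, 5, seed=0)
        for fold in range(5):
            members = y[fa.fold_of == fold]
            assert sorted(members) == ["abnormal", "normal"]

    def test_deterministic(self):
        y = np.array(["abnormal"] * 20 + ["normal"] * 20)
        np.testing.assert_array_equal(
            stratified_kfold(y, 5, seed=3).fold_of, stratified_kfold(y, 5, seed=3).fold_of
        )

    def test_small_class_rejected(self):
        y = np.array(["abnormal"] * 3 + ["normal"] * 10)
        with pytest.raises(ValueError, match="fewer than k"):
            stratified_kfold(y, 5)


class TestStandardize:
    def test_train_moments(self, rng):
        X = rng.normal(3.0, 2.0, size=(50, 4))
        tr, _, _ = standardize(X)
        np.testing.assert_allclose(tr.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(tr.std(axis=0), 1.0, atol=1e-12)

    def test_constant_column_passthrough(self, rng):
        X = rng.normal(size=(20, 3))
        X[:, 1] = 7.0
        tr, _, params = standardize(X)
        np.testing.assert_array_equal(tr[:, 1], 7.0)
        assert 1 in params["constant_columns"]

    def test_test_set_uses_train_params(self, rng):
        train = rng.normal(0.0, 1.0, size=(100, 2))
        test = train[:10] + 5.0  # shifted copy
        _, te, _ = standardize(train, test)
        # if test were scaled by its own stats its mean would be ~0
        assert te.mean() > 3.0

    def test_nan_imputed_with_train_median(self):
        train = np.array([[1.0], [2.0], [3.0], [np.nan]])
        other = np.array([[np.nan]])
        tr, ot, params = standardize(train, other)
        assert np.isfinite(tr).all() and np.isfinite(ot).all()
        assert params["median"][0] == 2.0


class TestTrainPredict:
    @pytest.mark.parametrize("model", ["svm_poly2", "knn", "dtree"])
    def test_separable_fixture_is_perfect(self, model):
        X, y = two_gaussians(50, seed=1)
        tr, te, _ = standardize(X, X)
        pred = train_predict(model, tr, y, te, seed=0)
        assert (pred == y).all()

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError, match="binary labels"):
            train_predict("svm_poly2", X, ["normal"] * 10, X)

    def test_unknown_model_rejected(self):
        X, y = two_gaussians(10)
        with pytest.raises(ValueError, match="unknown model"):
            train_predict("mlp", X, y, X)

    def test_deterministic(self):
        X, y = two_gaussians(30, sep=1.0, seed=5)
        a = train_predict("svm_poly2", X, y, X, seed=2)
        b = train_predict("svm_poly2", X, y, X, seed=2)
        np.testing.assert_array_equal(a, b)


class TestConfusionMetrics:
    def test_printed_formula_example(self):
        m = Metrics(TP=98, FN=2, TN=97, FP=3)
        assert m.sensitivity == pytest.approx(98.0)
        assert m.specificity == pytest.approx(97.0)
        assert m.accuracy == pytest.approx(97.5)
        assert m.precision == pytest.approx(100.0 * 98 / 101)

    def test_all_correct(self):
        y = ["abnormal", "normal", "abnormal"]
        m = confusion_metrics(y, y)
        assert (m.sensitivity, m.specificity, m.accuracy) == (100.0, 100.0, 100.0)

    def test_no_positive_truth_undefined_sensitivity(self):
        m = confusion_metrics(["normal", "normal"], ["normal", "abnormal"])
        assert np.isnan(m.sensitivity)

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            confusion_metrics(["abnormal", "weird"], ["normal", "normal"])

    def test_counts_from_labels(self):
        yt = ["abnormal"] * 4 + ["normal"] * 6
        yp = ["abnormal", "abnormal", "normal", "normal"] + ["normal"] * 5 + ["abnormal"]
        m = confusion_metrics(yt, yp)
        assert (m.TP, m.FN, m.TN, m.FP) == (2, 2, 5, 1)


class TestEvaluateCV:
    def test_pooled_counts_conserve_dataset(self):
        X, y = two_gaussians(50, sep=2.0, seed=3)
        rep = evaluate_cv(X, y, "knn", k=5, seed=0)
        assert rep.pooled.total == 100
        assert sum(m.total for m in rep.folds) == 100
        for name in ("TP", "FP", "TN", "FN"):
            assert getattr(rep.pooled, name) == sum(getattr(m, name) for m in rep.folds)

    def test_separable_fixture_100_percent(self):
        X, y = two_gaussians(50, seed=7)
        for model in ("svm_poly2", "knn", "dtree"):
            rep = evaluate_cv(X, y, model, k=5, seed=0)
            assert rep.pooled.accuracy == 100.0

    def test_shuffled_labels_at_chance(self):
        rng = np.random.default_rng(11)
        X, y = two_gaussians(200, sep=6.0, seed=11)
        y_shuffled = rng.permutation(y)
        rep = evaluate_cv(X, y_shuffled, "svm_poly2", k=5, seed=0)
        sd = 100 * 0.5 / np.sqrt(400)
        assert abs(rep.pooled.accuracy - 50.0) <= 3 * sd

    def test_accuracy_identity(self):
        X, y = two_gaussians(40, sep=1.5, seed=9)
        rep = evaluate_cv(X, y, "dtree", k=4, seed=2)
        m = rep.pooled
        P, N = m.TP + m.FN, m.TN + m.FP
        assert m.accuracy == pytest.approx((m.sensitivity * P + m.specificity * N) / (P + N))

    def test_deterministic(self):
        X, y = two_gaussians(30, sep=1.0, seed=5)
        a = evaluate_cv(X, y, "svm_poly2", k=5, seed=4)
        b = evaluate_cv(X, y, "svm_poly2", k=5, seed=4)
        assert a.as_dict() == b.as_dict()

    def test_no_leakage_from_test_outlier(self):
        """An extreme held-out point must not move the train-fold scaler."""
        X, y = two_gaussians(25, sep=4.0, seed=6)
        fa = stratified_kfold(y, 5, seed=0)
        test_mask = fa.fold_of == 0
        Xmod = X.copy()
        idx = np.nonzero(test_mask)[0][0]
        Xmod[idx] = 1e6
        _, _, p_ref = standardize(X[~test_mask])
        _, _, p_mod = standardize(Xmod[~test_mask], Xmod[test_mask])
        np.testing.assert_array_equal(p_ref["mean"], p_mod["mean"])
        np.testing.assert_array_equal(p_ref["scale"], p_mod["scale"])
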