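"""RDA shrinkage limits, classification contracts and ROC diagnostics."""

import numpy as np
import pytest

from woundshape import (
    RDAParams,
    classify,
    fit_rda,
    lda_params,
    mahalanobis_distances,
    roc_auc_one_vs_rest,
    standardize,
)
from woundshape.rda import (
    ClassificationResult,
    DiscriminantError,
    SingularCovarianceError,
    discriminant_scores,
    grid_search,
)


def gaussian_blobs(seed=0, n=30, p=5, k=3, sep=10.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n * k, p))
    y = np.repeat(np.arange(k), n)
    for i in range(k):
        X[y == i, i % p] += sep * (i + 1)
    return X, y


class TestStandardize:
    def test_training_columns_become_zero_mean_unit_sd(self):
        z, stats = standardize(np.array([[1.0], [2.0], [3.0]]))
        assert z.mean() == pytest.approx(0.0)
        assert z.std(ddof=1) == pytest.approx(1.0)
        assert stats.mean[0] == pytest.approx(2.0)

    def test_test_value_at_training_mean_maps_to_zero(self):
        _, stats = standardize(np.array([[1.0], [2.0], [3.0]]))
        z, _ = standardize(np.array([[2.0]]), reference=stats)
        assert z[0, 0] == pytest.approx(0.0)

    def test_idempotent_with_own_statistics(self):
        rng = np.random.default_rng(0)
        X = rng.normal(2, 3, size=(20, 4))
        z, stats = standardize(X)
        z2, _ = standardize(z)
        np.testing.assert_allclose(z, z2, atol=1e-12)

    def test_zero_variance_column_rejected(self):
        with pytest.raises(DiscriminantError, match="0"):
            standardize(np.ones((5, 1)))


class TestShrinkageLimits:
    def test_lambda_one_gamma_zero_matches_independent_lda(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X, y = gaussian_blobs(seed=1, sep=2.0)
        z, stats = standardize(X)
        model = fit_rda(z, y, lda_params(), standardization=stats)
        # all class covariances collapse onto the pooled covariance
        np.testing.assert_allclose(model.covariances[0], model.covariances[1])
        ours = classify(model, z).predicted
        ref = (
            LinearDiscriminantAnalysis(priors=np.full(3, 1 / 3))
            .fit(z, y)
            .predict(z)
        )
        np.testing.assert_array_equal(ours, ref)

    def test_lambda_zero_gamma_zero_is_qda(self):
        X, y = gaussian_blobs(seed=2)
        model = fit_rda(X, y, RDAParams(lam=0.0, gamma=0.0))
        for i in np.unique(y):
            np.testing.assert_allclose(
                model.covariances[i], np.cov(X[y == i].T, ddof=1), atol=1e-10
            )

    def test_gamma_one_is_exactly_spherical(self):
        X, y = gaussian_blobs(seed=3)
        model = fit_rda(X, y, RDAParams(lam=0.5, gamma=1.0))
        for cov in model.covariances:
            np.testing.assert_allclose(cov, cov[0, 0] * np.eye(cov.shape[0]), atol=1e-10)

    def test_gamma_increases_move_toward_sphericity(self):
        X, y = gaussian_blobs(seed=4)
        conds = []
        for gamma in (0.0, 0.3, 0.7, 1.0):
            model = fit_rda(X, y, RDAParams(lam=0.2, gamma=gamma))
            conds.append(np.linalg.cond(model.covariances[0]))
        assert all(a >= b - 1e-9 for a, b in zip(conds, conds[1:]))
        assert conds[-1] == pytest.approx(1.0)

    def test_covariances_are_positive_definite(self):
        X, y = gaussian_blobs(seed=5, n=6, p=20)  # p > n per class
        model = fit_rda(X, y, RDAParams(lam=0.99, gamma=0.001))
        for cov in model.covariances:
            assert np.linalg.eigvalsh(cov).min() > 0

    def test_singular_covariance_reported(self):
        # two identical coordinates in every sample -> pooled covariance
        # singular; with gamma=0 there is no rescue
        rng = np.random.default_rng(6)
        base = rng.normal(size=(30, 2))
        X = np.column_stack([base, base[:, 0]])
        y = np.repeat([0, 1], 15)
        with pytest.raises(SingularCovarianceError, match="gamma"):
            fit_rda(X, y, RDAParams(lam=1.0, gamma=0.0))


class TestClassify:
    def make_model(self, means, cov_scale=1.0):
        rng = np.random.default_rng(0)
        k, p = means.shape
        X = np.concatenate(
            [m + cov_scale * rng.normal(size=(50, p)) for m in means]
        )
        y = np.repeat(np.arange(k), 50)
        return fit_rda(X, y, RDAParams(lam=1.0, gamma=0.0))

    def test_nearest_mean_under_equal_covariance(self):
        model = self.make_model(np.array([[0.0, 0.0], [10.0, 0.0]]))
        result = classify(model, np.array([[1.0, 0.0]]))
        assert result.predicted[0] == 0

    def test_class_mean_classified_as_its_class(self):
        model = self.make_model(np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]]))
        result = classify(model, model.means)
        np.testing.assert_array_equal(result.predicted, model.class_labels)

    def test_equidistant_tie_breaks_to_lowest_class_index(self):
        means = np.array([[-1.0, 0.0], [1.0, 0.0]])
        model = self.make_model(means)
        # force an exact tie by symmetrizing the model
        model.means = means
        pooled = np.eye(2)
        model.covariances = np.stack([pooled, pooled])
        model.__post_init__()
        result = classify(model, np.array([[0.0, 5.0]]))
        assert result.predicted[0] == model.class_labels[0]

    def test_score_shift_invariance(self):
        model = self.make_model(np.array([[0.0, 0.0], [5.0, 0.0]]))
        X = np.random.default_rng(1).normal(size=(10, 2))
        scores = discriminant_scores(model, X)
        shifted = ClassificationResult(
            predicted=model.class_labels[np.argmin(scores + 123.4, axis=1)],
            scores=scores + 123.4,
            weights=np.zeros_like(scores),
            class_labels=model.class_labels,
        )
        np.testing.assert_array_equal(
            shifted.predicted, classify(model, X).predicted
        )

    def test_forced_separation_gives_perfect_training_crr(self):
        X, y = gaussian_blobs(seed=7, k=2, sep=20.0)  # >> 6 sd apart
        z, stats = standardize(X)
        model = fit_rda(z, y, RDAParams())
        assert np.all(classify(model, z).predicted == y)

    def test_feature_mismatch_rejected(self):
        model = self.make_model(np.array([[0.0, 0.0], [5.0, 0.0]]))
        with pytest.raises(DiscriminantError):
            classify(model, np.zeros((3, 5)))


class TestMahalanobis:
    def test_zero_at_class_mean_and_euclidean_reduction(self):
        X, y = gaussian_blobs(seed=8, k=2)
        model = fit_rda(X, y, RDAParams(lam=0.5, gamma=1.0))
        model.covariances = np.stack([np.eye(5), np.eye(5)])
        model.__post_init__()
        d = mahalanobis_distances(model, model.means)
        assert d[0, 0] == pytest.approx(0.0)
        assert d[1, 1] == pytest.approx(0.0)
        assert d[0, 1] == pytest.approx(np.linalg.norm(model.means[0] - model.means[1]))

    def test_one_dimensional_scaling(self):
        # covariance 4 in 1D and |x - mu| = 2 -> distance 1
        X = np.concatenate([np.array([-2.0, 0, 2, -2, 0, 2]), 100 + np.array([-2.0, 0, 2])])
        y = np.array([0] * 6 + [1] * 3)
        model = fit_rda(X[:, None], y, RDAParams(lam=0.0, gamma=0.0))
        model.covariances = np.stack([[[4.0]], [[4.0]]])
        model.means = np.array([[0.0], [100.0]])
        model.__post_init__()
        d = mahalanobis_distances(model, np.array([[2.0]]))
        assert d[0, 0] == pytest.approx(1.0)


class TestROC:
    def make_result(self, scores, labels):
        classes = np.unique(labels)
        return (
            ClassificationResult(
                predicted=classes[np.argmin(scores, axis=1)],
                scores=scores,
                weights=np.zeros_like(scores),
                class_labels=classes,
            ),
            labels,
        )

    def test_perfect_separation_auc_one(self):
        scores = np.array([[0.0, 9], [0, 9], [9, 0], [9, 0]])
        result, y = self.make_result(scores, np.array(["a", "a", "b", "b"]))
        aucs = roc_auc_one_vs_rest(result, y)
        assert aucs["a"] == 1.0 and aucs["b"] == 1.0

    def test_constant_scores_auc_half(self):
        scores = np.ones((6, 2))
        result, y = self.make_result(scores, np.array(["a"] * 3 + ["b"] * 3))
        assert roc_auc_one_vs_rest(result, y)["a"] == 0.5

    def test_inverted_scores_auc_zero(self):
        scores = np.array([[9.0, 0], [9, 0], [0, 9], [0, 9]])
        result, y = self.make_result(scores, np.array(["a", "a", "b", "b"]))
        assert roc_auc_one_vs_rest(result, y)["a"] == 0.0

    def test_matches_sklearn_on_random_scores(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        scores = rng.normal(size=(40, 3))
        y = rng.choice(["a", "b", "c"], size=40)
        result, _ = self.make_result(scores, y)
        aucs = roc_auc_one_vs_rest(result, y)
        for i, c in enumerate(result.class_labels):
            ref = roc_auc_score((y == c).astype(int), -scores[:, i])
            assert aucs[c] == pytest.approx(ref, abs=1e-12)

    def test_absent_class_rejected(self):
        scores = np.zeros((4, 2))
        result, _ = self.make_result(scores, np.array(["a", "a", "b", "b"]))
        with pytest.raises(DiscriminantError):
            roc_auc_one_vs_rest(result, np.array(["a", "a", "a", "a"]))


def test_grid_search_reports_crude_grid():
    X, y = gaussian_blobs(seed=10, k=2, sep=5.0)
    z, _ = standardize(X)
    rows = grid_search(z, y, lambdas=(0.5, 1.0), gammas=(0.001, 1.0))
    assert len(rows) == 4
    assert all(r["training_crr"] is None or 0 <= r["training_crr"] <= 1 for r in rows)
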