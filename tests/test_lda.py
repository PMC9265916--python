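"""From-scratch LDA against independent oracles, plus LOOCV behaviour."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from clamtrace import fit_lda, loocv, predict, project
from clamtrace.lda import ConfusionMatrix, discriminant_scores


def make_blobs(rng, means, n_per, sd=1.0):
    means = np.atleast_2d(np.asarray(means, dtype=float))
    X = np.vstack(
        [rng.normal(m, sd, size=(n, means.shape[1])) for m, n in zip(means, n_per)]
    )
    y = np.concatenate([[f"c{i}"] * n for i, n in enumerate(n_per)])
    return X, y


def oracle_predict(model, X):
    """Direct Gaussian-discriminant oracle: argmax of prior × N(μ_k, Σ)."""
    labels = []
    for x in np.atleast_2d(X):
        scores = [
            multivariate_normal.logpdf(x, model.class_means[i], model.pooled_cov)
            + np.log(model.priors[i])
            for i in range(len(model.class_labels))
        ]
        labels.append(model.class_labels[int(np.argmax(scores))])
    return labels


class TestFit:
    def test_well_separated_classes_train_perfectly(self, rng):
        X, y = make_blobs(rng, [[0, 0], [10, 10]], [15, 15])
        model = fit_lda(X, y)
        assert predict(model, X)[0] == list(y)

    def test_axis_count_is_min_k_minus_1_p(self, rng):
        X, y = make_blobs(rng, [[0, 0], [3, 0], [0, 3], [3, 3]], [5, 5, 5, 5])
        model = fit_lda(X, y)
        assert model.axes.shape == (2, 2)  # min(K-1, p) = min(3, 2)
        assert model.eigenvalues[0] >= model.eigenvalues[1] >= 0

    def test_small_class_and_degenerate_n_rejected(self, rng):
        X, y = make_blobs(rng, [[0], [5]], [4, 1])
        with pytest.raises(ValueError, match="at least 2"):
            fit_lda(X, y)
        with pytest.raises(ValueError, match="need at least 2 classes"):
            fit_lda(np.zeros((4, 1)), np.array(["a"] * 4))

    def test_priors(self, rng):
        X, y = make_blobs(rng, [[0], [5]], [30, 10])
        assert np.allclose(fit_lda(X, y, "proportional").priors, [0.75, 0.25])
        assert np.allclose(fit_lda(X, y, "uniform").priors, [0.5, 0.5])
        with pytest.raises(ValueError):
            fit_lda(X, y, "flat")

    def test_singular_covariance_is_ridge_stabilized(self, rng):
        base = rng.normal(size=(10, 1))
        X = np.hstack([base, 2 * base])  # rank-1 within-class scatter
        y = np.array(["a"] * 5 + ["b"] * 5)
        model = fit_lda(X, y)
        assert model.regularization > 0
        assert np.all(np.isfinite(discriminant_scores(model, X)))


class TestPredict:
    def test_sample_at_class_mean_classified_as_that_class(self, rng):
        X, y = make_blobs(rng, [[0, 0], [4, 4], [8, 0]], [10, 10, 10])
        model = fit_lda(X, y, priors_mode="uniform")
        labels, _ = predict(model, model.class_means)
        assert labels == model.class_labels

    def test_equidistant_tie_breaks_to_earliest_class(self):
        # perfectly symmetric classes around x = 0; test point at 0
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array(["a", "a", "b", "b"])
        model = fit_lda(X, y, priors_mode="uniform")
        labels, _ = predict(model, np.array([[0.0]]))
        assert labels == ["a"]

    def test_posteriors_sum_to_one(self, rng):
        X, y = make_blobs(rng, [[0, 0], [2, 1]], [8, 8])
        model = fit_lda(X, y)
        _, post = predict(model, rng.normal(size=(40, 2)))
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        X, y = make_blobs(rng, [[0, 0], [3, 3]], [5, 5])
        model = fit_lda(X, y)
        with pytest.raises(ValueError, match="dimension mismatch"):
            predict(model, np.zeros((2, 3)))

    def test_oracle_equivalence_on_random_small_instances(self):
        """Predictions equal the direct-formula Gaussian oracle exactly."""
        rng = np.random.default_rng(7)
        for _ in range(60):
            k = int(rng.integers(2, 4))
            p = int(rng.integers(1, 4))
            n_per = rng.integers(2, max(3, 12 // k + 1), size=k)
            X, y = make_blobs(rng, rng.normal(0, 2, size=(k, p)), n_per)
            if X.shape[0] <= k:
                continue
            model = fit_lda(X, y)
            test_points = rng.normal(0, 3, size=(6, p))
            assert predict(model, test_points)[0] == oracle_predict(model, test_points)

    def test_matches_reference_implementation(self, rng):
        """Class means, predictions and posteriors agree with scikit-learn."""
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        X, y = make_blobs(rng, [[0, 0, 0], [2, 1, 0], [4, 0, 1]], [20, 25, 15])
        model = fit_lda(X, y)
        ref = sklearn.LinearDiscriminantAnalysis().fit(X, y)
        assert np.allclose(model.class_means, ref.means_, atol=1e-6)
        labels, post = predict(model, X)
        assert list(ref.predict(X)) == labels
        assert np.allclose(post, ref.predict_proba(X), atol=1e-6)


class TestProject:
    def test_grand_mean_projects_to_origin(self, rng):
        X, y = make_blobs(rng, [[0, 0], [3, 1], [1, 4]], [8, 8, 8])
        model = fit_lda(X, y)
        assert np.allclose(project(model, model.grand_mean.reshape(1, -1)), 0.0)

    def test_between_class_variance_ordered_by_axis(self, rng):
        X, y = make_blobs(rng, [[0, 0], [4, 0], [0, 2]], [15, 15, 15])
        model = fit_lda(X, y)
        Z = project(model, X)
        per_axis = [
            np.var([Z[y == c, ax].mean() for c in np.unique(y)])
            for ax in range(Z.shape[1])
        ]
        assert per_axis[0] >= per_axis[1]

    def test_single_feature_axis_proportional_to_feature(self, rng):
        X, y = make_blobs(rng, [[0], [5]], [10, 10])
        model = fit_lda(X, y)
        Z = project(model, X)
        r = np.corrcoef(X.ravel(), Z.ravel())[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)


class TestLoocv:
    def test_well_separated_classes_fully_recovered(self, rng):
        X, y = make_blobs(rng, [[0, 0], [10, 10]], [20, 20])
        result = loocv(X, y)
        assert np.trace(result.confusion.counts) == 40

    def test_confusion_row_sums_equal_class_counts(self, rng):
        X, y = make_blobs(rng, [[0, 0], [1, 1], [2, 0]], [12, 9, 7])
        result = loocv(X, y)
        assert result.confusion.row_sums().tolist() == [12, 9, 7]

    def test_null_separation_accuracy_near_half(self):
        """Two identical distributions: mean LOOCV accuracy ≈ 50% ± 10%."""
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(100, 2))
            y = np.array(["a"] * 50 + ["b"] * 50)
            result = loocv(X, y)
            accs.append(np.trace(result.confusion.counts) / 100)
        assert 0.40 <= np.mean(accs) <= 0.60

    def test_permutation_invariance(self, rng):
        X, y = make_blobs(rng, [[0, 0], [1.5, 1.5]], [15, 15])
        before = loocv(X, y).confusion.counts
        perm = rng.permutation(len(y))
        after = loocv(X[perm], y[perm]).confusion.counts
        assert np.array_equal(before, after)

    def test_monotone_separation(self):
        """Accuracy is nondecreasing as the class gap grows (fixed noise)."""
        rng = np.random.default_rng(3)
        noise = rng.normal(size=(40, 2))
        y = np.array(["a"] * 20 + ["b"] * 20)
        accs = []
        for gap in [0, 2, 4, 6, 8, 10]:
            X = noise.copy()
            X[20:] += gap
            result = loocv(X, y)
            accs.append(np.trace(result.confusion.counts))
        assert all(b >= a for a, b in zip(accs, accs[1:]))

    def test_min_class_size_enforced(self, rng):
        X, y = make_blobs(rng, [[0], [5]], [2, 10])
        with pytest.raises(ValueError, match="c0"):
            loocv(X, y)

    def test_per_fold_scaling_policy_runs_and_differs_in_principle(self, rng):
        X, y = make_blobs(rng, [[0, 0], [1, 1]], [10, 10])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = loocv(X, y, scaling_policy="per_fold")
        assert res.confusion.counts.sum() == 20
        with pytest.raises(ValueError):
            loocv(X, y, scaling_policy="none")


class TestConfusionMatrix:
    def test_invalid_shapes_and_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(classes=["a", "b"], counts=np.zeros((2, 3)))
        with pytest.raises(ValueError):
            ConfusionMatrix(classes=["a"], counts=np.array([[-1]]))

    def test_report_table_layout(self):
        cm = ConfusionMatrix(classes=["CC", "GN"], counts=np.array([[9, 1], [2, 8]]))
        table = cm.to_table()
        assert list(table.columns) == ["CC", "GN", "Prediction (%)"]
        assert table.loc["CC", "Prediction (%)"] == 90.0
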