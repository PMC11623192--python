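import numpy as np
import pandas as pd
import pytest

from vitalwatch.dpca import (
    DiscriminantModel,
    FeatureMatrix,
    lda_fit,
    mahalanobis_classify,
    pca_fit,
    pca_project,
    pca_reconstruct,
    variance_proportion,
    window_features,
)
from vitalwatch.frames import SensorFrame, ValidationError


def make_frame(**channels):
    n = len(next(iter(channels.values())))
    data = {"time": np.arange(float(n))}
    data.update({k: np.asarray(v, dtype=float) for k, v in channels.items()})
    return SensorFrame(pd.DataFrame(data))


class TestWindowFeatures:
    def test_canonical_heart_rate_window_statistics(self, table1_heart_rate):
        frame = make_frame(heart_rate=table1_heart_rate)
        feats = window_features(frame, window=5, stride=1)
        row = dict(zip(feats.feature_names, feats.values[0]))
        assert row["heart_rate_mean"] == pytest.approx(74.0)
        assert row["heart_rate_min"] == 72.0
        assert row["heart_rate_max"] == 76.0

    def test_self_cross_correlation_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=32)
        frame = make_frame(a=x, b=x)
        feats = window_features(frame, window=32, stride=1, pairs=[("a", "b")])
        row = dict(zip(feats.feature_names, feats.values[0]))
        assert row["xcorr_a_b"] == pytest.approx(1.0)

    def test_constant_channel_gives_zero_sd_and_zero_xcorr(self):
        rng = np.random.default_rng(1)
        frame = make_frame(a=np.full(16, 3.0), b=rng.normal(size=16))
        feats = window_features(frame, window=16, stride=1, pairs=[("a", "b")])
        row = dict(zip(feats.feature_names, feats.values[0]))
        assert row["a_sd"] == 0.0
        assert row["xcorr_a_b"] == 0.0

    def test_window_longer_than_stream_rejected(self, small_stream):
        with pytest.raises(ValidationError):
            window_features(small_stream, window=1000, stride=1)

    def test_windows_with_excess_missingness_are_dropped(self):
        x = np.arange(40.0)
        x[8:16] = np.nan  # window [8,16) fully missing
        frame = make_frame(a=x)
        feats = window_features(frame, window=8, stride=8)
        spans = feats.window_spans
        assert (8, 16) not in spans
        assert (0, 8) in spans and (16, 24) in spans


class TestPCA:
    def test_collinear_points_closed_form(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        model = pca_fit(X)
        v = model.eigenvectors[:, 0]
        np.testing.assert_allclose(np.abs(v), [2**-0.5, 2**-0.5], atol=1e-12)
        assert model.eigenvalues[1] == pytest.approx(0.0, abs=1e-12)
        scores = pca_project(X, model, K=1).ravel()
        np.testing.assert_allclose(np.abs(scores), [2**0.5, 0.0, 2**0.5], atol=1e-12)

    def test_matches_sklearn_on_random_data(self):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 5)) @ rng.normal(size=(5, 5))
        ours = pca_fit(X)
        ref = sklearn_pca(n_components=5).fit(X)
        np.testing.assert_allclose(ours.eigenvalues, ref.explained_variance_, atol=1e-8)
        for j in range(5):
            a, b = ours.eigenvectors[:, j], ref.components_[j]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_single_feature_eigenvalue_is_sample_variance(self):
        x = np.array([[1.0], [2.0], [4.0], [7.0]])
        model = pca_fit(x)
        assert model.eigenvalues[0] == pytest.approx(np.var(x, ddof=1))

    def test_full_rank_projection_inverts_losslessly(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 4))
        model = pca_fit(X)
        rec = pca_reconstruct(pca_project(X, model, K=4), model)
        np.testing.assert_allclose(rec, X, atol=1e-8)

    def test_projecting_the_mean_gives_zero(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 3))
        model = pca_fit(X)
        np.testing.assert_allclose(
            pca_project(model.mean_vector[None, :], model, K=3), 0.0, atol=1e-10
        )

    def test_reconstruction_error_equals_sum_of_discarded_eigenvalues(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 6)) @ rng.normal(size=(6, 6))
        model = pca_fit(X)
        for K in (1, 3, 5):
            rec = pca_reconstruct(pca_project(X, model, K), model)
            err = np.sum((X - rec) ** 2) / (X.shape[0] - 1)
            assert err == pytest.approx(model.eigenvalues[K:].sum(), abs=1e-8)

    def test_variance_proportion_examples_and_monotonicity(self):
        from vitalwatch.dpca import PCAModel

        model = PCAModel(np.zeros(2), np.array([3.0, 1.0]), np.eye(2))
        assert variance_proportion(model, 1) == pytest.approx(0.75)
        assert variance_proportion(model, 2) == pytest.approx(1.0)
        null = PCAModel(np.zeros(2), np.array([2.0, 0.0]), np.eye(2))
        assert variance_proportion(null, 1) == pytest.approx(1.0)
        rng = np.random.default_rng(6)
        fitted = pca_fit(rng.normal(size=(50, 5)))
        props = [variance_proportion(fitted, M) for M in range(1, 6)]
        assert np.all(np.diff(props) >= -1e-12)
        assert props[-1] == pytest.approx(1.0)
        with pytest.raises(ValidationError):
            variance_proportion(fitted, 6)


class TestRegularizedDiscriminant:
    def two_class_data(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([
            rng.normal(0.0, 1.0, size=(n, 3)),
            rng.normal(2.0, 1.0, size=(n, 3)),
        ])
        y = np.repeat([0, 1], n)
        return X, y

    def test_rho_one_forces_scaled_identity(self):
        X, y = self.two_class_data()
        model = lda_fit(X, y, gamma=0.0, rho=1.0)
        for cov in model.reg_covariances:
            off = cov - np.diag(np.diag(cov))
            assert np.abs(off).max() < 1e-12
            assert np.allclose(np.diag(cov), cov[0, 0])

    def test_gamma_one_pools_all_class_covariances(self):
        X, y = self.two_class_data()
        model = lda_fit(X, y, gamma=1.0, rho=0.0)
        np.testing.assert_allclose(
            model.reg_covariances[0], model.reg_covariances[1], atol=1e-12
        )

    def test_one_dimensional_two_class_hand_example(self):
        # classes {-1, 1} and {9, 11}: means 0 and 10; scatter 2 each;
        # with the maximum-likelihood divisor n_j the class variance is 1
        X = np.array([[-1.0], [1.0], [9.0], [11.0]])
        y = np.array([0, 0, 1, 1])
        model = lda_fit(X, y, gamma=0.0, rho=0.0)
        np.testing.assert_allclose(model.class_means.ravel(), [0.0, 10.0], atol=1e-12)
        np.testing.assert_allclose(
            [c[0, 0] for c in model.reg_covariances], [1.0, 1.0], atol=1e-12
        )

    def test_classification_reduces_to_nearest_mean(self):
        model = DiscriminantModel(
            classes=np.array([0, 1]),
            class_means=np.array([[0.0], [2.0]]),
            reg_covariances=np.array([[[1.0]], [[1.0]]]),
            priors=np.array([0.5, 0.5]),
            gamma=0.0,
            rho=0.0,
        )
        label, _ = mahalanobis_classify([0.9], model)
        assert label == 0
        label, scores = mahalanobis_classify([0.0], model)
        assert label == 0
        assert scores[0] == pytest.approx(-2 * np.log(0.5))  # distance term zero

    def test_unequal_priors_break_ties_toward_majority(self):
        model = DiscriminantModel(
            classes=np.array([0, 1]),
            class_means=np.array([[0.0], [2.0]]),
            reg_covariances=np.array([[[1.0]], [[1.0]]]),
            priors=np.array([0.9, 0.1]),
            gamma=0.0,
            rho=0.0,
        )
        label, _ = mahalanobis_classify([1.0], model)  # equidistant
        assert label == 0

    def test_accuracy_approaches_bayes_rate_on_known_gaussians(self):
        rng = np.random.default_rng(7)
        n = 10_000
        X = np.concatenate([rng.normal(-1, 1, n), rng.normal(1, 1, n)])[:, None]
        y = np.repeat([0, 1], n)
        model = lda_fit(X, y, gamma=1.0, rho=0.0)
        pred, _ = mahalanobis_classify(X, model)
        acc = np.mean(pred == y)
        from scipy.stats import norm

        bayes = norm.cdf(1.0)  # optimal boundary at 0
        assert abs(acc - bayes) < 0.02

    def test_pipeline_invariant_to_feature_reordering(self):
        rng = np.random.default_rng(8)
        X = np.vstack([
            rng.normal(0, 1, size=(50, 4)),
            rng.normal(1.5, 1, size=(50, 4)),
        ]) @ rng.normal(size=(4, 4))
        y = np.repeat([0, 1], 50)
        perm = [2, 0, 3, 1]

        def classify(data):
            model = pca_fit(data)
            proj = pca_project(data, model, K=3)
            disc = lda_fit(proj, y, gamma=1.0, rho=0.1)
            pred, _ = mahalanobis_classify(proj, disc)
            return pred

        np.testing.assert_array_equal(classify(X), classify(X[:, perm]))

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            lda_fit(np.zeros((4, 2)), [0, 0, 0, 0])


class TestFeatureMatrixIO:
    def test_csv_round_trip_with_sidecar(self, tmp_path):
        fm = FeatureMatrix(
            np.array([[1.0, 2.0], [3.0, 4.0]]),
            ["a", "b"],
            [(0, 8), (8, 16)],
            np.array([0, 1]),
        )
        fm.to_csv(tmp_path / "f.csv", tmp_path / "f.json")
        back = FeatureMatrix.from_csv(tmp_path / "f.csv", tmp_path / "f.json")
        np.testing.assert_array_equal(back.values, fm.values)
        assert back.feature_names == fm.feature_names
        assert back.window_spans == fm.window_spans
        np.testing.assert_array_equal(back.labels, fm.labels)
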