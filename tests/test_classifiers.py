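"""The three from-scratch classifiers: hand-computed oracles, brute-force
cross-checks, determinism and serialization."""

import numpy as np
import pytest
from sklearn.naive_bayes import GaussianNB as SkGaussianNB
from sklearn.neighbors import KNeighborsClassifier as SkKNN

from gaitrec.classifiers import (
    FeedForwardANNClassifier,
    GaussianNBActivityClassifier,
    NearestNeighborActivityClassifier,
    ann_fit,
    ann_predict,
    knn_predict,
    load_model,
    nb_fit,
    nb_predict,
    save_model,
)


def gaussian_blobs(n_classes=5, per_class=30, dim=8, sep=20.0, sd=1.0, seed=0):
    """Well-separated class clusters: inter-mean distance >> noise sd."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(scale=sep, size=(n_classes, dim))
    X = np.vstack([
        centers[i] + rng.normal(scale=sd, size=(per_class, dim))
        for i in range(n_classes)
    ])
    y = np.repeat(np.arange(1, n_classes + 1), per_class)
    return X, y


class TestGaussianNB:
    def test_zero_variance_feature_is_filtered(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array([1, 1, 2, 2])
        model = GaussianNBActivityClassifier().fit(X, y)
        assert len(model.retained_features_) == 0
        # with no usable features prediction falls back to the priors
        label, post = nb_predict(model, [0.5])
        np.testing.assert_allclose(post, [0.5, 0.5])

    def test_feature_degenerate_in_one_class_is_filtered(self):
        X = np.array([[0.0, 1.0], [0.0, 2.0], [1.0, 3.0], [3.0, 4.0]])
        y = np.array([1, 1, 2, 2])
        model = GaussianNBActivityClassifier().fit(X, y)
        assert list(model.retained_features_) == [1]

    def test_priors_are_class_frequencies(self):
        X = np.array([[0.0], [0.1], [1.0]])
        y = np.array([1, 1, 2])
        model = GaussianNBActivityClassifier().fit(X, y)
        np.testing.assert_allclose(model.class_prior_, [2 / 3, 1 / 3])

    def test_log_posterior_matches_hand_computed_densities(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 2)) + np.repeat(
            np.array([[0.0, 0.0], [3.0, 1.0], [-2.0, 4.0]]), 10, axis=0
        )
        y = np.repeat([1, 2, 3], 10)
        model = GaussianNBActivityClassifier().fit(X, y)
        x = np.array([0.5, 1.5])
        # direct evaluation of prior * product of Gaussian densities
        jll = []
        for i in range(3):
            Xi = X[y == i + 1]
            mu, var = Xi.mean(axis=0), Xi.var(axis=0)
            dens = np.exp(-((x - mu) ** 2) / (2 * var)) / np.sqrt(2 * np.pi * var)
            jll.append(np.log(1 / 3) + np.log(dens).sum())
        expected = np.exp(jll - np.max(jll))
        expected /= expected.sum()
        _, post = nb_predict(model, x)
        np.testing.assert_allclose(post, expected, atol=1e-9)

    def test_class_mean_is_predicted_as_its_class(self):
        X, y = gaussian_blobs(per_class=20, seed=3)
        model = GaussianNBActivityClassifier().fit(X, y)
        for i, c in enumerate(model.classes_):
            mean = X[y == c].mean(axis=0)
            assert model.predict(mean[None])[0] == c

    def test_posteriors_normalize_for_random_inputs(self):
        X, y = gaussian_blobs(seed=4)
        model = GaussianNBActivityClassifier().fit(X, y)
        queries = np.random.default_rng(5).normal(scale=30, size=(50, X.shape[1]))
        np.testing.assert_allclose(model.predict_proba(queries).sum(axis=1), 1.0, atol=1e-9)

    def test_prediction_invariant_under_affine_feature_rescaling(self):
        X, y = gaussian_blobs(per_class=15, seed=6)
        rng = np.random.default_rng(7)
        scale = rng.uniform(0.5, 3.0, size=X.shape[1])
        shift = rng.normal(size=X.shape[1])
        queries = rng.normal(scale=30, size=(50, X.shape[1]))
        base = GaussianNBActivityClassifier().fit(X, y).predict(queries)
        rescaled = GaussianNBActivityClassifier().fit(X * scale + shift, y).predict(
            queries * scale + shift
        )
        np.testing.assert_array_equal(base, rescaled)

    def test_agrees_with_library_gaussian_nb_on_blobs(self):
        X, y = gaussian_blobs(seed=8)
        queries = np.random.default_rng(9).normal(scale=25, size=(100, X.shape[1]))
        ours = GaussianNBActivityClassifier().fit(X, y).predict(queries)
        theirs = SkGaussianNB(var_smoothing=0.0).fit(X, y).predict(queries)
        np.testing.assert_array_equal(ours, theirs)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            GaussianNBActivityClassifier().fit(np.empty((0, 3)), [])

    def test_dimension_mismatch_rejected(self):
        X, y = gaussian_blobs(seed=10)
        model = GaussianNBActivityClassifier().fit(X, y)
        with pytest.raises(ValueError, match="dimension"):
            model.predict(np.zeros((1, X.shape[1] + 1)))


class TestNearestNeighbor:
    def test_training_point_maps_to_itself(self):
        X, y = gaussian_blobs(per_class=10, seed=0)
        model = NearestNeighborActivityClassifier().fit(X, y)
        label, dist = knn_predict(model, X[17])
        assert label == y[17]
        assert dist == 0.0

    def test_midpoint_partition_in_one_dimension(self):
        model = NearestNeighborActivityClassifier().fit([[0.0], [10.0]], [1, 2])
        assert knn_predict(model, [4.0])[0] == 1
        assert knn_predict(model, [6.0])[0] == 2

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 6))
        y = rng.integers(1, 6, size=50)
        model = NearestNeighborActivityClassifier().fit(X, y)
        queries = rng.normal(size=(200, 6))
        for q in queries:
            d = np.sqrt(((X - q) ** 2).sum(axis=1))
            expected = y[int(np.argmin(d))]  # argmin takes the lowest index on ties
            assert knn_predict(model, q)[0] == expected

    def test_agrees_with_library_knn(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 5))
        y = rng.integers(1, 6, size=80)
        queries = rng.normal(size=(100, 5))
        ours = NearestNeighborActivityClassifier().fit(X, y).predict(queries)
        theirs = SkKNN(n_neighbors=1).fit(X, y).predict(queries)
        np.testing.assert_array_equal(ours, theirs)

    def test_distance_tie_breaks_to_lowest_training_index(self):
        model = NearestNeighborActivityClassifier().fit([[1.0], [1.0]], [2, 1])
        assert knn_predict(model, [1.0])[0] == 2

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="n_neighbors"):
            NearestNeighborActivityClassifier(n_neighbors=5).fit([[0.0]], [1])

    def test_dimension_mismatch_rejected(self):
        model = NearestNeighborActivityClassifier().fit([[0.0, 1.0]], [1])
        with pytest.raises(ValueError, match="dimension"):
            knn_predict(model, [0.0, 1.0, 2.0])


class TestFeedForwardANN:
    def test_same_seed_gives_identical_weights(self):
        X, y = gaussian_blobs(per_class=10, seed=0)
        a = FeedForwardANNClassifier(max_epochs=50, random_state=3).fit(X, y)
        b = FeedForwardANNClassifier(max_epochs=50, random_state=3).fit(X, y)
        for wa, wb in zip(a.coefs_, b.coefs_):
            np.testing.assert_array_equal(wa, wb)

    def test_training_reduces_loss(self):
        X, y = gaussian_blobs(per_class=10, seed=1)
        model = FeedForwardANNClassifier(max_epochs=200, random_state=0).fit(X, y)
        assert model.loss_curve_[-1] < model.loss_curve_[0]

    def test_separable_blobs_reach_perfect_training_accuracy(self):
        X, y = gaussian_blobs(per_class=30, seed=2)
        model = FeedForwardANNClassifier(n_hidden=8, random_state=0).fit(X, y)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_held_out_blob_points_classified_correctly(self):
        X, y = gaussian_blobs(per_class=30, seed=5)
        model = FeedForwardANNClassifier(n_hidden=8, random_state=0).fit(X, y)
        rng = np.random.default_rng(6)
        # fresh points from the same clusters
        for c in model.classes_:
            center = X[y == c].mean(axis=0)
            fresh = center + rng.normal(scale=1.0, size=(10, X.shape[1]))
            assert np.all(model.predict(fresh) == c)

    def test_probabilities_sum_to_one(self):
        X, y = gaussian_blobs(seed=7)
        model = FeedForwardANNClassifier(max_epochs=100, random_state=0).fit(X, y)
        queries = np.random.default_rng(8).normal(scale=25, size=(50, X.shape[1]))
        np.testing.assert_allclose(model.predict_proba(queries).sum(axis=1), 1.0, atol=1e-9)

    def test_zero_weight_network_is_uniform(self):
        X, y = gaussian_blobs(per_class=5, seed=9)
        model = FeedForwardANNClassifier(max_epochs=1, random_state=0).fit(X, y)
        model.coefs_ = [np.zeros_like(w) for w in model.coefs_]
        model.intercepts_ = [np.zeros_like(b) for b in model.intercepts_]
        proba = model.predict_proba(X[:3])
        np.testing.assert_allclose(proba, 0.2, atol=1e-12)

    def test_single_sample_training_rejected(self):
        with pytest.raises(ValueError, match="two samples"):
            FeedForwardANNClassifier().fit([[0.0, 1.0]], [1])

    def test_ann_fit_enforces_4n_inputs(self):
        X, y = gaussian_blobs(dim=8, seed=10)
        model = ann_fit(X, y, n_orders=2, num_hln=4, seed=0, max_epochs=20)
        assert model.coefs_[0].shape == (8, 4)
        with pytest.raises(ValueError, match="4\\*n_orders"):
            ann_fit(X, y, n_orders=3, num_hln=4, seed=0)

    def test_ann_predict_returns_label_proba_and_onehot(self):
        X, y = gaussian_blobs(per_class=10, seed=11)
        model = FeedForwardANNClassifier(n_hidden=6, random_state=0).fit(X, y)
        label, proba, pred = ann_predict(model, X[0])
        assert label == y[0]
        assert proba.sum() == pytest.approx(1.0)
        assert pred.sum() == 1.0 and pred[np.argmax(proba)] == 1.0


class TestSerialization:
    @pytest.mark.parametrize("factory", [
        lambda: GaussianNBActivityClassifier(),
        lambda: NearestNeighborActivityClassifier(),
        lambda: FeedForwardANNClassifier(n_hidden=4, max_epochs=30, random_state=0),
    ], ids=["nb", "knn", "ann"])
    def test_round_trip_preserves_predictions(self, factory, tmp_path):
        X, y = gaussian_blobs(per_class=10, seed=12)
        model = factory().fit(X, y)
        path = tmp_path / "model.json"
        save_model(model, path)
        restored = load_model(path)
        queries = np.random.default_rng(13).normal(scale=25, size=(20, X.shape[1]))
        np.testing.assert_array_equal(model.predict(queries), restored.predict(queries))
        np.testing.assert_allclose(
            model.predict_proba(queries), restored.predict_proba(queries), atol=1e-12
        )
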