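"""The three activity classifiers, written from scratch as
scikit-learn-style estimators.

* :class:`GaussianNBActivityClassifier` — naive Bayes with Gaussian
  per-feature likelihoods and a variance filter: any feature whose
  within-class variance is not positive for some training class is dropped
  (a degenerate Gaussian carries no usable density). Prediction is the
  maximum-a-posteriori class, computed in log space.
* :class:`NearestNeighborActivityClassifier` — K-nearest neighbors on
  Euclidean distance, K=1 by default; distance ties break toward the lowest
  training index, vote ties toward the lowest class code.
* :class:`FeedForwardANNClassifier` — a single-hidden-layer feed-forward
  network (4n inputs -> numHLN logistic-sigmoid hidden units -> softmax
  outputs) trained by full-batch gradient descent on cross-entropy, with
  z-score input standardization and seeded uniform(-0.5, 0.5) weight
  initialization so training is fully reproducible.

All three expose ``fit`` / ``predict`` / ``predict_proba`` and compose with
scikit-learn model selection via ``get_params`` / ``set_params``; the
module-level ``nb_fit`` / ``knn_predict`` / ``ann_fit`` ... functions are
thin convenience wrappers over them. Fitted models serialize to a
documented JSON file via :func:`save_model` / :func:`load_model`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin


def _check_Xy(X, y=None):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.ndim != 2:
        raise ValueError(f"X must be 2-D, got shape {X.shape}")
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if y is None:
        return X
    y = np.asarray(y).ravel().astype(int)
    if len(y) != X.shape[0]:
        raise ValueError(f"X and y length mismatch: {X.shape[0]} vs {len(y)}")
    return X, y


def _check_dim(X, n_features: int) -> np.ndarray:
    X = _check_Xy(X)
    if X.shape[1] != n_features:
        raise ValueError(
            f"feature dimension mismatch: model expects {n_features}, got {X.shape[1]}"
        )
    return X


class GaussianNBActivityClassifier(ClassifierMixin, BaseEstimator):
    """Gaussian naive Bayes with a training-set variance filter.

    Parameters
    ----------
    var_floor : float
        Lower bound applied to retained per-class variances for numerical
        stability.

    Attributes
    ----------
    classes_ : ndarray of class codes seen in fit
    class_prior_ : ndarray, relative class frequencies
    theta_, var_ : (n_classes, n_retained) per-class means and variances
    retained_features_ : indices of features that survived the filter
    """

    def __init__(self, var_floor: float = 1e-9):
        self.var_floor = var_floor

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n_classes = len(self.classes_)
        counts = np.bincount(y_idx, minlength=n_classes).astype(float)
        self.class_prior_ = counts / counts.sum()
        theta = np.empty((n_classes, X.shape[1]))
        var = np.empty((n_classes, X.shape[1]))
        for i in range(n_classes):
            Xi = X[y_idx == i]
            theta[i] = Xi.mean(axis=0)
            var[i] = Xi.var(axis=0)
        # Drop any feature that is degenerate (non-positive variance) in at
        # least one class: its Gaussian likelihood is undefined there.
        retained = np.flatnonzero(np.all(var > 0.0, axis=0))
        self.retained_features_ = retained
        self.theta_ = theta[:, retained]
        self.var_ = np.maximum(var[:, retained], self.var_floor)
        self.n_features_in_ = X.shape[1]
        return self

    def _joint_log_likelihood(self, X) -> np.ndarray:
        X = _check_dim(X, self.n_features_in_)
        Xr = X[:, self.retained_features_]
        jll = np.log(self.class_prior_)[None, :].repeat(len(Xr), axis=0)
        for i in range(len(self.classes_)):
            log_pdf = -0.5 * (
                np.log(2.0 * np.pi * self.var_[i])
                + (Xr - self.theta_[i]) ** 2 / self.var_[i]
            )
            jll[:, i] += log_pdf.sum(axis=1)
        return jll

    def predict_log_proba(self, X) -> np.ndarray:
        jll = self._joint_log_likelihood(X)
        norm = jll - jll.max(axis=1, keepdims=True)
        return norm - np.log(np.exp(norm).sum(axis=1, keepdims=True))

    def predict_proba(self, X) -> np.ndarray:
        return np.exp(self.predict_log_proba(X))

    def predict(self, X) -> np.ndarray:
        jll = self._joint_log_likelihood(X)
        return self.classes_[np.argmax(jll, axis=1)]


class NearestNeighborActivityClassifier(ClassifierMixin, BaseEstimator):
    """K-nearest-neighbor classifier on Euclidean distance (K=1 default).

    Ties in distance resolve to the lowest training index (stable sort);
    ties in the K-neighbor vote resolve to the lowest class code.
    """

    def __init__(self, n_neighbors: int = 1):
        self.n_neighbors = n_neighbors

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        if not 1 <= self.n_neighbors <= len(y):
            raise ValueError(
                f"n_neighbors must be in [1, {len(y)}], got {self.n_neighbors}"
            )
        self.X_ = X
        self.y_ = y
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        return self

    def _neighbor_ids(self, X) -> tuple[np.ndarray, np.ndarray]:
        X = _check_dim(X, self.n_features_in_)
        d2 = ((X[:, None, :] - self.X_[None, :, :]) ** 2).sum(axis=2)
        order = np.argsort(d2, axis=1, kind="stable")[:, : self.n_neighbors]
        dists = np.sqrt(np.take_along_axis(d2, order, axis=1))
        return order, dists

    def kneighbors(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Distances and training indices of each query's K neighbors."""
        order, dists = self._neighbor_ids(X)
        return dists, order

    def predict_proba(self, X) -> np.ndarray:
        order, _ = self._neighbor_ids(X)
        votes = np.zeros((len(order), len(self.classes_)))
        class_pos = {int(c): j for j, c in enumerate(self.classes_)}
        for i, idx in enumerate(order):
            for t in idx:
                votes[i, class_pos[int(self.y_[t])]] += 1.0
        return votes / self.n_neighbors

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


class FeedForwardANNClassifier(ClassifierMixin, BaseEstimator):
    """Single-hidden-layer feed-forward network trained by backpropagation.

    Architecture: ``n_features -> n_hidden (logistic sigmoid) -> n_classes
    (softmax)``. Training minimizes mean cross-entropy by full-batch
    gradient descent for at most ``max_epochs`` epochs, stopping early when
    the epoch-to-epoch loss improvement falls below ``tol``. Inputs are
    z-scored with training-set statistics; weights initialize uniformly in
    ``(-init_scale, init_scale)`` from a seeded generator, so fits are
    deterministic given ``random_state``.

    Attributes
    ----------
    coefs_ : [W1 (n_features, n_hidden), W2 (n_hidden, n_classes)]
    intercepts_ : [b1, b2]
    mean_, scale_ : standardization constants
    loss_curve_ : per-epoch training loss
    n_iter_ : epochs actually run
    """

    def __init__(
        self,
        n_hidden: int = 8,
        learning_rate: float = 0.1,
        max_epochs: int = 2000,
        tol: float = 1e-6,
        init_scale: float = 0.5,
        random_state: int = 0,
    ):
        self.n_hidden = n_hidden
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.tol = tol
        self.init_scale = init_scale
        self.random_state = random_state

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        if len(y) < 2:
            raise ValueError("ANN training needs at least two samples")
        if self.n_hidden < 1:
            raise ValueError(f"n_hidden must be >= 1, got {self.n_hidden}")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, d = X.shape
        c = len(self.classes_)
        self.mean_ = X.mean(axis=0)
        self.scale_ = np.maximum(X.std(axis=0), 1e-8)
        Z = (X - self.mean_) / self.scale_
        T = np.zeros((n, c))
        T[np.arange(n), y_idx] = 1.0

        rng = np.random.default_rng(self.random_state)
        s = self.init_scale
        W1 = rng.uniform(-s, s, (d, self.n_hidden))
        b1 = rng.uniform(-s, s, self.n_hidden)
        W2 = rng.uniform(-s, s, (self.n_hidden, c))
        b2 = rng.uniform(-s, s, c)

        lr = self.learning_rate
        losses = []
        prev = np.inf
        for _ in range(self.max_epochs):
            H = _sigmoid(Z @ W1 + b1)
            P = _softmax(H @ W2 + b2)
            loss = -np.mean(np.log(np.maximum(P[np.arange(n), y_idx], 1e-12)))
            losses.append(loss)
            # backpropagation (mean cross-entropy, softmax outputs)
            dZ2 = (P - T) / n
            dW2 = H.T @ dZ2
            db2 = dZ2.sum(axis=0)
            dH = (dZ2 @ W2.T) * H * (1.0 - H)
            dW1 = Z.T @ dH
            db1 = dH.sum(axis=0)
            W2 -= lr * dW2
            b2 -= lr * db2
            W1 -= lr * dW1
            b1 -= lr * db1
            if abs(prev - loss) < self.tol:
                break
            prev = loss

        self.coefs_ = [W1, W2]
        self.intercepts_ = [b1, b2]
        self.loss_curve_ = np.array(losses)
        self.n_iter_ = len(losses)
        self.n_features_in_ = d
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = _check_dim(X, self.n_features_in_)
        Z = (X - self.mean_) / self.scale_
        H = _sigmoid(Z @ self.coefs_[0] + self.intercepts_[0])
        return _softmax(H @ self.coefs_[1] + self.intercepts_[1])

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


# ---------------------------------------------------------------------------
# Thin functional wrappers with the (label, score ...) return contracts.
# ---------------------------------------------------------------------------

def nb_fit(X, y, **params) -> GaussianNBActivityClassifier:
    """Fit a Gaussian naive Bayes model on a feature matrix and labels."""
    return GaussianNBActivityClassifier(**params).fit(X, y)


def nb_predict(model: GaussianNBActivityClassifier, x):
    """Predict one sample; returns (class code, normalized posterior vector)."""
    proba = model.predict_proba(np.atleast_2d(x))[0]
    return int(model.classes_[np.argmax(proba)]), proba


def knn_fit(X, y, n_neighbors: int = 1) -> NearestNeighborActivityClassifier:
    """Fit (store) a K-nearest-neighbor model."""
    return NearestNeighborActivityClassifier(n_neighbors=n_neighbors).fit(X, y)


def knn_predict(model: NearestNeighborActivityClassifier, x):
    """Predict one sample; returns (class code, nearest-neighbor distance)."""
    dists, idx = model.kneighbors(np.atleast_2d(x))
    label = model.predict(np.atleast_2d(x))[0]
    return int(label), float(dists[0, 0])


def ann_fit(X, y, n_orders: int, num_hln: int = 8, seed: int = 0, **hyper):
    """Fit the feed-forward network; X must have 4*n_orders columns."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 4 * n_orders:
        raise ValueError(
            f"ANN expects 4*n_orders = {4 * n_orders} input features, "
            f"got {X.shape[1] if X.ndim == 2 else 'non-2D input'}"
        )
    return FeedForwardANNClassifier(
        n_hidden=num_hln, random_state=seed, **hyper
    ).fit(X, y)


def ann_predict(model: FeedForwardANNClassifier, x):
    """Predict one sample; returns (class code, probability vector, one-hot
    prediction vector)."""
    proba = model.predict_proba(np.atleast_2d(x))[0]
    k = int(np.argmax(proba))
    pred = np.zeros_like(proba)
    pred[k] = 1.0
    return int(model.classes_[k]), proba, pred


# ---------------------------------------------------------------------------
# JSON model serialization
# ---------------------------------------------------------------------------

_KIND_BY_CLASS = {
    GaussianNBActivityClassifier: "nb",
    NearestNeighborActivityClassifier: "knn",
    FeedForwardANNClassifier: "ann",
}
_CLASS_BY_KIND = {v: k for k, v in _KIND_BY_CLASS.items()}


def save_model(model, path) -> None:
    """Serialize a fitted classifier to a JSON file.

    The file records the model kind, constructor parameters, class codes
    and all fitted arrays (weights/means/variances/stored training data).
    """
    kind = _KIND_BY_CLASS.get(type(model))
    if kind is None:
        raise TypeError(f"cannot serialize model of type {type(model).__name__}")
    doc: dict = {
        "format": "gaitrec-model",
        "version": 1,
        "kind": kind,
        "params": model.get_params(),
        "classes": np.asarray(model.classes_).tolist(),
        "n_features_in": int(model.n_features_in_),
    }
    if kind == "nb":
        doc["fitted"] = {
            "class_prior": model.class_prior_.tolist(),
            "theta": model.theta_.tolist(),
            "var": model.var_.tolist(),
            "retained_features": model.retained_features_.tolist(),
        }
    elif kind == "knn":
        doc["fitted"] = {"X": model.X_.tolist(), "y": model.y_.tolist()}
    else:
        doc["fitted"] = {
            "coefs": [w.tolist() for w in model.coefs_],
            "intercepts": [b.tolist() for b in model.intercepts_],
            "mean": model.mean_.tolist(),
            "scale": model.scale_.tolist(),
        }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def load_model(path):
    """Load a classifier serialized by :func:`save_model`."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("format") != "gaitrec-model":
        raise ValueError(f"{path} is not a gaitrec model file")
    cls = _CLASS_BY_KIND[doc["kind"]]
    model = cls(**doc["params"])
    model.classes_ = np.array(doc["classes"])
    model.n_features_in_ = int(doc["n_features_in"])
    fitted = doc["fitted"]
    if doc["kind"] == "nb":
        model.class_prior_ = np.array(fitted["class_prior"])
        model.theta_ = np.array(fitted["theta"])
        model.var_ = np.array(fitted["var"])
        model.retained_features_ = np.array(fitted["retained_features"], dtype=int)
    elif doc["kind"] == "knn":
        model.X_ = np.array(fitted["X"])
        model.y_ = np.array(fitted["y"], dtype=int)
    else:
        model.coefs_ = [np.array(w) for w in fitted["coefs"]]
        model.intercepts_ = [np.array(b) for b in fitted["intercepts"]]
        model.mean_ = np.array(fitted["mean"])
        model.scale_ = np.array(fitted["scale"])
    return model
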