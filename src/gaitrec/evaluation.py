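"""K-fold cross-validation, confusion-matrix metrics and the
(n_orders, numHLN) grid search.

The evaluation protocol mirrors the study design of the recognition
method: samples are split into k (default 10) seeded, stratified folds of
as-equal-as-possible size; each fold serves once as the test set; the
reported recognition rate is the mean of per-fold accuracies (with equal
fold sizes this coincides with pooled accuracy — both are kept).
Per-class true/false positive rate, precision and recall come from the
pooled confusion matrix, whose rows are actual classes and columns
predicted classes in L1..L5 code order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.metrics import confusion_matrix as _sk_confusion

from .classifiers import FeedForwardANNClassifier
from .features import feature_matrix


def kfold_split(
    labels, k: int = 10, seed: int = 0, stratified: bool = True
) -> np.ndarray:
    """Assign each sample to one of k folds; returns an int fold-id array.

    Stratified mode shuffles each class independently (seeded) and deals
    per-class remainders to folds through a rotating pointer, so per-class
    fold counts differ by at most one AND total fold sizes stay balanced
    (e.g., 670 samples with the reference class mix give ten folds of 67).
    """
    labels = np.asarray(labels).ravel()
    n = len(labels)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    if not stratified:
        perm = rng.permutation(n)
        for f, chunk in enumerate(np.array_split(perm, k)):
            fold_of[chunk] = f
        return fold_of
    pointer = 0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < k:
            raise ValueError(
                f"class {c} has only {len(idx)} samples; stratified split "
                f"needs at least k={k} per class (or use stratified=False)"
            )
        rng.shuffle(idx)
        q, r = divmod(len(idx), k)
        sizes = np.full(k, q)
        for j in range(r):
            sizes[(pointer + j) % k] += 1
        pointer = (pointer + r) % k
        stop = np.cumsum(sizes)
        start = stop - sizes
        for f in range(k):
            fold_of[idx[start[f]:stop[f]]] = f
    return fold_of


def confusion_from_predictions(y_true, y_pred, labels=None) -> np.ndarray:
    """Confusion counts with rows = actual, columns = predicted class."""
    if labels is None:
        labels = np.unique(np.concatenate([np.asarray(y_true), np.asarray(y_pred)]))
    return _sk_confusion(y_true, y_pred, labels=np.asarray(labels))


@dataclass
class MetricsReport:
    """Per-class and overall metrics derived from one confusion matrix.

    Per-class arrays align with ``labels``. A metric whose denominator is
    zero (empty actual row for TPR/recall, empty predicted column for
    precision, no negatives for FPR) is NaN in the array and flagged False
    in the matching ``*_defined`` mask; macro averages skip undefined
    entries rather than propagating NaN.
    """

    confusion: np.ndarray
    labels: np.ndarray
    accuracy: float
    tpr: np.ndarray
    fpr: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    tpr_defined: np.ndarray
    fpr_defined: np.ndarray
    precision_defined: np.ndarray

    @property
    def macro_tpr(self) -> float:
        return float(np.mean(self.tpr[self.tpr_defined]))

    @property
    def macro_fpr(self) -> float:
        return float(np.mean(self.fpr[self.fpr_defined]))

    @property
    def macro_precision(self) -> float:
        return float(np.mean(self.precision[self.precision_defined]))

    @property
    def macro_recall(self) -> float:
        return self.macro_tpr


def metrics_from_confusion(C, labels=None) -> MetricsReport:
    """Accuracy and per-class TPR/FPR/precision/recall of a confusion matrix.

    accuracy = trace/total; TPR_i = C_ii / rowsum_i;
    precision_i = C_ii / colsum_i; FPR_i = (colsum_i - C_ii) /
    (total - rowsum_i); recall_i = TPR_i.
    """
    C = np.asarray(C)
    if C.ndim != 2 or C.shape[0] != C.shape[1] or C.size == 0:
        raise ValueError(f"confusion matrix must be square and non-empty, got {C.shape}")
    if np.any(C < 0):
        raise ValueError("confusion matrix entries must be nonnegative")
    C = C.astype(float)
    total = C.sum()
    if total <= 0:
        raise ValueError("confusion matrix total must be positive")
    if labels is None:
        labels = np.arange(1, C.shape[0] + 1)
    diag = np.diag(C)
    rowsum = C.sum(axis=1)
    colsum = C.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tpr = np.where(rowsum > 0, diag / rowsum, np.nan)
        precision = np.where(colsum > 0, diag / colsum, np.nan)
        fpr = np.where(total - rowsum > 0, (colsum - diag) / (total - rowsum), np.nan)
    return MetricsReport(
        confusion=C.astype(int),
        labels=np.asarray(labels),
        accuracy=float(np.trace(C) / total),
        tpr=tpr,
        fpr=fpr,
        precision=precision,
        recall=tpr.copy(),
        tpr_defined=rowsum > 0,
        fpr_defined=(total - rowsum) > 0,
        precision_defined=colsum > 0,
    )


@dataclass
class CVResult:
    """Outcome of one k-fold cross-validation run."""

    fold_accuracies: np.ndarray
    overall_accuracy: float          # mean of fold accuracies
    pooled_accuracy: float           # trace/total of the pooled confusion
    confusion: np.ndarray
    metrics: MetricsReport
    fold_of: np.ndarray
    labels: np.ndarray


def cross_validate(
    X, y, estimator, k: int = 10, seed: int = 0, stratified: bool = True
) -> CVResult:
    """Seeded k-fold cross-validation of an unfitted classifier.

    Each sample is tested exactly once; confusion counts are pooled over
    folds. The estimator is cloned per fold, so the input instance is
    never mutated.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel().astype(int)
    fold_of = kfold_split(y, k=k, seed=seed, stratified=stratified)
    labels = np.unique(y)
    y_pred = np.empty_like(y)
    fold_acc = np.empty(k)
    for f in range(k):
        test = fold_of == f
        train = ~test
        try:
            model = clone(estimator).fit(X[train], y[train])
            pred = model.predict(X[test])
        except Exception as exc:
            raise RuntimeError(f"classifier failed on fold {f}: {exc}") from exc
        y_pred[test] = pred
        fold_acc[f] = np.mean(pred == y[test])
    confusion = confusion_from_predictions(y, y_pred, labels=labels)
    metrics = metrics_from_confusion(confusion, labels=labels)
    return CVResult(
        fold_accuracies=fold_acc,
        overall_accuracy=float(fold_acc.mean()),
        pooled_accuracy=metrics.accuracy,
        confusion=confusion,
        metrics=metrics,
        fold_of=fold_of,
        labels=labels,
    )


@dataclass
class GridSearchResult:
    """Accuracy grid of the (n_orders, numHLN) sweep."""

    n_values: np.ndarray
    hln_values: np.ndarray
    accuracies: np.ndarray           # shape (len(n_values), len(hln_values))
    best_n: int
    best_hln: int
    best_accuracy: float
    per_n_mean: np.ndarray = field(default=None)
    n_runs: int = 0

    def __post_init__(self):
        if self.per_n_mean is None:
            self.per_n_mean = self.accuracies.mean(axis=1)


def grid_search(
    cycles,
    n_values=range(1, 17),
    hln_values=range(1, 21),
    k: int = 10,
    seed: int = 0,
    n_exp: int | None = None,
    ann_params: dict | None = None,
) -> GridSearchResult:
    """Cross-validated accuracy over every (n_orders, numHLN) pair.

    Runs one k-fold CV of the feed-forward network per grid cell (the full
    default grid is 16 x 20 = 320 runs) and reports the accuracy grid, the
    per-n average over numHLN, and the argmax cell. Ties at the maximum
    resolve to the smallest (n, numHLN).
    """
    n_values = np.asarray(list(n_values), dtype=int)
    hln_values = np.asarray(list(hln_values), dtype=int)
    if n_values.size == 0 or hln_values.size == 0:
        raise ValueError("grid ranges must be non-empty")
    ann_params = dict(ann_params or {})
    acc = np.empty((len(n_values), len(hln_values)))
    n_runs = 0
    for i, n_ord in enumerate(n_values):
        X, y, _ = feature_matrix(cycles, n_orders=int(n_ord), n_exp=n_exp)
        for j, hln in enumerate(hln_values):
            est = FeedForwardANNClassifier(
                n_hidden=int(hln), random_state=seed, **ann_params
            )
            acc[i, j] = cross_validate(X, y, est, k=k, seed=seed).overall_accuracy
            n_runs += 1
    best_flat = int(np.argmax(acc))
    bi, bj = np.unravel_index(best_flat, acc.shape)
    return GridSearchResult(
        n_values=n_values,
        hln_values=hln_values,
        accuracies=acc,
        best_n=int(n_values[bi]),
        best_hln=int(hln_values[bj]),
        best_accuracy=float(acc[bi, bj]),
        n_runs=n_runs,
    )
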