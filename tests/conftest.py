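"""Shared fixtures: published reference confusion matrices and seeded
synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from gaitrec import (
    ActivityLabel,
    FeedForwardANNClassifier,
    TemplateParams,
    generate_dataset,
)
from gaitrec.features import feature_matrix

# Reference 5x5 confusion matrices of the five-activity benchmark (670
# cycles; rows = actual, columns = predicted, classes L1..L5 = standing up,
# sitting down, walking, going upstairs, going downstairs), one block per
# classifier. They anchor the metric layer: accuracy, per-class TPR/FPR,
# precision and recall are recomputed from these counts in the tests.
REFERENCE_CONFUSIONS = {
    "nb": np.array(
        [
            [136, 0, 0, 1, 2],
            [0, 140, 0, 0, 0],
            [0, 0, 145, 4, 7],
            [1, 0, 3, 118, 0],
            [0, 0, 0, 2, 111],
        ]
    ),
    "knn": np.array(
        [
            [136, 0, 1, 2, 0],
            [0, 140, 0, 0, 0],
            [0, 0, 147, 9, 0],
            [1, 0, 5, 115, 1],
            [0, 0, 3, 4, 106],
        ]
    ),
    "ann": np.array(
        [
            [138, 0, 0, 1, 0],
            [0, 140, 0, 0, 0],
            [0, 0, 155, 0, 1],
            [2, 0, 0, 120, 0],
            [0, 0, 5, 3, 105],
        ]
    ),
}

#: Overall recognition rates implied by the blocks above (percent).
REFERENCE_ACCURACY_PCT = {"nb": 97.01, "knn": 96.12, "ann": 98.21}


@pytest.fixture(scope="session")
def default_dataset():
    """100 cycles per class at default noise, seed 42."""
    return generate_dataset({label: 100 for label in ActivityLabel}, seed=42)


@pytest.fixture(scope="session")
def default_features(default_dataset):
    X, y, n_exp = feature_matrix(default_dataset, n_orders=6)
    return X, y, n_exp


@pytest.fixture(scope="session")
def noiseless_dataset():
    """50 cycles per class with measurement noise switched off, seed 11."""
    params = TemplateParams.default().noiseless()
    return generate_dataset(
        {label: 50 for label in ActivityLabel}, params=params, seed=11
    )


@pytest.fixture(scope="session")
def detection_model(default_features):
    """The deployed network: n=6 spectral orders, 8 hidden nodes."""
    X, y, _ = default_features
    return FeedForwardANNClassifier(n_hidden=8, random_state=1).fit(X, y)
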