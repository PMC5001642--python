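"""Shared fixtures and test oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings
from sklearn.base import BaseEstimator, ClassifierMixin

from crosstest import Dataset

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


class BruteNN(BaseEstimator, ClassifierMixin):
    """Deterministic 1-nearest-neighbor classifier, written out in full so it
    can serve as an independent oracle for the schemes.

    Squared Euclidean distances; ties broken by the lowest training-sample
    index (argmin order).
    """

    def fit(self, X, y):
        self.X_ = np.asarray(X, dtype=float)
        self.y_ = np.asarray(y)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        d2 = ((X[:, None, :] - self.X_[None, :, :]) ** 2).sum(axis=2)
        return self.y_[np.argmin(d2, axis=1)]


def brute_nn_predict(train_X, train_y, X):
    """Free-function 1-NN used to hand-enumerate expected fold accuracies
    independently of the estimator plumbing."""
    train_X = np.asarray(train_X, dtype=float)
    X = np.asarray(X, dtype=float)
    preds = []
    for x in X:
        d2 = ((train_X - x) ** 2).sum(axis=1)
        preds.append(np.asarray(train_y)[int(np.argmin(d2))])
    return np.array(preds)


@pytest.fixture
def brute_nn():
    return BruteNN()


@pytest.fixture
def separable_clouds():
    """Two far-separated point clouds: any sane classifier scores 1.0."""
    rng = np.random.default_rng(42)
    n = 20
    X0 = rng.normal(0.0, 0.3, size=(n, 4))
    X1 = rng.normal(10.0, 0.3, size=(n, 4))
    X = np.vstack([X0, X1])
    y = np.repeat([0, 1], n)
    order = rng.permutation(2 * n)
    return Dataset(X[order], y[order])


@pytest.fixture
def small_random_dataset():
    rng = np.random.default_rng(7)
    return Dataset(rng.random((30, 3)), rng.permutation(np.repeat([0, 1], 15)))
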