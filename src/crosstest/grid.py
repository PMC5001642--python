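"""Candidate-model search space and the train/predict contract.

The search space is a small ordered grid over a preprocessing choice (raw
features vs. PCA keeping a fixed fraction of cumulative variance) crossed
with the soft-margin penalty ``c`` of a support-vector machine.  The default
grid holds the six combinations {no PCA, PCA@0.70} x {c in 1e-4, 1e-2, 1}.

Model fitting is deliberately explicit rather than a pipeline object:
features are standardized with training-partition statistics, PCA (when
requested) is fitted on the training partition only and truncated to the
smallest component count reaching the variance threshold, and the classifier
is an RBF-kernel SVM with scale-heuristic bandwidth.  Any scikit-learn-style
classifier can replace the SVM through ``estimator``; plug-in estimators
receive the raw (unstandardized, non-PCA) features so that deterministic
reference predictors such as 1-nearest-neighbor stay hand-checkable.

A training partition containing a single class yields a constant predictor
of that class (flagged as a fallback) instead of an error, so that sweeps at
very small sample sizes always complete.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import clone
from sklearn.decomposition import PCA
from sklearn.svm import SVC

__all__ = [
    "ParamCombo",
    "ParamGrid",
    "TrainedModel",
    "default_grid",
    "pca_component_count",
    "fit_model",
    "model_accuracy",
]

DEFAULT_PENALTIES = (0.0001, 0.01, 1.0)
DEFAULT_VARIANCE_THRESHOLD = 0.70


@dataclass(frozen=True)
class ParamCombo:
    """One candidate configuration: preprocessing choice plus SVM penalty."""

    use_pca: bool
    c_penalty: float
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD

    def __post_init__(self) -> None:
        if self.c_penalty <= 0:
            raise ValueError(f"c_penalty must be > 0, got {self.c_penalty}")
        if not 0 < self.variance_threshold <= 1:
            raise ValueError(
                f"variance_threshold must be in (0, 1], got {self.variance_threshold}"
            )

    def label(self) -> str:
        pca = f"pca{self.variance_threshold:g}" if self.use_pca else "raw"
        return f"{pca}/c={self.c_penalty:g}"


@dataclass(frozen=True)
class ParamGrid:
    """Ordered, duplicate-free list of candidate combinations.

    The declared order is part of the contract: cross-validation ties are
    broken in favor of the earliest combination.
    """

    combos: tuple[ParamCombo, ...]

    def __post_init__(self) -> None:
        if not self.combos:
            raise ValueError("grid must contain at least one combination")
        if len(set(self.combos)) != len(self.combos):
            raise ValueError("grid contains duplicate combinations")

    def __iter__(self):
        return iter(self.combos)

    def __len__(self) -> int:
        return len(self.combos)


def default_grid(
    penalties: Sequence[float] = DEFAULT_PENALTIES,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
) -> ParamGrid:
    """The default six-combination grid: preprocessing outer, penalty inner,
    penalties ascending."""
    combos = [
        ParamCombo(use_pca=use_pca, c_penalty=c, variance_threshold=variance_threshold)
        for use_pca in (False, True)
        for c in sorted(penalties)
    ]
    return ParamGrid(tuple(combos))


def pca_component_count(variance_ratios: Sequence[float], threshold: float) -> int:
    """Smallest number of leading components whose cumulative explained
    variance ratio reaches ``threshold``; the full count if it never does."""
    ratios = np.asarray(variance_ratios, dtype=float)
    if ratios.size == 0:
        raise ValueError("variance_ratios must be non-empty")
    if np.any(ratios < 0):
        raise ValueError("variance_ratios must be non-negative")
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    cumulative = np.cumsum(ratios)
    reached = np.flatnonzero(cumulative >= threshold - 1e-12)
    return int(reached[0]) + 1 if reached.size else int(ratios.size)


@dataclass
class TrainedModel:
    """A fitted predictor together with its configuration record.

    ``n_pca_components`` is 0 when PCA was not used; ``is_fallback`` marks a
    constant predictor returned for a single-class training partition.
    """

    params: ParamCombo
    n_pca_components: int
    is_fallback: bool
    n_features_in: int
    _predictor: object
    _mean: np.ndarray | None = None
    _scale: np.ndarray | None = None
    _pca: PCA | None = None
    _constant: int | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in:
            raise ValueError(
                f"expected {self.n_features_in} features, got shape {X.shape}"
            )
        if self._constant is not None:
            return np.full(X.shape[0], self._constant, dtype=int)
        if self._mean is not None:
            X = (X - self._mean) / self._scale
        if self._pca is not None:
            X = self._pca.transform(X)[:, : self.n_pca_components]
        return np.asarray(self._predictor.predict(X), dtype=int)


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0  # constant feature: leave centered at zero
    return (X - mean) / scale, mean, scale


def fit_model(
    X: np.ndarray,
    y: np.ndarray,
    params: ParamCombo,
    estimator=None,
) -> TrainedModel:
    """Fit one candidate model on a training partition.

    With the default SVM, features are standardized using training statistics
    and optionally PCA-reduced (components fitted on the training partition
    only) before the classifier is fitted.  A custom ``estimator`` (anything
    with ``fit``/``predict``) is cloned and fitted on the raw features, and
    the preprocessing flags of ``params`` are ignored.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("training set must contain at least one sample")
    if len(y) != X.shape[0]:
        raise ValueError("features and labels disagree in length")
    classes = np.unique(y)
    if classes.size == 1:
        return TrainedModel(
            params=params,
            n_pca_components=0,
            is_fallback=True,
            n_features_in=X.shape[1],
            _predictor=None,
            _constant=int(classes[0]),
        )

    if estimator is not None:
        predictor = clone(estimator)
        predictor.fit(X, y)
        return TrainedModel(
            params=params,
            n_pca_components=0,
            is_fallback=False,
            n_features_in=X.shape[1],
            _predictor=predictor,
        )

    Xs, mean, scale = _standardize_fit(X)
    pca = None
    n_components = 0
    if params.use_pca:
        pca = PCA(svd_solver="full")
        pca.fit(Xs)
        n_components = pca_component_count(
            pca.explained_variance_ratio_, params.variance_threshold
        )
        Xs = pca.transform(Xs)[:, :n_components]
    svm = SVC(C=params.c_penalty, kernel="rbf", gamma="scale")
    svm.fit(Xs, y)
    return TrainedModel(
        params=params,
        n_pca_components=n_components,
        is_fallback=False,
        n_features_in=X.shape[1],
        _predictor=svm,
        _mean=mean,
        _scale=scale,
        _pca=pca,
    )


def model_accuracy(model: TrainedModel, X: np.ndarray, y: np.ndarray) -> float:
    """Fraction of samples whose predicted label equals the true label."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] == 0:
        raise ValueError("evaluation set must be non-empty")
    predictions = model.predict(X)
    return float(np.mean(predictions == y))
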