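"""The three evaluation schemes for small-sample classification.

Given a labeled dataset and a finite grid of candidate configurations, each
scheme answers the same question — how accurately can this data be
classified, using cross-validation to pick the configuration — while
splitting the data differently:

* **Cross-validation and testing** (:class:`CrossValidationAndTest`): the
  data are split once into a cross-validation set and a test set.  The
  configuration with the highest k-fold CV accuracy on the CV set wins, a
  single model is fitted on the whole CV set, and its accuracy is measured
  on the untouched test set.  Yields an interpretable configuration *and* a
  deployable model, but the test set contributes nothing to model fitting.

* **Nested cross-validation** (:class:`NestedCrossValidation`): an outer
  k-fold loop estimates accuracy; within each outer training portion an
  inner CV picks that fold's configuration.  Maximally data-efficient, but
  neither a single configuration nor a single model results.

* **Cross-validation and cross-testing**
  (:class:`CrossValidationAndCrossTest`): the split and the configuration
  choice are exactly as in cross-validation and testing, but the test set is
  then partitioned into k' folds and, for each fold, a model is fitted on
  the CV set *plus the remaining test folds* and scored on the held-out
  fold.  Every scored sample is still unseen by the model scoring it, yet
  almost all data participate in fitting — an interpolation between the two
  classical schemes that keeps the chosen configuration interpretable.

All schemes stratify every split and fold by class, record an audit trail of
(training indices, evaluation indices) pairs, and are deterministic given
``random_state``.  The estimators follow scikit-learn conventions (``fit``,
``get_params``, trailing-underscore fitted attributes); thin functional
wrappers operate on :class:`~crosstest.datasets.Dataset` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from ._rng import as_generator
from .datasets import Dataset
from .grid import ParamCombo, ParamGrid, default_grid, fit_model, model_accuracy

__all__ = [
    "FoldAssignment",
    "SplitConfig",
    "SelectionResult",
    "SchemeResult",
    "make_folds",
    "split_cv_test",
    "select_params_cv",
    "cross_test",
    "CrossValidationAndTest",
    "CrossValidationAndCrossTest",
    "NestedCrossValidation",
    "evaluate_cv_and_test",
    "evaluate_cv_and_crosstest",
    "evaluate_nested_cv",
    "SCHEMES",
]


@dataclass(frozen=True)
class FoldAssignment:
    """A k-way partition of sample indices: ``fold_of[i]`` is the fold id of
    sample ``i``, in ``1..k``."""

    fold_of: np.ndarray
    k: int

    def indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)


@dataclass(frozen=True)
class SplitConfig:
    """Partition sizes shared by the split-based schemes."""

    test_fraction: float = 0.5
    k_select: int = 5
    k_test: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError(f"test_fraction must be in (0, 1), got {self.test_fraction}")
        if self.k_select < 2:
            raise ValueError("k_select must be >= 2")
        if self.k_test < 1:
            raise ValueError("k_test must be >= 1")


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the parameter-selection cross-validation."""

    best: ParamCombo
    mean_cv_accuracy: dict[ParamCombo, float]


@dataclass
class SchemeResult:
    """One full evaluation run: scheme name, accuracy, the selected
    configuration (absent for nested CV), and optional significance fields."""

    scheme: str
    accuracy: float
    selection: SelectionResult | None = None
    p_value: float | None = None
    p_strict: float | None = None
    significant: bool | None = None
    randomized: bool | None = None
    fallback_count: int = 0
    extras: dict = field(default_factory=dict)


def make_folds(labels, k: int, rng: np.random.Generator) -> FoldAssignment:
    """Stratified random k-fold assignment.

    Within each class the sample indices are shuffled and dealt round-robin
    into folds; the dealing position carries over between classes so total
    fold sizes stay balanced.  Within-class fold sizes differ by at most 1.
    """
    y = np.asarray(labels)
    n = len(y)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    fold_of = np.empty(n, dtype=int)
    cursor = 0
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        rng.shuffle(members)
        for idx in members:
            fold_of[idx] = cursor % k + 1
            cursor += 1
    return FoldAssignment(fold_of=fold_of, k=k)


def split_cv_test(
    labels, test_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random split into (cv indices, test indices).

    Per class, ``round(test_fraction * n_class)`` samples (half-up rounding)
    go to the test set.  Raises if any class would be absent from either
    side — the caller's sample size is then too small for this fraction.
    """
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    y = np.asarray(labels)
    cv_parts, test_parts = [], []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        n_cls = len(members)
        n_test = int(np.floor(test_fraction * n_cls + 0.5))
        if n_test < 1 or n_test >= n_cls:
            raise ValueError(
                f"test_fraction={test_fraction} leaves class {cls} with "
                f"{n_test} of {n_cls} samples in the test set; both sides of "
                f"the split need at least one sample per class"
            )
        rng.shuffle(members)
        test_parts.append(members[:n_test])
        cv_parts.append(members[n_test:])
    return np.sort(np.concatenate(cv_parts)), np.sort(np.concatenate(test_parts))


class _Audit:
    """Collects (train indices, eval indices) pairs for leakage checks."""

    def __init__(self) -> None:
        self.records: list[tuple[frozenset, frozenset]] = []

    def add(self, train_idx, eval_idx) -> None:
        self.records.append((frozenset(map(int, train_idx)), frozenset(map(int, eval_idx))))


def select_params_cv(
    X,
    y,
    grid: ParamGrid,
    k_select: int,
    rng: np.random.Generator,
    estimator=None,
    audit: _Audit | None = None,
    indices=None,
) -> tuple[SelectionResult, int]:
    """Choose the best combination by stratified k-fold cross-validation.

    One fold assignment is drawn and reused for every combination, so the
    comparison across the grid is paired.  Ties are broken in favor of the
    earliest combination in grid order.  Returns the selection and the
    number of degenerate-fold fallback models encountered.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(y) < k_select:
        raise ValueError(f"need at least k_select={k_select} samples, got {len(y)}")
    ids = np.arange(len(y)) if indices is None else np.asarray(indices)
    folds = make_folds(y, k_select, rng)
    fallbacks = 0
    table: dict[ParamCombo, float] = {}
    fold_masks = [(folds.fold_of == f) for f in range(1, k_select + 1)]
    for combo in grid:
        accs = []
        for mask in fold_masks:
            model = fit_model(X[~mask], y[~mask], combo, estimator=estimator)
            fallbacks += model.is_fallback
            accs.append(model_accuracy(model, X[mask], y[mask]))
            if audit is not None:
                audit.add(ids[~mask], ids[mask])
        table[combo] = float(np.mean(accs))
    best = max(grid, key=lambda c: table[c])  # max() keeps the first argmax
    return SelectionResult(best=best, mean_cv_accuracy=table), fallbacks


def cross_test(
    X_cv,
    y_cv,
    X_test,
    y_test,
    params: ParamCombo,
    k_test: int,
    rng: np.random.Generator,
    estimator=None,
    aggregate: str = "mean",
    audit: _Audit | None = None,
    cv_indices=None,
    test_indices=None,
) -> tuple[float, int]:
    """Cross-testing: evaluate ``params`` on the test set while recycling it
    for training.

    The test set is partitioned into ``k_test`` stratified folds; for each
    fold a model is fitted on the full CV set plus the *other* test folds
    and scored on the held-out fold.  With ``k_test=1`` this reduces exactly
    to the plain holdout evaluation.  ``aggregate`` is the unweighted mean
    of fold accuracies by default, or ``"pooled"`` for the pooled
    misclassification count.  Returns (accuracy, fallback count).
    """
    X_cv = np.asarray(X_cv, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_cv = np.asarray(y_cv)
    y_test = np.asarray(y_test)
    if k_test > len(y_test):
        raise ValueError(f"k_test={k_test} exceeds test-set size {len(y_test)}")
    if aggregate not in ("mean", "pooled"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    cv_ids = np.arange(len(y_cv)) if cv_indices is None else np.asarray(cv_indices)
    test_ids = (
        np.arange(len(y_cv), len(y_cv) + len(y_test))
        if test_indices is None
        else np.asarray(test_indices)
    )
    folds = make_folds(y_test, k_test, rng)
    fallbacks = 0
    fold_accs, fold_sizes = [], []
    for f in range(1, k_test + 1):
        mask = folds.fold_of == f
        X_train = np.vstack([X_cv, X_test[~mask]])
        y_train = np.concatenate([y_cv, y_test[~mask]])
        model = fit_model(X_train, y_train, params, estimator=estimator)
        fallbacks += model.is_fallback
        fold_accs.append(model_accuracy(model, X_test[mask], y_test[mask]))
        fold_sizes.append(int(mask.sum()))
        if audit is not None:
            audit.add(np.concatenate([cv_ids, test_ids[~mask]]), test_ids[mask])
    if aggregate == "pooled":
        accuracy = float(np.average(fold_accs, weights=fold_sizes))
    else:
        accuracy = float(np.mean(fold_accs))
    return accuracy, fallbacks


class _SchemeEstimator(BaseEstimator):
    """Shared plumbing: RNG substreams, grid default, audit trail."""

    scheme_name: str = ""

    def _resolve_grid(self) -> ParamGrid:
        return self.grid if self.grid is not None else default_grid()

    def _spawn_rngs(self, n: int):
        # Dedicated substreams: the split and selection streams are spent in
        # the same order by every split-based scheme, so two schemes given
        # the same seed pick the same partition and the same configuration.
        return as_generator(self.random_state).spawn(n)

    def _validate_Xy(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(y) != X.shape[0]:
            raise ValueError("X and y disagree in length")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X, y

    def result(self) -> SchemeResult:
        """Package the fitted attributes as a :class:`SchemeResult`."""
        return SchemeResult(
            scheme=self.scheme_name,
            accuracy=self.accuracy_,
            selection=getattr(self, "selection_", None),
            fallback_count=self.fallback_count_,
        )


class CrossValidationAndTest(_SchemeEstimator):
    """Classical split-once evaluation: CV-based selection, holdout testing.

    Parameters
    ----------
    grid : ParamGrid or None
        Candidate configurations; the default six-combination grid if None.
    test_fraction : float
        Fraction of each class routed to the test set.
    k_select : int
        Folds of the selection cross-validation.
    estimator : object or None
        Optional plug-in classifier replacing the default SVM.
    random_state : int, Generator or None

    Attributes (after ``fit``)
    --------------------------
    best_params_ : the selected configuration.
    selection_ : SelectionResult with the per-combination CV accuracy table.
    accuracy_ : holdout accuracy of the final model on the test set.
    cv_indices_, test_indices_ : the split actually used.
    audit_ : list of (train indices, eval indices) pairs, one per model fit
        that was scored, for leakage auditing.
    """

    scheme_name = "cv_and_test"

    def __init__(
        self,
        grid: ParamGrid | None = None,
        test_fraction: float = 0.5,
        k_select: int = 5,
        estimator=None,
        random_state=None,
    ):
        self.grid = grid
        self.test_fraction = test_fraction
        self.k_select = k_select
        self.estimator = estimator
        self.random_state = random_state

    def fit(self, X, y):
        X, y = self._validate_Xy(X, y)
        rng_split, rng_select, _ = self._spawn_rngs(3)
        audit = _Audit()
        cv_idx, test_idx = split_cv_test(y, self.test_fraction, rng_split)
        selection, fb_sel = select_params_cv(
            X[cv_idx], y[cv_idx], self._resolve_grid(), self.k_select,
            rng_select, estimator=self.estimator, audit=audit, indices=cv_idx,
        )
        final = fit_model(X[cv_idx], y[cv_idx], selection.best, estimator=self.estimator)
        audit.add(cv_idx, test_idx)
        self.accuracy_ = model_accuracy(final, X[test_idx], y[test_idx])
        self.best_params_ = selection.best
        self.selection_ = selection
        self.model_ = final
        self.fallback_count_ = fb_sel + final.is_fallback
        self.cv_indices_, self.test_indices_ = cv_idx, test_idx
        self.audit_ = audit.records
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        return self.model_.predict(X)

    def testing_evaluator(self):
        """Evaluator re-running only the testing stage with the selected
        configuration frozen (for fixed-selection permutation tests)."""
        params, fraction, est = self.best_params_, self.test_fraction, self.estimator

        def evaluate(X, y, rng):
            rng_split, _, _ = rng.spawn(3)
            cv_idx, test_idx = split_cv_test(y, fraction, rng_split)
            model = fit_model(X[cv_idx], y[cv_idx], params, estimator=est)
            return model_accuracy(model, X[test_idx], y[test_idx])

        return evaluate


class CrossValidationAndCrossTest(_SchemeEstimator):
    """Split-once evaluation with test-data recycling (cross-testing).

    Selection is identical to :class:`CrossValidationAndTest` — with the same
    ``random_state`` the two schemes draw the same split and choose the same
    configuration — but accuracy is then estimated by k'-fold cross-testing:
    each test fold is scored by a model trained on the CV set plus the other
    test folds.  See the module docstring for the rationale.
    """

    scheme_name = "cv_and_crosstest"

    def __init__(
        self,
        grid: ParamGrid | None = None,
        test_fraction: float = 0.5,
        k_select: int = 5,
        k_test: int = 5,
        aggregate: str = "mean",
        estimator=None,
        random_state=None,
    ):
        self.grid = grid
        self.test_fraction = test_fraction
        self.k_select = k_select
        self.k_test = k_test
        self.aggregate = aggregate
        self.estimator = estimator
        self.random_state = random_state

    def fit(self, X, y):
        X, y = self._validate_Xy(X, y)
        rng_split, rng_select, rng_test = self._spawn_rngs(3)
        audit = _Audit()
        cv_idx, test_idx = split_cv_test(y, self.test_fraction, rng_split)
        selection, fb_sel = select_params_cv(
            X[cv_idx], y[cv_idx], self._resolve_grid(), self.k_select,
            rng_select, estimator=self.estimator, audit=audit, indices=cv_idx,
        )
        accuracy, fb_test = cross_test(
            X[cv_idx], y[cv_idx], X[test_idx], y[test_idx],
            selection.best, self.k_test, rng_test,
            estimator=self.estimator, aggregate=self.aggregate,
            audit=audit, cv_indices=cv_idx, test_indices=test_idx,
        )
        self.accuracy_ = accuracy
        self.best_params_ = selection.best
        self.selection_ = selection
        self.fallback_count_ = fb_sel + fb_test
        self.cv_indices_, self.test_indices_ = cv_idx, test_idx
        self.audit_ = audit.records
        self.n_features_in_ = X.shape[1]
        return self

    def testing_evaluator(self):
        """Evaluator re-running split + cross-testing with the selected
        configuration frozen."""
        params, est = self.best_params_, self.estimator
        fraction, k_test, aggregate = self.test_fraction, self.k_test, self.aggregate

        def evaluate(X, y, rng):
            rng_split, _, rng_test = rng.spawn(3)
            cv_idx, test_idx = split_cv_test(y, fraction, rng_split)
            accuracy, _ = cross_test(
                X[cv_idx], y[cv_idx], X[test_idx], y[test_idx],
                params, k_test, rng_test, estimator=est, aggregate=aggregate,
            )
            return accuracy

        return evaluate


class NestedCrossValidation(_SchemeEstimator):
    """Nested cross-validation: outer folds estimate accuracy, inner CV
    selects a configuration per outer fold.

    No single configuration or model results; ``fold_params_`` records the
    per-fold choices and ``accuracy_`` is the unweighted mean of outer-fold
    accuracies.
    """

    scheme_name = "nested_cv"

    def __init__(
        self,
        grid: ParamGrid | None = None,
        k_outer: int = 5,
        k_inner: int = 5,
        estimator=None,
        random_state=None,
    ):
        self.grid = grid
        self.k_outer = k_outer
        self.k_inner = k_inner
        self.estimator = estimator
        self.random_state = random_state

    def fit(self, X, y):
        X, y = self._validate_Xy(X, y)
        classes, counts = np.unique(y, return_counts=True)
        if counts.min() < self.k_outer:
            raise ValueError(
                f"need at least k_outer={self.k_outer} samples of each class"
            )
        rngs = self._spawn_rngs(1 + self.k_outer)
        audit = _Audit()
        outer = make_folds(y, self.k_outer, rngs[0])
        grid = self._resolve_grid()
        fold_accs, fold_params, fallbacks = [], [], 0
        all_idx = np.arange(len(y))
        for f in range(1, self.k_outer + 1):
            mask = outer.fold_of == f
            train_idx, eval_idx = all_idx[~mask], all_idx[mask]
            selection, fb = select_params_cv(
                X[train_idx], y[train_idx], grid, self.k_inner,
                rngs[f], estimator=self.estimator, audit=audit, indices=train_idx,
            )
            model = fit_model(
                X[train_idx], y[train_idx], selection.best, estimator=self.estimator
            )
            audit.add(train_idx, eval_idx)
            fold_accs.append(model_accuracy(model, X[eval_idx], y[eval_idx]))
            fold_params.append(selection.best)
            fallbacks += fb + model.is_fallback
        self.accuracy_ = float(np.mean(fold_accs))
        self.fold_accuracies_ = fold_accs
        self.fold_params_ = fold_params
        self.fallback_count_ = fallbacks
        self.audit_ = audit.records
        self.n_features_in_ = X.shape[1]
        return self


SCHEMES = {
    cls.scheme_name: cls
    for cls in (CrossValidationAndTest, CrossValidationAndCrossTest, NestedCrossValidation)
}


def _run(cls, dataset: Dataset, grid, seed, **kwargs) -> SchemeResult:
    est = cls(grid=grid, random_state=seed, **kwargs)
    est.fit(dataset.features, dataset.labels)
    return est.result()


def evaluate_cv_and_test(
    dataset: Dataset,
    grid: ParamGrid | None = None,
    split: SplitConfig = SplitConfig(),
    seed: int | np.random.Generator | None = None,
    estimator=None,
) -> SchemeResult:
    """Run the cross-validation-and-testing scheme on a dataset."""
    return _run(
        CrossValidationAndTest, dataset, grid, seed,
        test_fraction=split.test_fraction, k_select=split.k_select, estimator=estimator,
    )


def evaluate_cv_and_crosstest(
    dataset: Dataset,
    grid: ParamGrid | None = None,
    split: SplitConfig = SplitConfig(),
    seed: int | np.random.Generator | None = None,
    estimator=None,
) -> SchemeResult:
    """Run the cross-validation-and-cross-testing scheme on a dataset."""
    return _run(
        CrossValidationAndCrossTest, dataset, grid, seed,
        test_fraction=split.test_fraction, k_select=split.k_select,
        k_test=split.k_test, estimator=estimator,
    )


def evaluate_nested_cv(
    dataset: Dataset,
    grid: ParamGrid | None = None,
    k_outer: int = 5,
    k_inner: int = 5,
    seed: int | np.random.Generator | None = None,
    estimator=None,
) -> SchemeResult:
    """Run nested cross-validation on a dataset."""
    return _run(
        NestedCrossValidation, dataset, grid, seed,
        k_outer=k_outer, k_inner=k_inner, estimator=estimator,
    )
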