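"""Synthetic two-class datasets and CSV I/O.

Two generators are provided:

* :func:`generate_simulated` — a six-feature, linearly inseparable two-class
  problem.  All features are uniform(0, 1); each class is a mixture of two
  subgroups with a constant offset added to selected dimensions, producing an
  XOR-like layout in the first two dimensions with identical per-class
  marginal means.
* :func:`generate_random` — a pure null: uniform(0, 1) features with labels
  assigned by independent fair coin flips, so no feature–label dependence
  exists by construction.  Used to calibrate the type-I error of the full
  evaluation pipelines.

Datasets travel as a lightweight :class:`Dataset` container (a float feature
matrix plus an integer 0/1 label vector).  CSV files carry one header row,
a ``label`` column and numeric feature columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import as_generator

__all__ = [
    "Dataset",
    "SimulatedSpec",
    "RandomSpec",
    "generate_simulated",
    "generate_random",
    "read_dataset_csv",
    "write_dataset_csv",
    "subsample",
]


class DatasetFormatError(ValueError):
    """Raised when a CSV file does not conform to the dataset format."""


@dataclass(frozen=True)
class Dataset:
    """A labeled tabular dataset: ``features`` (n_samples, n_features) and
    binary ``labels`` (n_samples,) encoded as integers 0/1."""

    features: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=float)
        y = np.asarray(self.labels)
        if X.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if y.ndim != 1 or len(y) != X.shape[0]:
            raise ValueError(
                f"labels length {y.shape} does not match {X.shape[0]} feature rows"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("features contain non-finite entries")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y.astype(int))

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> dict[int, int]:
        values, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(values.tolist(), counts.tolist()))


@dataclass(frozen=True)
class SimulatedSpec:
    """Parameters of the linearly inseparable simulated problem.

    ``per_subgroup`` samples are drawn for each of the four subgroups (two per
    class), for ``4 * per_subgroup`` samples in total; ``offset`` is added to
    dimension 0 and/or 1 depending on the subgroup.
    """

    per_subgroup: int = 2000
    n_features: int = 6
    offset: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.per_subgroup < 1:
            raise ValueError(f"per_subgroup must be >= 1, got {self.per_subgroup}")
        if self.n_features < 2:
            raise ValueError(f"n_features must be >= 2, got {self.n_features}")


@dataclass(frozen=True)
class RandomSpec:
    """Parameters of the random-label null dataset."""

    n_samples: int = 10_000
    n_features: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError(f"n_samples must be >= 2, got {self.n_samples}")
        if self.n_features < 1:
            raise ValueError(f"n_features must be >= 1, got {self.n_features}")


def generate_simulated(spec: SimulatedSpec = SimulatedSpec()) -> Dataset:
    """Generate the linearly inseparable two-class dataset.

    Class 0 mixes an unmodified subgroup with a subgroup offset in both of
    the first two dimensions; class 1 mixes subgroups offset in exactly one
    of them.  Per-class marginal means on every dimension are therefore
    identical, but the joint layout in dimensions (0, 1) is separable by a
    nonlinear boundary.  Rows are shuffled before return so that contiguous
    subsets are random with respect to the subgroup structure.
    """
    spec.validate()
    rng = as_generator(spec.seed)
    m, d, off = spec.per_subgroup, spec.n_features, spec.offset
    X = rng.random((4 * m, d))
    # subgroup blocks: [A1 | A2 | B1 | B2], each of size m
    X[m : 2 * m, 0] += off
    X[m : 2 * m, 1] += off
    X[2 * m : 3 * m, 0] += off
    X[3 * m : 4 * m, 1] += off
    y = np.repeat([0, 0, 1, 1], m)
    order = rng.permutation(4 * m)
    return Dataset(X[order], y[order])


def generate_random(spec: RandomSpec = RandomSpec()) -> Dataset:
    """Generate the random-label null dataset: uniform features, labels
    flipped independently with probability 1/2 each."""
    spec.validate()
    rng = as_generator(spec.seed)
    X = rng.random((spec.n_samples, spec.n_features))
    y = rng.integers(0, 2, size=spec.n_samples)
    return Dataset(X, y)


def subsample(dataset: Dataset, n: int, rng: np.random.Generator) -> Dataset:
    """Stratified subsample of ``n`` rows without replacement.

    Per-class counts are proportional to the class frequencies in the source
    (largest-remainder rounding), so small subsamples cannot collapse onto a
    single class as long as ``n >= 2``.
    """
    if n > dataset.n_samples:
        raise ValueError(f"cannot subsample {n} from {dataset.n_samples} rows")
    if n < 2:
        raise ValueError("subsample size must be >= 2")
    classes, counts = np.unique(dataset.labels, return_counts=True)
    quotas = counts * n / dataset.n_samples
    take = np.floor(quotas).astype(int)
    remainder = np.argsort(-(quotas - take))
    for idx in remainder[: n - take.sum()]:
        take[idx] += 1
    take = np.maximum(take, 1)
    while take.sum() > n:  # restore total if the floor-of-1 bumped it
        take[np.argmax(take)] -= 1
    picked = []
    for cls, cnt in zip(classes, take):
        members = np.flatnonzero(dataset.labels == cls)
        picked.append(rng.choice(members, size=cnt, replace=False))
    idx = np.concatenate(picked)
    rng.shuffle(idx)
    return Dataset(dataset.features[idx], dataset.labels[idx], dataset.feature_names)


def write_dataset_csv(dataset: Dataset, path) -> None:
    """Write a dataset as CSV: header row, numeric feature columns, and a
    ``label`` column; no index column."""
    names = dataset.feature_names or tuple(
        f"f{i}" for i in range(dataset.n_features)
    )
    frame = pd.DataFrame(dataset.features, columns=list(names))
    frame["label"] = dataset.labels
    frame.to_csv(path, index=False)


def read_dataset_csv(path) -> Dataset:
    """Read a dataset from CSV.

    Requires a ``label`` column and numeric feature columns.  Labels may be
    arbitrary values with exactly two distinct levels.  Literal 0/1 labels
    are kept as-is (so write-then-read round-trips exactly); any other pair
    is mapped to 0/1 in order of first occurrence, which makes the mapping
    deterministic.
    """
    frame = pd.read_csv(path)
    if "label" not in frame.columns:
        raise DatasetFormatError(f"{path}: no 'label' column in header")
    feature_cols = [c for c in frame.columns if c != "label"]
    if not feature_cols:
        raise DatasetFormatError(f"{path}: no feature columns besides 'label'")
    features = frame[feature_cols]
    bad = [c for c in feature_cols if not np.issubdtype(features[c].dtype, np.number)]
    if bad:
        raise DatasetFormatError(f"{path}: non-numeric feature column(s) {bad}")
    if features.isna().any().any():
        row, col = next(
            (r, c) for c in feature_cols for r in frame.index[features[c].isna()]
        )
        raise DatasetFormatError(f"{path}: missing value at row {row}, column {col!r}")
    raw = frame["label"].to_numpy()
    levels = list(pd.unique(raw))
    if len(levels) != 2:
        raise DatasetFormatError(
            f"{path}: expected exactly 2 distinct labels, found {len(levels)}"
        )
    if set(levels) == {0, 1}:
        y = raw.astype(int)
    else:
        y = np.array([levels.index(v) for v in raw])
    return Dataset(features.to_numpy(dtype=float), y, tuple(feature_cols))
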