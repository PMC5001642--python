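"""Monte-Carlo sweep experiments over the three evaluation schemes.

The study design: a large reference dataset is generated once (or loaded
from CSV); for each experimental condition — either a total sample size at a
fixed test fraction, or a test fraction at a fixed sample size — a stratified
subsample is drawn, one scheme is run on it, and a permutation test attaches
a significance call.  Repeating this ``n_reps`` times per condition yields
the two summary curves: mean accuracy and proportion of significant results.

Every replicate is a pure function of ``(master_seed, condition, scheme,
replicate index)``: each cell gets its own seed substream, so sweeps are
reproducible bit-for-bit and individual replicates can be rerun in
isolation.

Scale defaults are desk-sized (``n_reps=100`` replicates and ``N=199``
permutations rather than 1,000/1,000); Monte-Carlo standard errors are
reported alongside every aggregate so comparisons remain honest, and
full-scale values are plain config settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from ._rng import child_rng
from .datasets import (
    Dataset,
    RandomSpec,
    SimulatedSpec,
    generate_random,
    generate_simulated,
    read_dataset_csv,
    subsample,
)
from .grid import ParamGrid, default_grid
from .schemes import SCHEMES, SchemeResult, NestedCrossValidation
from .significance import SignificanceConfig, permutation_test

__all__ = [
    "ExperimentConfig",
    "SweepRow",
    "load_config",
    "make_reference",
    "run_one",
    "sweep_dataset_size",
    "sweep_test_fraction",
    "aggregate_rows",
    "REP_LOG_COLUMNS",
]

REP_LOG_COLUMNS = [
    "condition",
    "scheme",
    "rep",
    "accuracy",
    "p_geq",
    "p_gt",
    "significant",
    "randomized",
    "best_combo",
    "fallback_count",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Full description of one sweep.

    ``reference`` names the reference data source: ``"simulated"``,
    ``"random"``, or a CSV path prefixed with ``csv:``.  Exactly one of
    ``sizes`` / ``test_fractions`` must be set.
    """

    reference: str = "simulated"
    schemes: tuple[str, ...] = ("cv_and_test", "nested_cv", "cv_and_crosstest")
    sizes: tuple[int, ...] | None = None
    test_fractions: tuple[float, ...] | None = None
    fixed_n: int = 100
    fixed_test_fraction: float = 0.5
    n_reps: int = 100
    k_select: int = 5
    k_test: int = 5
    k_outer: int = 5
    k_inner: int = 5
    sig: SignificanceConfig = field(
        default_factory=lambda: SignificanceConfig(n_permutations=199, mode="fixed_selection")
    )
    run_significance: bool = True
    master_seed: int = 0
    generator_options: dict = field(default_factory=dict)
    grid: ParamGrid | None = None

    def __post_init__(self) -> None:
        if (self.sizes is None) == (self.test_fractions is None):
            raise ValueError("exactly one of sizes / test_fractions must be set")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        unknown = set(self.schemes) - set(SCHEMES)
        if unknown:
            raise ValueError(f"unknown scheme(s): {sorted(unknown)}")

    def resolve_grid(self) -> ParamGrid:
        return self.grid if self.grid is not None else default_grid()


@dataclass(frozen=True)
class SweepRow:
    """Aggregated cell of a sweep: one condition x one scheme."""

    condition: float
    scheme: str
    mean_accuracy: float
    proportion_significant: float | None
    n_reps: int
    se_accuracy: float
    se_significant: float | None


def load_config(path) -> ExperimentConfig:
    """Load an ExperimentConfig from a YAML or JSON file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    sig_raw = raw.pop("sig", None)
    kwargs = dict(raw)
    for key in ("schemes", "sizes", "test_fractions"):
        if kwargs.get(key) is not None:
            kwargs[key] = tuple(kwargs[key])
    if sig_raw is not None:
        kwargs["sig"] = SignificanceConfig(**sig_raw)
    try:
        return ExperimentConfig(**kwargs)
    except TypeError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def make_reference(config: ExperimentConfig) -> Dataset:
    """Build the reference dataset the sweep subsamples from."""
    seed = int(child_rng(config.master_seed, "reference").integers(2**31))
    opts = dict(config.generator_options)
    if config.reference == "simulated":
        return generate_simulated(SimulatedSpec(seed=seed, **opts))
    if config.reference == "random":
        return generate_random(RandomSpec(seed=seed, **opts))
    if config.reference.startswith("csv:"):
        return read_dataset_csv(config.reference[4:])
    raise ValueError(
        f"unknown reference {config.reference!r}; expected 'simulated', 'random' or 'csv:<path>'"
    )


def _build_estimator(scheme: str, config: ExperimentConfig, test_fraction: float, rng):
    cls = SCHEMES[scheme]
    if scheme == "nested_cv":
        return cls(
            grid=config.resolve_grid(), k_outer=config.k_outer,
            k_inner=config.k_inner, random_state=rng,
        )
    kwargs = dict(
        grid=config.resolve_grid(), test_fraction=test_fraction,
        k_select=config.k_select, random_state=rng,
    )
    if scheme == "cv_and_crosstest":
        kwargs["k_test"] = config.k_test
    return cls(**kwargs)


def run_one(
    condition: float,
    scheme: str,
    rep: int,
    config: ExperimentConfig,
    reference: Dataset,
    *,
    condition_kind: str = "size",
) -> SchemeResult:
    """Run one replicate: subsample the reference, evaluate one scheme, and
    attach permutation significance.

    Fully determined by ``(master_seed, condition_kind, condition, scheme,
    rep)``; the reference dataset itself is fixed by the master seed.
    """
    if condition_kind == "size":
        n, test_fraction = int(condition), config.fixed_test_fraction
    elif condition_kind == "test_fraction":
        n, test_fraction = config.fixed_n, float(condition)
    else:
        raise ValueError(f"unknown condition_kind {condition_kind!r}")
    if n > reference.n_samples:
        raise ValueError(
            f"condition n={n} exceeds reference size {reference.n_samples}"
        )
    rng = child_rng(
        config.master_seed, condition_kind, f"{condition:g}", scheme, rep
    )
    rng_sample, rng_scheme, rng_perm = rng.spawn(3)
    data = subsample(reference, n, rng_sample)
    est = _build_estimator(scheme, config, test_fraction, rng_scheme)
    est.fit(data.features, data.labels)
    result = est.result()
    if config.run_significance:
        sig = config.sig
        if sig.mode == "fixed_selection" and isinstance(est, NestedCrossValidation):
            # nested CV has no single selected configuration to freeze
            sig = replace(sig, mode="full_rerun")
        if sig.mode == "fixed_selection":
            evaluate = est.testing_evaluator()
        else:
            def evaluate(X, y, rng, _est=est):
                fresh = _est.__class__(**_est.get_params())
                fresh.set_params(random_state=rng)
                fresh.fit(X, y)
                return fresh.accuracy_

        outcome = permutation_test(
            evaluate, data.features, data.labels, sig, rng_perm,
            observed_accuracy=result.accuracy,
        )
        result.p_value = outcome.p_geq
        result.p_strict = outcome.p_gt
        result.significant = outcome.significant
        result.randomized = outcome.randomized
    return result


def _log_row(condition: float, scheme: str, rep: int, res: SchemeResult) -> dict:
    return {
        "condition": condition,
        "scheme": scheme,
        "rep": rep,
        "accuracy": res.accuracy,
        "p_geq": res.p_value,
        "p_gt": res.p_strict,
        "significant": res.significant,
        "randomized": res.randomized,
        "best_combo": res.selection.best.label() if res.selection else "",
        "fallback_count": res.fallback_count,
    }


def aggregate_rows(log: pd.DataFrame) -> list[SweepRow]:
    """Aggregate a per-replicate log into SweepRows (mean accuracy and
    proportion significant with Monte-Carlo standard errors)."""
    rows = []
    for (condition, scheme), cell in log.groupby(["condition", "scheme"], sort=True):
        acc = cell["accuracy"].to_numpy(dtype=float)
        n = len(acc)
        has_sig = cell["significant"].notna().all()
        prop = float(cell["significant"].astype(float).mean()) if has_sig else None
        rows.append(
            SweepRow(
                condition=float(condition),
                scheme=str(scheme),
                mean_accuracy=float(acc.mean()),
                proportion_significant=prop,
                n_reps=n,
                se_accuracy=float(acc.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
                se_significant=(
                    float(np.sqrt(prop * (1 - prop) / n)) if prop is not None else None
                ),
            )
        )
    return rows


def _sweep(
    config: ExperimentConfig,
    conditions: Sequence[float],
    condition_kind: str,
    schemes: Sequence[str],
) -> tuple[list[SweepRow], pd.DataFrame]:
    reference = make_reference(config)
    records = []
    for condition in conditions:
        for scheme in schemes:
            for rep in range(config.n_reps):
                res = run_one(
                    condition, scheme, rep, config, reference,
                    condition_kind=condition_kind,
                )
                records.append(_log_row(condition, scheme, rep, res))
    log = pd.DataFrame.from_records(records, columns=REP_LOG_COLUMNS)
    return aggregate_rows(log), log


def sweep_dataset_size(config: ExperimentConfig) -> tuple[list[SweepRow], pd.DataFrame]:
    """Vary the total sample size at a fixed test fraction.

    Returns (aggregated rows, per-replicate provenance log).
    """
    if config.sizes is None:
        raise ValueError("config.sizes must be set for a dataset-size sweep")
    return _sweep(config, config.sizes, "size", config.schemes)


def sweep_test_fraction(config: ExperimentConfig) -> tuple[list[SweepRow], pd.DataFrame]:
    """Vary the test fraction at a fixed total sample size.

    Only the two split-based schemes apply; nested cross-validation has no
    separate test set, hence no test fraction to vary.
    """
    if config.test_fractions is None:
        raise ValueError("config.test_fractions must be set for a test-fraction sweep")
    if "nested_cv" in config.schemes:
        raise ValueError(
            "nested_cv has no test fraction; restrict schemes to "
            "cv_and_test / cv_and_crosstest for a test-fraction sweep"
        )
    return _sweep(config, config.test_fractions, "test_fraction", config.schemes)


def null_calibration(
    n_datasets: int = 100,
    n_samples: int = 100,
    n_features: int = 20,
    n_permutations: int = 199,
    alpha: float = 0.05,
    test_fraction: float = 0.5,
    k: int = 5,
    mode: str = "fixed_selection",
    seed: int = 0,
) -> pd.DataFrame:
    """Type-I-error calibration of the cross-validation-and-cross-testing
    pipeline on pure-null data.

    Generates ``n_datasets`` independent random-label datasets (uniform
    features, fair-coin labels), runs the full pipeline with the default
    grid on each, and attaches a permutation significance call.  Because the
    labels carry no information, the mean accuracy should sit at chance
    (0.5) and the fraction of significant calls at ``alpha``.  Returns a
    per-dataset frame with columns ``accuracy``, ``p_geq``, ``p_gt``,
    ``significant``, ``randomized``.
    """
    from .schemes import CrossValidationAndCrossTest

    sig = SignificanceConfig(n_permutations=n_permutations, alpha=alpha, mode=mode)
    records = []
    for rep in range(1, n_datasets + 1):
        data_seed = int(child_rng(seed, "null-data", rep).integers(2**31))
        data = generate_random(
            RandomSpec(n_samples=n_samples, n_features=n_features, seed=data_seed)
        )
        est = CrossValidationAndCrossTest(
            test_fraction=test_fraction, k_select=k, k_test=k,
            random_state=child_rng(seed, "null-scheme", rep),
        )
        est.fit(data.features, data.labels)
        if sig.mode == "fixed_selection":
            evaluate = est.testing_evaluator()
        else:
            def evaluate(X, y, rng, _est=est):
                fresh = _est.__class__(**_est.get_params())
                fresh.set_params(random_state=rng)
                fresh.fit(X, y)
                return fresh.accuracy_

        outcome = permutation_test(
            evaluate, data.features, data.labels, sig,
            child_rng(seed, "null-perm", rep), observed_accuracy=est.accuracy_,
        )
        records.append(
            {
                "rep": rep,
                "accuracy": outcome.observed_accuracy,
                "p_geq": outcome.p_geq,
                "p_gt": outcome.p_gt,
                "significant": outcome.significant,
                "randomized": outcome.randomized,
            }
        )
    return pd.DataFrame.from_records(records)


def rows_to_frame(rows: Sequence[SweepRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "condition": r.condition,
                "scheme": r.scheme,
                "mean_accuracy": r.mean_accuracy,
                "proportion_significant": r.proportion_significant,
                "n_reps": r.n_reps,
                "se_accuracy": r.se_accuracy,
                "se_significant": r.se_significant,
            }
            for r in rows
        ]
    )
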