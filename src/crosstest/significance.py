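"""Permutation test of classification accuracy against chance.

The null hypothesis is that labels and features are independent, so any
label permutation is as likely as the observed assignment.  The test reruns
the evaluation pipeline on uniformly permuted label vectors and compares the
observed accuracy with the permutation distribution.  Two p-value estimates
are kept:

* ``p_geq = (b + 1) / (N + 1)`` — the add-one inclusive tail (the observed
  statistic counts itself), a valid p-value for any N;
* ``p_gt = b_strict / (N + 1)`` — the strict tail, the smallest level at
  which the run could possibly be declared significant.

Because accuracies are ratios of small integers, the permutation
distribution is discrete and the achievable p-values form a lattice that
rarely contains the nominal level alpha exactly; a plain ``p_geq <= alpha``
rule is then conservative.  :func:`randomized_decision` applies the
classical randomization device for discrete exact tests: when alpha falls
strictly between ``p_gt`` and ``p_geq`` the run is declared significant with
probability ``(alpha - p_gt) / (p_geq - p_gt)``, which makes the rejection
rate exactly alpha under exchangeability.  The plain conservative rule is
available via ``rule="plain"``.

Ties in accuracy are counted at an absolute tolerance of 1e-12: exact ties
between small-integer ratios are meaningful and must not be split by
floating-point noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from ._rng import as_generator

__all__ = [
    "SignificanceConfig",
    "PermutationOutcome",
    "randomized_decision",
    "permutation_test",
]

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class SignificanceConfig:
    """Permutation-test settings.

    ``mode`` selects what is rerun per permutation: ``"full_rerun"`` repeats
    parameter selection and testing (unambiguously valid under the null);
    ``"fixed_selection"`` freezes the originally selected configuration and
    reruns only the testing stage (substantially cheaper).  ``rule`` picks
    the decision rule: ``"randomized"`` (exact size) or ``"plain"``
    (conservative).
    """

    n_permutations: int = 1000
    alpha: float = 0.05
    mode: str = "full_rerun"
    rule: str = "randomized"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.mode not in ("full_rerun", "fixed_selection"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.rule not in ("randomized", "plain"):
            raise ValueError(f"unknown rule {self.rule!r}")


@dataclass(frozen=True)
class PermutationOutcome:
    """Result of one permutation test."""

    observed_accuracy: float
    p_geq: float
    p_gt: float
    significant: bool
    randomized: bool
    n_permutations: int


def randomized_decision(
    p_geq: float,
    p_gt: float,
    alpha: float,
    rng: np.random.Generator,
) -> tuple[bool, bool]:
    """Exact-size decision for a discrete permutation null.

    Returns ``(significant, randomized)`` where ``randomized`` flags whether
    the probabilistic boundary rule fired.  If ``p_geq <= alpha`` the run is
    significant outright; if ``p_gt >= alpha`` it is not; otherwise the
    observed statistic sits on the lattice atom straddling alpha and the run
    is declared significant with probability
    ``(alpha - p_gt) / (p_geq - p_gt)``.
    """
    if not 0 <= p_gt <= p_geq <= 1:
        raise ValueError(f"require 0 <= p_gt <= p_geq <= 1, got p_gt={p_gt}, p_geq={p_geq}")
    if p_geq <= alpha:
        return True, False
    if p_gt >= alpha:
        return False, False
    boundary_prob = (alpha - p_gt) / (p_geq - p_gt)
    return bool(rng.random() < boundary_prob), True


def permutation_test(
    evaluate: Callable[[np.ndarray, np.ndarray, np.random.Generator], float],
    X: np.ndarray,
    y: np.ndarray,
    config: SignificanceConfig = SignificanceConfig(),
    rng: int | np.random.Generator | None = None,
    observed_accuracy: float | None = None,
) -> PermutationOutcome:
    """Permutation test of ``evaluate``'s accuracy against chance.

    ``evaluate(X, y, rng)`` must map a dataset and an RNG to an accuracy —
    typically a scheme's full pipeline or its frozen testing stage.  The
    observed accuracy is computed on the true labels (or taken from
    ``observed_accuracy`` when the caller already ran the pipeline with the
    matching RNG stream); each of the N permutations jointly redraws the
    label permutation *and* the pipeline's internal partitions from its own
    substream, keeping permuted replicates exchangeable with the observed
    run.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    master = as_generator(rng)
    # one child per permutation + one for the observed run + one for the
    # boundary randomization, all independent
    children = master.spawn(config.n_permutations + 2)
    if observed_accuracy is None:
        observed_accuracy = evaluate(X, y, children[0])
    b_geq = 0
    b_gt = 0
    for i in range(config.n_permutations):
        perm_rng = children[1 + i]
        y_perm = y[perm_rng.permutation(len(y))]
        acc = evaluate(X, y_perm, perm_rng)
        if acc >= observed_accuracy - _TIE_TOL:
            b_geq += 1
            if acc > observed_accuracy + _TIE_TOL:
                b_gt += 1
    denom = config.n_permutations + 1
    p_geq = (b_geq + 1) / denom
    p_gt = b_gt / denom
    if config.rule == "randomized":
        significant, randomized = randomized_decision(p_geq, p_gt, config.alpha, children[-1])
    else:
        significant, randomized = p_geq <= config.alpha, False
    return PermutationOutcome(
        observed_accuracy=float(observed_accuracy),
        p_geq=p_geq,
        p_gt=p_gt,
        significant=significant,
        randomized=randomized,
        n_permutations=config.n_permutations,
    )
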