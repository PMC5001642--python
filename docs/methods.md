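# Methods

## Evaluation schemes

All three schemes answer the same question — how accurately can a two-class
dataset be classified when the configuration θ (preprocessing × SVM penalty)
is itself chosen by cross-validation — and differ only in how the data are
partitioned.

**Cross-validation and testing.** The dataset is split once, stratified by
class, into a CV set and a test set (test fraction τ, default 0.5, half-up
rounding per class stratum; an error is raised if any class would be absent
from either side). On the CV set a single stratified k-fold assignment
(k_select = 5) is drawn and reused for every grid combination; each
combination's score is the unweighted mean of its k held-out-fold
accuracies, and the argmax wins, ties broken by grid order (declared order:
preprocessing outer {raw, PCA}, penalty inner ascending). One model with θ*
is then fitted on the full CV set and scored on the test set.

**Cross-validation and cross-testing.** Identical split and selection — the
two schemes consume their split and selection RNG substreams in the same
order, so at equal seeds they select the identical θ*, isolating the
testing-stage difference. The test set is then partitioned into k_test = 5
stratified folds; for each fold a model with θ* is fitted on the CV set plus
the remaining test folds and scored on the held-out fold. The reported
accuracy is the unweighted mean of fold accuracies (a pooled-count variant
is available via `aggregate="pooled"`). With k_test = 1 the procedure
reduces exactly to the plain holdout evaluation; the suite asserts this as
an identity for a deterministic plug-in predictor. Every cross-testing
training set contains the entire CV set by construction.

**Nested cross-validation.** An outer stratified k_outer = 5 fold loop; in
each iteration an inner k_inner = 5 CV on the outer training portion selects
that fold's θ, a model is fitted on the outer training portion and scored on
the outer fold. The reported accuracy is the unweighted mean over outer
folds; because per-fold configurations may differ, no single θ is reported.

Folds are built by shuffling each class's indices and dealing them
round-robin, with the dealing position carried across classes: within-class
fold sizes differ by at most 1 and total sizes stay balanced. Stratification
of every split and fold is a deliberate choice (it prevents single-class
partitions at the smallest sweep sizes, e.g. n = 50 at 90% test); the
round-robin construction is hand-written because the RNG semantics and
tie-structure are part of the package's reproducibility contract.

All schemes record an audit trail of (training indices, evaluation indices)
pairs for every model fit that was scored; the suite asserts on instrumented
runs that no evaluated sample ever appears in its scoring model's training
set.

## Candidate models

The grid is {no preprocessing, PCA keeping 70% cumulative variance} ×
{c ∈ 1e-4, 1e-2, 1}, six combinations. For the default SVM path, features
are standardized to zero mean and unit variance with training-partition
statistics (penalties spanning four orders of magnitude are meaningless
without a fixed feature scale), PCA — when selected — is fitted on the
training partition only and truncated to the smallest m with cumulative
explained-variance ratio ≥ 0.70, and the classifier is an RBF-kernel SVM
with scikit-learn's `gamma="scale"` bandwidth. The kernel choice is a design
decision: the simulated classes are constructed to be linearly inseparable
(XOR-like), so a linear kernel would sit at chance; the RBF kernel with the
scale heuristic is the standard default and is configurable through the
pluggable-estimator hook. Plug-in estimators (used in the tests as a
deterministic 1-nearest-neighbor oracle) receive the raw, unstandardized
features, keeping hand-enumerated expectations and index-based audits exact.

A training partition containing a single class yields a constant predictor
of that class, flagged as a fallback rather than raised as an error, so that
small-n sweeps always complete; fallback counts are reported per run.

## Permutation significance

Under the null of label–feature independence every label permutation is
equally likely, so N uniformly permuted label vectors are scored by the same
pipeline and the observed accuracy is ranked among them: p≥ = (b + 1)/(N + 1)
(inclusive tail, the observed run counts itself, so p≥ ≥ 1/(N + 1)) and
p> = b_strict/(N + 1) (strict tail). Ties are counted at an absolute
tolerance of 1e-12 — accuracies are ratios of small integers, so exact ties
are meaningful and must not be split by float noise.

The permutation distribution is discrete; the achievable p-values form a
lattice of spacing 1/(N + 1) that rarely contains α. The randomized decision
rule rejects outright when p≥ ≤ α, accepts when p> ≥ α, and otherwise
rejects with probability (α − p>)/(p≥ − p>), giving exact size α under
exchangeability. When no ties occur and α lies on the lattice the rule
collapses to the plain p≥ ≤ α rule; the plain conservative rule remains
available (`rule="plain"`), and the suite verifies that the two rules'
null rejection rates differ by less than 0.03.

Two rerun modes govern what is recomputed per permutation. `full_rerun`
repeats parameter selection and testing — unambiguously valid under the
null. `fixed_selection` freezes the originally selected θ* and reruns only
the testing stage, at roughly one-sixth the cost; the package's own null
calibration (below) is the empirical check of its validity and passes. In
both modes the split and fold assignments are redrawn from each
permutation's private substream, jointly with the label permutation, keeping
permuted replicates exchangeable with the observed run; the observed
statistic is the scheme's own reported accuracy. Nested CV has no single θ*
to freeze, so it always uses `full_rerun`.

## Synthetic data

The **simulated** generator draws all features uniform(0, 1) and then, with
per_subgroup = m samples per subgroup (default 2,000, i.e. 8,000 samples
total), adds 0.8 to dimensions {0, 1} for one subgroup of class 0, to
dimension 0 for one subgroup of class 1 and to dimension 1 for the other.
Both classes therefore share identical marginal means (0.9 on the offset
dimensions, 0.5 elsewhere) while the joint layout in the first two
dimensions is an XOR: linearly inseparable, learnable by a nonlinear
boundary. Rows are shuffled before return so contiguous subsets are random
with respect to the subgroup structure. The **random** generator (default
10,000 × 20) draws uniform features and fair-coin labels — a pure null.

What the generators do not emulate: correlated or heavy-tailed features,
class imbalance beyond binomial fluctuation, temporal structure, or the
high-dimensional spectral features of real electrophysiological recordings.
Passing tests on these generators therefore demonstrate correctness and
calibration of the *procedures*, not expected effect sizes on real data;
real datasets enter as generic CSVs (numeric features plus a two-valued
`label` column).

## Experiments and scale

Sweeps vary either total sample size at fixed test fraction, or test
fraction at fixed n (the latter only for the two split-based schemes —
nested CV has no test fraction). Each replicate stratified-subsamples the
reference dataset without replacement, runs one scheme, and attaches a
permutation significance call; every replicate is a pure function of
(master_seed, condition, scheme, replicate index) through SHA-256-derived
`SeedSequence` spawn keys, so sweeps reproduce bit-for-bit and aggregates
(mean accuracy, proportion significant, with Monte-Carlo standard errors)
are recomputable from the per-replicate provenance log.

Default scale is desk-sized and chosen once: 100 replicates per condition
and N = 199 permutations, with full-scale values (1,000/1,000) plain config
settings. The reported Monte-Carlo standard errors keep reduced-scale
comparisons honest. The suite's heavier checks use 100 null datasets × 199
permutations for calibration, 200 replicates for the scheme-ordering
property, and 1,000 simulated discrete nulls (with the cheap 1-NN plug-in,
N = 99) for the exact-size property of the randomized rule.

## Known behaviors and limitations

On directly generated random-label data the mean pipeline accuracy sits
slightly above 50% (≈52–53% over 100 replicates at n = 100): label counts
fluctuate binomially, and the heavily regularized grid members (c = 1e-4)
act as majority-class predictors, whose expected accuracy on an imbalanced
null draw exceeds 1/2. This does not affect significance calibration — the
permutation distribution shares the imbalance — and the proportion of
significant runs stays at the nominal α, as both the test suite and
`scripts/acceptance.py` verify. Curve values on real datasets depend on
kernel and scaling choices that are configuration, not contract; only
ordering trends among schemes are asserted.
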