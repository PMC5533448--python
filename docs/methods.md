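# Methods

## Model and procedure

`swarmbalance` treats imbalanced-data rebalancing as a constrained
two-parameter optimization. The decision variables are SMOTE's oversampling
percentage `S` and neighbor count `K`; the objectives are the
cross-validated accuracy and Cohen's kappa of a verification classifier on
the rebalanced data. Accuracy is maximized subject to a kappa credibility
floor `T` (default 0.4): a candidate (S, K) replaces the incumbent iff

```
[ min(kappa_best, kappa_cand) > T  and  acc_cand > acc_best ]   (both credible)
or
[ kappa_cand > T  and  kappa_best < T ]                         (first credible win)
```

The rule is deliberately asymmetric: a credible incumbent can never be
displaced by a non-credible candidate, however accurate. Ties on accuracy
are rejected (strict `>`), keeping the earliest-found incumbent, and an
incumbent with kappa exactly `T` matches neither branch and is kept — the
rule is implemented exactly as stated, boundary included. The incumbent is
initialized from the first evaluated agent, not from a synthetic −∞ record;
this matters because the second branch compares against the incumbent's
actual kappa. When no visited point clears the floor, the max-kappa visited
point is returned flagged `credible=False` rather than failing the run.

## SMOTE parameterization

For M minority rows, percentage S synthesizes `floor(M·S/100)` samples; the
total minority size is `M + floor(M·S/100)`. This sizing rule is
reverse-engineered: it is the unique floor/ceil/round convention that
reproduces every published (S, M, minority-total) triple we checked (e.g.
M=48, S=6969 → 3393; M=16, S=9700 → 1568; M=22, S=26247 → 5796). The
synthesis quota is distributed round-robin over minority rows in row order
(base `floor(n_syn/M)` each, the first `n_syn mod M` rows one extra), which
generalizes the textbook "each sample synthesizes S/100 copies" to S values
that are not multiples of 100 while staying deterministic. Neighbor search
is Euclidean on raw features (a z-score option exists), excludes the seed
point, breaks distance ties toward the lower row id, and clamps K to M−1
with a warning when callers pass more neighbors than exist — published runs
themselves carry K values exceeding the window's minority count, so this is
tolerated rather than rejected. S may overshoot complete balance; that too
occurs in published runs and is allowed.

Search bounds: S ranges from 10% (whole-table mode) or 100% (windowed mode)
up to `floor(100·N_maj/M)`; K from 2 to M. Both are integer ranges — the
published exhaustive-search counts (9801 S-values, 186,219 combinations)
imply unit steps.

## Fitness evaluation

The default verification classifier is a single-hidden-layer network
(10 logistic units, plain SGD, constant learning rate 0.1, 200 epochs,
seeded; scikit-learn's `MLPClassifier` underneath). It is intentionally
modest: the method's claim is that rebalancing, not classifier tuning,
moves kappa, and the classifier is a pluggable interface (`ClassifierSpec`)
so tests can inject deterministic stubs.

Evaluation applies SMOTE to the full dataset first and then runs k-fold CV
on the augmented table, pooling per-fold confusion counts into one metric
block. This mirrors the published protocol (whose reported Psize values are
whole-dataset augmentations) but leaks synthetic copies of test-fold rows
into training folds; `leak_free=True` instead synthesizes inside each
training fold and tests only original rows, flagged as a deviation. CV is
stratified by default (with 22 positives in 10 folds, unstratified folds
can lack positives entirely), degrading to plain k-fold with a warning when
a class has fewer rows than folds. Fitness evaluations are memoized on
(S, K): population-20 × 1000-iteration swarms revisit grid points
constantly and must not retrain.

Weighted precision/recall/F1 use support-weighted two-class averaging, with
per-class values exposed for audit; ROC area is the rank (Mann–Whitney)
statistic with ties at ½, computed from the classifier's continuous scores
(hard labels stand in, flagged, if a classifier yields none).

## Swarms

Both optimizers fly in continuous 2-D space and decode positions (round
half-up, clamp) to integer grid points before each objective call. Defaults
follow the conventional parameterization: population 20, 1000 iterations,
c1 = c2 = 1.5 for PSO; loudness A = 0.5, pulse rate r = 1, frequency range
[0, 2] for BA. Design choices where the source formulation is open:

- **Inertia weight** ω is required by the PSO velocity equation but has no
  published value here; 0.729 (the standard constriction-equivalent
  setting) is the default, exposed in `SwarmConfig` and recorded in run
  metadata.
- **Velocity clamping** at half the range per dimension prevents positions
  from saturating at the bounds over long runs.
- **BA schedules**: on acceptance, loudness decays geometrically
  (α = 0.9) and the pulse rate follows r·(1 − exp(−γt)) with γ = 0.9, the
  canonical formulation. With the default r = 1 the local-walk branch
  (taken when rand > pulse rate) never fires — rand ∈ [0, 1) cannot exceed
  1 — so BA explores through frequency-tuned flights only and tends to
  stagnate on small grids once bats pin at the bounds. This is implemented
  faithfully and is configurable; tests assert exact grid-optimum recovery
  for PSO and the best-visited-point guarantee for BA.
- **Termination** is a fixed iteration budget; an early-stop on
  floor-satisfying stagnation exists behind a flag, off by default.

The exhaustive `brute_force_grid` sweep is retained as the search oracle;
its evaluation count is |S range| × |K range|.

## Windowed adaptive variant

With W = N(N+1)/2, window x's base length per class is `x·floor(count/W)`;
the remainder is distributed one row at a time cycling from the last window
toward the first (w_N, w_{N−1}, …, w_1, w_N, …). This rule is
reverse-engineered from the twelve published per-class window-length
strings (six datasets × two classes) and reproduces all of them exactly,
including the remainder-4 and remainder-5 rows that discriminate between
candidate orderings; the full verification table lives in the test suite.
Classes are segmented independently in original row order (stream
semantics; a seeded shuffle flag covers i.i.d. experiments), windows are
disjoint sequential segments, and window x is approximately x times window 1.

Exactly N−1 searches run per adaptive call. Window 1 searches from random
initialization over the windowed bounds (S from 100, K from 2); each later
search pins one agent to the previous window's optimum (warm start); window
N is evaluated once under window N−1's parameters. The final report is the
arithmetic mean of the N per-window accuracies and kappas, re-derivable
from the stored per-window records; pooled-fold metrics (not
mean-of-folds) enter the average, consistent with the evaluation loop. An
optional audit mode also evaluates each later window under every earlier
window's parameters (the "processed state" view). A window with fewer than
two minority rows cannot be synthesized from: it is flagged, excluded from
the averages with a warning, and parameter propagation skips over it.

## Synthetic data

The generator draws two spherical Gaussian clusters with the class means
`separation` pooled-sd units apart along the first axis, exact class
counts, and a seeded generator (byte-identical CSV on repeat). It emulates
the *shape* of clinical/bioassay screening tables — numeric features, a few
dozen positives against up to tens of thousands of negatives — but not
their feature distributions (binary fingerprints, heavy-tailed descriptors,
correlated assays). A Student-t option (df = 3) provides heavy tails for
robustness checks. Passing tests on this generator therefore demonstrate
the machinery (sizing, partitioning, acceptance logic, kappa recovery from
a majority-vote baseline), not performance claims on any real assay.

## Problem sizes and numerical choices

Package defaults are full-scale (population 20, 1000 iterations, 10
folds). The test suite and worked examples run at desk scale as the
package's own smoke preset: populations 4–12, 3–40 iterations, 3–5 folds,
20–50 training epochs, datasets from 72 to 3423 rows — enough for every
deterministic identity to be exact and for the qualitative kappa-recovery
effect (kappa ≈ 0 raw → kappa > 0.4 balanced) to be reproducible in
seconds. Degenerate cases are defined rather than fatal wherever a sweep
could hit them: kappa of a single-cell confusion matrix is 0 with a
warning; a class with no predictions gets precision 0 with a warning;
single-minority-row inputs raise a dedicated cannot-synthesize error.

## Known limitations

- The published whole-dataset protocol leaks synthetic information across
  CV folds; results under it are optimistic. The leak-free mode is provided
  but is not the default, to keep the published semantics primary.
- Kappa-floor search with T = 0.4 can fail on genuinely hard data; the
  not-credible report path is the designed outcome there, not an error.
- BA under its default parameterization is a weak grid searcher (see
  above); PSO is the default algorithm.
- Binary labels only; no categorical features; dense matrices only.
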