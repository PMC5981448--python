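# Methods

This note documents the models, conventions and numerical choices behind
`mirmoo`, and what its synthetic-data tests do and do not establish.

## Preprocessing of Cq matrices

Inputs are raw qPCR cycle-quantification (Cq) values, miRNAs × samples,
with explicit missingness (non-detects). Lower Cq means higher abundance.
The pipeline order is: missingness filter → quantile normalisation → KNN
imputation.

- **Missingness filter.** A miRNA is dropped when missing in more than
  `max_missing_frac` of samples (default 0.5, strict `>`). The filter is
  idempotent and applied before normalisation so the normalisation reference
  is not distorted by mostly-absent rows.
- **Quantile normalisation.** The reference distribution is the
  across-sample mean of per-sample empirical quantile functions. For
  complete data this is exactly the classical mean-of-sorted-vectors
  construction, and the operation is a fixed point on its own output.
  Missing entries are excluded from the reference and remain missing; ties
  receive the reference value at their average rank, so within-sample order
  is preserved (non-strictly).
- **KNN imputation.** A missing cell takes the unweighted mean of the
  k = 10 nearest miRNA rows (the original KNNimpute default)
  that are observed at that sample. Row distances are Euclidean over
  co-observed samples, scaled up by the fraction co-observed (the
  `nan_euclidean` convention), computed with scikit-learn; donor selection
  is deterministic with ties broken by row index. A fully missing row, or a
  missing cell with no co-observed donor, is an error rather than a silent
  column-mean fill.
- **Survival dichotomisation.** Short survival iff observed survival
  < 24 months; exactly 24 months is long; patients alive at the end of
  follow-up are long regardless of time.
- **SMOTE.** One synthetic sample per minority sample (the minority count
  exactly doubles), placed uniformly on the segment to one of its k = 5
  nearest minority neighbours; the majority class is never undersampled.
  Oversampling is intended for model-comparison runs only and is off by
  default in the pipeline — final signatures are identified on original
  data.
- **Differential expression and fold change.** Two-sided two-sample
  Kolmogorov–Smirnov or rank-sum tests via scipy, which computes exact
  small-sample p-values when possible; a miRNA with fewer than two observed
  values in a class gets an explicit NaN. Fold change is 2^(−ΔΔCq) with
  ΔΔCq = mean Cq(short) − mean Cq(long), so FC > 1 means over-expression in
  the short-survival class; the direction is configurable since it is a
  convention, not a fact of the data. Candidate filters (p < 0.05,
  FC > 1.5 in either direction) are independently switchable.

## Regulatory network and functional relevance

The cascade network is grown from the seed miRNAs: evidence-filtered
miRNA→gene edges first (kept when validated at least once or predicted by
two distinct databases), then every reached gene that appears as a
transcription factor in the global TF→target table contributes all of its
edges, recursively, until no new interaction can be added. The builder is a
breadth-first fixed-point computation; TF→TF cycles terminate through the
visited set, and every node in the result is reachable from a seed.

Functional relevance of a miRNA *m* is

    FR(m) = ε + Σ_{g ∈ reachable ranked genes} exp(−[d(m, g) + r_g]),

with ε = 10⁻³ by default (configurable) and r = 1 for elite disease genes,
r = 2 for the rest. Distances are minimum hop counts; because all edges have
unit positive weight the shortest-path computation is plain BFS, and tests
assert its equivalence to a textbook Bellman–Ford on random instances — the
contract is the minimum hop count, not a particular algorithm. A ranked
gene that is itself a TF contributes at whatever hop count it is reached.
Self-loops are permitted and irrelevant to miRNA→gene distances. FR is
monotone: adding ranked genes can only raise it, removing edges can only
lower it, and a miRNA reaching no ranked gene scores exactly ε.

## Objectives and the evolutionary search

A solution is a fixed-length bit string over the candidate miRNAs; the
all-zero string is invalid (1/FR̄ undefined) and is repaired by setting one
random bit. Objectives, all minimised:

1. **Err** — mean held-out misclassification fraction over repeated
   stratified 5-fold CV (3 repeats by default; 1 in the scaled test
   configurations). The default classifier is a linear-kernel SVM with C = 1
   inside a per-fold standardisation pipeline, so no held-out statistics
   leak into scaling; random forest and AdaBoost stumps are pluggable.
   Before fold assignment samples are sorted by (label, values), making the
   estimate invariant to input order given the CV seed.
2. **1/FR̄** with FR̄ the *sum* of member FR scores, as displayed in the
   defining equation; a mean mode exists behind a flag because the
   surrounding text can be read either way.
3. **|X|** (tri-objective mode only).

The engine is a standard elitist NSGA-II. Fast non-dominated sorting is
vectorised over the pairwise dominance matrix; crowding distance follows the
Deb formulation (boundary = ∞, interior = sum of range-normalised neighbour
gaps, zero-width ranges contribute 0). Environmental selection fills the
next population front by front from parents ∪ offspring, with the first
front capped at ⌈pareto_fraction × population⌉ (default 20 %); truncation is
by descending crowding distance with deterministic index tie-breaks.
Evaluations are memoised on the bit pattern, so deterministic evaluators are
computed once per distinct subset.

**Stopping rule.** The search stops at `max_generations` (default 50) or
earlier when the average generation-to-generation change of a front-spread
statistic over a 5-generation window falls below 1e-4. The spread statistic
used here is the drift of the per-objective extreme points plus the standard
deviation of the finite crowding distances; the exact semantics of the
named solver's spread are not published, so the metric, tolerance and
window are configurable and the generation cap always dominates. For
oracle-equivalence runs (exhaustive Pareto enumeration on ≤ 8-bit pools) the
early stop is disabled and mutation raised to 0.05: exact set equality
requires exhausting the search budget, and the 20 % front cap is likewise
lifted there because it is a truncation device for large fronts, not part
of the optimality contract.

## Discovery/validation harness

Outer evaluation mirrors the repeated-CV design of prognostic-signature
studies: stratified 5-fold splits repeated R times (study-scale R = 10 for
50 runs; the scaled test configuration uses R = 2 for 10 runs). Per split,
candidate selection (differential expression) and the evolutionary search
see the discovery portion only; the representative Pareto member is the one
with minimal error, ties broken lexicographically on the remaining
objectives — a documented convention, since no selection rule is published
for the bi-objective case. The classifier is refit on the discovery portion
with the chosen signature and scored on the held-out portion with 'long
survival' as the positive class. Outer and inner randomness use independent
seeded streams; a leakage test verifies that corrupting a held-out fold
cannot change the signature selected for it.

Signature stability is the mean pairwise Jaccard index across runs. The
permutation test draws random same-size signatures from the full pool of
miRNAs under study (not from the differential-expression shortlist — the
null must represent "any signature of this size", otherwise it is
conditioned on discriminative features), scalarises raw objective vectors by
Euclidean distance to the origin, and reports the nominal fraction at least
as close; a min-max-scaled scalarisation is available behind a flag because
raw Err ∈ [0, 1] and 1/FR̄ can differ by orders of magnitude.

## Enrichment

Over-representation p-values are exact hypergeometric upper tails computed
in scipy (no normal approximation). Two tail conventions are implemented:
`ge` (P(X ≥ k), the textbook over-representation probability, default for
pathway screens) and `gt` (P(X > k), the strict right tail, which is the
convention of the reference validation statistic 0.0084 at N = 310, K = 72,
n = 7, k = 4; the `ge` tail gives 0.053). FDR adjustment is
Benjamini–Hochberg via statsmodels. The universe defaults to the annotation
collection intersected with the network genes.

## Synthetic scenarios

The generator emulates the data shapes of a plasma-miRNA prognosis study:

- 100 miRNAs × 75 samples, 15 short / 60 long survival (the imbalance of the
  motivating cohort), survival times drawn uniformly on either side of the
  24-month cutoff;
- per-miRNA baselines Uniform(27 ± 3) Cq, i.i.d. Gaussian noise with
  SD 0.5 cycles — a plausible within-class spread for plasma qPCR panels
  that makes the planted one-cycle shift a 2-SD effect, detectable but not
  trivial at n = 15/60;
- an 8-miRNA planted signature shifted one cycle down (over-expressed) in
  the short class, so its expected fold change is exactly 2 under the
  package's convention;
- 5 % missingness completely at random, guarded against fully missing rows
  or columns;
- a 20-TF / 500-gene layer with random TF wiring, a guaranteed TF→TF cycle,
  single-database decoy records that the evidence filter must drop, and two
  direct elite targets per planted miRNA so planted FR clearly exceeds
  background;
- ground-truth hop counts computed by an internal plain BFS, independent of
  the network module, for oracle tests.

What these scenarios do **not** model: miRNA co-regulation and correlated
noise, batch or haemolysis artefacts, informative missingness (non-detects
are censored high Cq in reality, not missing at random), and annotation
bias in real target databases. Passing the planted-recovery tests therefore
demonstrates the machinery is correct and well-calibrated, not that real
cohorts of this size yield signatures with these accuracies.

## Problem sizes and numerical choices

End-to-end tests and the acceptance script run the search with population
40 and 15 generations, single-repeat inner CV, and 10 outer runs — sizes
chosen so a full discovery completes in about half a minute on one CPU
while leaving the recovery conclusions unchanged from larger runs. The
permuted-label null is evaluated on a balanced (30/30) variant of the
scenario because chance accuracy is only 0.5 under balance; on the
imbalanced design a majority-class predictor sits at 0.8 and "chance" is
not a meaningful reference. Null accuracies slightly below 0.5 can occur —
feature selection on permuted labels picks spuriously separating features
that mildly anti-predict held-out folds.

Floating-point conventions: FR scores are exact sums of `exp` terms
(verified to 1e-12 against brute force); hypergeometric tails come from
scipy's log-space implementation; Pareto-front comparisons in tests round
objective vectors to 9 decimals; all tie-breaks (crowding, donor selection,
representative choice) are deterministic by index so identical seeds give
bit-identical runs.

## Known limitations

- The rank-1 front cap (`pareto_fraction`) can discard interior
  non-dominated solutions when duplicates crowd the front; it reproduces
  the named solver's behaviour but is not part of the optimality contract
  and can be set to 1.0.
- The spread-based early stop can halt before rarely-generated front
  members are found (observed on small enumerable pools); raise
  `max_generations` or set `spread_tolerance` to 0 when completeness
  matters more than runtime.
- `estimate_error` refits the classifier per subset per fold; on large
  candidate pools with many generations this dominates runtime. Memoisation
  helps only for repeated subsets.
- Gene identity is exact string matching after case normalisation; alias
  resolution must happen upstream.
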