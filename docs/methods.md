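# Methods

## Problem setting

A GO domain restricted to is_a relationships is a rooted DAG in which
annotation sets must be ancestor-closed (the true-path-graph rule, TPG).
Per-term binary classifiers trained independently produce real-valued
scores that ignore this structure. The package casts consistency
restoration as probabilistic inference in a factor graph and compares it
against the TPR-DAG heuristic and flat thresholding.

## Factor graph construction

Every ontology term is a binary variable; every non-root term contributes
one logical factor spanning the term and all of its is_a parents. Grouping
all parents of a child into a single factor (rather than one factor per
edge) makes the factor's support exactly the set of locally TPG-consistent
assignments: the factor is 0 iff the child is positive and at least one
parent negative. Truth tables are materialised only for factors of degree
≤ 12 (the explicit table is exponential in the number of parents); beyond
that an equivalent closed-form predicate is used, and the two routes are
unit-tested for row-by-row agreement across degrees 2–8.

The factor set depends only on the edge set, so construction is
deterministic and independent of traversal order.

## Noise channel

Classifier scores enter as observations of an additive white Gaussian
noise channel y = x + z, x ∈ {+1, −1}, z ~ N(0, η) with a per-term
variance η. The channel posterior p(x|y) = 1/(1 + exp(−2yx/η)) is the leaf
message each observed term receives. Variances are estimated from
positively annotated validation samples only, η̂ = Σ(y−1)²/(L⁺−1), which
presumes the conditional score distributions over the two classes are
symmetric; the estimator is exposed separately so per-class empirical
variances can be inspected when that assumption is in doubt.

Numerical floor: η is clamped below at 10⁻⁶. A zero variance makes the
leaf message a hard 0/1 indicator, which can annihilate entire message
products on conflicting evidence; the floor keeps messages strictly
positive while remaining effectively deterministic. Scores are used as-is
(SVM margins are not rescaled), matching the channel model in which the
margin plays the role of the noisy ±1 signal.

## Message passing

Synchronous flooding schedule: per iteration all variable→factor messages
are recomputed from the current factor→variable messages and the fixed
leaf messages, then all factor→variable messages. Messages are binary
distributions stored by their p(+1) component and renormalised at every
step; a degenerate (all-zero) product is reset to uniform and recorded as
a warning. Factor→variable messages use closed forms that cost O(#parents)
per message (products of parent messages for the child direction; a
two-term sum for each parent direction), verified against truth-table
summation on small degrees.

Defaults: tolerance ξ = 10⁻³ on the maximum per-term marginal change,
iteration cap I_max = 50, damping 0 (off). Damping, when enabled, convexly
mixes old and new factor→variable messages; it is exposed for loopy graphs
that oscillate but is not needed on any graph in the test suite.
Initialisation is uniform messages, the standard uninformative start. The
per-term convergence test is aggregated with a maximum, i.e. every term
must move less than ξ. On non-convergence the last marginals are returned
with `converged=False` rather than raising: diagnostics (iterations,
residual, warnings) accompany every result.

MAP labels threshold marginals at 0.5, resolving exact ties to the
negative label (conservative: no annotation without evidence). On loopy
graphs the raw per-term argmax can violate the TPG rule, so the public
output `map_repaired` applies a top-down repair that zeroes any child with
a negative parent. Repair never invents positives — positives of the
output are a subset of the raw positives. Both label sets are retained so
the effect of repair is observable. Exact marginals (from the enumeration
oracle) are monotone along edges, p(parent) ≥ p(child), so thresholding
them at any level is consistent automatically; the repair only matters for
the loopy approximation.

The brute-force oracle enumerates all 2^n configurations (guarded at
n ≤ 20), weighting each by the product of logical factors and channel
posteriors. The partition function is always positive because the
all-negative configuration satisfies every logical factor.

## TPR-DAG baseline

Terms are levelled by maximum edge distance to the root. The bottom-up
sweep visits each term once, deepest first, replacing its value by the
mean of its own flat probability and the consensus values of children at
or above the 0.5 positivity threshold (children are final before parents
read them). The top-down sweep caps each term at its weakest corrected
parent, so thresholding at any level yields a consistent set. Within a
level, terms are processed in identifier order; the updates are
order-independent given the level discipline, but the fixed order makes
runs bit-reproducible. Terms are visited once each (single-visit,
decreasing-depth order), which resolves the ambiguity of how multi-path
revisits would mix flat and updated values.

## Flat scoring and calibration

Training sets follow the inclusive negative policy: positives of a term
are its closure positives; candidate negatives are genes annotated
somewhere in the sub-DAG but not to the term (closure semantics exclude
annotators of its descendants automatically). Negatives are subsampled to
at most `max_neg_ratio` (default 2.0) times the positives with a fixed
seed; the ratio is configuration, not dogma, since the balancing procedure
is only loosely constrained by precedent. The reference scorer is a
soft-margin linear SVM with C = 1 behind a pluggable estimator interface
(`fit` + `decision_function`); any margin-producing scorer can be
substituted. Platt's sigmoid fit (Bernoulli likelihood with smoothed
targets, BFGS with analytic gradients) maps margins to the probabilities
TPR-DAG consumes.

## Evaluation

Per-term AUC is the Mann-Whitney statistic. Hierarchical
precision/recall/F use the ancestor-based variant: per-sample intersection
ratios over ancestor-closed sets with the root excluded, macro-averaged;
empty-set conventions (HP = 1 when both sets empty, 0 when only the
prediction is non-empty, symmetrically for HR) make the metric total.
Inputs must be closed; the flat baseline's thresholded labels are made
consistent with the same top-down repair used for MAP output, keeping the
comparison on one convention.

Cross-validation partitions genes with a per-term stratification heuristic
(terms visited by increasing positive count; each term's unassigned
positives dealt to the fold currently poorest in that term). Because
closure nests the label columns, perfect ±1 balance for every term
simultaneously is not always attainable; the rarest terms, which need it
most, are dealt first and balanced exactly. Channel variances and Platt
calibrations are fitted on the training fold's own data — the positives'
in-sample margins — rather than a nested validation split, which would
starve rare terms of training data at these problem sizes. Terms that
cannot be trained in a fold (fewer than two positives, or no negatives)
keep an uninformative score (margin 0, probability 0.5) and are excluded
from that fold's AUC with a logged warning.

Method comparisons use the two-sided Wilcoxon rank-sum test, exact null
distribution for combined samples of ≤ 20 untied values and the
tie-corrected normal approximation otherwise, declaring a winner only
below the significance level (default α = 0.01).

Predicted-graph pruning starts from the repaired positive set and
iteratively removes sub-threshold leaves (default cut 0.95); removing a
leaf can expose its parent for testing. Only leaves are ever tested, so a
confident leaf retains its entire ancestor path regardless of intermediate
marginals — the trimmed graph is always ancestor-closed.

## Synthetic data generator

`random_godag` builds rooted level DAGs: the root alone at level 0, at
least one term per level, each non-root term drawing 1..max_parents
parents from strictly shallower levels. `sample_annotations` draws labels
top-down with a single conditional parameter θ: a term is positive with
probability θ when all parents are positive, otherwise negative — the
generative support therefore coincides exactly with the logical factors'
support, which is what parameter-recovery tests require.
`corrupt_scores` emits y = x + N(0, η) from the ±1-encoded labels.

Default study conditions: θ = 0.8 and η = 0.25 with n = 500 samples on a
30-term, 5-level DAG for the end-to-end leveraging check. η = 0.25 mirrors
the average base-classifier variance regime reported for well-characterised
(Pfam-style) inputs, where per-term sign errors run at a few percent and
structure-aware leveraging has measurable headroom. What the generator
does **not** emulate: realistic feature vectors (scores are generated at
the channel level), asymmetric or heavy-tailed score noise, annotation
incompleteness (false negatives in the gold standard), and
evidence-code heterogeneity. Passing tests therefore demonstrate
correctness of the machinery and its behaviour under the stated model,
not performance on any particular organism's annotation corpus.

## Problem sizes in the test and acceptance runs

Oracle-equivalence suites use 100 random trees of ≤ 12 terms and 100
four-term diamonds in the well-separated regime (|y|/η ≥ 2); posterior
monotonicity is checked on 1000 random DAGs of ≤ 9 terms against the
enumeration oracle; variance recovery uses L⁺ = 10⁴ scores; the
cross-validation example runs 3 folds over 120 genes and 10 terms. These
sizes make every claim checkable by exhaustive or high-precision
reference computations while the whole suite stays fast.

## Known limitations

* Only is_a structure is modelled; part_of/regulates edges are dropped at
  parse time.
* Loopy sum-product is approximate on graphs with multiple inheritance;
  the suite verifies MAP agreement with enumeration in the well-separated
  regime, not in general.
* The Gaussian channel with symmetric class-conditional noise is an
  idealisation of real margin distributions.
* Per-term variances are homoscedastic across samples.
* The inclusive-policy and balancing details are configuration-exposed
  readings of loosely specified conventions, not uniquely determined ones.
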