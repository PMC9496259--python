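# Methods

## The validation problem

A causal DAG over measured variables implies two families of statistical
statements. Any pair of nodes connected by a trek — a directed path, or two
directed paths diverging from a common source, with no collider — should be
marginally correlated, and if every edge carries a sign, the product of edge
signs along each trek predicts the direction: when all treks between a pair
agree, the pair has a determinate expected direction; when treks conflict or
any contributing edge sign is unknown, the expectation is recorded as
`ambiguous` and only the magnitude criterion applies (with a
`direction_untestable` flag). Conversely, any set Z that d-separates a
non-adjacent pair implies a vanishing partial correlation. A dataset
validates the diagram to the extent that its correlations respect both
families.

## Implication extraction

d-separation is decided by `networkx.is_d_separator`. For
conditional-independence statements we enumerate **all minimal separating
sets** of each non-adjacent pair, not one per missing edge: a single pair
can be separated by several distinct minimal sets (in the bone diagram,
strength ⊥ unloading both given {formation, resorption} and given
{mass, trabecular}), and each corresponds to a different testable partial
correlation. Minimal separators of a DAG pair always lie within the
ancestors of the pair, so the search enumerates ancestor subsets by
increasing cardinality and keeps a set iff no previously found separator is
a proper subset. This is exponential in the ancestor count; above 20
candidate nodes a warning is emitted and `max_sets_per_pair=1` switches to
one-minimal-set-per-pair mode. Statements are canonicalized (pair sorted
lexicographically, conditioning sets ordered by size then name) so reports
are deterministic.

Trek enumeration for expected signs uses simple collider-free skeleton
paths (Wright's path-tracing rules determine only the sign here, not the
magnitude).

## Estimation

**Marginal tests** use Spearman's ρ (average ranks for ties) on the pairwise
complete cases. The confidence interval is a BCa bootstrap over paired
resamples: bias correction z₀ = Φ⁻¹(fraction of replicate statistics below
the point estimate, ties counted half), acceleration a from the jackknife
skewness of leave-one-out estimates, endpoints the adjusted quantiles of the
replicate distribution. With z₀ = a = 0 the interval reduces exactly to the
percentile interval. Degenerate situations fall back gracefully and are
flagged rather than raised: constant resamples are dropped
(`constant_resamples_dropped`), an all-identical replicate distribution
returns the point interval (`degenerate`), and an undefined z₀ or zero
jackknife variance falls back to the percentile interval
(`percentile_fallback`). The exact leave-one-out jackknife is O(n²), so
above n = 500 the acceleration uses a delete-d grouped jackknife with 200
groups — at such sample sizes the acceleration is negligible anyway.
Bootstrap replicates default to 2000 and every interval is deterministic
given the seed, which the CLI makes mandatory.

**Conditional tests** take the Spearman correlation matrix of the *jointly*
complete cases of {X, Y} ∪ Z (never pooled pairwise, so the matrix is a
proper correlation matrix of one effective sample), invert the submatrix to
get the partial correlation, and attach a Fisher-z interval with standard
error 1/√(n − k − 3). The n is left unadjusted for the rank transform (some
conventions inflate the standard error by ≈1.06 for Spearman); since the
interval never binds a verdict this choice affects reporting only. A
first-order recursive implementation of the partial correlation is kept
privately and the two routes are required to agree to 1e−10 in the tests; a
residual-regression oracle provides a third, independent check.

Missing data are handled by testwise complete-case deletion — the effective
n therefore varies per test and is recorded on each estimate. No imputation,
no multiple-testing correction (the decision rule is deliberately
magnitude-based, see below).

## Decision rules

With threshold t (default 0.15 — a deliberate heuristic, configurable and
worth varying):

- marginal: validated iff direction matches and |ρ| **≥** t;
- conditional: validated iff |ρ_{XY·Z}| **<** t.

The boundary |ρ| = t therefore validates a marginal claim and fails a
conditional one; this literal asymmetry is intentional and pinned by tests.
The rationale for a magnitude threshold rather than a significance test: a
tiny correlation can be "significantly" non-zero with enough data yet be
biologically negligible, and a biologically large one can fail significance
in a 14-animal study. Confidence intervals are computed and reported, and
the report counts how many validated verdicts a CI-exclusion criterion would
overturn, but the CI never changes a verdict. Failed conditional verdicts
carry a `suspect_conditioning_on:` flag listing the conditioning variables,
since an invalid partial correlation often indicts the measures used for the
conditioning concepts rather than the diagram.

## Composites

When several assay columns measure one DAG concept, the composite is the
first principal component of the standardized columns (correlation-matrix
PCA), sign-oriented to correlate positively with a designated anchor column,
with the first component's explained-variance fraction reported. Per-study
scoring, a single component, and no rotation are defaults exposed in
`CompositeSpec`; alternative conventions can be swapped in at the config
level.

## Synthetic studies

The generator draws from a linear-Gaussian SEM: nodes in topological order,
each non-exposure node a coefficient-weighted sum of its parents plus
N(0, σ²) noise (σ = 1 by default). Coefficient signs must match the edge
signs, so generated data are faithful to the implied directions. The
exposure design options mirror the rodent study designs the toolkit is aimed
at: grouped 0/0.60/0.80 unloading (default n = 33 with a near-equal 11/11/11
split), binary flight-vs-control, or standard-normal continuous.
`make_study_suite` reproduces the coverage patterns of such studies — a full
six-variable study whose bone-turnover assays exist only on a 14-animal
sub-cohort (so conditional tests run at n_effective = 14), and four-variable
subsets ({exposure, formation, resorption, mass}, {exposure, mass,
trabecular, strength}) that reduce the testable implications to 6 + 2.
`perturb_spec` produces misspecified variants (sign flip, added edge, zeroed
edge) for power checks against a wrong diagram.

Alongside sampling, `implied_covariance` computes
Σ = (I − Bᵀ)⁻¹ Ω (I − Bᵀ)⁻ᵀ from the coefficient matrix B and exogenous
variances Ω (group designs contribute their finite-population variance), so
implied conditional independencies can be verified *exactly* at the
population level rather than only in large samples.

What the generator does not emulate: nonlinear or non-Gaussian mechanisms,
longitudinal remodelling dynamics, cross-sectional vs cumulative measurement
of turnover markers, and inter-species analog mismatch. Passing tests on
synthetic data therefore demonstrate correctness of the derivation and
estimation machinery under the linear-Gaussian ideal, not that any real
assay validly measures its DAG concept.

## Problem sizes and numerical choices

The test suite exercises the full pipeline at n = 10,000 with |β| = 0.5 for
recovery checks (all 23 bone-diagram verdicts validate; each perturbation
breaks exactly the implicated verdicts), estimates BCa coverage for ρ = 0 at
n = 50 over 1000 simulations with 2000 replicates each (expected 95 % ± 2),
and verifies d-separation exhaustively against a brute-force path-blocking
oracle on random DAGs of up to 7 nodes over every pair and conditioning
subset. Heavy bootstrap-based pipeline tests use 200–500 replicates — the
interval is non-binding, so replicate count affects only CI wiggle.
Hypothesis-based property tests are seeded through explicitly drawn integer
seeds, so runs are reproducible.

## Known limitations

- Only observational implications are derived; no adjustment-set or
  identification analysis, no Markov-equivalence reasoning (an equivalent
  DAG would pass the same tests).
- All-minimal-separator enumeration is exponential in the worst case.
- The validation logic never proposes diagram edits: fitting the diagram to
  the same data that test it would invalidate the exercise.
- Composites assume one dominant component; multi-factor measurement
  structures need a measurement model, not a PCA score.
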