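# dagvalid

Test whether empirical data are consistent with a causal diagram.

Causal explanations in epidemiology and physiology are often encoded as
directed acyclic graphs (DAGs): nodes are random variables, edges point from
cause to effect. A DAG is more than a picture — its structure *implies*
testable statistical statements. `dagvalid` derives those implications from
a signed DAG and confronts them with tabular data:

- **Marginal dependencies.** Every pair of variables connected by at least
  one trek (a collider-free path) should show a non-zero correlation, and
  propagating the edge signs (+/−) along the treks predicts its direction.
- **Conditional independencies.** Every set Z that d-separates a
  non-adjacent pair (X, Y) implies X ⊥ Y | Z; `dagvalid` enumerates *all
  minimal* separating sets per pair, so one pair can yield several distinct
  statements.

The motivating application is skeletal unloading in rodent models of
spaceflight bone loss: unloading suppresses bone formation and stimulates
bone resorption; both processes drive bone mass and trabecular
microarchitecture, which jointly determine bone strength. That six-node
diagram ships with the package (`dagvalid.bone_dag()`), implying 15 signed
marginal correlations and 8 conditional independencies.

## Statistical machinery

- Marginal correlations: Spearman's ρ (robust to monotone nonlinearity) with
  a bias-corrected accelerated (BCa) bootstrap confidence interval,
  deterministic given a seed.
- Conditional independencies: partial Spearman correlation ρ_{XY·Z}, computed
  from the rank-correlation matrix of the jointly complete cases of
  {X, Y} ∪ Z, with a Fisher-z interval (se = 1/√(n − k − 3), k = |Z|).
- Decision rule (threshold t = 0.15 by default, configurable):
  - a marginal expectation is **validated** iff the estimate is in the
    implied direction and |ρ| ≥ t;
  - a conditional independency is **validated** iff |ρ_{XY·Z}| < t;
  - confidence intervals are reported but never bind the verdict — in
    small-animal studies precision alone is a poor criterion. The report
    counts how many verdicts a CI-based criterion would flip.
- Multiple assay columns measuring one DAG concept can be collapsed to a
  composite: first principal component of the standardized columns, sign
  oriented by an anchor column.
- A linear-Gaussian structural-equation simulator draws synthetic studies
  from any signed DAG (including the 0/60/80 % partial-weightbearing
  exposure design and spaceflight-style binary exposure with reduced assay
  panels), and computes the covariance the path coefficients imply
  analytically — so the whole pipeline is testable without animal data.

## Worked example

```sh
dagvalid simulate --dag examples/bone.dag --n 33 --seed 7 --out study
dagvalid validate --dag examples/bone.dag --data study.csv \
    --mapping examples/mapping.yaml --seed 7 --out report
```

The simulated study mimics a hind-limb partial-weightbearing experiment
(33 animals in 0/60/80 % unloading groups, path coefficients ±0.5, unit
noise). The validation report (abridged):

```
params:  threshold=0.15 level=0.95 replicates=2000 seed=7

-- marginal --
+  corr(formation, mass) positive                    +0.563    [+0.22, +0.80]   33  validated
x  corr(formation, resorption) negative              +0.152    [-0.21, +0.48]   33  not_validated
+  corr(formation, unloading) negative               -0.444    [-0.68, -0.08]   33  validated
...
-- conditional --
x  formation _||_ resorption | {unloading}           +0.244    [-0.11, +0.55]   33  not_validated
+  strength _||_ unloading | {formation, resorption}  +0.099    [-0.26, +0.44]   33  validated
...
tested=23 validated=16 failed=7 untestable=0  (CI-criterion would flip 6 validated verdicts)
```

Each row is one implication: `+` validated, `x` failed. Here
`corr(formation, resorption)` came out +0.152 where the diagram implies a
negative association (their only connection is the common cause, unloading,
with opposite edge signs), so it fails on direction — at n = 33 such
failures arise from sampling noise even when the generating model *is* the
diagram, which is exactly the low-power regime the report's CI columns and
failure flags are meant to illuminate. A failed conditional verdict also
flags its conditioning variables (`suspect_conditioning_on:...`) as the
place to look for inappropriate measures.

`dagvalid implications --dag examples/bone.dag` prints the implied test set
alone (15 marginal + 8 conditional for the bone diagram), and the library
API (`dagvalid.expected_test_set`, `dagvalid.validate_dataset`, ...) exposes
every step programmatically.

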