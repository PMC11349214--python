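# Methods

This note records the models, the estimation choices and the reasoning
behind the package's defaults — the things a maintainer would need before
changing anything.

## Synthetic cohort model

`make_copd_like` draws a cohort from a fixed causal graph over named
baseline variables (sex, age, height, pack-years, current smoking, BMI,
an airway-wall analogue `pi10`, a CT-density/emphysema analogue `perc15`,
a small-airway flow analogue `fef2575`, a symptom score `sgrq`, two
baseline spirometric indices with role `spirometry-derived`), filler
covariates, SNP-like 3-level categoricals in rough Hardy–Weinberg
proportions, and `n_latent` continuous latent confounders that each feed
at least two observed variables.  Structural equations are linear-Gaussian
for continuous children and multinomial-logit for categorical children —
the model class under which the MGM's superset property is meaningful.
Missingness, when requested, is injected completely at random (MCAR); the
mechanism in the real cohorts this emulates is unknown, and KNN-imputation
testing needs a known one.

Two *follow-up* spirometric axes are linear in the standardized true
blanket variables plus Gaussian noise, mapped affinely to clinical scales
(FEV1 %predicted ≈ 0.974 ± 0.115, FEV1/FVC ≈ 0.786 ± 0.052).  The binary
outcome is `fev1pp < 0.80 or ratio < 0.70`; leavers split into an
obstructive subtype (ratio below threshold) and a PRISm subtype (ratio
preserved).  The airway analogue feeds **only** the FEV1 %predicted axis
and the emphysema analogue **only** the ratio axis, so the two subtypes
have genuinely different mechanisms and subtype-specific regressions can
detect the dissociation.

Calibrations, chosen once and frozen:

* **Event rate** — a shared intercept shift on both axes is found by
  bisection (≤ 50 iterations) so the realized event fraction is within 2
  percentage points of the target (default 20.3%); failure raises with
  diagnostics.
* **Axis noise** (`axis_noise_sd`, default 2.9 on the standardized axis
  scale) — sets the Bayes-optimal AUROC of the outcome given all baseline
  variables to ≈ 0.78, the operating regime the pipeline is designed for.
  `bayes_risk` evaluates the exact conditional event probability in closed
  form from the stored axis model.
* **Effect sizes** — axis weights are between 0.5 and 0.85 in standardized
  units and every structural coefficient is bounded away from zero
  (floor 0.3, exposed in `CohortSpec`), so blanket recovery is a fair
  test: each blanket member retains conditional signal given the others.
  For the same reason the baseline couplings into the flow analogue are
  deliberately moderate; a dominant common correlate would annihilate the
  partial associations of the remaining members regardless of method.

What the generator does **not** emulate: real spirometry curve shapes, CT
acquisition, linkage disequilibrium among SNPs (SNP columns are ordinary
3-level categoricals), informative dropout, and non-MCAR missingness.
Passing tests therefore demonstrate correctness of the machinery under the
stated model class, not robustness to those features of real data.

The generic generator (`sample_dag` + `simulate_mixed`) draws arbitrary
mixed SEMs with a designated outcome.  The outcome is a *sink* with
exactly `mb_size` parents, so its Markov blanket equals its parent set by
construction; this mirrors the temporal fact that a follow-up outcome
cannot cause baseline measurements, and makes the true blanket size exact
rather than approximate.  `oracle_independent` answers m-separation
queries by a reachability (Bayes-ball style) traversal written
independently of networkx; the two implementations are cross-checked in
the tests.

## MGM

The pseudo-likelihood is the sum over variables of each variable's
conditional negative log-likelihood given all others: unit-variance
Gaussian conditionals for (internally standardized) continuous variables,
multinomial logits for categorical ones, with every pairwise block shared
symmetrically between the two conditionals it enters.  The objective is
convex; optimization is FISTA with backtracking (tol 1e-5 relative, max
500 iterations), with the group-lasso prox applied per pairwise block
(scalar / level-vector / level-matrix).  Two implementation facts worth
knowing:

* the gradient restricted to the symmetric-matrix manifold is
  `(G + Gᵀ)/2`, and the prox threshold carries a factor ½ because each
  block appears twice in the full-matrix Frobenius norm;
* sum-to-zero identifiability of level-wise blocks is not imposed during
  iteration — uniform level shifts are absorbable by the unpenalized
  intercepts, so the group penalty prefers the centered representative —
  and an exact centering projection is applied at the end (it leaves every
  conditional unchanged).

Default penalty: λ = 1.5·√(log p / n).  The constant was chosen by
measuring, on default cohorts at n = 2000, the false-negative rate of
true-blanket adjacencies (5% over 10 seeds, against a 10% design bound)
against skeleton density (mean degree ≈ 3.6); smaller constants inflate
the skeleton several-fold without adding blanket edges, which matters
because the constraint-based stage's cost is combinatorial in node degree.
Edge weights are block Frobenius norms; edges exist above 1e-6.

## Conditional-independence tests

A test of x ⟂ y | S compares the conditional model of y on S against y on
S ∪ {x} (family chosen by y's kind) and symmetrizes by running both
directions and keeping the **larger** p-value.  For Gaussian responses the
likelihood ratio is evaluated in its exact finite-sample F form; for
categorical responses the asymptotic χ² LRT is used (it reduces to the
G-test in the marginal case).  Collinear designs are handled by
eigenvalue rank detection with degree-of-freedom adjustment; a response
constant in the data yields p = 1 with a log message.  Measured type-I
error at α = 0.05 (n = 1000) is 0.046/0.055/0.050 for
continuous–continuous / mixed / categorical–categorical pairs.

The tester caches p-values by (pair, conditioning set) and fitted
submodels by (response, regressor set) — with warm-started Newton solves
for nested models — because skeleton pruning over an α grid re-tests the
same triples many times.  These caches are exact, not approximate.

## FCI-max

Pruning is PC-stable (per-depth frozen adjacencies, lexicographic order,
conditioning sets of size 0..`max_cond`, default 3) over the MGM
adjacencies, recording a separating set per deleted edge.  A bounded
possible-d-sep pass follows (path length ≤ 3, conditioning sets of size 1
by default in the data path; unbounded in oracle verification), since
latent confounding can require separators outside the adjacency sets.
Orientation restarts from circles: each unshielded triple's collider
status is decided by the candidate separating set with the **maximum**
p-value (subsets of either endpoint's adjacencies plus the recorded
sepset; deterministic tie-breaks), colliders are applied in decreasing
order of separation confidence, and Zhang's R1–R4 run to fixpoint.  Rules
R5–R7 (selection bias) are out of scope for this design.  With oracle
tests and unbounded search the output equals a brute-force PAG built by
latent projection to a MAG plus independent rule closure; the test suite
verifies exact mark-level agreement on an exhaustive enumeration of DAGs
with up to 5 nodes (0 or 1 latent) and hundreds of random 6-node DAGs.

## Nested cross-validation and prediction

Stratified folds preserve the event rate.  Per (fold, α): the graph is
learned on the raw fold-training data, the outcome's blanket extracted,
a logistic model fit on the SMOTE-NC-rebalanced fold-training data, and
AUROC measured on the untouched fold-validation subjects.  Two choices
here are deliberate and differ from the most literal reading of the
workflow:

* **Graphs see raw, not oversampled, data.**  SMOTE-NC's categorical
  mode-voting shifts the synthetic minority's level frequencies, which
  manufactures outcome associations for variables that have none (we
  measured marginal p-values collapsing from 0.5 to 1e-9 for inert SNP
  columns after oversampling).  Conditional-independence tests are valid
  under class imbalance, so rebalancing buys nothing for structure
  learning and costs blanket precision.  `rebalance_graphs=True` restores
  the oversample-first order.
* **α selection uses the one-standard-error parsimony rule** (sparsest α
  within one SE of the best mean validation AUROC).  Mean differences
  among near-optimal α values (~0.005) are far inside fold noise, so a
  strict argmax degenerates into always choosing the densest graph; the
  one-SE rule is the standard generalization of "ties break sparse".

The final blanket is the one learned from the full training set at the
selected α (fold-level variability is reported separately in the
stability table).  Blanket extraction on a PAG is permissive: neighbours
plus nodes with an edge into a *possible* child (arrowhead or circle at
the child's end) — circles are treated as children to favour recall,
matching the blanket's role as a feature-selection superset.  Empty
blankets score AUROC 0.5.

SMOTE-NC itself follows the classic scheme — seed + u·(neighbour − seed)
for continuous features, neighbour-mode for categorical features, ties
keeping the seed's value — with plain Gower distance for the neighbour
search (the distance the rest of the pipeline uses) instead of the
original publication's categorical median-SD term.  Synthetic rows are
flagged and originals always form an unchanged prefix.

The random forest and elastic net tune their few hyperparameters
(trees × feature fraction; mixing × penalty) on the same folds by AUROC.
Shapley attributions use Monte-Carlo permutation sampling on the risk
scale with the training set as background; `n_mc` below 10 is refused.

## Preprocessing

Filtering reasons, in order: future-information roles, constants and
exact duplicates, missing fraction above `missing_max` (default 0.2),
categorical levels below `min_category_count` (default 10), and pairwise
correlation above `corr_max` (default 0.9; R² for continuous pairs,
Cramér's V for categorical pairs — mixed-pair screening is deliberately
omitted since no single statistic is standard).  The member with more
missingness is dropped, ties toward the later column; the procedure is
idempotent.  The 0.2/0.9 thresholds are package defaults, not values
taken from any study.  Sparse levels merge rarest-into-next-rarest until
all levels have `min_count` members *and* at most 3 levels remain; a
variable collapsing to one level is flagged for the filter rather than
silently kept.  KNN imputation (k = 5) uses Gower distance computed on
commonly observed variables, with continuous ranges frozen on the data
the imputer sees (train-side when used inside folds) so held-out
transforms leak nothing; donor ties break by record order.

## Numerical and degenerate-input conventions

Logistic reporting fits standardize continuous predictors and
reference-code categoricals; perfect separation falls back to a
ridge-stabilized Newton solve (penalty 1e-4) and flags the result.
AUROC is the Mann–Whitney concordance with ties counted ½, identical (to
1e-10) to the trapezoidal area of the tie-collapsed ROC.  Seeds propagate
explicitly everywhere; repeated runs with the same configuration are
bit-identical, which the pipeline manifest checks by content hashes.

## Problem sizes used in verification

The study conditions are the generator defaults: n = 2114 subjects, 30
observed variables, 3 latent confounders, blanket size 6, minority rate
20.3%.  The blanket-recovery and Bayes-bracketing studies use 20 seeds
with a 5-value α grid and 5 folds; held-out AUROC is measured on fresh
cohorts of 1e5 subjects drawn from each seed's own generative model.
Null-safety studies use permuted outcomes at both default and reduced
cohort sizes.  The acceptance script runs a 5-seed version of the same
studies.

## Known limitations

* The categorical-response LRT is asymptotic; at very small cell counts
  the type-I error can drift (the filter's sparse-category stage exists
  partly to avoid that regime).
* The possible-d-sep stage is bounded in the data path; adjacency
  correctness under latent confounding is exact only in the oracle
  regime.
* Exact-α edge-count monotonicity is an empirical property of the
  PC-style search, not a theorem; it holds in our tests on fixed data.
* The generator's linear-Gaussian/multinomial-logit class matches the
  MGM's assumptions; none of the tests probe model misspecification.
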