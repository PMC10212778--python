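# Methods

## The data and the model

A tricot trial yields one small partial ranking per participant: three
items out of a set of N, ordered by naming the best and the worst. We store
these as an integer matrix with 1 = best and 0 = not evaluated; the same
container accepts longer rankings derived from numeric measurements
(`rank_numeric`, largest value first by default, `ascending=True` when the
inputs are already ordinal ranks). Ties are rejected rather than modelled:
the best/worst design cannot produce them, and the optional seeded random
tie-break for numeric data is meant for robustness pipelines, not
inference.

Worths are estimated under the Plackett–Luce model. For a block ranking
items i₁ ≻ … ≻ i_k the likelihood is the product of sequential choices,
each proportional to the remaining items' worths γ = exp(λ). The
log-likelihood is maximised by Hunter's MM update

    γ_i ← W_i / Σ_{(b,s): i ∈ A(b,s)} ( Σ_{j ∈ A(b,s)} γ_j )⁻¹

with W_i the number of stages won by item i and A(b,s) the items still
unplaced at stage s of block b. Each MM step cannot decrease the
likelihood (assertable via `fit(check_monotone=True)`). Per-stage sums are
computed with log-sum-exp stabilisation.

**Identifiability.** One item's log-worth is fixed at zero (the first item
by default, user-selectable). Reported probability-scale worths are
normalized to sum to 1. The sum-contrast parameterisation used by some
implementations is intentionally not replicated; all contrasts are
available from the fixed-reference parameterisation.

**Regularisation (`npseudo`, default 0.5).** If some item always wins or
always loses within the observed comparisons, the MLE diverges. Adding
pseudo-rankings — a hypothetical item that beats and is beaten by every
real item once, with weight `npseudo` — keeps all estimates finite; the
hypothetical item is estimated and then discarded. With `npseudo=0` the fit
refuses disconnected win graphs (strong connectivity is checked first) and
returns the pure MLE otherwise. Reported log-likelihoods always exclude
the pseudo-rankings.

**Convergence.** Max-abs change of λ below `tol=1e-9` within `maxit=500`
iterations (both configurable); non-convergence returns the current
estimate flagged `converged=False` with a warning.

**Uncertainty.** The covariance of the free log-worths is the inverse of
the analytic observed information (Hessian of the data log-likelihood at
the estimate) with the reference row/column removed; a singular information
matrix falls back to the Moore–Penrose pseudo-inverse with a warning. This
is a design choice — delta-method standard errors from the observed
information — and at `npseudo=0` it reproduces the Bernoulli closed form
for two items. With `npseudo>0` the estimate is not exactly the data MLE,
so the information is evaluated slightly off-mode; with the default small
weight the effect is negligible at trial scale.

**Bradley–Terry.** Pairwise win counts are expanded into weighted two-item
rankings and fitted with the same MM core, which maximises exactly the
Bradley–Terry likelihood; deviance is −2·log-likelihood. Consequently BT
abilities coincide with a Plackett–Luce fit on data consisting only of
two-item blocks.

## Evaluation statistics

**Kendall τ** between two ranking matrices is computed per block over the
items ranked in both (τ-a; no tie correction, ties being excluded
upstream), then aggregated as a weighted mean with weight k_b − 1. The
Z statistic uses the normal approximation with effective sample size
N = Σ(k_b − 1) + 1:  z = τ·sqrt(9N(N−1) / (2(2N+5))). Both the weighting
and the effective-N convention are this package's concrete choices; they
are stated here because different packages aggregate incomplete-block τ
differently.

**Kendall's W** applies to complete m×n rank matrices only; incomplete
inputs are rejected with a pointer to restrict to co-ranked items first.

**Cross-validation** assigns blocks to k folds uniformly at random
(seeded) or takes an explicit fold vector verbatim (blocked CV by season or
site). The default score is the weighted τ between held-out rankings and
the ranking of the same items induced by the training fit's worths; worth
ties are broken by item order, deterministically. A fold whose training
data lose an item entirely is refitted on pseudo-rankings and flagged.

## Plackett–Luce trees

Model-based partitioning implementations commonly use score-based
parameter-instability tests. This package instead uses an exhaustive
likelihood-ratio search with permutation inference — same interface,
different inner test, chosen for transparency and exact finite-sample
control:

1. At a node, for each covariate, scan candidate binary cuts (midpoints of
   sorted unique values; ordered-level cutpoints for categorical columns)
   subject to `minsize` groups in both children, maximising
   Λ = 2(ℓ_left + ℓ_right − ℓ_parent).
2. Assess the best cut of each covariate by permuting that covariate
   across the node's groups (`n_permutations=99`) and recomputing max-Λ;
   the p-value uses the add-one convention (1 + #{perm ≥ obs})/(1 + n).
3. Bonferroni-adjust across the covariates tested; split on the most
   significant covariate if its adjusted p ≤ `alpha` (0.05); recurse to
   `max_depth` (default 3).

Defaults: `minsize = max(2·n_items, 30)` groups so every leaf can identify
its worth vector; numeric thresholds are reported at data midpoints. For
tractability the threshold scan is capped at `max_split_points=16`
quantile-spaced candidates per covariate (set `None` to scan all
midpoints); the same candidate rule is applied to the permuted scans, so
the null distribution matches the observed statistic. Search fits use a
relaxed tolerance (1e-6, warm-started from the parent estimate); accepted
node fits are re-run at full precision. The resolution of the reported
threshold is therefore about range/15 per covariate at default settings.

Per-node type-I error is approximately `alpha` after Bonferroni; a tree
grown on pure-noise covariates stays root-only in roughly 95% of runs, and
a genuine two-regime signal can still pick up one spurious second-level
split in on the order of 10% of runs (two child nodes each tested at
`alpha`). This is inherent to sequential testing at fixed `alpha`, not a
defect; reduce `alpha` or `max_depth` for stricter control.

## Forward covariate selection (`btpermute`)

A generic deviance-based forward loop over a pluggable fitter. The default
fitter scores a candidate by the summed likelihood-ratio improvement of the
best depth-1 split on that candidate within each leaf of the partition
built from already-accepted covariates. The permutation null permutes the
candidate's values across blocks and rescores; each candidate is tested
against its own (per-variable) null. The best candidate is accepted iff
its add-one p-value ≤ `alpha`; selection stops at the first rejection.
`n_permutations` must satisfy (1+n)·alpha ≥ 1 or the quantile is
unresolvable (error). With c pure-noise candidates the family-wise
per-step acceptance probability is ≈ 1−(1−alpha)^c, slightly below c·alpha;
no across-candidate correction is applied, matching the per-step testing
scheme described above.

## Decision heuristics

* **Reliability** is the head-to-head Luce win probability against a check
  item: r_i = 1/(1+exp(−(λ_i−λ_ref))), with delta-method SE
  r(1−r)·se(λ_i−λ_ref) from the fitted covariance. r_ref = 0.5 exactly, by
  definition, with zero SE. Other reliability variants exist in the
  breeding literature; this one is specifically the item-vs-check win
  probability. The accompanying worth column is per-scenario normalized.
* **Regret** operates on normalized worths per scenario (tree leaves,
  seasons): regret_{is} = max_j w_{js} − w_{is}; items are ordered by their
  worst-case regret, so the first row is the minimax choice. Normalized
  worths (not log-worths) are used so that scenarios are comparable and
  losses bounded.
* **Agreement (`compare`)** centres both log-worth vectors to mean zero
  before differencing, because Plackett–Luce scales are per-fit relative;
  the plot-ready output is per-item (mean, difference) with
  mean ± 1.96·sd limits.
* **Worth map / worth bar** are thin, validated reshapes of fitted
  log-worths (shared item set and reference enforced; the reference column
  is identically zero).

## The synthetic-trial generator

`generate_tricot_trial` emulates a decentralized variety trial: N items
(default 10), incomplete blocks of three allocated by shuffled item
repetition and chunking (near-balanced: appearance counts differ by at most
the block size; exact balanced-incomplete-block designs are deliberately
not used, matching randomized tricot practice), rankings sampled from the
true Plackett–Luce model by sequential choice, and best/worst recorded as
a tricot record. Defaults — 500 blocks, true log-worths evenly spread over
[0, 2], a rainfall-like covariate uniform on [100, 300] mm with an optional
regime switch at 200 mm (kept away from the edges so `minsize` is
satisfiable), plus uniform pure-noise covariates — define the study
conditions used throughout the tests. `generate_multi_trait` produces
correlated per-trait rankings (trait log-worths ρ·λ + (1−ρ)·ε with ε
standardized to the spread of λ) so trait-vs-overall τ rises with ρ.

What the generator does **not** emulate: spatial or temporal correlation
between farms, respondent-level response styles, item-by-participant
interactions beyond the covariate regime, and missing-data mechanisms.
Passing recovery tests therefore demonstrate correctness of the estimators
under the model's own assumptions, not robustness to the full messiness of
field data.

## Problem sizes used in tests and the acceptance script

Estimator checks use 20 random instances of ≤5 items × ≤60 blocks against
an independent BFGS optimisation of the same likelihood; parameter recovery
uses the default 10 × 500 trial; tree and selection recovery use 600- and
400-block two-regime trials, with type-I rates measured over 20 seeded
240-block pure-noise trials at the default 99 permutations. These sizes
are the package's chosen study conditions: large enough that recovery is
informative, small enough that the full suite runs in minutes.

## Known limitations

* No tie handling (Davidson-type extensions) anywhere in the pipeline.
* No item-level covariates inside the likelihood; environment effects are
  handled exclusively by partitioning.
* Tree inference is conditional on the greedy search; no honesty/sample
  splitting, surrogate splits or multiway splits.
* The Kendall-τ normal approximation is asymptotic; small trials should
  read the p-values as indicative.
* `rank_tricot` drops records with missing best/worst answers (with a
  warning and count) rather than modelling partial answers.
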