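# ranktrial

Analysis of rank-based trial data for agricultural experimentation, built
around the triadic comparison of technology options ("tricot") design:
each participant grows an incomplete block of three items (crop varieties,
practices, products) out of a larger set and reports which performed *best*
and which *worst*. Thousands of such small rankings, pooled, identify which
items win and under which conditions — without any participant ever scoring
an item on an absolute scale.

The package is aimed at breeders, agronomists and data scientists running
decentralized on-farm trials who need to go from raw best/worst answers to
variety recommendations.

## The model

Item worths are estimated with the **Plackett–Luce model**. Each item *i*
has a worth γᵢ > 0; a ranking of a block is a sequence of choices, each
picking the next item with probability proportional to the remaining
worths:

    P(i₁ ≻ i₂ ≻ … ≻ i_k) = ∏_{s=1}^{k−1}  γ_{i_s} / (γ_{i_s} + … + γ_{i_k})

With λ = log γ and a reference item fixed at λ_ref = 0, the maximum
likelihood estimate is found by Hunter's MM algorithm; standard errors come
from the observed information. The two-item special case is the
**Bradley–Terry model**, P(i beats j) = γᵢ/(γᵢ+γⱼ).

On top of the fits the package provides:

* **Evaluation** — Kendall τ between rankings (weighted over incomplete
  blocks, with Z and p), Kendall's W, McFadden's pseudo-R², AIC, and k-fold
  or blocked cross-validation.
* **Plackett–Luce trees** — recursive partitioning of blocks on covariates
  (e.g. rainfall) with a separate worth model per leaf, using a
  likelihood-ratio split search guarded by per-covariate permutation tests.
* **Covariate selection** — deviance-based forward selection with
  permutation nulls (`btpermute`).
* **Decision heuristics** — reliability (probability of beating a check
  variety), minimax regret across scenarios, Bland–Altman agreement between
  traits, and worth-map / worth-bar tables ready for plotting.
* **A synthetic-trial simulator** — generates tricot trials with known true
  worths (optionally switching regimes at a covariate threshold), used as
  ground truth by the entire test suite.

## Worked example

```python
import ranktrial as rt

# a synthetic tricot trial: 10 varieties, 500 farms, true log-worths
# spread over [0, 2]
trial = rt.generate_tricot_trial(n_items=10, n_blocks=500, seed=42)
R = trial.rankings()                       # 500 x 10 partial-ranking matrix

res = rt.fit_plackett_luce(R)              # MM fit, item01 as reference
print(res.summary())
```

```
Plackett-Luce model (10 items, 500 rankings)
ref: item01 (log-worth fixed at 0)   npseudo: 0.5
log-lik: -784.990   null: -895.880   AIC: 1587.98   McFadden R2: 0.1238
converged: True in 40 iterations
  item  worth  log_worth     se
item01 0.0283     0.0000 0.0000
item02 0.0403     0.3546 0.2001
...
item10 0.2155     2.0302 0.2078
```

`worth` is the probability-scale worth (sums to 1); `log_worth` is λ with
the reference at 0 — here the estimate for `item10` (true value 2.0) is
2.03 ± 0.21. The reliability of each variety against the check:

```python
print(res.reliability())           # P(item beats the reference)
```

```
  item  reliability  reliability_se  worth
item01        0.500           0.000  0.028
item02        0.588           0.048  0.040
...
item10        0.884           0.021  0.215
```

The reference's reliability against itself is 0.500 by definition;
`item10` beats the check in 88% of head-to-head choices. When worths
depend on the environment, a Plackett–Luce tree finds the split:

```python
import numpy as np

low = np.linspace(0, 2, 10)
regime = rt.TwoRegimeWorths(tuple(low), tuple(low[::-1]))  # order flips at 200 mm
trial = rt.generate_tricot_trial(n_items=10, n_blocks=600,
                                 true_log_worth=regime, seed=7)
tree = rt.fit_pl_tree(trial.grouped(), trial.covariates, seed=3)
print(tree.summary())
```

```
Plackett-Luce tree: 3 nodes, depth 1, alpha=0.05, minsize=30
joint log-lik -939.266 (root -1068.098)
  node 2 [rainfall <= 205.312]: 320 groups, top: item10, item09, item07
  node 3 [rainfall > 205.312]: 280 groups, top: item01, item02, item03
```

The tree recovers the regime switch (true threshold 200) and the flipped
variety ordering on either side. `rt.reliability_by_node(tree)` then gives
per-environment recommendation tables, and `rt.regret` ranks varieties by
their worst-case shortfall across the leaves.

The same workflow is available from the shell:

```sh
ranktrial simulate --n-items 10 --n-blocks 500 --seed 42 --out sim
ranktrial convert sim/tricot.csv --out conv
ranktrial fit conv/rankings.csv --out fit
ranktrial reliability conv/rankings.csv --out rel
```

## Documentation

`docs/methods.md` describes the model, the estimation and testing
procedures, the defaults and their rationale, what the simulator does and
does not emulate, and known limitations.
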