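"""Bradley-Terry fitting on pairwise reductions and permutation-guarded
forward covariate selection.

The Bradley-Terry model is the two-item special case of Plackett-Luce:
P(i beats j) = gamma_i / (gamma_i + gamma_j).  Fitting expands the pairwise
win counts into weighted two-item rankings and runs the same MM core as the
Plackett-Luce fit, which maximises exactly the Bradley-Terry likelihood.

``btpermute`` is a deviance-based forward selection over block covariates.
At each step every remaining candidate is scored by the deviance reduction
(-2 * log-likelihood) obtained by the best depth-1 split on that candidate
within each leaf of the partition built from the already-selected
covariates; a per-candidate permutation null (refitting with the candidate's
values permuted across blocks) guards acceptance.  Selection stops at the
first rejection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plackett_luce import PlackettLuce, PlackettLuceResults
from .rankings import ItemSet, PairwiseCounts, RankingMatrix, group
from .tree import PLTree

__all__ = ["BradleyTerry", "BTResults", "fit_bradley_terry",
           "SelectionStep", "SelectionTrace", "btpermute"]


class BradleyTerry:
    """Bradley-Terry ability model for :class:`PairwiseCounts`.

    ``npseudo > 0`` regularises exactly as in the Plackett-Luce fit; with
    ``npseudo = 0`` a disconnected comparison graph is an error naming the
    components.
    """

    def __init__(self, counts: PairwiseCounts, ref: str | None = None,
                 npseudo: float = 0.0):
        self.counts = counts
        rows, weights = [], []
        n = len(counts.items)
        for i in range(n):
            for j in range(n):
                if i == j or counts.wins[i, j] == 0:
                    continue
                row = np.zeros(n, dtype=np.int64)
                row[i], row[j] = 1, 2
                rows.append(row)
                weights.append(float(counts.wins[i, j]))
        if not rows:
            raise ValueError("no pairwise comparisons")
        R = RankingMatrix(np.asarray(rows), counts.items, validate=False)
        self.n_pairs = int(counts.wins.sum())
        self._pl = PlackettLuce(R, ref=ref, npseudo=npseudo,
                                weights=np.asarray(weights))

    def fit(self, tol: float = 1e-9, maxit: int = 500) -> "BTResults":
        res = self._pl.fit(tol=tol, maxit=maxit)
        return BTResults(self, res)


class BTResults:
    """Fitted Bradley-Terry model: log-abilities (ref = 0) and deviance."""

    def __init__(self, model: BradleyTerry, pl_results: PlackettLuceResults):
        self.model = model
        self._pl = pl_results
        self.converged = pl_results.converged
        self.n_pairs = model.n_pairs
        self.ref = pl_results.ref

    @property
    def items(self) -> ItemSet:
        return self.model.counts.items

    @property
    def log_ability(self) -> pd.Series:
        s = self._pl.log_worth.copy()
        s.name = "log_ability"
        return s

    @property
    def llf(self) -> float:
        return self._pl.llf

    @property
    def deviance(self) -> float:
        return -2.0 * self.llf

    @property
    def vcov(self) -> pd.DataFrame:
        return self._pl.vcov

    @property
    def aic(self) -> float:
        return self.deviance + 2.0 * (len(self.items) - 1)

    def prob_beats(self, i: str, j: str) -> float:
        d = self.log_ability[i] - self.log_ability[j]
        return float(1.0 / (1.0 + np.exp(-d)))

    def summary(self) -> str:
        head = (
            f"Bradley-Terry model ({len(self.items)} items, {self.n_pairs} pairs)\n"
            f"ref: {self.ref}   deviance: {self.deviance:.3f}   "
            f"converged: {self.converged}\n"
        )
        tab = pd.DataFrame({
            "item": list(self.items.labels),
            "log_ability": self.log_ability.values,
            "se": self._pl.bse.values,
        })
        return head + tab.to_string(index=False, float_format=lambda x: f"{x:.4f}")


def fit_bradley_terry(pairs: PairwiseCounts, ref: str | None = None,
                      npseudo: float = 0.0, **kwargs) -> BTResults:
    """Fit a Bradley-Terry model from pairwise win counts."""
    return BradleyTerry(pairs, ref=ref, npseudo=npseudo).fit(**kwargs)


# -- forward selection --------------------------------------------------------

@dataclass
class SelectionStep:
    variable: str
    deviance_reduction: float
    permutation_threshold: float
    p_value: float
    accepted: bool


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)
    n_permutations: int = 99
    alpha: float = 0.05
    base_deviance: float = float("nan")
    final_deviance: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "type": "selection_trace",
            "steps": [vars(s) for s in self.steps],
            "selected": self.selected,
            "n_permutations": self.n_permutations,
            "alpha": self.alpha,
            "base_deviance": self.base_deviance,
            "final_deviance": self.final_deviance,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        lines = [
            f"forward selection: alpha={self.alpha}, "
            f"{self.n_permutations} permutations",
            f"base deviance {self.base_deviance:.3f}",
        ]
        for s in self.steps:
            flag = "accepted" if s.accepted else "rejected"
            lines.append(
                f"  {s.variable}: reduction {s.deviance_reduction:.3f} vs "
                f"null 95% {s.permutation_threshold:.3f} (p={s.p_value:.3f}) -> {flag}"
            )
        lines.append(f"selected: {self.selected or '(none)'}")
        return "\n".join(lines)


def _partition_leaves(helper: PLTree, partition: list[np.ndarray],
                      values: np.ndarray, parents: list[PlackettLuceResults]):
    """Total deviance reduction of the best depth-1 split per leaf, with splits."""
    total = 0.0
    splits = []
    for leaf_groups, parent in zip(partition, parents):
        v = pd.Series(values[leaf_groups], name="v")
        best = helper._scan(leaf_groups, v, parent)
        if best is not None and best[0] > 0:
            total += best[0]
            splits.append(best[1])
        else:
            splits.append(None)
    return total, splits


def btpermute(
    R: RankingMatrix,
    covariates: pd.DataFrame,
    candidates: list[str] | None = None,
    n_permutations: int = 99,
    alpha: float = 0.05,
    seed: int | None = None,
    npseudo: float = 0.5,
    minsize: int | None = None,
    max_split_points: int | None = 16,
) -> SelectionTrace:
    """Deviance-based forward covariate selection with permutation guards.

    Parameters
    ----------
    R : RankingMatrix
    covariates : DataFrame
        One row per block, aligned with the rows of ``R``.
    candidates : list of column names (default: all covariate columns)
    n_permutations, alpha
        Permutation-null size and significance level; the acceptance rule is
        the add-one p-value ``p = (1 + #{perm >= obs}) / (1 + n_perm)``
        compared to ``alpha``, which requires ``(1 + n_perm) * alpha >= 1``.
    seed : int
        Seeds the permutation stream; runs are fully reproducible.
    """
    if len(covariates) != R.n_blocks:
        raise ValueError(
            f"covariates has {len(covariates)} rows but there are {R.n_blocks} blocks"
        )
    if candidates is None:
        candidates = list(covariates.columns)
    if (1 + n_permutations) * alpha < 1:
        raise ValueError(
            f"n_permutations={n_permutations} cannot resolve alpha={alpha}; "
            f"need at least {int(np.ceil(1 / alpha)) - 1}"
        )
    rng = np.random.default_rng(seed)
    grouped = group(R, np.arange(R.n_blocks))
    helper = PLTree(
        grouped, covariates, npseudo=npseudo, minsize=minsize,
        max_split_points=max_split_points, alpha=alpha,
        n_permutations=n_permutations,
    )
    base = helper._fit_groups(np.arange(grouped.n_groups), full=True)
    trace = SelectionTrace(n_permutations=n_permutations, alpha=alpha,
                           base_deviance=-2.0 * base.llf)
    partition: list[np.ndarray] = [np.arange(grouped.n_groups)]
    parents: list[PlackettLuceResults] = [base]
    remaining = list(candidates)
    current_deviance = trace.base_deviance
    while remaining:
        scores = {}
        for var in remaining:
            values = np.asarray(covariates[var])
            if np.unique(values.astype(str)).size < 2:
                warnings.warn(f"candidate {var!r} is constant; skipped",
                              UserWarning, stacklevel=2)
                continue
            obs, splits = _partition_leaves(helper, partition, values, parents)
            perm_vals = np.empty(n_permutations)
            for p in range(n_permutations):
                perm_vals[p], _ = _partition_leaves(
                    helper, partition, rng.permutation(values), parents
                )
            exceed = int(np.sum(perm_vals >= obs - 1e-12))
            p_value = (1 + exceed) / (1 + n_permutations)
            threshold = float(np.quantile(perm_vals, 1 - alpha))
            scores[var] = (obs, threshold, p_value, splits)
        if not scores:
            break
        best_var = max(scores, key=lambda v: scores[v][0])
        obs, threshold, p_value, splits = scores[best_var]
        accepted = p_value <= alpha
        trace.steps.append(SelectionStep(best_var, obs, threshold, p_value, accepted))
        if not accepted:
            break
        trace.selected.append(best_var)
        remaining.remove(best_var)
        current_deviance -= obs
        # apply the accepted splits, refining the partition
        new_partition, new_parents = [], []
        values = np.asarray(covariates[best_var])
        for leaf_groups, parent, sp in zip(partition, parents, splits):
            if sp is None:
                new_partition.append(leaf_groups)
                new_parents.append(parent)
                continue
            arr = values[leaf_groups]
            if np.issubdtype(arr.dtype, np.number):
                arr = arr.astype(float)
            else:
                arr = arr.astype(str)
            left = sp.goes_left(arr)
            for side in (leaf_groups[left], leaf_groups[~left]):
                new_partition.append(side)
                new_parents.append(helper._fit_groups(side, full=True))
        partition, parents = new_partition, new_parents
    trace.final_deviance = sum(-2.0 * p.llf for p in parents)
    return trace
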