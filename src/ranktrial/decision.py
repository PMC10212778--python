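"""Decision heuristics and presentation tables for fitted worth models.

* ``reliability`` — probability that an item beats a reference (check) item
  in a head-to-head Luce choice: r_i = 1 / (1 + exp(-(lambda_i - lambda_ref))),
  with a delta-method standard error r(1-r) * se(lambda_i - lambda_ref).
  The reference's reliability against itself is 0.5 exactly.
* ``regret`` — an item's worth shortfall against the best item within each
  scenario (tree leaf, season, ...); items are ranked by their worst-case
  shortfall (minimax regret).
* ``compare`` — Bland-Altman-style agreement between two log-worth vectors
  (e.g. overall appreciation vs yield): per item the mean of and difference
  between the two centred vectors, with mean +- 1.96 sd limits.
* ``worth_map_data`` / ``worth_bar_data`` — plot-ready matrices/tables of
  (log-)worths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plackett_luce import PlackettLuceResults
from .tree import PLTreeResults

__all__ = ["reliability", "reliability_by_node", "regret", "compare",
           "AgreementData", "worth_map_data", "worth_bar_data"]


def reliability(results: PlackettLuceResults, ref: str | None = None) -> pd.DataFrame:
    """Per-item probability of outperforming the reference item, with SE.

    Returns a table (item, reliability, reliability_se, worth); the worth
    column is normalized to sum 1.
    """
    if ref is None:
        ref = results.ref
    if ref not in results.items:
        raise KeyError(f"reference item {ref!r} not in the model's item set")
    lam = results.log_worth
    diff = lam - lam[ref]
    r = 1.0 / (1.0 + np.exp(-diff))
    V = results.vcov_full()
    labs = list(results.items.labels)
    var_diff = np.array(
        [V.loc[i, i] + V.loc[ref, ref] - 2.0 * V.loc[i, ref] for i in labs]
    )
    se_diff = np.sqrt(np.clip(var_diff, 0.0, None))
    se_r = r.values * (1.0 - r.values) * se_diff
    return pd.DataFrame(
        {
            "item": labs,
            "reliability": r.values,
            "reliability_se": se_r,
            "worth": results.worth.values,
        }
    )


def reliability_by_node(tree: PLTreeResults, ref: str | None = None) -> pd.DataFrame:
    """Reliability table per leaf of a Plackett-Luce tree (node column first)."""
    frames = []
    for leaf in tree.leaves():
        leaf_ref = ref if ref is not None else leaf.results.ref
        if leaf_ref not in leaf.results.items:
            warnings.warn(
                f"reference {leaf_ref!r} absent from node {leaf.id}; node skipped",
                UserWarning, stacklevel=2,
            )
            continue
        tab = reliability(leaf.results, ref=leaf_ref)
        tab.insert(0, "node", leaf.id)
        frames.append(tab)
    if not frames:
        raise ValueError("reference absent from every leaf")
    return pd.concat(frames, ignore_index=True)


def regret(worths_by_scenario: pd.DataFrame) -> pd.DataFrame:
    """Minimax-regret table from an item x scenario matrix of normalized worths.

    regret_(i,s) = max_j worth_(j,s) - worth_(i,s); ``worst_regret`` is the
    maximum over scenarios and the output is sorted ascending by it, so the
    first row is the minimax choice.
    """
    W = worths_by_scenario
    if W.shape[1] < 2:
        raise ValueError(
            "regret needs at least 2 scenarios; with one scenario rank by worth directly"
        )
    col_sums = W.sum(axis=0)
    if not np.allclose(col_sums, 1.0, atol=1e-6):
        raise ValueError(
            f"each scenario's worths must sum to 1, got sums {col_sums.to_dict()}"
        )
    reg = W.max(axis=0) - W
    out = W.copy()
    out["worst_regret"] = reg.max(axis=1)
    out["mean_worth"] = W.mean(axis=1)
    out = out.sort_values(["worst_regret", "mean_worth"],
                          ascending=[True, False], kind="stable")
    out.index.name = "item"
    return out


@dataclass
class AgreementData:
    """Bland-Altman agreement between two centred log-worth vectors."""

    data: pd.DataFrame  # per item: mean, difference
    mean_difference: float
    lower_limit: float
    upper_limit: float

    def summary(self) -> str:
        return (
            f"mean difference {self.mean_difference:.4f}; limits of agreement "
            f"[{self.lower_limit:.4f}, {self.upper_limit:.4f}]\n"
            + self.data.to_string(float_format=lambda x: f"{x:.4f}")
        )


def compare(log_worth_a: pd.Series, log_worth_b: pd.Series) -> AgreementData:
    """Agreement between two measures on the same items.

    Both vectors are centred to mean 0 first (worth scales are per-fit
    relative, so only contrasts are comparable); per item the x coordinate
    is the mean of the two centred values and the y coordinate their
    difference.  Items centred near y = 0 agree across the two measures.
    """
    a = pd.Series(log_worth_a).astype(float)
    b = pd.Series(log_worth_b).astype(float)
    if len(a) != len(b):
        raise ValueError("vectors must have the same length")
    if not a.index.equals(b.index):
        if set(a.index) != set(b.index):
            raise ValueError("vectors must cover the same items")
        b = b.reindex(a.index)
    a = a - a.mean()
    b = b - b.mean()
    diff = a - b
    sd = float(diff.std(ddof=1)) if len(diff) > 1 else 0.0
    mean_diff = float(diff.mean())  # 0 after centring, kept for the record
    data = pd.DataFrame({"mean": (a + b) / 2.0, "difference": diff})
    data.index.name = "item"
    return AgreementData(
        data=data,
        mean_difference=mean_diff,
        lower_limit=mean_diff - 1.96 * sd,
        upper_limit=mean_diff + 1.96 * sd,
    )


def worth_map_data(models_by_trait: dict[str, PlackettLuceResults]) -> pd.DataFrame:
    """Trait x item matrix of log-worths (heatmap-ready).

    All models must share the item set and reference; the reference column is
    identically 0 by construction.
    """
    if not models_by_trait:
        raise ValueError("no models given")
    traits = list(models_by_trait)
    first = models_by_trait[traits[0]]
    labels = first.items.labels
    ref = first.ref
    rows = {}
    for trait, res in models_by_trait.items():
        if res.items.labels != labels:
            raise ValueError(
                f"model for {trait!r} has a different item set than {traits[0]!r}"
            )
        if res.ref != ref:
            raise ValueError(
                f"model for {trait!r} uses reference {res.ref!r}, expected {ref!r}"
            )
        rows[trait] = res.log_worth
    out = pd.DataFrame(rows).T
    out.index.name = "trait"
    return out


def worth_bar_data(results: PlackettLuceResults) -> pd.DataFrame:
    """(item, worth) table sorted descending; worths sum to 1."""
    w = results.worth.sort_values(ascending=False)
    return pd.DataFrame({"item": w.index, "worth": w.values})
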