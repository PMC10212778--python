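"""Plackett-Luce trees: recursive partitioning of grouped rankings on covariates.

Each tree node holds a Plackett-Luce fit of the rankings belonging to the
node's groups.  Node splitting is an exhaustive likelihood-ratio search: for
every covariate the candidate thresholds (midpoints of sorted unique values;
for categorical columns, cutpoints along the ordered levels) are scanned for
the largest

    Lambda = 2 * (llf_left + llf_right - llf_parent)

subject to a minimum child size.  Significance of the best cut of each
covariate is assessed by permuting that covariate across the node's groups
and recomputing max-Lambda; the permutation p-values are Bonferroni-adjusted
across the covariates tested, and the node splits on the most significant
covariate when the adjusted p-value is at most ``alpha``.

With many groups the threshold scan is restricted by default to at most
``max_split_points`` quantile-spaced candidates (set ``None`` to scan every
midpoint); search fits use a relaxed tolerance and warm starts from the
parent estimate, while accepted node fits are run at full precision.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plackett_luce import PlackettLuce, PlackettLuceResults
from .rankings import GroupedRankings

__all__ = ["Split", "TreeNode", "PLTree", "PLTreeResults", "fit_pl_tree",
           "node_labels", "node_rules", "top_items", "predict_worth"]


@dataclass(frozen=True)
class Split:
    """Binary split rule: numeric ``var <= threshold`` or ``var in left_levels``."""

    var: str
    threshold: float | None = None
    left_levels: tuple | None = None

    @property
    def is_numeric(self) -> bool:
        return self.threshold is not None

    def goes_left(self, values) -> np.ndarray:
        values = np.asarray(values)
        if self.is_numeric:
            return values.astype(float) <= self.threshold
        return np.isin(values, np.asarray(self.left_levels))

    def rule_strings(self) -> tuple[str, str]:
        if self.is_numeric:
            return (f"{self.var} <= {self.threshold:g}", f"{self.var} > {self.threshold:g}")
        left = ", ".join(map(str, self.left_levels))
        return (f"{self.var} in {{{left}}}", f"{self.var} not in {{{left}}}")


@dataclass
class TreeNode:
    id: int
    depth: int
    groups: np.ndarray
    results: PlackettLuceResults
    n_groups: int
    loglik: float
    split: Split | None = None
    children: tuple[int, int] | None = None
    p_value: float | None = None          # Bonferroni-adjusted p of the applied split
    covariate_tests: dict = field(default_factory=dict)  # var -> (max-Lambda, adj p)

    @property
    def is_leaf(self) -> bool:
        return self.children is None


class PLTree:
    """Plackett-Luce tree model over grouped rankings and per-group covariates.

    Parameters
    ----------
    grouped : GroupedRankings
    covariates : DataFrame
        One row per group, positionally aligned with group ids ``0..G-1``.
    alpha : float
        Significance level for the Bonferroni-adjusted permutation test.
    minsize : int, optional
        Minimum number of groups in each child (default
        ``max(2 * n_items, 30)``; a warning flags values below
        ``2 * n_items`` as likely to produce unstable leaf fits).
    n_permutations : int
        Permutations per covariate test (default 99).
    max_depth : int
        Maximum split depth (0 = root only).
    max_split_points : int or None
        Cap on candidate thresholds per covariate (quantile-spaced subset of
        the midpoints); ``None`` scans all midpoints.
    """

    def __init__(
        self,
        grouped: GroupedRankings,
        covariates: pd.DataFrame,
        ref: str | None = None,
        npseudo: float = 0.5,
        alpha: float = 0.05,
        minsize: int | None = None,
        n_permutations: int = 99,
        max_depth: int = 3,
        max_split_points: int | None = 16,
        search_tol: float = 1e-6,
        search_maxit: int = 150,
        tol: float = 1e-9,
        maxit: int = 500,
    ):
        if len(covariates) != grouped.n_groups:
            raise ValueError(
                f"covariates has {len(covariates)} rows but there are "
                f"{grouped.n_groups} groups"
            )
        self.grouped = grouped
        self.covariates = covariates.reset_index(drop=True)
        self.ref = ref
        self.npseudo = npseudo
        self.alpha = alpha
        n_items = grouped.rankings.n_items
        self.minsize = minsize if minsize is not None else max(2 * n_items, 30)
        if self.minsize < 2 * n_items:
            warnings.warn(
                f"minsize={self.minsize} < 2*n_items={2*n_items}: leaf fits may be unstable",
                UserWarning, stacklevel=2,
            )
        self.n_permutations = n_permutations
        self.max_depth = max_depth
        self.max_split_points = max_split_points
        self.search_tol = search_tol
        self.search_maxit = search_maxit
        self.tol = tol
        self.maxit = maxit

    # -- fitting helpers ------------------------------------------------------
    def _fit_groups(self, groups: np.ndarray, start=None, full=True) -> PlackettLuceResults:
        rows = self.grouped.rows_of_groups(groups)
        sub = self.grouped.rankings.subset(rows)
        with warnings.catch_warnings():
            if not full:
                warnings.simplefilter("ignore")
            model = PlackettLuce(sub, ref=self.ref, npseudo=self.npseudo)
            if full:
                return model.fit(tol=self.tol, maxit=self.maxit)
            return model.fit(tol=self.search_tol, maxit=self.search_maxit, start=start)

    def _candidates(self, values: np.ndarray) -> list[Split] | None:
        """Candidate splits for one covariate column at a node."""
        name = values.name if hasattr(values, "name") else "x"
        arr = np.asarray(values)
        numeric = np.issubdtype(arr.dtype, np.number)
        out: list[Split] = []
        if numeric:
            u = np.unique(arr.astype(float))
            if u.size < 2:
                return None
            mids = (u[:-1] + u[1:]) / 2.0
            if self.max_split_points is not None and mids.size > self.max_split_points:
                idx = np.unique(
                    np.round(np.linspace(0, mids.size - 1, self.max_split_points)).astype(int)
                )
                mids = mids[idx]
            out = [Split(name, threshold=float(t)) for t in mids]
        else:
            levels = sorted(map(str, np.unique(arr.astype(str))))
            if len(levels) < 2:
                return None
            cuts = [Split(name, left_levels=tuple(levels[: i + 1]))
                    for i in range(len(levels) - 1)]
            if self.max_split_points is not None and len(cuts) > self.max_split_points:
                idx = np.unique(
                    np.round(np.linspace(0, len(cuts) - 1, self.max_split_points)).astype(int)
                )
                cuts = [cuts[i] for i in idx]
            out = cuts
        return out or None

    def _scan(self, groups, values, parent) -> tuple[float, Split] | None:
        """Max likelihood-ratio statistic over candidate cuts of one covariate."""
        cands = self._candidates(values)
        if cands is None:
            return None
        start = parent.log_worth.to_numpy()
        best: tuple[float, Split] | None = None
        arr = np.asarray(values)
        if np.issubdtype(arr.dtype, np.number):
            arr = arr.astype(float)
        else:
            arr = arr.astype(str)
        for sp in cands:
            left = sp.goes_left(arr)
            nl = int(left.sum())
            if nl < self.minsize or groups.size - nl < self.minsize:
                continue
            res_l = self._fit_groups(groups[left], start=start, full=False)
            res_r = self._fit_groups(groups[~left], start=start, full=False)
            lam = 2.0 * (res_l.llf + res_r.llf - parent.llf)
            if best is None or lam > best[0]:
                best = (lam, sp)
        return best

    def _test_node(self, node: TreeNode, rng: np.random.Generator):
        tested: dict[str, tuple[float, float, Split]] = {}
        for col in self.covariates.columns:
            values = self.covariates.loc[node.groups, col]
            arr = np.asarray(values)
            if np.unique(arr.astype(str)).size < 2:
                warnings.warn(
                    f"covariate {col!r} constant at node {node.id}; skipped",
                    UserWarning, stacklevel=2,
                )
                continue
            values = pd.Series(arr, name=col)
            obs = self._scan(node.groups, values, node.results)
            if obs is None:
                continue
            lam_obs, split = obs
            exceed = 0
            for _ in range(self.n_permutations):
                perm = pd.Series(rng.permutation(arr), name=col)
                res = self._scan(node.groups, perm, node.results)
                if res is not None and res[0] >= lam_obs - 1e-12:
                    exceed += 1
            p = (1 + exceed) / (1 + self.n_permutations)
            tested[col] = (lam_obs, p, split)
        if not tested:
            return None
        n_tested = len(tested)
        adj = {c: min(1.0, p * n_tested) for c, (lam, p, sp) in tested.items()}
        node.covariate_tests = {c: (tested[c][0], adj[c]) for c in tested}
        best_col = min(tested, key=lambda c: (adj[c], -tested[c][0]))
        if adj[best_col] <= self.alpha:
            return tested[best_col][2], adj[best_col]
        return None

    def fit(self, seed: int | None = None) -> "PLTreeResults":
        rng = np.random.default_rng(seed)
        nodes: dict[int, TreeNode] = {}
        counter = [0]

        def grow(groups: np.ndarray, depth: int) -> int:
            counter[0] += 1
            nid = counter[0]
            res = self._fit_groups(groups, full=True)
            node = TreeNode(nid, depth, groups, res, groups.size, res.llf)
            nodes[nid] = node
            if depth < self.max_depth and groups.size >= 2 * self.minsize:
                accepted = self._test_node(node, rng)
                if accepted is not None:
                    split, p_adj = accepted
                    arr = np.asarray(self.covariates.loc[groups, split.var])
                    left = split.goes_left(
                        arr.astype(float)
                        if np.issubdtype(arr.dtype, np.number)
                        else arr.astype(str)
                    )
                    node.split = split
                    node.p_value = p_adj
                    lid = grow(groups[left], depth + 1)
                    rid = grow(groups[~left], depth + 1)
                    node.children = (lid, rid)
            return nid

        grow(np.arange(self.grouped.n_groups), 0)
        return PLTreeResults(self, nodes, seed)


class PLTreeResults:
    """Fitted Plackett-Luce tree: nodes, leaf models and reporting utilities."""

    def __init__(self, model: PLTree, nodes: dict[int, TreeNode], seed):
        self.model = model
        self.nodes = nodes
        self.seed = seed
        self.items = model.grouped.rankings.items

    @property
    def root(self) -> TreeNode:
        return self.nodes[1]

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.nodes.values() if n.is_leaf]

    @property
    def depth(self) -> int:
        return max(n.depth for n in self.nodes.values())

    @property
    def loglik(self) -> float:
        """Joint data log-likelihood: sum over leaf fits."""
        return sum(n.loglik for n in self.leaves())

    # -- description ----------------------------------------------------------
    def node_labels(self) -> list[str]:
        """Splitting covariate of every internal node (root first)."""
        return [n.split.var for n in sorted(self.nodes.values(), key=lambda x: x.id)
                if n.split is not None]

    def node_rules(self) -> dict[int, str]:
        """Per-leaf conjunction of the rules on the path from the root."""
        rules: dict[int, str] = {}

        def walk(nid: int, path: list[str]) -> None:
            node = self.nodes[nid]
            if node.is_leaf:
                rules[nid] = " & ".join(path)
                return
            left_s, right_s = node.split.rule_strings()
            walk(node.children[0], path + [left_s])
            walk(node.children[1], path + [right_s])

        walk(1, [])
        return rules

    def top_items(self, n: int = 1) -> dict[int, list[str]]:
        """Top-n items by worth in each leaf."""
        if n > len(self.items):
            warnings.warn(
                f"n={n} exceeds the {len(self.items)} items; clipped",
                UserWarning, stacklevel=2,
            )
            n = len(self.items)
        out = {}
        for leaf in self.leaves():
            out[leaf.id] = leaf.results.predicted_ranking()[:n]
        return out

    # -- prediction -----------------------------------------------------------
    def route(self, row: pd.Series) -> int:
        node = self.root
        while not node.is_leaf:
            v = row[node.split.var]
            if pd.isna(v):
                raise ValueError(
                    f"missing value for covariate {node.split.var!r} used by a split"
                )
            goes_left = bool(node.split.goes_left(np.asarray([v]))[0])
            node = self.nodes[node.children[0 if goes_left else 1]]
        return node.id

    def predict_worth(self, new_covariates: pd.DataFrame) -> pd.DataFrame:
        """Normalized leaf worths for every row of ``new_covariates``."""
        rows = []
        for _, row in new_covariates.iterrows():
            leaf = self.nodes[self.route(row)]
            rows.append(leaf.results.worth)
        return pd.DataFrame(rows, index=new_covariates.index)

    # -- reporting ------------------------------------------------------------
    def summary(self) -> str:
        lines = [
            f"Plackett-Luce tree: {len(self.nodes)} nodes, depth {self.depth}, "
            f"alpha={self.model.alpha}, minsize={self.model.minsize}",
            f"joint log-lik {self.loglik:.3f} (root {self.root.loglik:.3f})",
        ]
        rules = self.node_rules()
        for leaf in self.leaves():
            rule = rules[leaf.id] or "<root>"
            top = ", ".join(leaf.results.predicted_ranking()[:3])
            lines.append(
                f"  node {leaf.id} [{rule}]: {leaf.n_groups} groups, "
                f"top: {top}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        nodes = []
        for n in sorted(self.nodes.values(), key=lambda x: x.id):
            d = {
                "id": n.id,
                "depth": n.depth,
                "n_groups": int(n.n_groups),
                "loglik": n.loglik,
                "is_leaf": n.is_leaf,
            }
            if n.split is not None:
                d["split"] = {
                    "var": n.split.var,
                    "threshold": n.split.threshold,
                    "left_levels": (
                        list(n.split.left_levels) if n.split.left_levels else None
                    ),
                }
                d["children"] = list(n.children)
                d["p_value"] = n.p_value
            if n.is_leaf:
                d["log_worth"] = n.results.log_worth.tolist()
                d["worth"] = n.results.worth.tolist()
            nodes.append(d)
        return {
            "type": "pl_tree",
            "labels": list(self.items.labels),
            "nodes": nodes,
            "rules": {str(k): v for k, v in self.node_rules().items()},
            "settings": {
                "alpha": self.model.alpha,
                "minsize": self.model.minsize,
                "n_permutations": self.model.n_permutations,
                "max_depth": self.model.max_depth,
                "npseudo": self.model.npseudo,
                "ref": self.model.ref,
                "seed": self.seed,
            },
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def __repr__(self) -> str:
        return f"<PLTreeResults {len(self.nodes)} nodes depth={self.depth}>"


# -- functional wrappers ------------------------------------------------------

def fit_pl_tree(
    G: GroupedRankings,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    minsize: int | None = None,
    n_permutations: int = 99,
    max_depth: int = 3,
    npseudo: float = 0.5,
    seed: int | None = None,
    **kwargs,
) -> PLTreeResults:
    """Fit a Plackett-Luce tree (convenience wrapper over :class:`PLTree`)."""
    return PLTree(
        G, covariates, alpha=alpha, minsize=minsize,
        n_permutations=n_permutations, max_depth=max_depth, npseudo=npseudo,
        **kwargs,
    ).fit(seed=seed)


def node_labels(tree: PLTreeResults) -> list[str]:
    return tree.node_labels()


def node_rules(tree: PLTreeResults) -> dict[int, str]:
    return tree.node_rules()


def top_items(tree: PLTreeResults, n: int = 1) -> dict[int, list[str]]:
    return tree.top_items(n)


def predict_worth(tree: PLTreeResults, new_covariates: pd.DataFrame) -> pd.DataFrame:
    return tree.predict_worth(new_covariates)
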