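"""Rank-agreement statistics and cross-validation for ranking models.

Kendall's tau is computed per block over the items ranked in both inputs
(tau-a: concordant minus discordant pairs over all pairs; ties are excluded
upstream) and aggregated as a weighted mean with weight ``k_b - 1`` per
block.  The normal approximation for the Z statistic uses the effective
sample size ``N = sum(k_b - 1) + 1``:

    z = tau * sqrt( 9 N (N - 1) / (2 (2 N + 5)) )

Kendall's W (coefficient of concordance) applies to complete rankings of the
same items by m judges.  Cross-validation refits a model on each training
fold and scores the held-out blocks with the ranking induced by the
estimated worths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from .plackett_luce import PlackettLuce, PlackettLuceResults
from .rankings import RankingMatrix

__all__ = ["KendallResult", "CVResult", "kendall_tau", "kendall_w",
           "crossvalidation", "predicted_matrix"]


@dataclass
class KendallResult:
    tau: float
    n_effective: float
    z_value: float
    p_value: float

    def __iter__(self):  # allow tuple-unpacking
        return iter((self.tau, self.n_effective, self.z_value, self.p_value))


def _block_tau(r1: np.ndarray, r2: np.ndarray) -> tuple[float, int] | None:
    """tau-a and block size over items ranked in both rows, or None if < 2."""
    both = (r1 > 0) & (r2 > 0)
    k = int(both.sum())
    if k < 2:
        return None
    a = r1[both].astype(float)
    b = r2[both].astype(float)
    da = np.sign(a[:, None] - a[None, :])
    db = np.sign(b[:, None] - b[None, :])
    iu = np.triu_indices(k, 1)
    s = float(np.sum(da[iu] * db[iu]))  # C - D
    return s / (k * (k - 1) / 2.0), k


def kendall_tau(R1: RankingMatrix, R2: RankingMatrix) -> KendallResult:
    """Weighted-mean Kendall tau between two ranking matrices, with Z and p.

    Blocks are compared over the items ranked in both matrices; blocks with
    fewer than two co-ranked items contribute nothing.
    """
    if R1.ranks.shape != R2.ranks.shape or R1.items != R2.items:
        raise ValueError("ranking matrices must share shape and item set")
    taus, weights = [], []
    for b in range(R1.n_blocks):
        res = _block_tau(R1.ranks[b], R2.ranks[b])
        if res is None:
            continue
        tau_b, k = res
        taus.append(tau_b)
        weights.append(k - 1)
    if not taus:
        raise ValueError("no block has two or more co-ranked items")
    taus = np.asarray(taus)
    w = np.asarray(weights, dtype=float)
    tau = float(np.sum(w * taus) / np.sum(w))
    N = float(np.sum(w)) + 1.0
    z = tau * np.sqrt(9.0 * N * (N - 1.0) / (2.0 * (2.0 * N + 5.0)))
    p = 2.0 * stats.norm.sf(abs(z))
    p = float(min(max(p, np.nextafter(0, 1)), 1.0))
    return KendallResult(tau, float(np.sum(w)), float(z), p)


def kendall_w(rankings_by_judges: np.ndarray) -> float:
    """Kendall's coefficient of concordance W for m complete rankings.

    ``rankings_by_judges`` is an m x n matrix of ranks (each row a complete
    ranking of the same n items).  W = 12 S / (m^2 (n^3 - n)) with S the sum
    of squared deviations of the item rank sums from their mean.
    """
    M = np.asarray(rankings_by_judges, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need an m x n matrix with m >= 2 judges")
    m, n = M.shape
    for i in range(m):
        if sorted(M[i].tolist()) != list(range(1, n + 1)):
            raise ValueError(
                "incomplete or tied row; restrict to co-ranked items and re-rank first"
            )
    rank_sums = M.sum(axis=0)
    S = float(np.sum((rank_sums - m * (n + 1) / 2.0) ** 2))
    return 12.0 * S / (m**2 * (n**3 - n))


def predicted_matrix(results: PlackettLuceResults, R: RankingMatrix) -> RankingMatrix:
    """Rankings of each block's items induced by the model's estimated worths."""
    lam = results.log_worth.reindex(list(R.items.labels)).to_numpy()
    out = np.zeros_like(R.ranks)
    for b in range(R.n_blocks):
        idx = np.nonzero(R.ranks[b])[0]
        # best-first by worth; exact ties broken by item order (stable sort)
        order = idx[np.argsort(-lam[idx], kind="stable")]
        out[b, order] = np.arange(1, idx.size + 1)
    return RankingMatrix(out, R.items, R.block_ids, validate=False)


@dataclass
class CVResult:
    k: int
    fold_assignment: np.ndarray
    values: list = field(default_factory=list)
    mean: float = float("nan")
    sd: float = float("nan")

    def summary(self) -> str:
        lines = [f"{len(self.values)}-fold cross-validation"]
        for f, v in enumerate(self.values):
            lines.append(f"  fold {f}: {v:.4f}")
        lines.append(f"  mean {self.mean:.4f}  sd {self.sd:.4f}")
        return "\n".join(lines)


def _default_fitter(Rtrain: RankingMatrix) -> PlackettLuceResults:
    return PlackettLuce(Rtrain, npseudo=0.5).fit()


def _ktau_metric(results: PlackettLuceResults, Rtest: RankingMatrix) -> float:
    return kendall_tau(Rtest, predicted_matrix(results, Rtest)).tau


def crossvalidation(
    R: RankingMatrix,
    k: int = 10,
    folds: np.ndarray | None = None,
    fitter: Callable[[RankingMatrix], PlackettLuceResults] | None = None,
    metric: str | Callable = "ktau",
    seed: int | None = None,
) -> CVResult:
    """k-fold cross-validation of a ranking model.

    Folds are assigned uniformly at random (seeded) unless an explicit
    ``folds`` vector is given — one label per block, honoured verbatim, which
    supports blocked cross-validation by season or location.  The default
    metric is the weighted-mean Kendall tau between held-out rankings and
    the worth-induced predicted rankings.
    """
    if fitter is None:
        fitter = _default_fitter
    if metric == "ktau":
        metric_fn = _ktau_metric
    elif callable(metric):
        metric_fn = metric
    else:
        raise ValueError(f"unknown metric {metric!r}")
    n = R.n_blocks
    if folds is not None:
        folds = np.asarray(folds)
        if folds.shape[0] != n:
            raise ValueError(
                f"fold vector has length {folds.shape[0]} but there are {n} blocks"
            )
        _, assignment = np.unique(folds, return_inverse=True)
    else:
        if k < 2:
            raise ValueError("k must be >= 2")
        if k > n:
            raise ValueError("more folds than blocks")
        rng = np.random.default_rng(seed)
        assignment = np.sort(np.arange(n) % k)
        rng.shuffle(assignment)
    labels = np.unique(assignment)
    values = []
    for f in labels:
        test = np.nonzero(assignment == f)[0]
        train = np.nonzero(assignment != f)[0]
        Rtr, Rte = R.subset(train), R.subset(test)
        missing = ~(Rtr.ranks > 0).any(axis=0)
        if missing.any():
            labs = [R.items.labels[i] for i in np.nonzero(missing)[0]]
            warnings.warn(
                f"fold {f}: items {labs} absent from training data; their worths "
                "rest on the pseudo-ranking regularisation only",
                UserWarning, stacklevel=2,
            )
        res = fitter(Rtr)
        values.append(float(metric_fn(res, Rte)))
    values_arr = np.asarray(values)
    return CVResult(
        k=len(labels),
        fold_assignment=assignment,
        values=values,
        mean=float(values_arr.mean()),
        sd=float(values_arr.std(ddof=1)) if len(values) > 1 else 0.0,
    )
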