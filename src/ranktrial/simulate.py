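"""Synthetic tricot-trial generator with known ground truth.

Emulates a decentralized on-farm trial: N items (default 10, the size of the
bean-variety case this package is modelled on), incomplete blocks of three
items allocated near-balanced to participants, and best/worst answers drawn
from a Plackett-Luce model with known log-worths.  Optionally the worths
switch between two regimes at a threshold of a rainfall-like covariate,
which is what the tree estimators are asked to recover, and extra pure-noise
covariates are carried along for type-I-error checks.

Defaults: 10 items, 500 blocks, true log-worths evenly spread over [0, 2],
rainfall drawn uniform on [100, 300] mm with the regime threshold at 200 mm
(away from the edges so minimum-child-size constraints are satisfiable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rankings import ItemSet, RankingMatrix, TricotRecord, group, rank_tricot

__all__ = ["TwoRegimeWorths", "SyntheticTrial", "sample_pl_ranking",
           "generate_tricot_trial", "generate_multi_trait"]

_POS = ("A", "B", "C")


@dataclass(frozen=True)
class TwoRegimeWorths:
    """Covariate-dependent truth: worths are ``low`` when x <= threshold else ``high``."""

    low: tuple
    high: tuple
    covariate: str = "rainfall"
    threshold: float = 200.0
    range: tuple[float, float] = (100.0, 300.0)

    def __post_init__(self):
        if len(self.low) != len(self.high):
            raise ValueError("low and high regimes must have the same length")
        lo, hi = self.range
        if not lo < self.threshold < hi:
            raise ValueError("threshold must lie strictly inside the covariate range")


@dataclass
class SyntheticTrial:
    """Generated tricot blocks with covariates and the true worths behind them."""

    items: ItemSet
    records: list[TricotRecord]
    covariates: pd.DataFrame          # one row per block
    true_log_worth: np.ndarray        # static truth, or low regime if two-regime
    regime: TwoRegimeWorths | None
    seed: int | None
    design: dict = field(default_factory=dict)

    @property
    def n_blocks(self) -> int:
        return len(self.records)

    def rankings(self) -> RankingMatrix:
        return rank_tricot(self.records, self.items)

    def grouped(self):
        """One group per block, aligned with the covariate table rows."""
        return group(self.rankings(), np.arange(self.n_blocks))

    def block_log_worth(self, b: int) -> np.ndarray:
        """True log-worths in force for block ``b``."""
        if self.regime is None:
            return self.true_log_worth
        x = self.covariates.iloc[b][self.regime.covariate]
        return np.asarray(
            self.regime.low if x <= self.regime.threshold else self.regime.high,
            dtype=float,
        )

    def appearance_counts(self) -> pd.Series:
        counts = pd.Series(0, index=list(self.items.labels))
        for rec in self.records:
            for lab in rec.items:
                counts[lab] += 1
        return counts


def sample_pl_ranking(log_worths: np.ndarray, subset: list[int],
                      rng: np.random.Generator) -> list[int]:
    """Sample an ordering of ``subset`` (best first) from a Plackett-Luce model.

    Sequential sampling without replacement: each stage picks item j from the
    remaining set with probability exp(lambda_j) / sum_remaining exp(lambda).
    """
    if len(subset) < 2:
        raise ValueError("need at least 2 items to rank")
    lam = np.asarray(log_worths, dtype=float)
    remaining = list(subset)
    out: list[int] = []
    while remaining:
        w = np.exp(lam[remaining] - np.max(lam[remaining]))
        pick = rng.choice(len(remaining), p=w / w.sum())
        out.append(remaining.pop(pick))
    return out


def _allocate_blocks(n_items: int, n_blocks: int, rng: np.random.Generator,
                     block_size: int = 3) -> np.ndarray:
    """Near-balanced incomplete blocks: shuffled item repetition then chunking.

    The multiset of assignments gives per-item counts differing by at most 1;
    duplicate items within a block are repaired by swapping with a later
    position holding a compatible item, which preserves the multiset.
    """
    total = n_blocks * block_size
    pool = np.tile(np.arange(n_items), int(np.ceil(total / n_items)))[:total]
    rng.shuffle(pool)
    pool = pool.reshape(n_blocks, block_size)
    for b in range(n_blocks):
        guard = 0
        while len(set(pool[b])) < block_size:
            guard += 1
            if guard > 1000:  # pragma: no cover - pathological n_items < 3
                raise RuntimeError("could not form distinct blocks")
            dup_pos = next(
                i for i in range(block_size) if list(pool[b]).count(pool[b, i]) > 1
            )
            ob, op = rng.integers(n_blocks), rng.integers(block_size)
            if ob == b:
                continue
            cand = pool[ob, op]
            if cand not in pool[b] and pool[b, dup_pos] not in np.delete(pool[ob], op):
                pool[ob, op], pool[b, dup_pos] = pool[b, dup_pos], cand
    return pool


def generate_tricot_trial(
    n_items: int = 10,
    n_blocks: int = 500,
    true_log_worth: np.ndarray | TwoRegimeWorths | None = None,
    noise_covariates: tuple[str, ...] = ("noise",),
    labels: list[str] | None = None,
    seed: int | None = None,
) -> SyntheticTrial:
    """Generate a reproducible synthetic tricot trial.

    Parameters
    ----------
    true_log_worth : array or TwoRegimeWorths, optional
        Static truth (default: evenly spread over [0, 2]) or a two-regime
        specification driven by a rainfall-like uniform covariate.
    noise_covariates : names of additional uniform(0, 100) columns carrying
        no signal (for selection/tree type-I checks).
    """
    if n_items < 3:
        raise ValueError("tricot blocks need at least 3 items")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"item{i + 1:02d}" for i in range(n_items)]
    items = ItemSet(labels)
    regime: TwoRegimeWorths | None = None
    if true_log_worth is None:
        static = np.linspace(0.0, 2.0, n_items)
    elif isinstance(true_log_worth, TwoRegimeWorths):
        regime = true_log_worth
        if len(regime.low) != n_items:
            raise ValueError(
                f"regime worths have length {len(regime.low)}, expected {n_items}"
            )
        static = np.asarray(regime.low, dtype=float)
    else:
        static = np.asarray(true_log_worth, dtype=float)
        if static.shape != (n_items,):
            raise ValueError(
                f"true_log_worth has shape {static.shape}, expected ({n_items},)"
            )

    blocks = _allocate_blocks(n_items, n_blocks, rng)
    cov = {}
    if regime is not None:
        lo, hi = regime.range
        cov[regime.covariate] = rng.uniform(lo, hi, size=n_blocks)
    for name in noise_covariates:
        cov[name] = rng.uniform(0.0, 100.0, size=n_blocks)
    covariates = pd.DataFrame(cov, index=pd.RangeIndex(n_blocks, name="block"))

    records: list[TricotRecord] = []
    high = None if regime is None else np.asarray(regime.high, dtype=float)
    for b in range(n_blocks):
        if regime is None:
            lam = static
        else:
            x = covariates.iloc[b][regime.covariate]
            lam = static if x <= regime.threshold else high
        triple = blocks[b].tolist()
        order = sample_pl_ranking(lam, triple, rng)
        best = _POS[triple.index(order[0])]
        worst = _POS[triple.index(order[-1])]
        records.append(
            TricotRecord(b, tuple(items.labels[i] for i in triple), best, worst)
        )
    return SyntheticTrial(
        items=items,
        records=records,
        covariates=covariates,
        true_log_worth=static,
        regime=regime,
        seed=seed,
        design={"n_items": n_items, "n_blocks": n_blocks, "block_size": 3,
                "noise_covariates": list(noise_covariates)},
    )


def generate_multi_trait(
    trial: SyntheticTrial,
    rho: dict[str, float],
    seed: int | None = None,
) -> dict[str, RankingMatrix]:
    """Per-trait rankings on the same blocks, correlated with the overall truth.

    Each trait t gets log-worths ``rho_t * lambda + (1 - rho_t) * eps`` where
    ``eps`` is independent noise standardized to the spread of ``lambda``, so
    the Kendall tau between a trait's rankings and the overall rankings
    increases with ``rho_t`` (identical in distribution at rho = 1, unrelated
    at rho = 0).  Only static-truth trials are supported.
    """
    if trial.regime is not None:
        raise ValueError("multi-trait generation requires a static-truth trial")
    rng = np.random.default_rng(seed)
    lam = trial.true_log_worth
    scale = float(np.std(lam)) or 1.0
    out: dict[str, RankingMatrix] = {}
    n = len(trial.items)
    for trait, r in rho.items():
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"rho for {trait!r} must be in [0, 1], got {r}")
        eps = rng.standard_normal(n)
        eps = (eps - eps.mean()) / (np.std(eps) or 1.0) * scale
        lam_t = r * lam + (1.0 - r) * eps
        R = np.zeros((trial.n_blocks, n), dtype=np.int64)
        for b, rec in enumerate(trial.records):
            triple = [trial.items.position(x) for x in rec.items]
            order = sample_pl_ranking(lam_t, triple, rng)
            for rank0, idx in enumerate(order):
                R[b, idx] = rank0 + 1
        out[trait] = RankingMatrix(R, trial.items, [rec.block_id for rec in trial.records])
    return out
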