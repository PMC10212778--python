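"""Partial rankings from triadic (tricot) and numeric trial observations.

A tricot trial asks each participant to grow/assess a small incomplete block
(here three items out of the full set) and name the *best* and the *worst*
item.  That answer pins down a full ordering of the block, which we store as
an integer rank matrix: rows are blocks, columns are items, ``1`` marks the
highest-ranked item and ``0`` marks an item the block did not evaluate.

This module holds the containers (:class:`ItemSet`, :class:`TricotRecord`,
:class:`RankingMatrix`, :class:`GroupedRankings`, :class:`PairwiseCounts`)
and the converters (:func:`rank_tricot`, :func:`rank_numeric`,
:func:`to_binomial_frequencies`, :func:`to_paircomp`, :func:`group`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ItemSet",
    "TricotRecord",
    "RankingMatrix",
    "GroupedRankings",
    "PairwiseCounts",
    "rank_tricot",
    "rank_numeric",
    "to_binomial_frequencies",
    "to_paircomp",
    "group",
]

_POSITIONS = ("A", "B", "C")


class ItemSet:
    """Ordered set of unique item labels with a label -> position map.

    Positions are 0-based internally; all reported output uses labels.
    """

    def __init__(self, labels: Iterable[str]):
        labels = tuple(str(x) for x in labels)
        if not labels:
            raise ValueError("ItemSet requires at least one label")
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate item labels: {dup}")
        self.labels = labels
        self.index = {lab: i for i, lab in enumerate(labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __contains__(self, label) -> bool:
        return label in self.index

    def __eq__(self, other) -> bool:
        return isinstance(other, ItemSet) and self.labels == other.labels

    def __repr__(self) -> str:
        return f"ItemSet({list(self.labels)!r})"

    def position(self, label: str) -> int:
        try:
            return self.index[label]
        except KeyError:
            raise KeyError(f"unknown item label {label!r}") from None


@dataclass(frozen=True)
class TricotRecord:
    """One incomplete block: three items and the best/worst answers.

    ``best`` and ``worst`` are the position letters "A"/"B"/"C" referring to
    ``items``, matching how tricot exports encode the answers.  ``None`` for
    either answer marks a missing response (the record is dropped on
    conversion, with a warning).
    """

    block_id: object
    items: tuple[str, str, str]
    best: str | None
    worst: str | None

    def __post_init__(self):
        if len(set(self.items)) != 3:
            raise ValueError(
                f"block {self.block_id!r}: the three items must be distinct, got {self.items}"
            )
        for ans, name in ((self.best, "best"), (self.worst, "worst")):
            if ans is not None and ans not in _POSITIONS:
                raise ValueError(
                    f"block {self.block_id!r}: {name} must be one of A/B/C, got {ans!r}"
                )


class RankingMatrix:
    """Dense integer matrix of partial rankings.

    ``ranks[b, i]`` is the rank of item ``i`` in block ``b`` (1 = best);
    0 means the item was not evaluated in that block.  Per row the nonzero
    entries are exactly ``1..k_b`` with ``k_b >= 2`` (no ties).
    """

    def __init__(
        self,
        ranks: np.ndarray,
        items: ItemSet,
        block_ids: Sequence | None = None,
        validate: bool = True,
    ):
        ranks = np.asarray(ranks, dtype=np.int64)
        if ranks.ndim != 2:
            raise ValueError("ranks must be a 2-d array")
        if ranks.shape[1] != len(items):
            raise ValueError(
                f"ranks has {ranks.shape[1]} columns but item set has {len(items)} items"
            )
        if block_ids is None:
            block_ids = list(range(ranks.shape[0]))
        elif len(block_ids) != ranks.shape[0]:
            raise ValueError("block_ids length must equal the number of rows")
        self.ranks = ranks
        self.items = items
        self.block_ids = list(block_ids)
        if validate:
            self._validate()

    def _validate(self) -> None:
        R = self.ranks
        if np.any(R < 0):
            raise ValueError("ranks must be non-negative")
        for b in range(R.shape[0]):
            nz = R[b][R[b] > 0]
            k = nz.size
            if k < 2:
                raise ValueError(
                    f"block {self.block_ids[b]!r}: needs at least 2 ranked items"
                )
            if sorted(nz.tolist()) != list(range(1, k + 1)):
                raise ValueError(
                    f"block {self.block_ids[b]!r}: nonzero ranks must be a "
                    f"permutation of 1..{k}, got {sorted(nz.tolist())}"
                )

    @property
    def n_blocks(self) -> int:
        return self.ranks.shape[0]

    @property
    def n_items(self) -> int:
        return self.ranks.shape[1]

    def block_sizes(self) -> np.ndarray:
        return (self.ranks > 0).sum(axis=1)

    def subset(self, rows) -> "RankingMatrix":
        rows = np.asarray(rows)
        return RankingMatrix(
            self.ranks[rows],
            self.items,
            [self.block_ids[i] for i in np.atleast_1d(rows)],
            validate=False,
        )

    def ordered_items(self, b: int) -> list[str]:
        """Item labels of block ``b`` from rank 1 downwards."""
        row = self.ranks[b]
        idx = np.nonzero(row)[0]
        return [self.items.labels[i] for i in idx[np.argsort(row[idx])]]

    def reversed(self) -> "RankingMatrix":
        """Every block's order flipped (rank 1 <-> rank k)."""
        R = self.ranks
        k = self.block_sizes()[:, None]
        out = np.where(R > 0, k + 1 - R, 0)
        return RankingMatrix(out, self.items, self.block_ids, validate=False)

    def to_frame(self) -> pd.DataFrame:
        """Wide block x item rank table (0 = not evaluated)."""
        return pd.DataFrame(
            self.ranks, index=pd.Index(self.block_ids, name="block"),
            columns=list(self.items.labels),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RankingMatrix":
        items = ItemSet(frame.columns)
        return cls(frame.to_numpy(dtype=np.int64), items, list(frame.index))

    def __repr__(self) -> str:
        return f"<RankingMatrix {self.n_blocks} blocks x {self.n_items} items>"


@dataclass
class GroupedRankings:
    """Rankings with a row -> group map, aligned with a covariate table.

    Group ids are re-coded to contiguous ``0..G-1`` (order of sorted original
    ids); ``group_ids[g]`` reports the original id of group ``g`` so covariate
    rows can be aligned by the caller.
    """

    rankings: RankingMatrix
    group_of_row: np.ndarray
    group_ids: list = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return len(self.group_ids)

    def rows_of_groups(self, groups) -> np.ndarray:
        mask = np.isin(self.group_of_row, np.asarray(groups))
        return np.nonzero(mask)[0]


@dataclass
class PairwiseCounts:
    """Win tallies per ordered item pair: ``wins[i, j]`` = blocks ranking i above j."""

    items: ItemSet
    wins: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long binomial-frequency table: one row per unordered pair."""
        rows = []
        labs = self.items.labels
        n = len(labs)
        for i in range(n):
            for j in range(i + 1, n):
                w1, w2 = int(self.wins[i, j]), int(self.wins[j, i])
                if w1 + w2 > 0:
                    rows.append((labs[i], labs[j], w1, w2))
        return pd.DataFrame(rows, columns=["item1", "item2", "win1", "win2"])


def rank_tricot(
    records: Sequence[TricotRecord], items: ItemSet | None = None
) -> RankingMatrix:
    """Convert tricot best/worst answers to a ranking matrix.

    Each record yields one row: the best item gets rank 1, the worst rank 3
    and the remaining item rank 2.  Records with a missing best or worst
    answer are dropped with a warning reporting the count; ``best == worst``
    or an item outside ``items`` is an error.
    """
    if items is None:
        labels = sorted({lab for r in records for lab in r.items})
        items = ItemSet(labels)
    kept, dropped = [], []
    for rec in records:
        if rec.best is None or rec.worst is None:
            dropped.append(rec.block_id)
            continue
        if rec.best == rec.worst:
            raise ValueError(f"block {rec.block_id!r}: best equals worst ({rec.best})")
        for lab in rec.items:
            if lab not in items:
                raise KeyError(
                    f"block {rec.block_id!r}: unknown item label {lab!r}"
                )
        kept.append(rec)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} record(s) with missing best/worst answers: "
            f"{dropped[:10]}{'...' if len(dropped) > 10 else ''}",
            UserWarning,
            stacklevel=2,
        )
    R = np.zeros((len(kept), len(items)), dtype=np.int64)
    ids = []
    for b, rec in enumerate(kept):
        pos = {"A": 0, "B": 1, "C": 2}
        middle = ({"A", "B", "C"} - {rec.best, rec.worst}).pop()
        R[b, items.position(rec.items[pos[rec.best]])] = 1
        R[b, items.position(rec.items[pos[middle]])] = 2
        R[b, items.position(rec.items[pos[rec.worst]])] = 3
        ids.append(rec.block_id)
    return RankingMatrix(R, items, ids)


def rank_numeric(
    observations,
    ascending: bool = False,
    items: ItemSet | None = None,
    tie_break: str | None = None,
    seed: int | None = None,
) -> RankingMatrix:
    """Convert long-format numeric observations to rankings.

    Parameters
    ----------
    observations : DataFrame or iterable of (block, item, value)
        One measured value per (block, item); a DataFrame must have columns
        ``block``, ``item``, ``value``.
    ascending : bool
        ``False`` (default): the largest value is ranked 1 — natural for
        yield-like measurements.  ``True``: the smallest value is ranked 1 —
        for inputs that are already ordinal ranks.
    tie_break : {None, "random"}
        Ties within a block are an error by default; ``"random"`` breaks them
        with the given ``seed``.
    """
    if isinstance(observations, pd.DataFrame):
        df = observations[["block", "item", "value"]].copy()
    else:
        df = pd.DataFrame(list(observations), columns=["block", "item", "value"])
    df["item"] = df["item"].astype(str)
    if df.duplicated(["block", "item"]).any():
        bad = df[df.duplicated(["block", "item"])].iloc[0]
        raise ValueError(f"duplicate (block, item) observation: {bad['block']!r}, {bad['item']!r}")
    if items is None:
        items = ItemSet(sorted(df["item"].unique()))
    rng = np.random.default_rng(seed)
    blocks = list(dict.fromkeys(df["block"]))  # preserve input order
    R = np.zeros((len(blocks), len(items)), dtype=np.int64)
    for b, blk in enumerate(blocks):
        sub = df[df["block"] == blk]
        if len(sub) < 2:
            raise ValueError(f"block {blk!r}: needs at least 2 items, got {len(sub)}")
        vals = sub["value"].to_numpy(dtype=float)
        if np.unique(vals).size != vals.size:
            if tie_break == "random":
                vals = vals + rng.uniform(-0.5, 0.5, size=vals.size) * 1e-9 * (
                    1.0 + np.abs(vals)
                )
                if np.unique(vals).size != vals.size:  # pragma: no cover
                    vals = vals + rng.normal(0, 1e-9, size=vals.size)
            else:
                raise ValueError(
                    f"ties in block {blk!r}; pass tie_break='random' with a seed to break them"
                )
        order = np.argsort(vals if ascending else -vals, kind="stable")
        for rank0, pos in enumerate(order):
            R[b, items.position(sub["item"].iloc[pos])] = rank0 + 1
    return RankingMatrix(R, items, blocks)


def to_binomial_frequencies(R: RankingMatrix) -> PairwiseCounts:
    """Aggregate rankings into pairwise win counts (binomial frequencies).

    Each ranked block of size k contributes k(k-1)/2 pairwise outcomes.
    """
    A = R.ranks
    n = R.n_items
    wins = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            both = (A[:, i] > 0) & (A[:, j] > 0)
            wins[i, j] = int(np.sum(both & (A[:, i] < A[:, j])))
    return PairwiseCounts(R.items, wins)


def to_paircomp(R: RankingMatrix) -> list[tuple[object, str, str]]:
    """Per-block ordered pair outcomes ``(block_id, winner, loser)``.

    Block identity is preserved (one record per pair per block) so pairwise
    models can be linked to block-level covariates.
    """
    out: list[tuple[object, str, str]] = []
    labs = R.items.labels
    for b in range(R.n_blocks):
        row = R.ranks[b]
        idx = np.nonzero(row)[0]
        order = idx[np.argsort(row[idx])]
        for a in range(order.size):
            for c in range(a + 1, order.size):
                out.append((R.block_ids[b], labs[order[a]], labs[order[c]]))
    return out


def group(R: RankingMatrix, index: Sequence) -> GroupedRankings:
    """Attach a group id to every ranking row (for covariate-linked models).

    ``index`` has one entry per block; ids are re-coded to contiguous
    ``0..G-1`` (sorted original ids) with the mapping kept in ``group_ids``.
    """
    index = np.asarray(index)
    if index.shape[0] != R.n_blocks:
        raise ValueError(
            f"group index has length {index.shape[0]} but there are {R.n_blocks} blocks"
        )
    uniq, coded = np.unique(index, return_inverse=True)
    return GroupedRankings(R, coded.astype(np.int64), list(uniq))
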