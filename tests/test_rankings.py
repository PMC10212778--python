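"""Converters from tricot and numeric observations to partial rankings."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ranktrial import (
    ItemSet,
    RankingMatrix,
    TricotRecord,
    group,
    rank_numeric,
    rank_tricot,
    to_binomial_frequencies,
    to_paircomp,
)
from conftest import random_partial_rankings


class TestRankTricot:
    @pytest.mark.parametrize(
        "best,worst,expected",
        [
            ("A", "C", [1, 2, 3]),
            ("B", "A", [3, 1, 2]),
            ("C", "B", [2, 3, 1]),
        ],
    )
    def test_best_worst_fix_the_row(self, best, worst, expected):
        rec = TricotRecord(0, ("v1", "v2", "v3"), best, worst)
        R = rank_tricot([rec], ItemSet(["v1", "v2", "v3"]))
        assert R.ranks[0].tolist() == expected

    def test_best_equals_worst_rejected(self):
        rec = TricotRecord(9, ("v1", "v2", "v3"), "A", "A")
        with pytest.raises(ValueError, match="best equals worst"):
            rank_tricot([rec])

    def test_unknown_label_names_label_and_block(self):
        rec = TricotRecord(5, ("v1", "v2", "vX"), "A", "B")
        with pytest.raises(KeyError, match=r"5.*'vX'"):
            rank_tricot([rec], ItemSet(["v1", "v2", "v3"]))

    def test_missing_answers_dropped_with_warning(self):
        recs = [
            TricotRecord(0, ("a", "b", "c"), "A", "C"),
            TricotRecord(1, ("a", "b", "c"), None, "C"),
            TricotRecord(2, ("a", "b", "c"), "B", None),
        ]
        with pytest.warns(UserWarning, match="dropped 2"):
            R = rank_tricot(recs)
        assert R.n_blocks == 1

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(
        st.tuples(st.permutations(["v1", "v2", "v3", "v4", "v5"]),
                  st.sampled_from("ABC"), st.sampled_from("ABC")),
        min_size=1, max_size=20,
    ))
    def test_round_trip_recovers_best_and_worst(self, raw):
        records = [
            TricotRecord(i, tuple(perm[:3]), b, w)
            for i, (perm, b, w) in enumerate(raw) if b != w
        ]
        if not records:
            return
        R = rank_tricot(records, ItemSet(["v1", "v2", "v3", "v4", "v5"]))
        pos = {"A": 0, "B": 1, "C": 2}
        for row, rec in zip(R.ranks, records):
            best_item = R.items.labels[int(np.where(row == 1)[0][0])]
            worst_item = R.items.labels[int(np.where(row == 3)[0][0])]
            assert best_item == rec.items[pos[rec.best]]
            assert worst_item == rec.items[pos[rec.worst]]


class TestRankNumeric:
    def test_descending_default(self):
        obs = [(1, "v1", 5.0), (1, "v2", 2.0), (1, "v3", 9.0)]
        R = rank_numeric(obs)
        assert R.to_frame().loc[1].to_dict() == {"v1": 2, "v2": 3, "v3": 1}

    def test_ascending_for_ordinal_inputs(self):
        obs = [(1, "v1", 5.0), (1, "v2", 2.0), (1, "v3", 9.0)]
        R = rank_numeric(obs, ascending=True)
        assert R.to_frame().loc[1].to_dict() == {"v1": 2, "v2": 1, "v3": 3}

    def test_ties_error_by_default(self):
        with pytest.raises(ValueError, match="ties in block"):
            rank_numeric([(1, "v1", 4.0), (1, "v2", 4.0)])

    def test_seeded_tie_break_is_reproducible(self):
        obs = [(1, "v1", 4.0), (1, "v2", 4.0), (1, "v3", 1.0)]
        a = rank_numeric(obs, tie_break="random", seed=3)
        b = rank_numeric(obs, tie_break="random", seed=3)
        assert np.array_equal(a.ranks, b.ranks)
        assert a.ranks[0, 2] == 3  # the clearly-lowest value stays last

    def test_duplicate_observation_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            rank_numeric([(1, "v1", 4.0), (1, "v1", 5.0), (1, "v2", 1.0)])


class TestRowInvariants:
    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_nonzero_ranks_form_permutation(self, seed):
        R = random_partial_rankings(np.random.default_rng(seed), n_blocks=15)
        for b in range(R.n_blocks):
            nz = R.ranks[b][R.ranks[b] > 0]
            assert sorted(nz.tolist()) == list(range(1, nz.size + 1))
            assert nz.size >= 2

    def test_single_item_row_rejected(self, abc_items):
        with pytest.raises(ValueError, match="at least 2"):
            RankingMatrix(np.array([[1, 0, 0]]), abc_items)

    def test_tied_row_rejected(self, abc_items):
        with pytest.raises(ValueError, match="permutation"):
            RankingMatrix(np.array([[1, 1, 2]]), abc_items)


class TestPairwiseReductions:
    def test_single_row_full_enumeration(self, abc_items):
        R = RankingMatrix(np.array([[1, 2, 3]]), abc_items)
        pc = to_binomial_frequencies(R)
        assert pc.wins[0, 1] == pc.wins[0, 2] == pc.wins[1, 2] == 1
        assert pc.wins[1, 0] == pc.wins[2, 0] == pc.wins[2, 1] == 0

    def test_opposed_rows_are_symmetric(self, abc_items):
        R = RankingMatrix(np.array([[1, 2, 3], [3, 2, 1]]), abc_items)
        pc = to_binomial_frequencies(R)
        assert np.array_equal(pc.wins, pc.wins.T)
        assert pc.wins[0, 1] == 1

    def test_counts_match_brute_force_pair_scan(self):
        rng = np.random.default_rng(11)
        R = random_partial_rankings(rng, n_blocks=100, n_items=5)
        pc = to_binomial_frequencies(R)
        n = R.n_items
        expected = np.zeros((n, n), dtype=int)
        for b in range(R.n_blocks):
            for i in range(n):
                for j in range(n):
                    ri, rj = R.ranks[b, i], R.ranks[b, j]
                    if ri > 0 and rj > 0 and ri < rj:
                        expected[i, j] += 1
        assert np.array_equal(pc.wins, expected)
        # wins + losses = co-occurrence count
        co = (R.ranks > 0).astype(int).T @ (R.ranks > 0).astype(int)
        np.fill_diagonal(co, 0)
        assert np.array_equal(pc.wins + pc.wins.T, co)

    def test_paircomp_preserves_blocks_and_aggregates_to_counts(self, abc_items):
        R = RankingMatrix(np.array([[1, 2, 3]]), abc_items, block_ids=[7])
        assert to_paircomp(R) == [(7, "A", "B"), (7, "A", "C"), (7, "B", "C")]
        rng = np.random.default_rng(5)
        R2 = random_partial_rankings(rng, n_blocks=40)
        pc = to_binomial_frequencies(R2)
        agg = np.zeros_like(pc.wins)
        for _, w, l in to_paircomp(R2):
            agg[R2.items.position(w), R2.items.position(l)] += 1
        assert np.array_equal(agg, pc.wins)

    def test_paircomp_empty_matrix(self, abc_items):
        R = RankingMatrix(np.zeros((0, 3), dtype=int), abc_items)
        assert to_paircomp(R) == []


class TestGroup:
    def test_contiguous_groups(self, simple_rankings):
        g = group(simple_rankings, [0, 0, 1, 1])
        assert g.n_groups == 2
        assert g.group_of_row.tolist() == [0, 0, 1, 1]

    def test_gap_recoded_with_mapping(self, simple_rankings):
        g = group(simple_rankings, [0, 2, 2, 5])
        assert g.n_groups == 3
        assert g.group_ids == [0, 2, 5]
        assert g.group_of_row.tolist() == [0, 1, 1, 2]

    def test_length_mismatch(self, simple_rankings):
        with pytest.raises(ValueError, match="length"):
            group(simple_rankings, [0, 1])
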