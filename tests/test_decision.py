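"""Reliability, regret, agreement and worth-table heuristics."""

import math

import numpy as np
import pandas as pd
import pytest

from ranktrial import (
    compare,
    fit_plackett_luce,
    generate_multi_trait,
    generate_tricot_trial,
    regret,
    reliability,
    reliability_by_node,
    worth_bar_data,
    worth_map_data,
)


@pytest.fixture(scope="module")
def fitted(small_trial_module=None):
    trial = generate_tricot_trial(n_items=6, n_blocks=120, seed=2024)
    return fit_plackett_luce(trial.rankings())


class TestReliability:
    def test_reference_self_reliability_is_exactly_half(self, fitted):
        tab = reliability(fitted)
        row = tab[tab["item"] == fitted.ref].iloc[0]
        assert row["reliability"] == 0.5
        assert tab["worth"].sum() == pytest.approx(1.0)

    def test_logistic_closed_form(self, fitted):
        # lambda_i - lambda_ref = log 3  =>  reliability 0.75
        lam = fitted.log_worth
        tab = reliability(fitted)
        for _, row in tab.iterrows():
            expected = 1 / (1 + math.exp(-(lam[row["item"]] - lam[fitted.ref])))
            assert row["reliability"] == pytest.approx(expected)
        assert 1 / (1 + math.exp(-math.log(3))) == pytest.approx(0.75)

    def test_sign_matches_log_worth_ordering(self, fitted):
        lam = fitted.log_worth
        tab = reliability(fitted)
        for _, row in tab.iterrows():
            if row["item"] == fitted.ref:
                continue
            assert (row["reliability"] > 0.5) == (lam[row["item"]] > lam[fitted.ref])

    def test_unknown_reference_rejected(self, fitted):
        with pytest.raises(KeyError, match="nope"):
            reliability(fitted, ref="nope")

    def test_se_positive_for_non_reference(self, fitted):
        tab = reliability(fitted)
        non_ref = tab[tab["item"] != fitted.ref]
        assert (non_ref["reliability_se"] > 0).all()


class TestReliabilityByNode:
    def test_root_only_tree_equals_pooled_fit(self):
        from ranktrial import PLTree

        trial = generate_tricot_trial(n_items=5, n_blocks=80, seed=5)
        tree = PLTree(trial.grouped(), trial.covariates, max_depth=0).fit(seed=0)
        by_node = reliability_by_node(tree)
        pooled = reliability(tree.root.results)
        assert by_node["node"].unique().tolist() == [1]
        assert np.allclose(by_node["reliability"].values,
                           pooled["reliability"].values)

    def test_per_leaf_values_match_direct_calls(self):
        from ranktrial import PLTree, TwoRegimeWorths

        low = np.linspace(0, 2, 5)
        reg = TwoRegimeWorths(tuple(low), tuple(low[::-1]))
        trial = generate_tricot_trial(n_items=5, n_blocks=200,
                                      true_log_worth=reg, seed=8)
        tree = PLTree(trial.grouped(), trial.covariates, n_permutations=49,
                      minsize=25).fit(seed=1)
        by_node = reliability_by_node(tree)
        for leaf in tree.leaves():
            sub = by_node[by_node["node"] == leaf.id]
            direct = reliability(leaf.results)
            assert np.allclose(sub["reliability"].values,
                               direct["reliability"].values)
            assert sub["worth"].sum() == pytest.approx(1.0)


class TestRegret:
    def test_hand_enumerated_two_by_two(self):
        W = pd.DataFrame({"s1": [0.6, 0.4], "s2": [0.3, 0.7]}, index=["A", "B"])
        out = regret(W)
        assert out.loc["A", "worst_regret"] == pytest.approx(0.4)
        assert out.loc["B", "worst_regret"] == pytest.approx(0.2)
        assert out.index[0] == "B"  # minimax choice first

    def test_dominant_item_has_zero_regret(self):
        W = pd.DataFrame({"s1": [0.5, 0.3, 0.2], "s2": [0.6, 0.2, 0.2]},
                         index=["A", "B", "C"])
        out = regret(W)
        assert out.loc["A", "worst_regret"] == 0.0
        assert out.index[0] == "A"

    def test_scenario_order_irrelevant(self):
        rng = np.random.default_rng(3)
        W = rng.dirichlet(np.ones(5), size=3).T
        df = pd.DataFrame(W, index=list("ABCDE"), columns=["s1", "s2", "s3"])
        a = regret(df)["worst_regret"]
        b = regret(df[["s3", "s1", "s2"]])["worst_regret"]
        assert np.allclose(a.sort_index(), b.sort_index())

    def test_minimax_matches_brute_force(self):
        rng = np.random.default_rng(7)
        W = pd.DataFrame(rng.dirichlet(np.ones(6), size=4).T,
                         index=list("ABCDEF"), columns=list("wxyz"))
        out = regret(W)
        brute = {
            item: max(W[s].max() - W.loc[item, s] for s in W.columns)
            for item in W.index
        }
        minimax_value = min(brute.values())
        assert out["worst_regret"].iloc[0] == pytest.approx(minimax_value)

    def test_single_scenario_rejected(self):
        W = pd.DataFrame({"s1": [0.6, 0.4]}, index=["A", "B"])
        with pytest.raises(ValueError, match="2 scenarios"):
            regret(W)


class TestCompare:
    def test_identical_measures_center_to_zero(self, fitted):
        agr = compare(fitted.log_worth, fitted.log_worth)
        assert np.allclose(agr.data["difference"], 0.0)
        assert agr.mean_difference == pytest.approx(0.0)

    def test_constant_shift_invariance(self, fitted):
        lam = fitted.log_worth
        agr = compare(lam, lam + 5.0)
        assert np.allclose(agr.data["difference"], 0.0, atol=1e-12)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(10)
        idx = list("ABCDE")
        a = pd.Series(rng.normal(size=5), index=idx)
        b = pd.Series(rng.normal(size=5), index=idx)
        agr = compare(a, b)
        ac, bc = a - a.mean(), b - b.mean()
        assert np.allclose(agr.data["mean"], (ac + bc) / 2)
        assert np.allclose(agr.data["difference"], ac - bc)
        sd = (ac - bc).std(ddof=1)
        assert agr.upper_limit == pytest.approx(agr.mean_difference + 1.96 * sd)
        assert agr.data["difference"].sum() == pytest.approx(0.0)

    def test_length_mismatch_rejected(self, fitted):
        with pytest.raises(ValueError, match="length"):
            compare(fitted.log_worth, fitted.log_worth.iloc[:-1])


class TestWorthTables:
    def test_worth_map_reference_column_is_zero(self):
        trial = generate_tricot_trial(n_items=5, n_blocks=60, seed=3)
        traits = generate_multi_trait(trial, {"t1": 1.0, "t2": 0.5}, seed=3)
        models = {t: fit_plackett_luce(R) for t, R in traits.items()}
        tab = worth_map_data(models)
        ref = models["t1"].ref
        assert (tab[ref] == 0.0).all()
        for t, res in models.items():
            assert np.allclose(tab.loc[t].values, res.log_worth.values)

    def test_worth_map_mismatched_items_rejected(self):
        t1 = generate_tricot_trial(n_items=5, n_blocks=60, seed=3)
        t2 = generate_tricot_trial(n_items=6, n_blocks=60, seed=3)
        with pytest.raises(ValueError, match="item set"):
            worth_map_data({
                "a": fit_plackett_luce(t1.rankings()),
                "b": fit_plackett_luce(t2.rankings()),
            })

    def test_worth_bar_sorted_and_sums_to_one(self, fitted):
        tab = worth_bar_data(fitted)
        assert tab["worth"].sum() == pytest.approx(1.0)
        assert (np.diff(tab["worth"].values) <= 1e-15).all()
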