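"""Plackett-Luce likelihood, MM estimation, covariance and fit metrics."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from ranktrial import (
    ItemSet,
    PlackettLuce,
    RankingMatrix,
    fit_plackett_luce,
    loglik_pl,
)
from conftest import random_partial_rankings


def naive_loglik(lam, R):
    """Stage-by-stage enumeration of sequential-choice probabilities."""
    total = 0.0
    for b in range(R.n_blocks):
        row = R.ranks[b]
        idx = np.nonzero(row)[0]
        order = idx[np.argsort(row[idx])]
        remaining = list(order)
        while len(remaining) > 1:
            chosen = remaining[0]
            total += lam[chosen] - math.log(sum(math.exp(lam[j]) for j in remaining))
            remaining = remaining[1:]
    return total


def two_item_matrix(wins_a, wins_b):
    ranks = np.array([[1, 2]] * wins_a + [[2, 1]] * wins_b)
    return RankingMatrix(ranks, ItemSet(["A", "B"]))


class TestLoglik:
    def test_uniform_choice_two_items(self):
        R = two_item_matrix(1, 0)
        assert loglik_pl(np.zeros(2), R) == pytest.approx(-math.log(2))

    def test_uniform_choice_three_items(self, abc_items):
        R = RankingMatrix(np.array([[1, 2, 3]]), abc_items)
        assert loglik_pl(np.zeros(3), R) == pytest.approx(-math.log(3) - math.log(2))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_naive_stagewise_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        R = random_partial_rankings(rng, n_blocks=12, n_items=5, k=3)
        lam = rng.normal(0, 1.5, size=5)
        assert loglik_pl(lam, R) == pytest.approx(naive_loglik(lam, R), abs=1e-10)


class TestFit:
    def test_two_item_closed_form(self):
        res = fit_plackett_luce(two_item_matrix(3, 1), npseudo=0)
        ratio = math.exp(res.log_worth["A"] - res.log_worth["B"])
        assert ratio == pytest.approx(3.0, abs=1e-8)

    def test_separation_detected_and_regularized(self):
        R = two_item_matrix(5, 0)
        with pytest.raises(ValueError, match="disconnected"):
            fit_plackett_luce(R, npseudo=0)
        res = fit_plackett_luce(R, npseudo=0.5)
        assert np.isfinite(res.log_worth).all()
        assert res.log_worth["A"] > res.log_worth["B"]

    def test_item_never_ranked_raises_without_regularization(self, abc_items):
        R = RankingMatrix(np.array([[1, 2, 0]]), abc_items)
        with pytest.raises(ValueError, match=r"never ranked.*\['C'\]"):
            fit_plackett_luce(R, npseudo=0)

    def test_non_convergence_warns_and_flags(self):
        rng = np.random.default_rng(0)
        R = random_partial_rankings(rng, n_blocks=60, n_items=5)
        with pytest.warns(UserWarning, match="did not converge"):
            res = PlackettLuce(R, npseudo=0).fit(maxit=2)
        assert not res.converged

    def test_mm_matches_scipy_optimizer(self):
        rng = np.random.default_rng(77)
        R = random_partial_rankings(rng, n_blocks=50, n_items=4)
        res = fit_plackett_luce(R, npseudo=0)

        def nll(free):
            return -loglik_pl(np.concatenate([[0.0], free]), R)

        opt = minimize(nll, np.zeros(3), method="BFGS", options={"gtol": 1e-10})
        assert np.max(np.abs(res.log_worth.values[1:] - opt.x)) < 1e-4

    def test_mm_never_decreases_likelihood(self):
        rng = np.random.default_rng(8)
        R = random_partial_rankings(rng, n_blocks=40, n_items=5)
        PlackettLuce(R, npseudo=0).fit(check_monotone=True)  # asserts internally

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(21)
        R = random_partial_rankings(rng, n_blocks=50, n_items=5)
        res = fit_plackett_luce(R, npseudo=0)
        perm = rng.permutation(5)
        items_p = ItemSet([R.items.labels[i] for i in perm])
        Rp = RankingMatrix(R.ranks[:, perm], items_p)
        res_p = fit_plackett_luce(Rp, ref=res.ref, npseudo=0)
        for lab in R.items.labels:
            assert res_p.log_worth[lab] == pytest.approx(res.log_worth[lab], abs=1e-7)

    def test_reference_is_exactly_zero_and_selectable(self, small_trial):
        R = small_trial.rankings()
        res = fit_plackett_luce(R, ref="item03")
        assert res.log_worth["item03"] == 0.0
        assert res.worth.sum() == pytest.approx(1.0)

    def test_loglik_at_least_null_when_converged(self):
        rng = np.random.default_rng(4)
        R = random_partial_rankings(rng, n_blocks=60, n_items=5)
        res = fit_plackett_luce(R, npseudo=0)
        assert res.llf >= res.llnull


class TestVcov:
    def test_two_item_bernoulli_information(self):
        # wins 3-1: var(lambda_B) = 1 / (n p (1-p)) with p = 3/4, n = 4
        res = fit_plackett_luce(two_item_matrix(3, 1), npseudo=0)
        assert res.vcov.loc["B", "B"] == pytest.approx(4.0 / 3.0, abs=1e-6)

    def test_duplicating_data_halves_vcov(self):
        rng = np.random.default_rng(13)
        R = random_partial_rankings(rng, n_blocks=40, n_items=4)
        res1 = fit_plackett_luce(R, npseudo=0)
        R2 = RankingMatrix(np.vstack([R.ranks, R.ranks]), R.items)
        res2 = fit_plackett_luce(R2, npseudo=0)
        assert np.allclose(res1.log_worth, res2.log_worth, atol=1e-7)
        assert np.allclose(res2.vcov.values, res1.vcov.values / 2.0, atol=1e-6)

    def test_diagonal_nonnegative(self, small_trial):
        res = fit_plackett_luce(small_trial.rankings())
        assert (np.diag(res.vcov.values) >= 0).all()


class TestMetrics:
    def test_aic_arithmetic(self):
        res = fit_plackett_luce(two_item_matrix(3, 1), npseudo=0)
        assert res.aic == pytest.approx(-2 * res.llf + 2 * 1)
        assert res.null_aic == pytest.approx(-2 * res.llnull)

    def test_pseudo_r2_zero_at_null(self, abc_items):
        # perfectly balanced data: the MLE is the null model
        ranks = np.array([[1, 2, 3], [2, 3, 1], [3, 1, 2],
                          [3, 2, 1], [2, 1, 3], [1, 3, 2]])
        res = fit_plackett_luce(RankingMatrix(ranks, abc_items), npseudo=0)
        assert res.pseudo_r2()["mcfadden"] == pytest.approx(0.0, abs=1e-8)

    def test_pseudo_r2_increases_with_signal(self):
        from ranktrial import generate_tricot_trial

        strong = generate_tricot_trial(n_items=5, n_blocks=80,
                                       true_log_worth=np.linspace(0, 3, 5), seed=1)
        flat = generate_tricot_trial(n_items=5, n_blocks=80,
                                     true_log_worth=np.zeros(5), seed=1)
        r2_strong = fit_plackett_luce(strong.rankings()).pseudo_r2()["mcfadden"]
        r2_flat = fit_plackett_luce(flat.rankings()).pseudo_r2()["mcfadden"]
        assert r2_strong > r2_flat


class TestSerialization:
    def test_json_round_trip_is_exact(self, small_trial):
        res = fit_plackett_luce(small_trial.rankings())
        d = res.to_dict()
        assert json.loads(res.to_json()) == json.loads(json.dumps(d))
        assert d["log_worth"] == res.log_worth.tolist()
        assert d["settings"]["ref"] == res.ref

    def test_worth_table_and_summary(self, small_trial):
        res = fit_plackett_luce(small_trial.rankings())
        tab = res.worth_table()
        assert tab["worth"].sum() == pytest.approx(1.0)
        assert "Plackett-Luce" in res.summary()
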