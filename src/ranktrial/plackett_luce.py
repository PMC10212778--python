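"""Maximum-likelihood Plackett-Luce estimation for partial rankings.

The Plackett-Luce model assigns each item i a worth gamma_i > 0 and gives a
ranking of a block the probability of its sequential choices: at each stage
the next-ranked item is drawn from the items not yet placed, with probability
proportional to its worth.  Writing lambda = log(gamma), the log-likelihood is

    l(lambda) = sum_blocks sum_{s=1..k_b-1} [ lambda_{c(b,s)}
                - log sum_{j in A(b,s)} exp(lambda_j) ]

where c(b,s) is the item ranked s in block b and A(b,s) the items ranked s or
lower.  Identifiability is resolved by fixing lambda_ref = 0 for a reference
item.  Estimation uses Hunter's minorise-maximise (MM) update

    gamma_i <- W_i / sum_{(b,s): i in A(b,s)} ( sum_{j in A(b,s)} gamma_j )^-1

with W_i the number of stages in which i is the chosen item; each iteration
cannot decrease the likelihood.

When the win graph is disconnected (some item always wins or always loses
against the rest) the MLE is not finite.  A small regularisation, weight
``npseudo`` pseudo-rankings in which a hypothetical item beats and is beaten
by every real item once, keeps all estimates finite; the hypothetical item is
discarded from the output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .rankings import ItemSet, RankingMatrix

__all__ = [
    "PlackettLuce",
    "PlackettLuceResults",
    "fit_plackett_luce",
    "loglik_pl",
    "aic",
    "pseudo_r2",
    "vcov_pl",
]


@dataclass
class _Stages:
    """Flattened sequential-choice structure of a set of (weighted) rankings.

    Stage memberships are stored contiguously by stage so that per-stage
    reductions are single ``reduceat`` calls.
    """

    n_items: int
    n_stages: int
    set_item: np.ndarray   # item index of each (stage, member) pair
    set_stage: np.ndarray  # global stage index of each pair (sorted)
    ptr: np.ndarray        # stage start offsets into set_item
    chosen: np.ndarray     # chosen item per stage
    stage_w: np.ndarray    # weight per stage (from row weights)
    win_w: np.ndarray      # per-item total weight of stages it wins

    @classmethod
    def compile(cls, ranks: np.ndarray, weights: np.ndarray | None = None) -> "_Stages":
        n_blocks, n_items = ranks.shape
        if weights is None:
            weights = np.ones(n_blocks)
        rows, cols = np.nonzero(ranks)
        r = ranks[rows, cols] - 1  # 0-based rank
        k = (ranks > 0).sum(axis=1)
        stages_per_block = k - 1
        offset = np.concatenate([[0], np.cumsum(stages_per_block)])
        n_stages = int(offset[-1])
        # item of rank r belongs to stages 0..min(r, k-2) of its block
        m = np.minimum(r + 1, stages_per_block[rows])
        set_item = np.repeat(cols, m)
        set_block = np.repeat(rows, m)
        cum = np.cumsum(m)
        local = np.arange(int(cum[-1])) - np.repeat(cum - m, m)
        set_stage = offset[set_block] + local
        order = np.argsort(set_stage, kind="stable")
        set_stage = set_stage[order]
        set_item = set_item[order]
        ptr = np.searchsorted(set_stage, np.arange(n_stages))
        chosen = np.empty(n_stages, dtype=np.int64)
        sel = r < stages_per_block[rows]
        chosen[offset[rows[sel]] + r[sel]] = cols[sel]
        stage_w = np.repeat(weights, stages_per_block)
        win_w = np.bincount(chosen, weights=stage_w, minlength=n_items)
        return cls(n_items, n_stages, set_item, set_stage, ptr, chosen, stage_w, win_w)

    def loglik(self, lam: np.ndarray) -> float:
        """Log-likelihood with per-stage log-sum-exp stabilisation."""
        v = lam[self.set_item]
        mx = np.maximum.reduceat(v, self.ptr)
        s = np.add.reduceat(np.exp(v - mx[self.set_stage]), self.ptr)
        lse = mx + np.log(s)
        return float(np.sum(self.stage_w * (lam[self.chosen] - lse)))

    def mm_step(self, gamma: np.ndarray) -> np.ndarray:
        denom_stage = np.add.reduceat(gamma[self.set_item], self.ptr)
        contrib = (self.stage_w / denom_stage)[self.set_stage]
        item_denom = np.bincount(self.set_item, weights=contrib, minlength=self.n_items)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(item_denom > 0, self.win_w / item_denom, gamma)
        return out

    def neg_hessian(self, lam: np.ndarray) -> np.ndarray:
        """Observed information: -d2l/dlam2 = sum_s w_s (diag(p_s) - p_s p_s')."""
        v = lam[self.set_item]
        mx = np.maximum.reduceat(v, self.ptr)
        e = np.exp(v - mx[self.set_stage])
        s = np.add.reduceat(e, self.ptr)
        p = e / s[self.set_stage]
        w_member = self.stage_w[self.set_stage]
        diag = np.bincount(self.set_item, weights=w_member * p, minlength=self.n_items)
        M = sparse.csr_matrix(
            (p, (self.set_stage, self.set_item)), shape=(self.n_stages, self.n_items)
        )
        MtWM = (M.T @ sparse.diags(self.stage_w) @ M).toarray()
        return np.diag(diag) - MtWM


def _check_items_ranked(R: RankingMatrix) -> None:
    appears = (R.ranks > 0).any(axis=0)
    if not appears.all():
        missing = [R.items.labels[i] for i in np.nonzero(~appears)[0]]
        raise ValueError(f"items never ranked in any block: {missing}")


def _strongly_connected(wins: np.ndarray) -> list[list[str]] | None:
    """Return None if the win graph is strongly connected, else the components."""
    adj = sparse.csr_matrix((wins > 0).astype(np.int8))
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    if n_comp == 1:
        return None
    return [list(np.nonzero(labels == c)[0]) for c in range(n_comp)]


class PlackettLuce:
    """Plackett-Luce worth model for a :class:`RankingMatrix`.

    Parameters
    ----------
    rankings : RankingMatrix
    ref : str, optional
        Reference item whose log-worth is fixed at 0 (default: first item).
    npseudo : float
        Weight of the regularising pseudo-rankings against a hypothetical
        item (default 0.5).  Set 0 for the pure MLE; this raises an error if
        the win graph is disconnected.
    weights : array, optional
        Per-block ranking weights (internal use, e.g. pairwise counts).
    """

    def __init__(
        self,
        rankings: RankingMatrix,
        ref: str | None = None,
        npseudo: float = 0.5,
        weights: np.ndarray | None = None,
    ):
        if rankings.n_items < 2:
            raise ValueError("need at least 2 items")
        if npseudo < 0:
            raise ValueError("npseudo must be >= 0")
        if npseudo == 0:
            _check_items_ranked(rankings)
        else:
            appears = (rankings.ranks > 0).any(axis=0)
            if not appears.all():
                labs = [rankings.items.labels[i] for i in np.nonzero(~appears)[0]]
                warnings.warn(
                    f"items never ranked: {labs}; estimates rest on pseudo-rankings only",
                    UserWarning, stacklevel=2,
                )
        self.rankings = rankings
        self.ref = ref if ref is not None else rankings.items.labels[0]
        self.ref_idx = rankings.items.position(self.ref)
        self.npseudo = float(npseudo)
        self.weights = None if weights is None else np.asarray(weights, dtype=float)
        self._data_stages = _Stages.compile(rankings.ranks, self.weights)
        self._fit_stages = self._build_fit_stages()

    def _build_fit_stages(self) -> _Stages:
        if self.npseudo == 0:
            from .rankings import to_binomial_frequencies

            comps = _strongly_connected(to_binomial_frequencies(self.rankings).wins)
            if comps is not None:
                groups = [[self.rankings.items.labels[i] for i in c] for c in comps]
                raise ValueError(
                    "win graph is disconnected; the maximum-likelihood estimate is "
                    f"not finite (components: {groups}). Use npseudo > 0."
                )
            return self._data_stages
        n = self.rankings.n_items
        B = self.rankings.n_blocks
        aug = np.zeros((B + 2 * n, n + 1), dtype=np.int64)
        aug[:B, :n] = self.rankings.ranks
        for i in range(n):  # hypothetical item at column n
            aug[B + 2 * i, [i, n]] = [1, 2]       # i beats hypothetical
            aug[B + 2 * i + 1, [i, n]] = [2, 1]   # hypothetical beats i
        w = np.ones(B) if self.weights is None else self.weights
        aug_w = np.concatenate([w, np.full(2 * n, self.npseudo)])
        return _Stages.compile(aug, aug_w)

    # -- likelihood interface -------------------------------------------------
    def loglik(self, log_worth: np.ndarray) -> float:
        """Data log-likelihood (pseudo-rankings excluded) at ``log_worth``."""
        lam = np.asarray(log_worth, dtype=float)
        if lam.shape != (self.rankings.n_items,):
            raise ValueError("log_worth must have one entry per item")
        return self._data_stages.loglik(lam)

    @property
    def null_loglik(self) -> float:
        return self._data_stages.loglik(np.zeros(self.rankings.n_items))

    def fit(
        self,
        tol: float = 1e-9,
        maxit: int = 500,
        start: np.ndarray | None = None,
        check_monotone: bool = False,
    ) -> "PlackettLuceResults":
        """Run the MM iteration to convergence.

        Convergence is declared when the max-abs change of the free log-worths
        falls below ``tol``.  ``check_monotone`` asserts the MM ascent
        property every iteration (diagnostic; meaningful at ``npseudo=0``).
        """
        st = self._fit_stages
        n_fit = st.n_items
        gamma = np.ones(n_fit) if start is None else np.exp(
            np.concatenate([start, [0.0]]) if n_fit > start.size else start
        )
        gamma = gamma / gamma[self.ref_idx]
        obj = st.loglik(np.log(gamma)) if check_monotone else None
        converged = False
        it = 0
        for it in range(1, maxit + 1):
            new = st.mm_step(gamma)
            new = new / new[self.ref_idx]
            if check_monotone:
                new_obj = st.loglik(np.log(new))
                assert new_obj >= obj - 1e-8, "MM step decreased the likelihood"
                obj = new_obj
            delta = float(np.max(np.abs(np.log(new) - np.log(gamma))))
            gamma = new
            if delta < tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"MM did not converge in {maxit} iterations (tol={tol})",
                UserWarning,
                stacklevel=2,
            )
        lam = np.log(gamma)[: self.rankings.n_items]  # drop hypothetical item
        lam = lam - lam[self.ref_idx]
        return PlackettLuceResults(self, lam, converged, it)


class PlackettLuceResults:
    """Fitted Plackett-Luce model: estimates, covariance and diagnostics."""

    def __init__(self, model: PlackettLuce, log_worth: np.ndarray,
                 converged: bool, n_iter: int):
        self.model = model
        self._lam = np.asarray(log_worth, dtype=float)
        self.converged = converged
        self.n_iter = n_iter
        self.ref = model.ref
        self.npseudo = model.npseudo
        self.llf = model.loglik(self._lam)
        self.llnull = model.null_loglik
        self.n_rankings = model.rankings.n_blocks
        self.df_model = model.rankings.n_items - 1
        self._vcov: pd.DataFrame | None = None
        self._vcov_pinv = False

    # -- estimates ------------------------------------------------------------
    @property
    def items(self) -> ItemSet:
        return self.model.rankings.items

    @property
    def log_worth(self) -> pd.Series:
        return pd.Series(self._lam, index=list(self.items.labels), name="log_worth")

    @property
    def worth(self) -> pd.Series:
        g = np.exp(self._lam - self._lam.max())
        return pd.Series(g / g.sum(), index=list(self.items.labels), name="worth")

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.df_model

    @property
    def null_aic(self) -> float:
        """AIC of the equal-worth null model (zero free parameters)."""
        return -2.0 * self.llnull

    def pseudo_r2(self) -> dict:
        """McFadden's pseudo-R2 = 1 - llf/llnull against the equal-worth null."""
        if self.llnull == 0:
            raise ZeroDivisionError("null log-likelihood is 0; pseudo-R2 undefined")
        return {
            "mcfadden": 1.0 - self.llf / self.llnull,
            "loglik": self.llf,
            "null_loglik": self.llnull,
        }

    # -- uncertainty ----------------------------------------------------------
    @property
    def vcov(self) -> pd.DataFrame:
        """Covariance of the free log-worths (reference excluded).

        Inverse of the observed information (analytic Hessian of the data
        log-likelihood at the estimate) with the reference fixed; falls back
        to the Moore-Penrose pseudo-inverse, with a warning, if singular.
        """
        if self._vcov is None:
            negH = self.model._data_stages.neg_hessian(self._lam)
            free = [i for i in range(self.items.__len__()) if i != self.model.ref_idx]
            sub = negH[np.ix_(free, free)]
            try:
                cov = np.linalg.inv(sub)
                if not np.all(np.isfinite(cov)):
                    raise np.linalg.LinAlgError
            except np.linalg.LinAlgError:
                warnings.warn(
                    "singular Hessian; using pseudo-inverse for vcov",
                    UserWarning, stacklevel=2,
                )
                cov = np.linalg.pinv(sub)
                self._vcov_pinv = True
            cov = (cov + cov.T) / 2.0
            labs = [self.items.labels[i] for i in free]
            self._vcov = pd.DataFrame(cov, index=labs, columns=labs)
        return self._vcov

    def vcov_full(self) -> pd.DataFrame:
        """n x n covariance with zero row/column for the reference item."""
        labs = list(self.items.labels)
        full = pd.DataFrame(0.0, index=labs, columns=labs)
        v = self.vcov
        full.loc[v.index, v.columns] = v.values
        return full

    @property
    def bse(self) -> pd.Series:
        se = np.sqrt(np.clip(np.diag(self.vcov_full().values), 0, None))
        return pd.Series(se, index=list(self.items.labels), name="se")

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy import stats

        z = stats.norm.ppf(1 - alpha / 2)
        se = self.bse
        return pd.DataFrame(
            {"lower": self.log_worth - z * se, "upper": self.log_worth + z * se}
        )

    # -- prediction -----------------------------------------------------------
    def predicted_ranking(self, labels=None) -> list[str]:
        """Items ordered best-first by estimated worth.

        Exact worth ties are broken by item-set order (deterministic).
        """
        labels = list(self.items.labels) if labels is None else list(labels)
        lam = self.log_worth
        pos = {lab: i for i, lab in enumerate(self.items.labels)}
        return sorted(labels, key=lambda lab: (-lam[lab], pos[lab]))

    def reliability(self, ref: str | None = None) -> pd.DataFrame:
        from .decision import reliability as _rel

        return _rel(self, ref=ref)

    # -- reporting ------------------------------------------------------------
    def worth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item": list(self.items.labels),
                "worth": self.worth.values,
                "log_worth": self._lam,
                "se": self.bse.values,
            }
        )

    def summary(self) -> str:
        pr2 = self.pseudo_r2()["mcfadden"] if self.llnull != 0 else float("nan")
        head = (
            f"Plackett-Luce model ({self.items.__len__()} items, "
            f"{self.n_rankings} rankings)\n"
            f"ref: {self.ref} (log-worth fixed at 0)   npseudo: {self.npseudo}\n"
            f"log-lik: {self.llf:.3f}   null: {self.llnull:.3f}   "
            f"AIC: {self.aic:.2f}   McFadden R2: {pr2:.4f}\n"
            f"converged: {self.converged} in {self.n_iter} iterations\n"
        )
        tab = self.worth_table()
        body = tab.to_string(index=False, float_format=lambda x: f"{x:.4f}")
        return head + body

    # -- serialisation --------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "type": "plackett_luce",
            "labels": list(self.items.labels),
            "log_worth": self._lam.tolist(),
            "vcov": self.vcov.values.tolist(),
            "vcov_labels": list(self.vcov.index),
            "loglik": self.llf,
            "null_loglik": self.llnull,
            "n_rankings": self.n_rankings,
            "settings": {
                "ref": self.ref,
                "npseudo": self.npseudo,
                "converged": self.converged,
                "iterations": self.n_iter,
            },
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def __repr__(self) -> str:
        return (
            f"<PlackettLuceResults ref={self.ref!r} llf={self.llf:.3f} "
            f"converged={self.converged}>"
        )


# -- functional wrappers ------------------------------------------------------

def fit_plackett_luce(
    R: RankingMatrix,
    ref: str | None = None,
    npseudo: float = 0.5,
    tol: float = 1e-9,
    maxit: int = 500,
    **kwargs,
) -> PlackettLuceResults:
    """Fit a Plackett-Luce model (convenience wrapper over :class:`PlackettLuce`)."""
    return PlackettLuce(R, ref=ref, npseudo=npseudo).fit(tol=tol, maxit=maxit, **kwargs)


def loglik_pl(log_worth: np.ndarray, R: RankingMatrix) -> float:
    """Plackett-Luce log-likelihood of ``R`` at the given log-worths."""
    return _Stages.compile(R.ranks).loglik(np.asarray(log_worth, dtype=float))


def aic(results: PlackettLuceResults) -> float:
    return results.aic


def pseudo_r2(results: PlackettLuceResults) -> dict:
    return results.pseudo_r2()


def vcov_pl(results: PlackettLuceResults) -> pd.DataFrame:
    return results.vcov
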