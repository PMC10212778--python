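import numpy as np
import pytest

from ranktrial import ItemSet, RankingMatrix, generate_tricot_trial


@pytest.fixture
def abc_items():
    return ItemSet(["A", "B", "C"])


@pytest.fixture
def simple_rankings(abc_items):
    """Four complete 3-item rankings with A generally on top."""
    ranks = np.array(
        [
            [1, 2, 3],
            [1, 3, 2],
            [2, 1, 3],
            [1, 2, 3],
        ]
    )
    return RankingMatrix(ranks, abc_items)


@pytest.fixture(scope="session")
def small_trial():
    """Static-truth synthetic trial shared across tests (seeded)."""
    return generate_tricot_trial(n_items=6, n_blocks=120, seed=2024)


def random_partial_rankings(rng, n_blocks=30, n_items=5, k=3):
    """Random partial rankings: k distinct items per block, random order."""
    R = np.zeros((n_blocks, n_items), dtype=np.int64)
    for b in range(n_blocks):
        items = rng.choice(n_items, size=k, replace=False)
        order = rng.permutation(k)
        for rank0, pos in enumerate(order):
            R[b, items[pos]] = rank0 + 1
    return RankingMatrix(R, ItemSet([f"i{j}" for j in range(n_items)]))
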