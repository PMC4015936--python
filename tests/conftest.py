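import numpy as np
import pytest

from crowdrank.rank_io import Ordering, RankingDataset, ordering_to_ranking


def orderings_to_dataset(orderings, truth=None, labels=None):
    """Build a RankingDataset from a list of orderings (items in placed order)."""
    n = len(orderings[0])
    labels = labels or tuple(chr(ord("A") + i) for i in range(n))
    ids = tuple(f"p{j}" for j in range(len(orderings)))
    rows = np.vstack([ordering_to_ranking(Ordering(o)).as_array() for o in orderings])
    return RankingDataset(labels, ids, rows, truth=Ordering(truth) if truth is not None else None)


def brute_force_tau(a, b) -> int:
    """Independent O(N^2) discordant-pair count on ordering sequences."""
    pos_a = {item: p for p, item in enumerate(a)}
    pos_b = {item: p for p, item in enumerate(b)}
    items = list(pos_a)
    count = 0
    for x in range(len(items)):
        for y in range(x + 1, len(items)):
            i, k = items[x], items[y]
            if (pos_a[i] - pos_a[k]) * (pos_b[i] - pos_b[k]) < 0:
                count += 1
    return count


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_dataset():
    """Three participants ranking three items, with ground truth (A, B, C)."""
    return orderings_to_dataset(
        [(0, 1, 2), (0, 2, 1), (1, 0, 2)], truth=(0, 1, 2)
    )
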