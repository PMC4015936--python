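"""Aggregate (crowd) rankings: posterior-based and Borda count.

The model-based aggregate orders items by the posterior mean of their latent
locations (ascending: smaller location = placed earlier).  The Borda count
baseline gives item i a tally of N - 1 - position in each participant's
ranking and sorts tallies descending; any positional scoring that decreases
affinely in position yields the same ordering.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .model import Posterior
from .rank_io import Ordering, RankingDataset

__all__ = [
    "AggregateResult",
    "aggregate_ranking",
    "pairwise_order_probability",
    "borda_count",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AggregateResult:
    """A crowd ordering with the per-item scores that produced it.

    ``scores`` holds posterior-mean locations (method "thurstone") or Borda
    tallies (method "borda").  ``pairwise`` is the N x N matrix of posterior
    probabilities that item i is placed before item k (None for Borda).
    """

    ordering: Ordering
    scores: np.ndarray
    method: str
    item_labels: tuple
    pairwise: Optional[np.ndarray] = None
    tallies: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.pairwise is not None:
            p = self.pairwise
            if np.any(p < 0) or np.any(p > 1):
                raise ValueError("pairwise probabilities must lie in [0, 1]")
            off = ~np.eye(p.shape[0], dtype=bool)
            if not np.allclose((p + p.T)[off], 1.0):
                raise ValueError("pairwise probabilities must satisfy p(i,k) + p(k,i) = 1")

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-item table: label, score, aggregate position (0-based)."""
        pos = np.argsort(self.ordering.as_array())
        return pd.DataFrame(
            {
                "item": list(self.item_labels),
                "score": self.scores,
                "aggregate_position": pos,
            }
        )

    def save(self, prefix: Union[str, Path]) -> None:
        """Write ``<prefix>.csv`` (per-item) and, if present, ``<prefix>_pairwise.json``."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(prefix.with_suffix(".csv"), index=False)
        if self.pairwise is not None:
            payload = {
                "item_labels": list(self.item_labels),
                "p_before": self.pairwise.tolist(),
            }
            with open(f"{prefix}_pairwise.json", "w", encoding="utf-8") as fh:
                json.dump(payload, fh)


def _warn_on_ties(scores: np.ndarray, what: str) -> None:
    s = np.sort(scores)
    if np.any(s[1:] == s[:-1]):
        logger.warning("%s contains ties; breaking by item index", what)


def aggregate_ranking(post: Posterior) -> AggregateResult:
    """Crowd ordering from the posterior: ascending posterior-mean locations.

    Ties (exactly equal means) are broken by item index.  The pairwise matrix
    entry (i, k) is the fraction of retained draws placing item i before k.
    """
    if post.n_draws == 0:
        raise ValueError("posterior has no draws")
    means = post.mean_locations()
    _warn_on_ties(means, "posterior-mean locations")
    ordering = Ordering(np.argsort(means, kind="stable"))
    N = means.size
    mu = post.mu
    less = mu[:, :, None] < mu[:, None, :]
    equal = mu[:, :, None] == mu[:, None, :]
    pairwise = less.mean(axis=0) + 0.5 * equal.mean(axis=0)
    np.fill_diagonal(pairwise, 0.5)
    return AggregateResult(
        ordering=ordering,
        scores=means,
        method="thurstone",
        item_labels=post.item_labels,
        pairwise=pairwise,
    )


def pairwise_order_probability(post: Posterior, i: int, k: int) -> float:
    """Posterior probability that item i is placed before item k."""
    if i == k:
        raise ValueError("pairwise order probability needs two distinct items")
    less = post.mu[:, i] < post.mu[:, k]
    equal = post.mu[:, i] == post.mu[:, k]
    return float(less.mean() + 0.5 * equal.mean())


def borda_count(d: RankingDataset) -> AggregateResult:
    """Borda-count aggregate: positional tallies summed over participants.

    Item i scores N - 1 - position for each participant (best position scores
    N - 1, worst scores 0); the ordering sorts tallies descending with ties
    broken by item index.
    """
    N = d.n_items
    tallies = (N - 1 - d.rankings).sum(axis=0).astype(float)
    _warn_on_ties(tallies, "Borda tallies")
    ordering = Ordering(np.argsort(-tallies, kind="stable"))
    return AggregateResult(
        ordering=ordering,
        scores=tallies,
        method="borda",
        item_labels=d.item_labels,
        tallies=tallies,
    )
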