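"""Synthetic ranking datasets drawn from the model's own generative process.

Each scenario fixes true item locations on the latent continuum and a true
noise scale per participant; every participant's observed ordering is the
ascending sort of their mental samples x_ij ~ Normal(mu_i, sigma_j).  The
true ordering (ascending true locations) is attached to the dataset, and the
true sigmas are returned so parameter-recovery studies can compare inferred
expertise against the values that generated the data.

Defaults: locations equally spaced with unit gap, and heterogeneous
expertise with sigma_j drawn log-uniformly between 0.5 and 3 — a spread wide
enough that some participants are near-perfect and others near chance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .rank_io import Ordering, RankingDataset

__all__ = ["ScenarioSpec", "GeneratedData", "generate_dataset", "make_default_suite"]

SIGMA_LOG_RANGE = (0.5, 3.0)  # default log-uniform expertise spread


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic ranking study.

    ``true_locations`` defaults to 0, 1, ..., n_items-1 (equally spaced, unit
    gap).  ``true_sigma`` may be an explicit per-participant sequence; if
    None, sigmas are drawn log-uniformly over ``sigma_range`` using ``seed``.
    """

    n_items: int
    n_participants: int
    seed: int
    true_locations: Optional[Sequence[float]] = None
    true_sigma: Optional[Sequence[float]] = None
    sigma_range: tuple[float, float] = SIGMA_LOG_RANGE
    name: str = ""

    def __post_init__(self):
        if self.n_items < 2:
            raise ValueError("need at least 2 items")
        if self.n_participants < 1:
            raise ValueError("need at least 1 participant")
        if self.true_locations is not None:
            locs = np.asarray(self.true_locations, dtype=float)
            if locs.shape != (self.n_items,):
                raise ValueError("true_locations length must equal n_items")
            if np.unique(locs).size != locs.size:
                raise ValueError("true_locations must be distinct")
            object.__setattr__(self, "true_locations", tuple(locs.tolist()))
        if self.true_sigma is not None:
            sig = np.asarray(self.true_sigma, dtype=float)
            if sig.shape != (self.n_participants,):
                raise ValueError("true_sigma length must equal n_participants")
            if np.any(sig <= 0):
                raise ValueError("all true sigmas must be positive")
            object.__setattr__(self, "true_sigma", tuple(sig.tolist()))
        lo, hi = self.sigma_range
        if not (0 < lo <= hi):
            raise ValueError("sigma_range must satisfy 0 < lo <= hi")

    def locations(self) -> np.ndarray:
        if self.true_locations is not None:
            return np.asarray(self.true_locations, dtype=float)
        return np.arange(self.n_items, dtype=float)


@dataclass(frozen=True)
class GeneratedData:
    """A synthetic dataset together with the parameters that generated it."""

    dataset: RankingDataset
    true_locations: np.ndarray
    true_sigma: np.ndarray
    spec: ScenarioSpec

    def save_sidecar(self, path: Union[str, Path]) -> None:
        """JSON record of the generating locations and sigmas."""
        payload = {
            "true_locations": self.true_locations.tolist(),
            "true_sigma": self.true_sigma.tolist(),
            "seed": self.spec.seed,
            "n_items": self.spec.n_items,
            "n_participants": self.spec.n_participants,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def generate_dataset(spec: ScenarioSpec) -> GeneratedData:
    """Simulate a ranking study: mental samples per participant, sorted.

    Deterministic given ``spec.seed``.  The attached ground truth is the
    ascending order of the true locations.
    """
    rng = np.random.default_rng(spec.seed)
    locs = spec.locations()
    if spec.true_sigma is not None:
        sigma = np.asarray(spec.true_sigma, dtype=float)
    else:
        lo, hi = spec.sigma_range
        sigma = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_participants))
    x = rng.normal(locs, sigma[:, None], size=(spec.n_participants, spec.n_items))
    orderings = np.argsort(x, axis=1)
    rankings = np.argsort(orderings, axis=1)
    labels = tuple(f"item{i:02d}" for i in range(spec.n_items))
    ids = tuple(f"p{j:03d}" for j in range(spec.n_participants))
    truth = Ordering(np.argsort(locs, kind="stable"))
    dataset = RankingDataset(labels, ids, rankings, truth)
    return GeneratedData(dataset, locs, sigma, spec)


def make_default_suite(seed: int) -> list[ScenarioSpec]:
    """Named standard scenarios used throughout the tests and examples.

    * ``ten-items`` — the common 10-item general-knowledge shape (J=40);
    * ``presidents-scale`` — 44 items ranked by 26 participants;
    * ``heterogeneous-expertise`` — 10 items, 30 participants, wide sigma
      spread, the wisdom-of-the-crowd testbed;
    * ``low-noise`` — 10 items, 20 near-expert participants.
    """
    return [
        ScenarioSpec(10, 40, seed=seed, name="ten-items"),
        ScenarioSpec(44, 26, seed=seed + 1, name="presidents-scale"),
        ScenarioSpec(10, 30, seed=seed + 2, name="heterogeneous-expertise"),
        ScenarioSpec(
            10, 20, seed=seed + 3, true_sigma=(0.4,) * 20, name="low-noise"
        ),
    ]
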