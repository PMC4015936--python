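"""Thurstonian ranking model with individual differences, fit by Gibbs sampling.

The generative story: each of N items has a latent location mu_i on a single
psychological continuum shared by everyone.  When participant j ranks the
items, they take one noisy "mental sample" per item,

    x_ij ~ Normal(mu_i, sigma_j),

and report the items sorted by those samples (smallest first).  The
per-person standard deviation sigma_j captures how precise that person's
knowledge is — a small sigma_j means an expert whose reported ranking
rarely strays from the order of the true locations.

Inference is by Gibbs sampling with truncated-normal data augmentation.
Conditional on a participant's observed ordering, the latent samples x_ij
live in the order-constrained region {x at position 1 < x at position 2 <
...}; each x_ij is redrawn from its normal conditional truncated between the
latent values of the neighbouring items in that participant's ordering.
Locations then have conjugate normal full conditionals and per-person
precisions lambda_j = sigma_j**-2 have conjugate gamma full conditionals.

The likelihood is invariant under jointly rescaling (mu, sigma, x), so
weakly-informative proper priors pin the scale: mu_i ~ Normal(0, 1) and
lambda_j ~ Gamma(shape=2, rate=2) by default (prior mean precision 1,
matching the unit location scale).  All hyperparameters are configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .rank_io import Ordering, RankingDataset

__all__ = [
    "SamplerConfig",
    "LatentState",
    "Posterior",
    "sample_truncated_normal",
    "initialize_state",
    "gibbs_update_latents",
    "gibbs_update_locations",
    "gibbs_update_precisions",
    "gibbs_update_translation",
    "run_sampler",
    "ranking_probability",
]


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC schedule and prior hyperparameters.

    Defaults reproduce the standard schedule for this model family:
    4 independent chains, 10,000 burn-in sweeps, then 1,000 retained draws
    per chain recording every 10th sweep.  Burn-in is counted in raw sweeps
    (pre-thinning).
    """

    n_chains: int = 4
    n_burnin: int = 10_000
    n_retained_per_chain: int = 1_000
    thin: int = 10
    base_seed: int = 0
    prior_location_sd: float = 1.0
    prior_precision_shape: float = 2.0
    prior_precision_rate: float = 2.0

    def __post_init__(self):
        if self.n_chains < 1 or self.n_retained_per_chain < 1:
            raise ValueError("chain and retained-draw counts must be positive")
        if self.n_burnin < 0:
            raise ValueError("burn-in must be non-negative")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        for name in ("prior_location_sd", "prior_precision_shape", "prior_precision_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class LatentState:
    """Current Gibbs state: locations, precisions and augmented mental samples.

    ``mu`` has length N, ``lam`` (precisions, sigma_j = lam_j**-0.5) length J,
    and ``x`` is (J, N).  For every participant j, sorting ``x[j]`` ascending
    must reproduce j's observed ordering.
    """

    mu: np.ndarray
    lam: np.ndarray
    x: np.ndarray

    @property
    def sigma(self) -> np.ndarray:
        return self.lam ** -0.5

    def check_order_constraint(self, ordermat: np.ndarray) -> None:
        """Raise if any participant's samples violate their observed ordering."""
        rows = np.take_along_axis(self.x, ordermat, axis=1)
        if not np.all(np.diff(rows, axis=1) > 0):
            bad = int(np.argmin(np.all(np.diff(rows, axis=1) > 0, axis=1)))
            raise RuntimeError(f"order constraint violated for participant index {bad}")
        if not np.all(self.lam > 0):
            raise RuntimeError("non-positive precision in latent state")


@dataclass(frozen=True)
class Posterior:
    """Retained MCMC draws, tagged by chain.

    ``mu`` is (S, N) location draws and ``sigma`` (S, J) noise-scale draws,
    with S = n_chains * n_retained_per_chain; ``chain[s]`` is the 0-based
    chain index of draw s.
    """

    mu: np.ndarray
    sigma: np.ndarray
    chain: np.ndarray
    config: SamplerConfig
    item_labels: tuple
    participant_ids: tuple

    def __post_init__(self):
        S = self.config.n_chains * self.config.n_retained_per_chain
        if self.mu.shape != (S, len(self.item_labels)):
            raise ValueError(f"location draws shape {self.mu.shape} inconsistent with config")
        if self.sigma.shape != (S, len(self.participant_ids)):
            raise ValueError(f"sigma draws shape {self.sigma.shape} inconsistent with config")
        if self.chain.shape != (S,):
            raise ValueError("chain index vector has wrong length")
        if not np.all(self.sigma > 0):
            raise ValueError("all sigma draws must be positive")

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0]

    def mean_locations(self) -> np.ndarray:
        return self.mu.mean(axis=0)

    def mean_sigma(self) -> np.ndarray:
        return self.sigma.mean(axis=0)

    def by_chain(self, values: np.ndarray) -> np.ndarray:
        """Reshape per-draw values (S, ...) into (n_chains, draws_per_chain, ...)."""
        c = self.config
        return values.reshape(c.n_chains, c.n_retained_per_chain, *values.shape[1:])

PathLike = Union[str, Path]


def _posterior_save(self: Posterior, prefix: PathLike) -> None:
    """Write ``<prefix>.json``, ``<prefix>_locations.csv``, ``<prefix>_sigma.csv``."""
    prefix = Path(prefix)
    meta = {
        "config": {k: getattr(self.config, k) for k in SamplerConfig.__dataclass_fields__},
        "item_labels": list(self.item_labels),
        "participant_ids": list(self.participant_ids),
    }
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.with_suffix(".json"), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)
    loc = pd.DataFrame(self.mu, columns=list(self.item_labels))
    loc.insert(0, "chain", self.chain)
    loc.to_csv(f"{prefix}_locations.csv", index=False)
    sig = pd.DataFrame(self.sigma, columns=list(self.participant_ids))
    sig.insert(0, "chain", self.chain)
    sig.to_csv(f"{prefix}_sigma.csv", index=False)


def _posterior_load(prefix: PathLike) -> Posterior:
    prefix = Path(prefix)
    with open(prefix.with_suffix(".json"), encoding="utf-8") as fh:
        meta = json.load(fh)
    config = SamplerConfig(**meta["config"])
    loc = pd.read_csv(f"{prefix}_locations.csv")
    sig = pd.read_csv(f"{prefix}_sigma.csv")
    chain = loc.pop("chain").to_numpy()
    sig.pop("chain")
    return Posterior(
        mu=loc.to_numpy(float),
        sigma=sig.to_numpy(float),
        chain=chain,
        config=config,
        item_labels=tuple(meta["item_labels"]),
        participant_ids=tuple(meta["participant_ids"]),
    )


Posterior.save = _posterior_save  # type: ignore[method-assign]
Posterior.load = staticmethod(_posterior_load)  # type: ignore[attr-defined]


# ---------------------------------------------------------------------------
# Truncated normal sampling
# ---------------------------------------------------------------------------

def _truncated_standard(a: np.ndarray, b: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF draw of standard normal restricted to (a, b), elementwise.

    Intervals in the upper tail are reflected onto the lower tail, where the
    normal CDF and its inverse keep full relative precision near zero; a
    midpoint fallback covers intervals so far out that their mass underflows.
    """
    z = np.empty(a.shape)
    hi = a >= 0  # reflect: work with the survival function side
    lo = ~hi

    Fa = ndtr(a[lo])
    Fb = ndtr(b[lo])
    z[lo] = ndtri(Fa + u[lo] * (Fb - Fa))

    Pa = ndtr(-a[hi])  # = P(Z > a), small and accurate
    Pb = ndtr(-b[hi])
    z[hi] = -ndtri(Pb + u[hi] * (Pa - Pb))

    # underflowed-mass or zero-width intervals: fall back to the midpoint
    bad = ~np.isfinite(z) | (z < a) | (z > b)
    if bad.any():
        mid = np.where(
            np.isfinite(a[bad]) & np.isfinite(b[bad]),
            0.5 * (a[bad] + b[bad]),
            np.where(np.isfinite(a[bad]), a[bad], b[bad]),
        )
        z[bad] = mid
    # strict interior, required by the order constraint downstream
    finite_a = np.isfinite(a)
    finite_b = np.isfinite(b)
    z = np.where(finite_a & (z <= a), np.nextafter(a, np.inf), z)
    z = np.where(finite_b & (z >= b), np.nextafter(b, -np.inf), z)
    return z


def sample_truncated_normal(mean, sd, lower, upper, rng: np.random.Generator, size=None):
    """Draw from Normal(mean, sd) restricted to the open interval (lower, upper).

    All arguments broadcast; ``lower``/``upper`` may be ``-inf``/``+inf``.
    Returns a scalar when all inputs are scalars and ``size`` is None.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if not (np.all(np.isfinite(mean)) and np.all(np.isfinite(sd))):
        raise ValueError("mean and sd must be finite")
    if np.any(sd <= 0):
        raise ValueError("sd must be positive")
    if np.any(~(lower < upper)):
        raise ValueError("lower bound must be strictly below upper bound")
    a = (lower - mean) / sd
    b = (upper - mean) / sd
    shape = np.broadcast_shapes(mean.shape, sd.shape, a.shape, b.shape)
    if size is not None:
        shape = (size,) + shape if isinstance(size, int) else tuple(size) + shape
    a = np.broadcast_to(a, shape)
    b = np.broadcast_to(b, shape)
    u = rng.random(shape)
    z = _truncated_standard(np.asarray(a, float), np.asarray(b, float), u)
    out = mean + sd * z
    # guard strictness on the original scale too
    out = np.where(np.isfinite(lower) & (out <= lower), np.nextafter(lower, np.inf), out)
    out = np.where(np.isfinite(upper) & (out >= upper), np.nextafter(upper, -np.inf), out)
    if out.shape == ():
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Gibbs updates
# ---------------------------------------------------------------------------

def initialize_state(d: RankingDataset, config: SamplerConfig, rng: np.random.Generator) -> LatentState:
    """Deterministic-in-mu initial state satisfying the order constraint.

    Locations start at standardized *negative* positional tallies, so items
    the crowd placed early get small mu.  Mental samples start at each
    participant's observed positions mapped linearly onto the mu range, with
    a sub-gap jitter so the order is strict but seeds differ.
    """
    J, N = d.rankings.shape
    tally = (N - 1 - d.rankings).sum(axis=0).astype(float)
    sd = tally.std()
    mu = -(tally - tally.mean()) / (sd if sd > 0 else 1.0)

    lo, hi = float(mu.min()), float(mu.max())
    gap = (hi - lo) / (N - 1) if hi > lo else 1.0
    base = lo + d.rankings * gap  # position p -> lo + p*gap, per item
    x = base + rng.uniform(0.0, 0.4 * gap, size=(J, N))
    return LatentState(mu=mu, lam=np.ones(J), x=x)


def gibbs_update_latents(
    state: LatentState, d: RankingDataset, rng: np.random.Generator,
    ordermat: Optional[np.ndarray] = None,
) -> LatentState:
    """Redraw every mental sample from its order-constrained full conditional.

    Positions are scanned in observed placement order; the sample for the
    item at position p is truncated between the current samples of the items
    placed immediately before and after it (unbounded at the ends).
    """
    if ordermat is None:
        ordermat = d.ordering_matrix()
    J, N = state.x.shape
    x = state.x
    sigma = state.sigma
    rows = np.arange(J)
    ninf = np.full(J, -np.inf)
    pinf = np.full(J, np.inf)
    for p in range(N):
        items = ordermat[:, p]
        lower = x[rows, ordermat[:, p - 1]] if p > 0 else ninf
        upper = x[rows, ordermat[:, p + 1]] if p < N - 1 else pinf
        x[rows, items] = sample_truncated_normal(state.mu[items], sigma, lower, upper, rng)
    return state


def gibbs_update_locations(
    state: LatentState, d: RankingDataset, config: SamplerConfig, rng: np.random.Generator
) -> LatentState:
    """Redraw each location from its conjugate normal full conditional.

    Posterior precision is prior precision plus the summed participant
    precisions; the mean is the precision-weighted combination of the prior
    mean (zero) and the column of mental samples.
    """
    prior_prec = config.prior_location_sd ** -2.0
    post_prec = prior_prec + state.lam.sum()
    post_mean = (state.lam @ state.x) / post_prec
    state.mu = rng.normal(post_mean, post_prec ** -0.5)
    return state


def gibbs_update_precisions(
    state: LatentState, d: RankingDataset, config: SamplerConfig, rng: np.random.Generator
) -> LatentState:
    """Redraw each participant precision from its conjugate gamma full conditional."""
    N = state.x.shape[1]
    shape = config.prior_precision_shape + 0.5 * N
    resid = state.x - state.mu
    rate = config.prior_precision_rate + 0.5 * (resid ** 2).sum(axis=1)
    state.lam = rng.gamma(shape, 1.0 / rate)
    return state


def gibbs_update_translation(
    state: LatentState, config: SamplerConfig, rng: np.random.Generator
) -> LatentState:
    """Group move along the likelihood-invariant common-shift direction.

    The likelihood (and the order constraints) are unchanged when all
    locations and mental samples shift together, so that direction feels only
    the location prior and would otherwise random-walk slowly.  Sampling the
    shift from its exact conditional, delta ~ Normal(-mean(mu), s0^2 / N),
    and applying it to mu and x jointly is a valid translation-group update
    that decorrelates the chain in one step.
    """
    n = state.mu.size
    delta = rng.normal(-state.mu.mean(), config.prior_location_sd / np.sqrt(n))
    state.mu = state.mu + delta
    state.x = state.x + delta
    return state


def _run_chain(
    d: RankingDataset, config: SamplerConfig, seed: int, debug: bool
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    ordermat = d.ordering_matrix()
    state = initialize_state(d, config, rng)
    mu_draws = np.empty((config.n_retained_per_chain, d.n_items))
    sigma_draws = np.empty((config.n_retained_per_chain, d.n_participants))

    def sweep():
        gibbs_update_latents(state, d, rng, ordermat)
        gibbs_update_locations(state, d, config, rng)
        gibbs_update_precisions(state, d, config, rng)
        gibbs_update_translation(state, config, rng)
        if debug:
            state.check_order_constraint(ordermat)

    for _ in range(config.n_burnin):
        sweep()
    for s in range(config.n_retained_per_chain):
        for _ in range(config.thin):
            sweep()
        mu_draws[s] = state.mu
        sigma_draws[s] = state.sigma
    return mu_draws, sigma_draws


def run_sampler(d: RankingDataset, config: SamplerConfig = SamplerConfig(), debug: bool = False) -> Posterior:
    """Fit the model: independent Gibbs chains, burn-in discarded, thinned draws kept.

    Chain c is seeded ``base_seed + c``, so the same dataset and config give a
    bit-identical posterior.  A sweep updates mental samples, then locations,
    then precisions, then applies the translation group move.  With
    ``debug=True`` the order constraint is verified after every sweep.
    """
    if d.n_participants < 1 or d.n_items < 2:
        raise ValueError("need at least 1 participant and 2 items")
    mus, sigmas, chains = [], [], []
    for c in range(config.n_chains):
        mu_c, sigma_c = _run_chain(d, config, config.base_seed + c, debug)
        mus.append(mu_c)
        sigmas.append(sigma_c)
        chains.append(np.full(config.n_retained_per_chain, c))
    return Posterior(
        mu=np.vstack(mus),
        sigma=np.vstack(sigmas),
        chain=np.concatenate(chains),
        config=config,
        item_labels=d.item_labels,
        participant_ids=d.participant_ids,
    )


def ranking_probability(
    mu: Sequence[float], sigma: float, o: Ordering, n_mc: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo probability that one participant's mental samples yield ordering ``o``.

    Draws ``n_mc`` vectors of mental samples from Normal(mu, sigma) and counts
    how often sorting them ascending reproduces ``o``.  Standard error is at
    most 1/(2*sqrt(n_mc)).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    mu = np.asarray(mu, dtype=float)
    if not isinstance(o, Ordering):
        o = Ordering(o)
    if len(o) != mu.size:
        raise ValueError("ordering length does not match number of items")
    x = rng.normal(mu, sigma, size=(n_mc, mu.size))
    achieved = np.argsort(x, axis=1)
    hits = np.all(achieved == o.as_array(), axis=1)
    return float(hits.mean())
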