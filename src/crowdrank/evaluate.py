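"""Performance analytics and MCMC diagnostics for ranking aggregation.

Performance is measured by the Kendall tau distance — the number of item
pairs two orderings disagree on, equivalently the minimal number of adjacent
swaps turning one into the other.  The module provides:

* exact chance distribution of tau for a uniformly random ordering
  (the Mahonian inversion-count distribution);
* the posterior distribution of tau implied by MCMC location draws;
* the correlation between inferred expertise (posterior-mean sigma) and
  actual performance (tau to the ground truth);
* better/worse-than proportions comparing an aggregation method against the
  individual participants;
* the Gelman-Rubin potential-scale-reduction diagnostic;
* pairwise tau distances between participants and their classical
  (Torgerson) multidimensional-scaling embedding.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .model import Posterior
from .rank_io import Ordering, RankingDataset, ordering_to_ranking

__all__ = [
    "TauDistribution",
    "EvaluationReport",
    "kendall_tau",
    "n_orderings",
    "chance_tau_distribution",
    "posterior_tau_distribution",
    "participant_taus",
    "expertise_performance_correlation",
    "better_worse_proportions",
    "gelman_rubin",
    "rhat_table",
    "pairwise_tau_matrix",
    "classical_mds",
    "evaluate_run",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TauDistribution:
    """Probability mass over tau distances 0 .. N(N-1)/2 for N-item orderings."""

    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probability masses must be non-negative and sum to 1")
        object.__setattr__(self, "probs", p)

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.probs.size)

    @property
    def max_distance(self) -> int:
        return self.probs.size - 1

    def mean(self) -> float:
        return float(self.support @ self.probs)

    def total_variation(self, other: "TauDistribution") -> float:
        if self.probs.size != other.probs.size:
            raise ValueError("distributions have different supports")
        return 0.5 * float(np.abs(self.probs - other.probs).sum())


def _positions(o: Ordering) -> np.ndarray:
    if not isinstance(o, Ordering):
        o = Ordering(o)
    return ordering_to_ranking(o).as_array()


def kendall_tau(a: Ordering, b: Ordering) -> int:
    """Number of item pairs placed in opposite relative order by a and b."""
    pa, pb = _positions(a), _positions(b)
    if pa.size != pb.size:
        raise ValueError(f"orderings have different lengths ({pa.size} vs {pb.size})")
    da = pa[:, None] - pa[None, :]
    db = pb[:, None] - pb[None, :]
    discordant = (da * db) < 0
    return int(np.triu(discordant, k=1).sum())


def n_orderings(n: int) -> int:
    """Number of distinct complete orderings of n items (n factorial)."""
    if n < 1:
        raise ValueError("need at least one item")
    return math.factorial(n)


def chance_tau_distribution(n: int) -> TauDistribution:
    """Exact tau-distance distribution of a uniformly random n-item ordering.

    The distance from a uniform permutation to any fixed ordering equals its
    inversion count, whose distribution is the convolution of discrete
    uniforms on {0..k} for k = 0..n-1 (the Mahonian distribution).  Computed
    in normalized (probability) arithmetic to avoid huge integers.
    """
    if n < 2:
        raise ValueError("need at least two items")
    support_size = n * (n - 1) // 2 + 1
    if support_size > 50_000_000:
        raise MemoryError(f"tau support of size {support_size} is too large to allocate")
    probs = np.ones(1)
    for k in range(1, n):
        block = np.full(k + 1, 1.0 / (k + 1))
        probs = np.convolve(probs, block)
    probs /= probs.sum()
    return TauDistribution(probs)


def _draw_taus(mu_draws: np.ndarray, truth: Ordering) -> np.ndarray:
    """Tau distance to truth of the ordering implied by each location draw."""
    truth_pos = _positions(truth)
    if mu_draws.shape[1] != truth_pos.size:
        raise ValueError("posterior item count does not match ground-truth length")
    order = np.argsort(mu_draws, axis=1)
    pos = np.argsort(order, axis=1)
    dt = truth_pos[:, None] - truth_pos[None, :]
    iu, ku = np.triu_indices(truth_pos.size, k=1)
    dpos = pos[:, iu] - pos[:, ku]
    return ((dpos * dt[iu, ku]) < 0).sum(axis=1)


def posterior_tau_distribution(post: Posterior, truth: Ordering) -> TauDistribution:
    """Distribution of tau-to-truth over the rankings implied by posterior draws.

    Each retained location draw defines one ordering (ascending locations);
    the mass at distance t is the fraction of draws whose ordering sits at t.
    """
    taus = _draw_taus(post.mu, truth)
    n = post.mu.shape[1]
    counts = np.bincount(taus, minlength=n * (n - 1) // 2 + 1)
    return TauDistribution(counts / counts.sum())


def participant_taus(d: RankingDataset, truth: Optional[Ordering] = None) -> np.ndarray:
    """Tau distance from each participant's ordering to the ground truth."""
    truth = truth if truth is not None else d.truth
    if truth is None:
        raise ValueError("dataset has no ground truth")
    return np.array([kendall_tau(d.ordering(j), truth) for j in range(d.n_participants)])


def expertise_performance_correlation(
    post: Posterior,
    d: RankingDataset,
    truth: Optional[Ordering] = None,
    scale: str = "sd",
    method: str = "pearson",
) -> float:
    """Correlation between inferred expertise and actual performance.

    Expertise is each participant's posterior-mean noise scale sigma_j
    (``scale="precision"`` uses mean 1/sigma_j**2 instead, flipping the
    expected sign); performance is their tau distance to the ground truth.
    A strongly positive sigma-tau correlation means the model identified the
    accurate participants without ever seeing the truth.
    """
    truth = truth if truth is not None else d.truth
    if truth is None:
        raise ValueError("expertise-performance correlation requires a ground truth")
    if d.n_participants < 3:
        raise ValueError("need at least 3 participants for a meaningful correlation")
    if scale == "sd":
        expertise = post.mean_sigma()
    elif scale == "precision":
        expertise = (post.sigma ** -2.0).mean(axis=0)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    taus = participant_taus(d, truth).astype(float)
    if np.ptp(taus) == 0 or np.ptp(expertise) == 0:
        raise ValueError("zero variance in expertise or performance; correlation undefined")
    if method == "pearson":
        return float(stats.pearsonr(expertise, taus).statistic)
    if method == "spearman":
        return float(stats.spearmanr(expertise, taus).statistic)
    raise ValueError(f"unknown method {method!r}")


def better_worse_proportions(
    method_tau: int, participant_taus: Sequence[int]
) -> tuple[float, float]:
    """Fractions of participants a method beat and lost to, ties in neither.

    Returns ``(better_than, worse_than)``: the proportion of participants with
    strictly larger tau than the method, and with strictly smaller tau.
    """
    taus = np.asarray(participant_taus)
    if taus.size == 0:
        raise ValueError("no participant tau distances given")
    better = float((taus > method_tau).mean())
    worse = float((taus < method_tau).mean())
    return better, worse


def gelman_rubin(chains: Union[np.ndarray, Sequence[Sequence[float]]], split: bool = False) -> float:
    """Classic potential-scale-reduction factor R-hat for one parameter.

    ``chains`` is (n_chains, n_draws).  With ``split=True`` each chain is
    halved first, which also flags non-stationarity within chains.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2:
        raise ValueError("chains must be a 2-D array (n_chains, n_draws)")
    if split:
        half = arr.shape[1] // 2
        arr = np.vstack([arr[:, :half], arr[:, half: 2 * half]])
    m, n = arr.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 chains with at least 2 draws each")
    chain_means = arr.mean(axis=1)
    W = arr.var(axis=1, ddof=1).mean()
    if W == 0:
        raise ValueError("zero within-chain variance; R-hat undefined")
    B = n * chain_means.var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def rhat_table(post: Posterior, split: bool = False) -> dict[str, float]:
    """R-hat for every location and noise-scale parameter of a posterior."""
    out: dict[str, float] = {}
    mu_c = post.by_chain(post.mu)
    for i, label in enumerate(post.item_labels):
        out[f"mu[{label}]"] = gelman_rubin(mu_c[:, :, i], split=split)
    sig_c = post.by_chain(post.sigma)
    for j, pid in enumerate(post.participant_ids):
        out[f"sigma[{pid}]"] = gelman_rubin(sig_c[:, :, j], split=split)
    return out


def pairwise_tau_matrix(d: RankingDataset) -> np.ndarray:
    """Symmetric J x J matrix of tau distances between participants' orderings."""
    if d.n_participants < 2:
        raise ValueError("need at least two participants")
    pos = d.rankings
    iu, ku = np.triu_indices(d.n_items, k=1)
    dpos = pos[:, iu] - pos[:, ku]  # (J, n_pairs) signed pair orientations
    disc = (dpos[:, None, :] * dpos[None, :, :]) < 0
    return disc.sum(axis=2).astype(float)


def classical_mds(dist: np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS embedding of a distance matrix.

    Double-centers the squared distances and eigendecomposes; coordinates come
    from the top ``dims`` eigenpairs, scaled by the square roots of the
    eigenvalues.  Negative eigenvalues among those retained (a non-Euclidean
    distance matrix) are clipped to zero with a warning.
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")
    n = D.shape[0]
    if not (1 <= dims <= n - 1):
        raise ValueError(f"dims must be in 1..{n - 1} for {n} points")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1][:dims]
    top_vals = eigvals[order]
    if np.any(top_vals < -1e-9 * max(1.0, abs(eigvals).max())):
        logger.warning(
            "distance matrix is not Euclidean-realizable in %d dims; "
            "clipping %d negative eigenvalue(s)", dims, int((top_vals < 0).sum()),
        )
    top_vals = np.clip(top_vals, 0.0, None)
    return eigvecs[:, order] * np.sqrt(top_vals)


@dataclass(frozen=True)
class EvaluationReport:
    """Bundle of performance analytics for one fitted dataset.

    Truth-dependent fields are None when the task has no ground truth.
    """

    participant_taus: Optional[np.ndarray]
    model_tau: Optional[int]
    borda_tau: Optional[int]
    posterior_tau: Optional[TauDistribution]
    expertise_correlation: Optional[float]
    model_better_worse: Optional[tuple[float, float]]
    borda_better_worse: Optional[tuple[float, float]]
    rhat: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def tup(v):
            return None if v is None else [x.item() if hasattr(x, "item") else x for x in v]

        return {
            "participant_taus": tup(self.participant_taus),
            "model_tau": self.model_tau,
            "borda_tau": self.borda_tau,
            "posterior_tau_probs": None
            if self.posterior_tau is None
            else self.posterior_tau.probs.tolist(),
            "expertise_correlation": self.expertise_correlation,
            "model_better_worse": tup(self.model_better_worse),
            "borda_better_worse": tup(self.borda_better_worse),
            "rhat": self.rhat,
        }


def evaluate_run(
    post: Posterior, d: RankingDataset, truth: Optional[Ordering] = None
) -> EvaluationReport:
    """Full evaluation of a fitted dataset against its ground truth, if any."""
    from .aggregate import aggregate_ranking, borda_count

    truth = truth if truth is not None else d.truth
    rhat = rhat_table(post)
    if truth is None:
        return EvaluationReport(None, None, None, None, None, None, None, rhat)
    taus = participant_taus(d, truth)
    model_tau = kendall_tau(aggregate_ranking(post).ordering, truth)
    b_tau = kendall_tau(borda_count(d).ordering, truth)
    try:
        corr = expertise_performance_correlation(post, d, truth)
    except ValueError:
        corr = None
    return EvaluationReport(
        participant_taus=taus,
        model_tau=model_tau,
        borda_tau=b_tau,
        posterior_tau=posterior_tau_distribution(post, truth),
        expertise_correlation=corr,
        model_better_worse=better_worse_proportions(model_tau, taus),
        borda_better_worse=better_worse_proportions(b_tau, taus),
        rhat=rhat,
    )
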