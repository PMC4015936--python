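"""Optional figure helpers (matplotlib) for evaluation results.

Two standard views: a task performance panel (participant tau histogram,
posterior tau mass, model/Borda markers against the chance curve) and an MDS
map of participants in ranking space.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .evaluate import EvaluationReport, TauDistribution, classical_mds  # noqa: E402

__all__ = ["performance_figure", "mds_figure"]


def performance_figure(
    report: EvaluationReport,
    chance: TauDistribution,
    path: Union[str, Path],
    title: str = "",
) -> None:
    """Tau-distance summary of one task: people, posterior mass, aggregates, chance.

    Green/red markers flag the best (0) and worst (max) possible distances;
    "T" and "B" mark the single model ranking and the Borda ranking.
    """
    if report.participant_taus is None:
        raise ValueError("report has no ground-truth analytics to plot")
    support = chance.support
    fig, ax = plt.subplots(figsize=(7, 4))
    counts = np.bincount(report.participant_taus, minlength=support.size)
    ax.bar(support, counts / counts.sum(), width=0.9, color="0.75",
           label="participants")
    ax.bar(support, report.posterior_tau.probs, width=0.5, color="tab:blue",
           alpha=0.6, label="model posterior")
    ax.plot(support, chance.probs, "k:", label="chance")
    ymax = ax.get_ylim()[1]
    ax.plot(0, ymax * 0.02, "o", color="green", clip_on=False)
    ax.plot(support[-1], ymax * 0.02, "o", color="red", clip_on=False)
    ax.annotate("T", (report.model_tau, ymax * 0.9), color="tab:blue",
                ha="center", fontweight="bold")
    ax.annotate("B", (report.borda_tau, ymax * 0.8), color="goldenrod",
                ha="center", fontweight="bold")
    ax.set_xlabel("Kendall tau distance to truth")
    ax.set_ylabel("probability / proportion")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def mds_figure(
    tau_matrix: np.ndarray,
    path: Union[str, Path],
    expertise: Optional[np.ndarray] = None,
    title: str = "",
) -> np.ndarray:
    """2-D classical MDS map of participants from their pairwise tau distances.

    If per-participant expertise values are given (posterior-mean sigma),
    points are coloured by them.  Returns the coordinates used.
    """
    coords = classical_mds(tau_matrix, dims=2)
    fig, ax = plt.subplots(figsize=(5, 5))
    sc = ax.scatter(coords[:, 0], coords[:, 1], c=expertise, cmap="viridis")
    if expertise is not None:
        fig.colorbar(sc, ax=ax, label="posterior-mean sigma")
    ax.set_xlabel("MDS dimension 1")
    ax.set_ylabel("MDS dimension 2")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return coords
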