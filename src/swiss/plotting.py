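"""Optional matplotlib figures for comparison and sweep reports."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .permutation import PermutationReport
from .sweep import SweepResult

__all__ = ["plot_null_distribution", "plot_sweep"]


def plot_null_distribution(report: PermutationReport, path: Union[str, Path], seed: int = 0) -> None:
    """Null SWISS population as jittered dots plus a smoothed histogram,
    with vertical lines at the two observed scores.

    The dot heights are random jitter for visibility only; the kernel
    density curve is cosmetic (default Gaussian KDE bandwidth).
    """
    null = np.asarray(report.null_scores, dtype=float)
    rng = np.random.default_rng(seed)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(null, rng.uniform(0.02, 0.25, size=null.size), "k.", ms=3, alpha=0.4)
    if null.std() > 0:
        from scipy.stats import gaussian_kde

        grid = np.linspace(null.min(), null.max(), 256)
        dens = gaussian_kde(null)(grid)
        ax.plot(grid, dens / dens.max(), "k-", lw=1.5)
    ax.axvline(report.swiss_a, color="red", lw=2, label=f"{report.method_a}: {report.swiss_a:.4f}")
    ax.axvline(report.swiss_b, color="blue", lw=2, label=f"{report.method_b}: {report.swiss_b:.4f}")
    ax.set_xlabel("SWISS score")
    ax.set_yticks([])
    ax.set_title(
        f"p_better = {report.p_better:.4f}, p_worse = {report.p_worse:.4f} — {report.verdict}"
    )
    ax.legend(loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_sweep(result: SweepResult, path: Union[str, Path]) -> None:
    """SWISS vs retained gene count, one curve per method, CI bars if present."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for name in result.method_names:
        ax.plot(result.counts, result.scores[name], "o-", label=name)
    if result.ci90 is not None:
        los = [result.ci90[c][0] for c in result.counts]
        his = [result.ci90[c][1] for c in result.counts]
        mid = [(lo + hi) / 2 for lo, hi in zip(los, his)]
        yerr = [[m - lo for m, lo in zip(mid, los)], [hi - m for m, hi in zip(mid, his)]]
        ax.errorbar(result.counts, mid, yerr=yerr, fmt="none", ecolor="black",
                    capsize=3, label="null 90% CI")
    ax.set_xscale("log", base=2)
    ax.set_xlabel("number of retained top-variance genes")
    ax.set_ylabel("SWISS score")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
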