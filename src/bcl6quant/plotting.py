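"""Presentation figures: group intensity curves and the HSCORE scatter."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .stats import GroupDistribution, RegressionResult


def plot_group_distributions(
    groups: Sequence[GroupDistribution], path: str | Path, title: str = ""
) -> Path:
    """Mean +/- SEM intensity curves, one line and band per group."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for g in groups:
        (line,) = ax.plot(g.levels, g.mean, label=f"{g.group_label} (n={g.n_sections})")
        ax.fill_between(
            g.levels, g.mean - g.sem, g.mean + g.sem,
            alpha=0.25, color=line.get_color(), linewidth=0,
        )
    ax.set_xlabel("grey level")
    ax.set_ylabel("mean normalized frequency")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_hscore_regression(
    pairs: Sequence[tuple[float, float]],
    reg: RegressionResult,
    path: str | Path,
) -> Path:
    """HSCORE vs fitted distribution mean, with the OLS line."""
    arr = np.asarray(pairs, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4.5))
    ax.scatter(arr[:, 1], arr[:, 0], s=25, alpha=0.8)
    xs = np.linspace(arr[:, 1].min(), arr[:, 1].max(), 50)
    ax.plot(xs, reg.intercept + reg.slope * xs, "k-", lw=1)
    ax.set_xlabel("fitted distribution mean (grey level)")
    ax.set_ylabel("HSCORE")
    ax.set_title(f"r = {reg.r:.3f}, p = {reg.p_value:.2e}, n = {reg.n}")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
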