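"""Figures: the four-criteria panels and the differential efficiency function."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .optimizer import DifferentialSeries, SerGridResult  # noqa: E402

__all__ = ["plot_four_criteria", "plot_differential"]

_PANELS = (
    ("mean_efficiency", "Mean efficiency"),
    ("mean_n_items", "Mean number of items"),
    ("mean_se", "Mean SE(theta)"),
    ("mean_abs_delta_t", "Mean |T-score difference|"),
)


def plot_four_criteria(result: SerGridResult, path: str | Path) -> None:
    """Four outcome criteria vs SER threshold, overall and by floor subgroup."""
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    x = result.thresholds
    for ax, (field, label) in zip(axes.ravel(), _PANELS):
        for summaries, name, style in (
            (result.overall, "all", "-"),
            (result.floor, "floor", "--"),
            (result.nonfloor, "non-floor", ":"),
        ):
            ax.plot(x, [getattr(s, field) for s in summaries], style, label=name)
        base = getattr(result.baseline, field)
        ax.axhline(base, color="grey", lw=0.8, alpha=0.7)
        ax.set_ylabel(label)
    for ax in axes[-1]:
        ax.set_xlabel("SER threshold")
    axes[0, 0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_differential(
    series: DifferentialSeries, path: str | Path, chosen: Optional[float] = None
) -> None:
    """The differential function of efficiency across the SER grid."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(series.thresholds, series.delta_efficiency, "-o", ms=2.5)
    if chosen is not None:
        ax.axvline(chosen, color="crimson", lw=1.0, ls="--", label=f"selected = {chosen}")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("SER threshold")
    ax.set_ylabel("Change in mean efficiency")
    ax.axhline(0.0, color="grey", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
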