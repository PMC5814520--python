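"""Optional matplotlib views of the reproducibility statistics: the
identification saturation curve, the replica observation-frequency
histogram, and median pair CV per log2-intensity bin."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt.subplots()[1]


def plot_saturation(table: pd.DataFrame, ax=None, label: str | None = None,
                    color: str = "tab:orange"):
    """Mean unique residue pairs vs number of LC-MS runs."""
    ax = _axes(ax)
    ax.plot(table["k"], table["mean_unique_pairs"], "o-", color=color,
            label=label)
    ax.set_xlabel("number of runs")
    ax.set_ylabel("mean unique residue pairs")
    if label:
        ax.legend()
    return ax


def plot_observation_frequency(hist: dict[int, int], ax=None,
                               color: str = "tab:blue"):
    """How many residue pairs were observed in exactly m replicas."""
    ax = _axes(ax)
    ax.bar(list(hist), list(hist.values()), color=color)
    ax.set_xlabel("observed in m replicas")
    ax.set_ylabel("unique residue pairs")
    return ax


def plot_cv_by_intensity(bins: pd.DataFrame, ax=None,
                         color: str = "tab:orange"):
    """Median pair CV per log2 peak-area bin."""
    ax = _axes(ax)
    ax.bar(bins["bin_left"], bins["median_cv"], width=0.9, color=color)
    ax.set_xlabel("log2 median peak area (bin)")
    ax.set_ylabel("median pair CV [%]")
    return ax


def save(ax, path: str | Path) -> None:
    ax.figure.savefig(path, dpi=150, bbox_inches="tight")
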