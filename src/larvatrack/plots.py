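"""Figure helpers: population time courses, navigation index, occupancy
distributions.  All functions return the matplotlib Figure and optionally
save a PNG."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_population_timecourse(
    summary: pd.DataFrame, ylabel: str = "speed (mm/s)", path=None
):
    """Across-animal mean with an SD band, Fig-3 style."""
    fig, ax = plt.subplots(figsize=(6, 3))
    t = summary["time_s"] / 3600.0
    ax.plot(t, summary["mean"], color="crimson")
    ax.fill_between(
        t,
        summary["mean"] - summary["sd"],
        summary["mean"] + summary["sd"],
        alpha=0.3,
        color="crimson",
        linewidth=0,
    )
    ax.set_xlabel("time (h)")
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig


def plot_navigation_index(windows_by_animal: dict[int, np.ndarray], window_min: float, path=None):
    """Per-window navigation index, population mean with SD band."""
    fig, ax = plt.subplots(figsize=(6, 3))
    M = np.vstack([v for v in windows_by_animal.values()])
    t = (np.arange(M.shape[1]) + 0.5) * window_min / 60.0
    mean = np.nanmean(M, axis=0)
    sd = np.nanstd(M, axis=0)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.plot(t, mean, color="navy")
    ax.fill_between(t, mean - sd, mean + sd, alpha=0.3, color="navy", linewidth=0)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("navigation index")
    ax.set_ylim(-1, 1)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig


def plot_occupancy(bin_edges: np.ndarray, population: np.ndarray, individual: np.ndarray, path=None):
    """Population vs mean-of-individual occupancy distributions, Fig-6 style."""
    fig, ax = plt.subplots(figsize=(5, 3))
    c = (bin_edges[:-1] + bin_edges[1:]) / 2
    ax.plot(c, population, color="crimson", label="population")
    ax.plot(c, individual, color="purple", label="mean of individuals")
    ax.set_xlabel("navigation index")
    ax.set_ylabel("probability")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig
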