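"""Plotting helpers for explicit simulation output.

Time series are drawn as right-continuous steps (``drawstyle="steps-post"``)
— the honest rendering of a discrete-event jump process.  Matplotlib is
imported lazily so the package core carries no display dependency.
"""

from __future__ import annotations

import numpy as np

from .analysis import TimeWeightedDistribution
from .trajectory import Trajectory

__all__ = [
    "plot_time_series",
    "plot_propensities",
    "plot_distribution",
    "plot_waiting_time_pdf",
    "plot_autocorrelation",
]


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_time_series(trajectory: Trajectory, species=None, ax=None):
    """Step plot of copy numbers against time."""
    ax = _axes(ax)
    names = species if species is not None else trajectory.species_names
    for name in names:
        ax.plot(trajectory.times, trajectory.species_series(name),
                drawstyle="steps-post", label=name)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("copy number")
    ax.legend(frameon=False)
    return ax


def plot_propensities(trajectory: Trajectory, channels=None, ax=None):
    """Step plot of reaction propensities against time."""
    ax = _axes(ax)
    names = channels if channels is not None else trajectory.reaction_names
    for name in names:
        j = trajectory.reaction_index(name)
        ax.plot(trajectory.times, trajectory.propensities[:, j],
                drawstyle="steps-post", label=name)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("propensity (min$^{-1}$)")
    ax.legend(frameon=False)
    return ax


def plot_distribution(dist: TimeWeightedDistribution, ax=None, label=None, **kwargs):
    """Stem-style plot of a discrete stationary distribution."""
    ax = _axes(ax)
    ax.plot(dist.support, dist.probabilities, marker="o", linestyle="-",
            drawstyle="steps-mid", label=label, **kwargs)
    ax.set_xlabel("value")
    ax.set_ylabel("probability")
    if label:
        ax.legend(frameon=False)
    return ax


def plot_waiting_time_pdf(edges: np.ndarray, density: np.ndarray, ax=None,
                          logx=False, logy=True, label=None):
    """Histogram density of event waiting times (log y by default)."""
    ax = _axes(ax)
    centers = 0.5 * (edges[:-1] + edges[1:])
    ax.plot(centers, density, drawstyle="steps-mid", label=label)
    if logx:
        ax.set_xscale("log")
    if logy:
        ax.set_yscale("log")
    ax.set_xlabel("waiting time (min)")
    ax.set_ylabel("probability density")
    if label:
        ax.legend(frameon=False)
    return ax


def plot_autocorrelation(lags, acf, ax=None, label=None):
    ax = _axes(ax)
    ax.plot(lags, acf, marker="o", label=label)
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("lag (min)")
    ax.set_ylabel("autocorrelation")
    if label:
        ax.legend(frameon=False)
    return ax
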