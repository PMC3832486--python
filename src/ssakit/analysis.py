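"""Statistics on explicit simulation output.

Explicit output (state + propensities at every event) enables statistics
that fixed-interval snapshots cannot provide: event waiting times per
reaction channel, holding-time-weighted stationary distributions of copy
numbers and propensities, their moments, and autocorrelation functions in
physical time.

Stationary estimates are weighted by *holding time* — the duration the
process spends in each state — which is the estimator consistent with the
master equation's stationary measure.  Per-event weighting would bias the
estimate toward fast-switching states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .trajectory import TERMINAL_ROW, Trajectory

__all__ = [
    "TimeWeightedDistribution",
    "MomentSummary",
    "event_waiting_times",
    "species_distribution",
    "propensity_distribution",
    "moments",
    "autocorrelation",
    "regrid_fixed_interval",
    "average_trajectories",
    "windowed_time_average",
    "waiting_time_pdf",
    "total_variation",
]


class AnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class TimeWeightedDistribution:
    """Discrete distribution: value → probability (holding-time weights).

    ``support`` is sorted and distinct; probabilities are non-negative and
    sum to 1.
    """

    support: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "support", np.asarray(self.support, dtype=float))
        object.__setattr__(
            self, "probabilities", np.asarray(self.probabilities, dtype=float)
        )
        if len(self.support) != len(self.probabilities):
            raise AnalysisError("support/probability length mismatch")
        if np.any(np.diff(self.support) <= 0):
            raise AnalysisError("support must be sorted and distinct")
        if np.any(self.probabilities < -1e-15):
            raise AnalysisError("negative probability")
        total = self.probabilities.sum()
        if abs(total - 1.0) > 1e-9:
            raise AnalysisError(f"probabilities sum to {total}, not 1")

    def mean(self) -> float:
        return float(self.support @ self.probabilities)

    def variance(self) -> float:
        mu = self.mean()
        return float(((self.support - mu) ** 2) @ self.probabilities)

    def std(self) -> float:
        return float(np.sqrt(self.variance()))

    def pmf(self, value: float) -> float:
        i = np.searchsorted(self.support, value)
        if i < len(self.support) and self.support[i] == value:
            return float(self.probabilities[i])
        return 0.0

    def scaled(self, factor: float) -> "TimeWeightedDistribution":
        """Distribution of ``factor * X`` (support transform, weights kept)."""
        if factor == 0:
            return TimeWeightedDistribution([0.0], [1.0])
        sup = self.support * factor
        order = np.argsort(sup)
        return TimeWeightedDistribution(sup[order], self.probabilities[order])


def total_variation(p: TimeWeightedDistribution, q) -> float:
    """TV distance ½Σ|p−q| over the union of supports.

    *q* may be another TimeWeightedDistribution or a (support, pmf) pair.
    """
    if isinstance(q, TimeWeightedDistribution):
        q_sup, q_p = q.support, q.probabilities
    else:
        q_sup, q_p = np.asarray(q[0], dtype=float), np.asarray(q[1], dtype=float)
    support = np.union1d(p.support, q_sup)
    pv = np.zeros(len(support))
    qv = np.zeros(len(support))
    pv[np.searchsorted(support, p.support)] = p.probabilities
    qv[np.searchsorted(support, q_sup)] = q_p
    return 0.5 * float(np.abs(pv - qv).sum())


@dataclass(frozen=True)
class MomentSummary:
    """Time-weighted mean, standard deviation, and Fano factor of a species.

    The Fano factor (variance/mean) is None — flagged undefined — when the
    mean is zero; it equals 1 for a Poisson-distributed copy number.
    """

    mean: float
    std: float
    fano: float | None

    @property
    def variance(self) -> float:
        return self.std**2


# ---------------------------------------------------------------------------
# Event waiting times
# ---------------------------------------------------------------------------


def _require_exact(trajectory: Trajectory) -> None:
    if not trajectory.exact:
        raise AnalysisError(
            "event waiting times are undefined for tau-leap output: leaps "
            "aggregate multiple firings; rerun with an exact solver"
        )


def event_waiting_times(trajectory: Trajectory, channel: int | str) -> np.ndarray:
    """Intervals between consecutive firings of one reaction channel.

    The span from t0 to the channel's first firing is excluded — a waiting
    time requires a preceding firing of the same channel.
    """
    _require_exact(trajectory)
    j = trajectory.reaction_index(channel)
    t_fire = trajectory.times[trajectory.fired == j]
    return np.diff(t_fire)


def all_waiting_times(trajectory: Trajectory) -> dict[str, np.ndarray]:
    """Waiting-time lists for every reaction channel, keyed by name."""
    return {
        name: event_waiting_times(trajectory, j)
        for j, name in enumerate(trajectory.reaction_names)
    }


# ---------------------------------------------------------------------------
# Time-weighted distributions and moments
# ---------------------------------------------------------------------------


def _holding_weights(trajectory: Trajectory, burn_in: float) -> tuple[np.ndarray, np.ndarray]:
    """Row indices (state rows) and their holding durations after burn-in.

    Row k's state holds on [t_k, t_{k+1}); the final row has zero holding
    time (time-mode terminal rows exist precisely to close this interval).
    """
    if not 0 <= burn_in < 1:
        raise AnalysisError("burn_in must lie in [0, 1)")
    times = trajectory.times
    if len(times) < 2 or trajectory.duration <= 0:
        raise AnalysisError("zero-duration trajectory")
    t_start = trajectory.t0 + burn_in * trajectory.duration
    # clip each holding interval [t_k, t_{k+1}) below at the burn-in cut
    starts = np.maximum(times[:-1], t_start)
    durations = times[1:] - starts
    durations = np.maximum(durations, 0.0)
    if durations.sum() <= 0:
        raise AnalysisError("no time remains after burn-in")
    return np.arange(len(times) - 1), durations


def _weighted_distribution(values: np.ndarray, weights: np.ndarray) -> TimeWeightedDistribution:
    support, inverse = np.unique(values, return_inverse=True)
    mass = np.bincount(inverse, weights=weights, minlength=len(support))
    return TimeWeightedDistribution(support, mass / mass.sum())


def species_distribution(
    trajectory: Trajectory, species: int | str, burn_in: float = 0.0
) -> TimeWeightedDistribution:
    """Holding-time-weighted copy-number distribution over the observed
    interval (stationary estimate once burn-in has removed the transient)."""
    rows, durations = _holding_weights(trajectory, burn_in)
    values = trajectory.species_series(species)[rows]
    return _weighted_distribution(values, durations)


def propensity_distribution(
    trajectory: Trajectory, channel: int | str, burn_in: float = 0.0
) -> TimeWeightedDistribution:
    """Holding-time-weighted distribution of one channel's propensity.

    For a first-order channel this is the species distribution with the
    support scaled by the rate constant; for a zero-order channel it is a
    point mass at the constant."""
    j = trajectory.reaction_index(channel)
    rows, durations = _holding_weights(trajectory, burn_in)
    values = trajectory.propensities[rows, j]
    return _weighted_distribution(values, durations)


def moments(
    trajectory: Trajectory, species: int | str, burn_in: float = 0.0
) -> MomentSummary:
    """Time-weighted mean, std, and Fano factor of a species copy number."""
    dist = species_distribution(trajectory, species, burn_in)
    mu = dist.mean()
    var = dist.variance()
    fano = var / mu if mu != 0 else None
    return MomentSummary(mean=mu, std=float(np.sqrt(var)), fano=fano)


# ---------------------------------------------------------------------------
# Autocorrelation and regridding
# ---------------------------------------------------------------------------


def autocorrelation(
    trajectory: Trajectory,
    species: int | str,
    lags: list[float],
    grid_dt: float | None = None,
    burn_in: float = 0.0,
) -> np.ndarray:
    """Normalized autocorrelation at the requested time lags.

    The trajectory is resampled to a uniform grid (zero-order hold; default
    spacing = mean inter-event time) and the standard biased ACF estimator
    is evaluated at the nearest grid lag.  ACF(0) = 1 by construction.
    """
    lags = np.asarray(lags, dtype=float)
    if grid_dt is None:
        n_ev = max(trajectory.n_events, 1)
        grid_dt = trajectory.duration / n_ev
    if grid_dt <= 0:
        raise AnalysisError("grid_dt must be positive")
    t_start = trajectory.t0 + burn_in * trajectory.duration
    duration = trajectory.t_end - t_start
    if np.any(lags < 0) or np.any(lags > duration):
        raise AnalysisError("lags must lie within the trajectory duration")
    if duration < 10 * lags.max(initial=0.0):
        warnings.warn(
            "trajectory duration is less than 10× the largest lag; "
            "autocorrelation estimates will be noisy",
            RuntimeWarning,
            stacklevel=2,
        )
    grid = np.arange(t_start, trajectory.t_end, grid_dt)
    i = (
        trajectory.species_index(species)
        if isinstance(species, str)
        else int(species)
    )
    series = trajectory.sample_at(grid)[:, i].astype(float)
    series = series - series.mean()
    var = series @ series / len(series)
    out = np.empty(len(lags))
    for idx, lag in enumerate(lags):
        k = int(round(lag / grid_dt))
        if k == 0:
            out[idx] = 1.0
        elif var == 0:
            out[idx] = np.nan
        else:
            out[idx] = (series[:-k] @ series[k:]) / (len(series) * var)
    return out


def regrid_fixed_interval(
    trajectory: Trajectory, n_intervals: int
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-interval snapshot of the trajectory.

    Returns (grid times, states) with ``n_intervals`` equally spaced sample
    points spanning [t0, t_end]; each sample is the state after the last
    event at or before the sample time (zero-order hold).  This is the
    conventional fixed-interval output other simulators return, provided
    for accuracy comparisons against explicit output.
    """
    if n_intervals < 2:
        raise AnalysisError("n_intervals must be >= 2")
    if len(trajectory.times) == 0:
        raise AnalysisError("empty trajectory")
    grid = np.linspace(trajectory.t0, trajectory.t_end, n_intervals)
    return grid, trajectory.sample_at(grid)


def gridded_distribution(
    trajectory: Trajectory, species: int | str, n_intervals: int, burn_in: float = 0.0
) -> TimeWeightedDistribution:
    """Equal-weight distribution of fixed-interval samples (for comparing
    fixed-interval accuracy against the explicit-output estimate)."""
    grid, states = regrid_fixed_interval(trajectory, n_intervals)
    i = trajectory.species_index(species) if isinstance(species, str) else int(species)
    keep = grid >= trajectory.t0 + burn_in * trajectory.duration
    values = states[keep, i]
    return _weighted_distribution(values, np.ones(len(values)))


def windowed_time_average(
    trajectory: Trajectory, species: int | str, edges: np.ndarray
) -> np.ndarray:
    """Holding-time-weighted mean copy number over consecutive time windows.

    ``edges`` are window boundaries (monotone, within [t0, t_end]).  Used to
    compare an implicit-dilution run against per-generation means of an
    explicit-division lineage with the same estimator on both sides.
    """
    edges = np.asarray(edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise AnalysisError("edges must be increasing with at least one window")
    if edges[0] < trajectory.t0 - 1e-9 or edges[-1] > trajectory.t_end + 1e-9:
        raise AnalysisError("windows must lie within the trajectory span")
    i = trajectory.species_index(species) if isinstance(species, str) else int(species)
    x = trajectory.states[:, i].astype(float)
    times = trajectory.times
    # cumulative integral of the right-continuous step series
    cum = np.concatenate([[0.0], np.cumsum(x[:-1] * np.diff(times))])

    def integral(t):
        k = np.clip(np.searchsorted(times, t, side="right") - 1, 0, len(times) - 1)
        return cum[k] + x[k] * (t - times[k])

    vals = integral(edges)
    return np.diff(vals) / np.diff(edges)


def average_trajectories(
    ensemble: list[Trajectory], species: int | str, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and sd of a species across an ensemble on a common grid."""
    if len(ensemble) < 2:
        raise AnalysisError("need at least 2 trajectories to average")
    names = ensemble[0].species_names
    if any(tr.species_names != names for tr in ensemble):
        raise AnalysisError("ensemble members come from different models")
    i = ensemble[0].species_index(species) if isinstance(species, str) else int(species)
    grid = np.asarray(grid, dtype=float)
    samples = np.stack([tr.sample_at(grid)[:, i] for tr in ensemble]).astype(float)
    return samples.mean(axis=0), samples.std(axis=0, ddof=0)


def waiting_time_pdf(
    intervals: np.ndarray, bins: int = 30, scale: str = "linear"
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized histogram density of event waiting times.

    Returns (bin edges, density).  ``scale="log"`` uses logarithmically
    spaced bins, appropriate for two-timescale distributions such as bursty
    transcription waiting times.
    """
    intervals = np.asarray(intervals, dtype=float)
    if len(intervals) == 0:
        raise AnalysisError("empty interval list")
    if len(intervals) < 10:
        warnings.warn(
            f"only {len(intervals)} waiting times; density estimate unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    if scale == "log":
        lo, hi = intervals.min(), intervals.max()
        if lo <= 0:
            raise AnalysisError("log binning requires positive intervals")
        edges = np.geomspace(lo, hi, bins + 1)
    elif scale == "linear":
        edges = np.linspace(0.0, intervals.max(), bins + 1)
    else:
        raise AnalysisError(f"unknown bin scale {scale!r}")
    density, edges = np.histogram(intervals, bins=edges, density=True)
    return edges, density
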