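"""Explicit-output trajectory container.

A trajectory records the full system state and propensity vector at every
reaction event — not at fixed sampling intervals.  Row 0 holds the initial
condition (fired index −1).  Trajectories produced in time mode carry a
terminal non-event row at exactly t_end (fired index −2) so that
holding-time-weighted statistics cover the whole simulated interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trajectory", "INITIAL_ROW", "TERMINAL_ROW"]

INITIAL_ROW = -1
TERMINAL_ROW = -2


@dataclass
class Trajectory:
    """Event-indexed record of a stochastic simulation.

    Attributes
    ----------
    times : (n_rows,) float array, strictly increasing
    states : (n_rows, n_species) int array; row k is the state *after* the
        k-th recorded event (row 0 = initial state)
    propensities : (n_rows, n_reactions) float array evaluated at the
        recorded state
    fired : (n_rows,) int array of fired reaction indices; −1 for the
        initial row, −2 for a terminal time-mode marker row
    exact : False for tau-leap output, where ``firings`` holds per-leap
        Poisson firing counts instead of a single fired index
    absorbed : True if the simulation halted because all propensities
        reached zero
    """

    times: np.ndarray
    states: np.ndarray
    propensities: np.ndarray
    fired: np.ndarray
    species_names: list[str]
    reaction_names: list[str]
    exact: bool = True
    absorbed: bool = False
    firings: np.ndarray | None = None
    model_ref: str = "model"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=np.int64)
        self.propensities = np.asarray(self.propensities, dtype=float)
        self.fired = np.asarray(self.fired, dtype=np.int64)
        n = len(self.times)
        if self.states.shape[0] != n or self.propensities.shape[0] != n:
            raise ValueError("times/states/propensities row counts differ")
        if len(self.fired) != n:
            raise ValueError("fired length does not match times")
        if n and np.any(np.diff(self.times) <= 0):
            # the terminal marker row may coincide with the last event time
            bad = np.flatnonzero(np.diff(self.times) <= 0)
            ok = (
                len(bad) == 1
                and bad[0] == n - 2
                and self.fired[-1] == TERMINAL_ROW
                and self.times[-1] == self.times[-2]
            )
            if not ok:
                raise ValueError("times must be strictly increasing")
        if np.any(self.states < 0):
            raise ValueError("negative copy number in trajectory")

    @property
    def n_events(self) -> int:
        """Number of recorded reaction events (excludes initial/terminal rows)."""
        if not self.exact and self.firings is not None:
            return int(len(self.times) - 1 - (self.fired == TERMINAL_ROW).sum())
        return int((self.fired >= 0).sum())

    @property
    def t0(self) -> float:
        return float(self.times[0])

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    @property
    def duration(self) -> float:
        return self.t_end - self.t0

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def reaction_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            try:
                return self.reaction_names.index(channel)
            except ValueError:
                raise KeyError(f"unknown reaction channel {channel!r}") from None
        if not 0 <= channel < len(self.reaction_names):
            raise KeyError(f"unknown reaction channel {channel}")
        return int(channel)

    def species_series(self, species: int | str) -> np.ndarray:
        i = self.species_index(species) if isinstance(species, str) else int(species)
        return self.states[:, i]

    def sample_at(self, grid: np.ndarray) -> np.ndarray:
        """Zero-order-hold state samples at the given times (right-continuous)."""
        grid = np.asarray(grid, dtype=float)
        idx = np.searchsorted(self.times, grid, side="right") - 1
        idx = np.clip(idx, 0, len(self.times) - 1)
        return self.states[idx]

    def __repr__(self) -> str:  # pragma: no cover
        kind = "exact" if self.exact else "tau-leap"
        return (
            f"<Trajectory {self.model_ref}: {self.n_events} events, "
            f"t∈[{self.t0:g}, {self.t_end:g}], {kind}"
            f"{', absorbed' if self.absorbed else ''}>"
        )
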