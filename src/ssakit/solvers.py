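"""Exact and approximate stochastic simulation algorithms.

All solvers produce explicit output: a :class:`~ssakit.trajectory.Trajectory`
with the state and propensity vectors recorded at every reaction event.

* ``direct`` — Gillespie's direct method: τ ~ Exp(a0), channel j w.p. a_j/a0.
* ``first_reaction`` — one candidate time per channel, fire the minimum.
* ``next_reaction`` — Gibson–Bruck: absolute putative times in an indexed
  priority queue, dependency-graph updates, putative-time reuse by
  propensity-ratio rescaling.
* ``tau_leap`` — adaptive explicit tau-leaping with the Cao et al. (2006)
  step-size selection and critical-reaction partitioning; leap rows carry a
  firing-count vector and the trajectory is marked non-exact.

Determinism: identical (model, settings, seed) produce bit-identical
trajectories; ensemble member k draws from an independent stream spawned
from (seed, k).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .model import CompiledModel, MassAction, Model
from .trajectory import INITIAL_ROW, TERMINAL_ROW, Trajectory

__all__ = [
    "SolverSettings",
    "build_dependency_graph",
    "simulate",
    "simulate_direct",
    "simulate_first_reaction",
    "simulate_next_reaction",
    "simulate_tau_leap",
    "run_ensemble",
]

_SOLVER_ALIASES = {
    "direct": "direct",
    "first": "first_reaction",
    "first_reaction": "first_reaction",
    "next": "next_reaction",
    "next_reaction": "next_reaction",
    "tau": "tau_leap",
    "tau_leap": "tau_leap",
}


@dataclass(frozen=True)
class SolverSettings:
    """Simulation run configuration.

    ``end`` is a step count (``mode="steps"``) or an end time
    (``mode="time"``).  ``tau_epsilon`` bounds the expected relative change
    of each propensity per leap; channels within ``critical_threshold``
    firings of exhausting a reactant are simulated exactly inside a leap.
    """

    end: float
    mode: Literal["steps", "time"] = "steps"
    n_trajectories: int = 1
    seed: int | None = None
    solver: str = "direct"
    tau_epsilon: float = 0.03
    critical_threshold: int = 10

    def __post_init__(self):
        if self.end <= 0:
            raise ValueError("end must be positive")
        if self.mode not in ("steps", "time"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "steps" and self.end != int(self.end):
            raise ValueError("steps mode requires an integer end value")
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be >= 1")
        if self.solver not in _SOLVER_ALIASES:
            raise ValueError(f"unknown solver {self.solver!r}")
        if not 0 < self.tau_epsilon < 1:
            raise ValueError("tau_epsilon must lie in (0, 1)")
        if self.critical_threshold < 0:
            raise ValueError("critical_threshold must be >= 0")

    @property
    def canonical_solver(self) -> str:
        return _SOLVER_ALIASES[self.solver]


def build_dependency_graph(model: Model | CompiledModel) -> list[frozenset[int]]:
    """``affects[i]`` = reactions whose propensity may change when i fires.

    Reaction j is affected by i iff the species i changes intersect the
    species j's rate law reads; every reaction affects itself.
    """
    cm = model if isinstance(model, CompiledModel) else model.compile()
    changes = [frozenset(np.flatnonzero(cm.net[i]).tolist()) for i in range(cm.n_reactions)]
    affects = []
    for i in range(cm.n_reactions):
        deps = {i}
        for j in range(cm.n_reactions):
            if changes[i] & cm.read_sets[j]:
                deps.add(j)
        affects.append(frozenset(deps))
    return affects


class _Recorder:
    """Growable column store for trajectory rows."""

    def __init__(self, n_species: int, n_reactions: int, with_firings: bool = False):
        cap = 1024
        self.t = np.empty(cap)
        self.s = np.empty((cap, n_species), dtype=np.int64)
        self.a = np.empty((cap, n_reactions))
        self.f = np.empty(cap, dtype=np.int64)
        self.k = np.zeros((cap, n_reactions), dtype=np.int64) if with_firings else None
        self.n = 0

    def _grow(self):
        cap = 2 * len(self.t)
        self.t = np.resize(self.t, cap)
        self.s = np.resize(self.s, (cap, self.s.shape[1]))
        self.a = np.resize(self.a, (cap, self.a.shape[1]))
        self.f = np.resize(self.f, cap)
        if self.k is not None:
            self.k = np.resize(self.k, (cap, self.k.shape[1]))

    def append(self, t, state, props, fired, firings=None):
        if self.n == len(self.t):
            self._grow()
        i = self.n
        self.t[i] = t
        self.s[i] = state
        self.a[i] = props
        self.f[i] = fired
        if self.k is not None:
            self.k[i] = 0 if firings is None else firings
        self.n += 1

    def finish(self, model: Model, exact: bool, absorbed: bool) -> Trajectory:
        n = self.n
        return Trajectory(
            times=self.t[:n].copy(),
            states=self.s[:n].copy(),
            propensities=self.a[:n].copy(),
            fired=self.f[:n].copy(),
            species_names=model.species_names,
            reaction_names=model.reaction_names,
            exact=exact,
            absorbed=absorbed,
            firings=None if self.k is None else self.k[:n].copy(),
            model_ref=model.name,
        )


# ---------------------------------------------------------------------------
# Exact solvers
# ---------------------------------------------------------------------------


def _core_direct(cm, state, t, end, mode, rng, rec):
    a = cm.propensities(state)
    rec.append(t, state, a, INITIAL_ROW)
    steps = 0
    absorbed = False
    while True:
        a0 = a.sum()
        if a0 <= 0.0:
            absorbed = True
            break
        tau = rng.exponential() / a0
        if mode == "time" and t + tau > end:
            break
        t = t + tau
        j = int(np.searchsorted(a.cumsum(), rng.random() * a0, side="right"))
        j = min(j, len(a) - 1)  # guard against roundoff at the upper edge
        state = state + cm.net[j]
        a = cm.propensities(state)
        rec.append(t, state, a, j)
        steps += 1
        if mode == "steps" and steps >= end:
            break
    return state, t, absorbed


def _core_first_reaction(cm, state, t, end, mode, rng, rec):
    m = cm.n_reactions
    a = cm.propensities(state)
    rec.append(t, state, a, INITIAL_ROW)
    steps = 0
    absorbed = False
    while True:
        with np.errstate(divide="ignore"):
            taus = np.where(a > 0.0, rng.exponential(size=m) / np.where(a > 0, a, 1.0), np.inf)
        j = int(np.argmin(taus))  # ties resolve to the lowest index
        tau = taus[j]
        if not np.isfinite(tau):
            absorbed = True
            break
        if mode == "time" and t + tau > end:
            break
        t = t + tau
        state = state + cm.net[j]
        a = cm.propensities(state)
        rec.append(t, state, a, j)
        steps += 1
        if mode == "steps" and steps >= end:
            break
    return state, t, absorbed


class IndexedPriorityQueue:
    """Binary min-heap over reaction indices keyed by putative firing times,
    with an index→position table for O(log m) keyed updates (Gibson–Bruck)."""

    def __init__(self, values: Sequence[float]):
        self.val = list(map(float, values))
        m = len(self.val)
        self.heap = list(range(m))
        self.pos = list(range(m))
        for i in range(m // 2 - 1, -1, -1):
            self._sift_down(i)

    def top(self) -> tuple[float, int]:
        j = self.heap[0]
        return self.val[j], j

    def update(self, index: int, value: float) -> None:
        old = self.val[index]
        self.val[index] = value
        p = self.pos[index]
        if value < old:
            self._sift_up(p)
        else:
            self._sift_down(p)

    def _swap(self, i, j):
        h = self.heap
        h[i], h[j] = h[j], h[i]
        self.pos[h[i]] = i
        self.pos[h[j]] = j

    def _sift_up(self, i):
        while i > 0:
            parent = (i - 1) // 2
            if self.val[self.heap[i]] < self.val[self.heap[parent]]:
                self._swap(i, parent)
                i = parent
            else:
                break

    def _sift_down(self, i):
        m = len(self.heap)
        while True:
            left, right = 2 * i + 1, 2 * i + 2
            best = i
            if left < m and self.val[self.heap[left]] < self.val[self.heap[best]]:
                best = left
            if right < m and self.val[self.heap[right]] < self.val[self.heap[best]]:
                best = right
            if best == i:
                break
            self._swap(i, best)
            i = best


def _core_next_reaction(cm, state, t, end, mode, rng, rec):
    m = cm.n_reactions
    affects = build_dependency_graph(cm)
    a = cm.propensities(state)
    rec.append(t, state, a, INITIAL_ROW)
    putative = [t + rng.exponential() / a[j] if a[j] > 0 else math.inf for j in range(m)]
    ipq = IndexedPriorityQueue(putative)
    steps = 0
    absorbed = False
    while True:
        t_next, mu = ipq.top()
        if not math.isfinite(t_next):
            absorbed = True
            break
        if mode == "time" and t_next > end:
            break
        t = t_next
        state = state + cm.net[mu]
        for j in affects[mu]:
            a_new = cm.propensity(j, state)
            a_old = a[j]
            if j == mu:
                t_j = t + rng.exponential() / a_new if a_new > 0 else math.inf
            elif a_new <= 0:
                t_j = math.inf
            elif a_old > 0 and math.isfinite(ipq.val[j]):
                # reuse the pending exponential: rescale the residual time
                t_j = t + (a_old / a_new) * (ipq.val[j] - t)
            else:
                # channel re-activated from zero propensity: fresh clock
                t_j = t + rng.exponential() / a_new
            a[j] = a_new
            ipq.update(j, t_j)
        rec.append(t, state, a, mu)
        steps += 1
        if mode == "steps" and steps >= end:
            break
    return state, t, absorbed


# ---------------------------------------------------------------------------
# Tau-leaping
# ---------------------------------------------------------------------------


def _hor_g_factors(cm: CompiledModel, state: np.ndarray) -> np.ndarray:
    """Cao et al. g_i factors from the highest order of reaction in which
    each species appears as a reactant (expression-law reads count as order 1)."""
    n = cm.n_species
    g = np.ones(n)
    for j, r in enumerate(cm.model.reactions):
        if isinstance(r.rate_law, MassAction):
            order = sum(r.reactants.values())
            for sp, mult in r.reactants.items():
                i = cm.model.species_index(sp)
                x = max(int(state[i]), mult)
                if order == 1:
                    gj = 1.0
                elif order == 2:
                    gj = 2.0 if mult == 1 else 2.0 + 1.0 / max(x - 1, 1)
                else:
                    gj = 3.0 if mult == 1 else 3.0 + 1.0 / max(x - 1, 1)
                g[i] = max(g[i], gj)
        else:
            for i in cm.read_sets[j]:
                g[i] = max(g[i], 1.0)
    return g


def _core_tau_leap(cm, state, t, end, mode, rng, rec, eps, nc):
    m = cm.n_reactions
    consumed = np.maximum(-cm.net, 0)  # consumption per firing, per species
    a = cm.propensities(state)
    rec.append(t, state, a, INITIAL_ROW)
    steps = 0
    absorbed = False
    read_any = sorted(set().union(*cm.read_sets)) if m else []
    while True:
        a0 = a.sum()
        if a0 <= 0.0:
            absorbed = True
            break
        # critical channels: could exhaust a reactant within nc firings
        critical = np.zeros(m, dtype=bool)
        for j in range(m):
            if a[j] <= 0:
                continue
            cons = consumed[j]
            used = np.flatnonzero(cons)
            if used.size:
                l_j = np.min(state[used] // cons[used])
                if l_j < nc:
                    critical[j] = True
        ncr = ~critical & (a > 0)
        if ncr.any():
            g = _hor_g_factors(cm, state)
            mu = cm.net[ncr].T @ a[ncr]
            sig2 = (cm.net[ncr] ** 2).T @ a[ncr]
            tau1 = math.inf
            for i in read_any:
                bound = max(eps * state[i] / g[i], 1.0)
                if mu[i] != 0:
                    tau1 = min(tau1, bound / abs(mu[i]))
                if sig2[i] > 0:
                    tau1 = min(tau1, bound * bound / sig2[i])
        else:
            tau1 = math.inf
        if tau1 < 10.0 / a0:
            # leap would be smaller than a few exact steps: fall back to SSA
            done = False
            for _ in range(100):
                a0 = a.sum()
                if a0 <= 0.0:
                    absorbed = True
                    done = True
                    break
                tau = rng.exponential() / a0
                if mode == "time" and t + tau > end:
                    done = True
                    break
                t = t + tau
                j = int(np.searchsorted(a.cumsum(), rng.random() * a0, side="right"))
                j = min(j, m - 1)
                state = state + cm.net[j]
                a = cm.propensities(state)
                unit = np.zeros(m, dtype=np.int64)
                unit[j] = 1
                rec.append(t, state, a, INITIAL_ROW, firings=unit)
                steps += 1
                if mode == "steps" and steps >= end:
                    done = True
                    break
            if done:
                break
            continue
        a0c = a[critical].sum()
        tau2 = rng.exponential() / a0c if a0c > 0 else math.inf
        fire_critical = tau2 <= tau1
        tau = min(tau1, tau2)
        capped = False
        if mode == "time" and t + tau > end:
            tau = end - t
            capped = True
            fire_critical = False
        # draw firing counts; halve tau and redraw if any population would go negative
        for _attempt in range(64):
            k = np.zeros(m, dtype=np.int64)
            if ncr.any():
                k[ncr] = rng.poisson(a[ncr] * tau)
            if fire_critical:
                ac = np.where(critical, a, 0.0)
                jc = int(np.searchsorted(ac.cumsum(), rng.random() * ac.sum(), side="right"))
                jc = min(jc, m - 1)
                k[jc] += 1
            new_state = state + k @ cm.net
            if np.all(new_state >= 0):
                break
            tau = tau / 2.0
            capped = False
            fire_critical = False
        else:
            raise RuntimeError("tau-leap could not find a non-negative step")
        t = t + tau
        state = new_state
        a = cm.propensities(state)
        rec.append(t, state, a, INITIAL_ROW, firings=k)
        steps += 1
        if mode == "steps" and steps >= end:
            break
        if capped:
            break
    return state, t, absorbed


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------


def _run(model: Model, settings: SolverSettings, rng: np.random.Generator,
         state0: np.ndarray | None = None, t0: float = 0.0) -> Trajectory:
    cm = model.compile()
    state = model.initial_state() if state0 is None else np.asarray(state0, dtype=np.int64)
    if np.any(state < 0):
        raise ValueError("negative initial state")
    solver = settings.canonical_solver
    exact = solver != "tau_leap"
    rec = _Recorder(cm.n_species, cm.n_reactions, with_firings=not exact)
    end = settings.end if settings.mode == "steps" else t0 + settings.end
    if solver == "direct":
        state, t, absorbed = _core_direct(cm, state, t0, end, settings.mode, rng, rec)
    elif solver == "first_reaction":
        state, t, absorbed = _core_first_reaction(cm, state, t0, end, settings.mode, rng, rec)
    elif solver == "next_reaction":
        state, t, absorbed = _core_next_reaction(cm, state, t0, end, settings.mode, rng, rec)
    else:
        state, t, absorbed = _core_tau_leap(
            cm, state, t0, end, settings.mode, rng, rec,
            settings.tau_epsilon, settings.critical_threshold,
        )
    if settings.mode == "time" and rec.t[rec.n - 1] < end:
        # terminal non-event row: carries the final state out to exactly t_end
        rec.append(end, state, rec.a[rec.n - 1], TERMINAL_ROW)
    return rec.finish(model, exact=exact, absorbed=absorbed)


def simulate(model: Model, settings: SolverSettings) -> Trajectory:
    """Run a single trajectory with the solver named in *settings*."""
    rng = np.random.default_rng(settings.seed)
    return _run(model, settings, rng)


def simulate_direct(model: Model, settings: SolverSettings) -> Trajectory:
    return simulate(model, replace(settings, solver="direct"))


def simulate_first_reaction(model: Model, settings: SolverSettings) -> Trajectory:
    return simulate(model, replace(settings, solver="first_reaction"))


def simulate_next_reaction(model: Model, settings: SolverSettings) -> Trajectory:
    return simulate(model, replace(settings, solver="next_reaction"))


def simulate_tau_leap(model: Model, settings: SolverSettings) -> Trajectory:
    return simulate(model, replace(settings, solver="tau_leap"))


def run_segment(
    model: Model,
    state: np.ndarray,
    t0: float,
    t_end: float,
    rng: np.random.Generator,
    solver: str = "direct",
) -> Trajectory:
    """Continue an exact simulation from (t0, state) until t_end.

    Used by the cell-division driver; the returned segment always covers
    [t0, t_end] (terminal marker row included)."""
    if _SOLVER_ALIASES[solver] == "tau_leap":
        raise ValueError("segments require an exact solver")
    settings = SolverSettings(end=t_end - t0, mode="time", solver=solver)
    return _run(model, settings, rng, state0=state, t0=t0)


def run_ensemble(model: Model, settings: SolverSettings) -> list[Trajectory]:
    """Simulate ``settings.n_trajectories`` independent trajectories.

    Member k uses a dedicated stream spawned from (seed, k), so ensembles
    are reproducible and members are statistically independent.
    """
    streams = np.random.SeedSequence(settings.seed).spawn(settings.n_trajectories)
    return [_run(model, settings, np.random.default_rng(s)) for s in streams]
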