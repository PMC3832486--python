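"""Cell division on top of exact stochastic simulation.

Two formulations of growth and division of a single cell lineage:

* **explicit** — sequential simulation: run the network until the next
  division time (gamma-distributed by default), binomially partition the
  molecular content between two daughters, follow one daughter, repeat.
* **implicit** — dilution: add a first-order degradation reaction per
  dilutable species with rate equal to the population growth rate, and
  simulate a single uninterrupted trajectory.

Interrupting the SSA at a division time is exact for exponential reaction
clocks (memorylessness): the pending event is discarded and propensities
are recomputed from the post-partition state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import MassAction, Model, ModelError, Reaction
from .solvers import SolverSettings, run_segment
from .trajectory import Trajectory

__all__ = [
    "DivisionSettings",
    "PartitionRecord",
    "DivisionLineage",
    "sample_division_interval",
    "binomial_partition",
    "simulate_with_divisions",
    "add_dilution",
]


@dataclass(frozen=True)
class DivisionSettings:
    """Division-timing and partitioning configuration.

    Inter-division intervals are Gamma(shape, scale) minutes; shape 1.0 /
    scale 60.0 gives exponentially distributed generation times with a one
    hour mean.  At division each molecule of a partitioned species goes to
    the tracked daughter with probability ``partition_probability``.
    Exactly one of ``end_generations`` / ``end_time`` must be set.

    ``fixed_interval`` replaces the gamma draw with the deterministic mean
    (shape·scale); ``deterministic_halving`` replaces the binomial split
    with exact halving, alternating floor/ceil for odd copy numbers — the
    fixed-generation-time convention of earlier whole-cell models.
    """

    shape: float = 1.0
    scale: float = 60.0
    partition_probability: float = 0.5
    end_generations: int | None = None
    end_time: float | None = None
    fixed_interval: bool = False
    deterministic_halving: bool = False

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma shape and scale must be positive")
        if not 0 < self.partition_probability < 1:
            raise ValueError("partition_probability must lie in (0, 1)")
        if (self.end_generations is None) == (self.end_time is None):
            raise ValueError("set exactly one of end_generations / end_time")
        if self.end_generations is not None and self.end_generations < 1:
            raise ValueError("end_generations must be >= 1")
        if self.end_time is not None and self.end_time <= 0:
            raise ValueError("end_time must be positive")

    @property
    def mean_interval(self) -> float:
        return self.shape * self.scale


@dataclass(frozen=True)
class PartitionRecord:
    """State bookkeeping for one division event."""

    time: float
    mother: np.ndarray
    daughter: np.ndarray
    discarded: np.ndarray


@dataclass
class DivisionLineage:
    """Concatenated single-lineage simulation across cell generations.

    ``segments[g]`` covers generation g on the global (continuous) time
    axis; ``division_times`` are the g → g+1 boundaries, and
    ``partition_records[g]`` holds the mother/daughter/discarded states.
    """

    segments: list[Trajectory]
    division_times: list[float]
    partition_records: list[PartitionRecord]
    species_names: list[str] = field(default_factory=list)

    @property
    def n_generations(self) -> int:
        return len(self.segments)

    def generation_means(self, species: int | str) -> np.ndarray:
        """Per-generation holding-time-weighted mean copy number."""
        from .analysis import moments

        return np.array([moments(seg, species).mean for seg in self.segments])

    def concatenated_series(self, species: int | str) -> tuple[np.ndarray, np.ndarray]:
        """(times, copy numbers) across all generations, division jumps included."""
        ts, xs = [], []
        for seg in self.segments:
            i = seg.species_index(species) if isinstance(species, str) else int(species)
            ts.append(seg.times)
            xs.append(seg.states[:, i])
        return np.concatenate(ts), np.concatenate(xs)


def sample_division_interval(
    settings: DivisionSettings, rng: np.random.Generator
) -> float:
    """One inter-division time draw (gamma, or the fixed mean interval)."""
    if settings.fixed_interval:
        return settings.mean_interval
    return float(rng.gamma(settings.shape, settings.scale))


def binomial_partition(
    state: np.ndarray,
    settings: DivisionSettings,
    rng: np.random.Generator,
    partition_mask: np.ndarray | None = None,
    halving_phase: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition a mother state over two daughters.

    Partitioned species n → tracked daughter ~ Binomial(n, p), discarded
    daughter n − tracked (exact conservation).  Species excluded by
    ``partition_mask`` pass unchanged to both daughters (the tracked
    daughter keeps the copy — gene/DNA semantics).  With
    ``deterministic_halving`` odd copies alternate floor/ceil via
    ``halving_phase``.
    """
    state = np.asarray(state)
    if np.any(state < 0) or not np.issubdtype(state.dtype, np.integer):
        raise ValueError("state must be non-negative integers")
    if partition_mask is None:
        partition_mask = np.ones(len(state), dtype=bool)
    daughter = state.copy()
    discarded = state.copy()
    idx = np.flatnonzero(partition_mask)
    if settings.deterministic_halving:
        half = state[idx] // 2
        odd = state[idx] % 2
        keep_extra = odd if halving_phase % 2 == 0 else np.zeros_like(odd)
        daughter[idx] = half + keep_extra
    else:
        daughter[idx] = rng.binomial(state[idx], settings.partition_probability)
    discarded[idx] = state[idx] - daughter[idx]
    return daughter, discarded


def simulate_with_divisions(
    model: Model,
    solver_settings: SolverSettings,
    division_settings: DivisionSettings,
) -> DivisionLineage:
    """Explicit sequential single-lineage simulation with division events.

    Each generation is simulated with the exact solver named in
    ``solver_settings`` until the sampled division time, the state is
    partitioned, and simulation continues with the tracked daughter.
    Species with ``partition_at_division=False`` (and fixed species) are
    carried over unchanged.
    """
    if solver_settings.canonical_solver == "tau_leap":
        raise ValueError("explicit division requires an exact solver")
    rng = np.random.default_rng(solver_settings.seed)
    mask = np.array(
        [sp.partition_at_division and not sp.fixed for sp in model.species],
        dtype=bool,
    )
    state = model.initial_state()
    t = 0.0
    ds = division_settings
    segments: list[Trajectory] = []
    division_times: list[float] = []
    records: list[PartitionRecord] = []
    generation = 0
    while True:
        interval = sample_division_interval(ds, rng)
        t_div = t + interval
        if ds.end_time is not None and t_div >= ds.end_time:
            if ds.end_time > t:
                segments.append(
                    run_segment(model, state, t, ds.end_time, rng,
                                solver_settings.canonical_solver)
                )
            break
        seg = run_segment(model, state, t, t_div, rng, solver_settings.canonical_solver)
        segments.append(seg)
        mother = seg.states[-1].copy()
        daughter, discarded = binomial_partition(
            mother, ds, rng, partition_mask=mask, halving_phase=generation
        )
        division_times.append(t_div)
        records.append(PartitionRecord(t_div, mother, daughter, discarded))
        state = daughter
        t = t_div
        generation += 1
        if ds.end_generations is not None and generation >= ds.end_generations:
            break
    return DivisionLineage(segments, division_times, records, model.species_names)


def add_dilution(model: Model, growth_rate: float, suffix: str = "_dilution") -> Model:
    """Implicit division: first-order loss at the growth rate per species.

    Returns a new model with one added degradation reaction per dilutable
    species (partitioning, non-fixed); the input model is untouched.  With
    growth rate ln 2 / mean generation time this approximates balanced
    exponential growth without discrete division events.
    """
    if growth_rate <= 0:
        raise ValueError("growth_rate must be positive")
    existing = set(model.reaction_names)
    new_reactions = list(model.reactions)
    for sp in model.species:
        if sp.fixed or not sp.partition_at_division:
            continue
        rname = f"{sp.name}{suffix}"
        if rname in existing:
            raise ModelError(f"dilution reaction name {rname!r} collides")
        new_reactions.append(
            Reaction(rname, {sp.name: 1}, {}, MassAction(growth_rate))
        )
    return Model(
        model.species, new_reactions, model.parameters, name=f"{model.name}+dilution"
    )
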