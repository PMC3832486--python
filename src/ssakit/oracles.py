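"""Independent numeric oracles: truncated master equation, phase-type
waiting-time laws, and closed forms for the linear birth–death process.

These provide reference answers for validating simulation output:

* :class:`TruncatedCME` enumerates the state space up to per-species caps,
  assembles the sparse generator Q, and solves Qᵀp = 0 for the stationary
  distribution.
* :func:`phase_type_waiting_pdf` gives the density of the absorption time
  of a transient Markov chain — the law of inter-event waiting times for a
  monitored reaction channel.
* :func:`analytic_poisson` / :func:`analytic_acf` are the closed forms for
  the immigration-death (linear birth–death) process: Poisson(ksyn/kd)
  stationary law and exp(−kd·τ) autocorrelation.
"""

from __future__ import annotations

from typing import Callable, Mapping

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import stats

from .analysis import TimeWeightedDistribution
from .model import Model

__all__ = [
    "TruncatedCME",
    "cme_stationary",
    "analytic_poisson",
    "analytic_acf",
    "phase_type_waiting_pdf",
    "phase_type_cdf",
    "enzyme_turnover_phase_type",
    "gene_synthesis_phase_type",
    "log_slope",
]


class OracleError(ValueError):
    pass


class TruncatedCME:
    """Truncated chemical-master-equation generator for a model.

    The state space is the product of ``0..cap`` for every non-fixed
    species (fixed species are held at their initial copy number).
    Transitions leaving the truncated space are dropped; the probability
    mass accumulating at the truncation boundary measures the adequacy of
    the caps.
    """

    def __init__(self, model: Model, caps: Mapping[str, int] | int):
        self.model = model
        cm = model.compile()
        free = [i for i, spc in enumerate(model.species) if not spc.fixed]
        if isinstance(caps, int):
            caps = {model.species[i].name: caps for i in free}
        self.caps = {name: int(caps[name]) for name in (model.species[i].name for i in free)}
        cap_vec = np.array([self.caps[model.species[i].name] for i in free])
        self._free = free
        self._caps_vec = cap_vec

        # breadth-first reachability from the initial state within the caps:
        # unreachable states would make the generator reducible (singular)
        init = model.initial_state()
        if np.any(init[free] > cap_vec):
            raise OracleError("initial state exceeds the truncation caps")
        index: dict[tuple, int] = {tuple(init): 0}
        states = [init.copy()]
        rows, cols, vals = [], [], []
        diag = [0.0]
        truncated = [False]
        head = 0
        while head < len(states):
            s = states[head]
            for j in range(cm.n_reactions):
                a = cm.propensity(j, s)
                if a <= 0.0:
                    continue
                target = s + cm.net[j]
                if np.any(target < 0):
                    continue
                if np.any(target[free] > cap_vec):
                    truncated[head] = True  # reflecting truncation: edge dropped
                    continue
                key = tuple(target)
                k = index.get(key)
                if k is None:
                    k = len(states)
                    if k >= 10**6:
                        raise OracleError("truncated space too large (>1e6 states)")
                    index[key] = k
                    states.append(target)
                    diag.append(0.0)
                    truncated.append(False)
                rows.append(head)
                cols.append(k)
                vals.append(a)
                diag[head] -= a
            head += 1
        n_states = len(states)
        self.states = np.array(states)
        self._truncated = np.array(truncated)
        rows.extend(range(n_states))
        cols.extend(range(n_states))
        vals.extend(diag)
        self.Q = sp.coo_matrix(
            (vals, (rows, cols)), shape=(n_states, n_states)
        ).tocsr()
        self._p: np.ndarray | None = None

    def stationary(self) -> np.ndarray:
        """Stationary probability vector: normalized null vector of Qᵀ."""
        if self._p is None:
            n = self.Q.shape[0]
            A = self.Q.T.tolil()
            A[n - 1] = np.ones(n)  # replace one balance equation by normalization
            b = np.zeros(n)
            b[n - 1] = 1.0
            p = spla.spsolve(A.tocsr(), b)
            p = np.clip(p, 0.0, None)
            self._p = p / p.sum()
        return self._p

    def boundary_mass(self) -> float:
        """Stationary mass on states with at least one truncation-dropped edge."""
        p = self.stationary()
        return float(p[self._truncated].sum())

    def marginal(self, species: str) -> TimeWeightedDistribution:
        p = self.stationary()
        i = self.model.species_index(species)
        values = self.states[:, i]
        support = np.arange(values.max() + 1)
        mass = np.bincount(values, weights=p, minlength=len(support))
        return TimeWeightedDistribution(support, mass / mass.sum())

    def mean(self, species: str) -> float:
        return self.marginal(species).mean()


def cme_stationary(
    model: Model,
    caps: Mapping[str, int] | int,
    boundary_tol: float = 1e-6,
    boundary_max: float = 1e-4,
) -> TruncatedCME:
    """Solve the truncated CME and check the truncation is adequate.

    Emits a warning if the boundary mass exceeds ``boundary_tol`` and raises
    if it exceeds ``boundary_max``.
    """
    cme = TruncatedCME(model, caps)
    bm = cme.boundary_mass()
    if bm > boundary_max:
        raise OracleError(
            f"truncation boundary holds probability {bm:.3g} > {boundary_max:g}; "
            "increase the caps"
        )
    if bm > boundary_tol:
        import warnings

        warnings.warn(
            f"truncation boundary mass {bm:.3g} exceeds {boundary_tol:g}",
            RuntimeWarning,
            stacklevel=2,
        )
    return cme


def analytic_poisson(
    mean: float, support: np.ndarray | int, normalized: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson pmf on a finite support (the immigration-death stationary law).

    ``support`` may be an array of copy numbers or an int upper bound
    (inclusive, starting at 0).  With ``normalized=True`` the truncated pmf
    is renormalized to sum to 1.
    """
    if mean <= 0:
        raise OracleError("mean must be positive")
    if np.isscalar(support):
        support = np.arange(int(support) + 1)
    support = np.asarray(support)
    pmf = stats.poisson.pmf(support, mean)
    if normalized:
        pmf = pmf / pmf.sum()
    return support, pmf


def analytic_acf(kd: float, lag: np.ndarray | float) -> np.ndarray | float:
    """Stationary autocorrelation exp(−kd·lag) of the linear birth–death
    process (decay rate sets the correlation time, 1/kd)."""
    if kd <= 0:
        raise OracleError("kd must be positive")
    return np.exp(-kd * np.asarray(lag, dtype=float))


# ---------------------------------------------------------------------------
# Phase-type waiting-time laws
# ---------------------------------------------------------------------------


def _validate_subgenerator(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise OracleError("sub-generator must be square")
    off = S - np.diag(np.diag(S))
    if np.any(off < -1e-12):
        raise OracleError("sub-generator off-diagonals must be non-negative")
    row_sums = S.sum(axis=1)
    if np.any(row_sums > 1e-9):
        raise OracleError("non-conservative sub-generator: positive row sum")
    if np.all(np.abs(row_sums) < 1e-12):
        raise OracleError("sub-generator has no exit rates: not a transient chain")
    return S


def _phase_type_terms(S: np.ndarray, alpha: np.ndarray):
    S = _validate_subgenerator(S)
    alpha = np.asarray(alpha, dtype=float)
    if len(alpha) != S.shape[0] or abs(alpha.sum() - 1.0) > 1e-9 or np.any(alpha < 0):
        raise OracleError("initial distribution must be a probability vector over states")
    exit_rates = -S.sum(axis=1)
    w, V = np.linalg.eig(S)
    Vinv = np.linalg.inv(V)
    # f(t) = α expm(St) s  =  Σ_k c_k e^{w_k t}, via the eigenbasis
    left = alpha @ V
    right = Vinv @ exit_rates
    coef_pdf = left * right
    right_cdf = Vinv @ np.ones(S.shape[0])
    coef_surv = left * right_cdf
    return w, coef_pdf, coef_surv


def phase_type_waiting_pdf(
    S: np.ndarray, alpha: np.ndarray, t_grid: np.ndarray
) -> np.ndarray:
    """Density of the absorption time: f(t) = α·exp(tS)·s with s = −S·1.

    *S* is the generator restricted to the transient states of the cycle
    between consecutive firings of the monitored channel; *alpha* is the
    distribution over transient states just after a firing.
    """
    w, coef, _ = _phase_type_terms(S, alpha)
    t_grid = np.asarray(t_grid, dtype=float)
    vals = (coef[None, :] * np.exp(np.outer(t_grid, w))).sum(axis=1)
    return np.maximum(vals.real, 0.0)


def phase_type_cdf(S: np.ndarray, alpha: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    """CDF callable F(t) = 1 − α·exp(tS)·1 (for Kolmogorov–Smirnov tests)."""
    w, _, coef_surv = _phase_type_terms(S, alpha)

    def cdf(t):
        t = np.asarray(t, dtype=float)
        surv = (coef_surv[None, :] * np.exp(np.outer(np.atleast_1d(t), w))).sum(axis=1).real
        out = np.clip(1.0 - surv, 0.0, 1.0)
        return out if t.ndim else float(out[0])

    return cdf


def enzyme_turnover_phase_type(
    k1s: float, km1: float, k2: float
) -> tuple[np.ndarray, np.ndarray]:
    """(S, α) for single-enzyme product-formation waiting times.

    Transient states (E free, ES bound); after each product release the
    enzyme is free, so α = (1, 0).  Exit (catalysis) occurs from ES at k2.
    """
    S = np.array([[-k1s, k1s], [km1, -(km1 + k2)]])
    alpha = np.array([1.0, 0.0])
    return S, alpha


def gene_synthesis_phase_type(
    kon: float, koff: float, ksyn: float
) -> tuple[np.ndarray, np.ndarray]:
    """(S, α) for telegraph-gene mRNA-synthesis waiting times.

    Transient states (gene ON, gene OFF); a synthesis event leaves the gene
    ON, so α = (1, 0).  Exit (the next synthesis) occurs from ON at ksyn.
    With kon, koff ≪ ksyn the density shows two log-slope regimes: fast
    within-burst intervals and slow between-burst intervals.
    """
    S = np.array([[-(koff + ksyn), koff], [kon, -kon]])
    alpha = np.array([1.0, 0.0])
    return S, alpha


def log_slope(t_grid: np.ndarray, density: np.ndarray) -> float:
    """Least-squares slope of log f(t) against t over the given window.

    Evaluating a waiting-time density on an early and a late window and
    comparing the two slopes exposes two-timescale (bursty) distributions:
    the within-burst regime decays at the fast rate, the between-burst
    regime at the slow one.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    density = np.asarray(density, dtype=float)
    pos = density > 0
    if pos.sum() < 2:
        raise OracleError("need at least two positive density values")
    return float(np.polyfit(t_grid[pos], np.log(density[pos]), 1)[0])
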