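"""Exact and approximate solvers: contracts, determinism, equivalence."""

import numpy as np
import pytest

import ssakit as sk
from ssakit.model import parse_mdl
from ssakit.solvers import build_dependency_graph
from ssakit.trajectory import TERMINAL_ROW

ALL_SOLVERS = ["direct", "first_reaction", "next_reaction", "tau_leap"]
EXACT_SOLVERS = ["direct", "first_reaction", "next_reaction"]


class TestStepContract:
    def test_steps_mode_records_exact_event_count(self, id_model):
        tr = sk.simulate_direct(id_model, sk.SolverSettings(end=1000, seed=3))
        assert tr.n_events == 1000
        assert len(tr.times) == 1001  # initial row + 1000 events

    def test_zero_propensity_start_absorbs(self):
        m = parse_mdl("R1: A > B, 1.0\nA = 0\nB = 0\n")
        for solver in ALL_SOLVERS:
            tr = sk.simulate(m, sk.SolverSettings(end=100, seed=1, solver=solver))
            assert tr.n_events == 0 and tr.absorbed

    def test_exhaustion_gives_exactly_n_events(self):
        m = parse_mdl("R1: A > B, 1.0\nA = 5\nB = 0\n")
        tr = sk.simulate_direct(m, sk.SolverSettings(end=1e6, mode="time", seed=2))
        assert tr.n_events == 5 and tr.absorbed
        assert tr.states[-1].tolist() == [0, 5]
        # terminal marker row closes the interval at exactly t_end
        assert tr.fired[-1] == TERMINAL_ROW and tr.t_end == 1e6

    def test_time_mode_events_within_end(self, id_model):
        tr = sk.simulate_direct(id_model, sk.SolverSettings(end=50.0, mode="time", seed=4))
        assert tr.t_end == 50.0
        assert np.all(tr.times[tr.fired >= 0] <= 50.0)

    def test_invalid_settings(self):
        with pytest.raises(ValueError):
            sk.SolverSettings(end=0)
        with pytest.raises(ValueError):
            sk.SolverSettings(end=10.5, mode="steps")
        with pytest.raises(ValueError):
            sk.SolverSettings(end=10, solver="gillespie2")
        with pytest.raises(ValueError):
            sk.SolverSettings(end=10, tau_epsilon=1.5)


class TestDeterminism:
    @pytest.mark.parametrize("solver", ALL_SOLVERS)
    def test_same_seed_bit_identical(self, id_model, solver):
        s = sk.SolverSettings(end=2000, seed=11, solver=solver)
        a = sk.simulate(id_model, s)
        b = sk.simulate(id_model, s)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.propensities, b.propensities)
        assert np.array_equal(a.fired, b.fired)


class TestTrajectoryInvariants:
    @pytest.mark.parametrize("solver", EXACT_SOLVERS)
    def test_stoichiometric_consistency(self, two_state_bursty, solver):
        tr = sk.simulate(
            two_state_bursty, sk.SolverSettings(end=3000, seed=5, solver=solver)
        )
        net = two_state_bursty.net_stoichiometry()
        deltas = np.diff(tr.states, axis=0)
        for k, j in enumerate(tr.fired[1:]):
            assert np.array_equal(deltas[k], net[j])
        assert np.all(tr.states >= 0)
        assert np.all(np.diff(tr.times) > 0)

    @pytest.mark.parametrize("name", sk.FIXTURE_NAMES)
    @pytest.mark.parametrize("solver", ALL_SOLVERS)
    def test_every_fixture_runs_on_every_solver(self, name, solver):
        m = sk.build_fixture(name).model
        tr = sk.simulate(m, sk.SolverSettings(end=10**4, seed=6, solver=solver))
        assert np.all(tr.states >= 0)
        assert len(tr.times) >= 1


class TestNextReaction:
    def test_forced_chain_fires_in_order(self):
        m = parse_mdl("R1: A > B, 1.0\nR2: B > C, 2.0\nA = 1\nB = 0\nC = 0\n")
        tr = sk.simulate_next_reaction(m, sk.SolverSettings(end=100, seed=8))
        assert tr.n_events == 2 and tr.absorbed
        assert tr.fired[1:].tolist() == [0, 1]

    def test_reactivated_channel_never_fires_at_zero_propensity(self):
        # degradation starts disabled (A=0) and is re-enabled by synthesis
        m = parse_mdl("Rsyn: $pool > A, 1.0\nRdeg: A > $pool, 10.0\nA = 0\n")
        tr = sk.simulate_next_reaction(m, sk.SolverSettings(end=3000, seed=9))
        deg = m.reaction_index("Rdeg")
        fired_rows = np.flatnonzero(tr.fired == deg)
        # at the row before each degradation firing, A must have been > 0
        assert np.all(tr.states[fired_rows - 1, 0] > 0)
        assert np.all(tr.states >= 0)

    def test_agrees_with_direct_on_stationary_mean(self, id_model):
        a = sk.simulate_direct(id_model, sk.SolverSettings(end=10**5, seed=10))
        b = sk.simulate_next_reaction(id_model, sk.SolverSettings(end=10**5, seed=20))
        ma = sk.moments(a, "mRNA", burn_in=0.1).mean
        mb = sk.moments(b, "mRNA", burn_in=0.1).mean
        assert abs(ma - mb) < 1.0  # ~5 standard errors at this length


class TestDependencyGraph:
    def test_immigration_death_structure(self, id_model):
        g = build_dependency_graph(id_model)
        syn, deg = 0, 1
        assert g[syn] == {syn, deg}  # synthesis changes mRNA, read by Rdeg
        assert g[deg] == {deg}  # zero-order synthesis reads nothing

    def test_disjoint_pairs_give_two_components(self):
        m = parse_mdl(
            "R1: $pool > A, 1.0\nR2: A > $pool, 1.0\n"
            "R3: $pool > B, 1.0\nR4: B > $pool, 1.0\nA = 0\nB = 0\n"
        )
        g = build_dependency_graph(m)
        # synthesis affects its pair's degradation; zero-order synthesis
        # reads nothing, so degradation affects only itself
        assert g[0] == {0, 1} and g[1] == {1}
        assert g[2] == {2, 3} and g[3] == {3}
        # no dependency crosses the two disjoint species pairs
        assert not (g[0] | g[1]) & (g[2] | g[3])

    def test_expression_read_set(self):
        m = parse_mdl(
            "k : 1.0\nR1: $pool > A, 1.0\nR2: $pool > B, 1.0\n"
            "R3: $pool > C, k*(A+B)\nA = 0\nB = 0\nC = 0\n"
        )
        g = build_dependency_graph(m)
        assert 2 in g[0] and 2 in g[1]  # A- and B-changing reactions affect R3
        assert g[2] == {2}  # R3 changes only C, read by nobody


class TestTauLeap:
    def test_epsilon_to_zero_collapses_to_exact_stepping(self, id_model):
        tr = sk.simulate_tau_leap(
            id_model,
            sk.SolverSettings(end=100, seed=12, solver="tau_leap", tau_epsilon=1e-6),
        )
        assert not tr.exact
        assert tr.firings.sum(axis=1).max() <= 1

    def test_low_copy_channel_is_critical_hence_exact(self):
        m = parse_mdl("R1: A > $pool, 1.0\nA = 3\n")
        tr = sk.simulate_tau_leap(
            m, sk.SolverSettings(end=10.0, mode="time", seed=13, solver="tau_leap")
        )
        # 3 < critical_threshold=10: every firing is handled one at a time
        assert tr.firings.sum(axis=1).max() <= 1
        assert tr.states[-1, 0] == 0

    def test_leaps_aggregate_firings_at_high_copy_number(self):
        m = parse_mdl("Rsyn: $pool > X, 1000.0\nRdeg: X > $pool, 0.2\nX = 5000\n")
        tr = sk.simulate_tau_leap(
            m, sk.SolverSettings(end=100.0, mode="time", seed=14, solver="tau_leap")
        )
        assert tr.firings.max() > 100  # genuinely leaping
        assert len(tr.times) < 1000  # far fewer rows than the ~2e5 exact events
        mean = sk.moments(tr, "X", burn_in=0.2).mean
        assert mean == pytest.approx(5000, rel=0.02)

    def test_stationary_mean_close_to_exact(self, id_model):
        tr = sk.simulate_tau_leap(
            id_model, sk.SolverSettings(end=10**4, mode="time", seed=15, solver="tau_leap")
        )
        mean = sk.moments(tr, "mRNA", burn_in=0.1).mean
        # se of the time-average ≈ sqrt(var * 2*tau_c / T) ≈ 0.24
        assert abs(mean - 50.0) < 3 * 0.25

    def test_waiting_times_refused(self, id_model):
        tr = sk.simulate_tau_leap(
            id_model, sk.SolverSettings(end=100.0, mode="time", seed=16, solver="tau_leap")
        )
        with pytest.raises(ValueError, match="tau-leap"):
            sk.event_waiting_times(tr, 0)


class TestEnsemble:
    def test_reproducible(self, id_model):
        s = sk.SolverSettings(end=200, seed=17, n_trajectories=5)
        e1 = sk.run_ensemble(id_model, s)
        e2 = sk.run_ensemble(id_model, s)
        for a, b in zip(e1, e2):
            assert np.array_equal(a.times, b.times)
            assert np.array_equal(a.states, b.states)

    def test_members_use_distinct_streams(self, id_model):
        e = sk.run_ensemble(id_model, sk.SolverSettings(end=200, seed=18, n_trajectories=3))
        assert not np.array_equal(e[0].times, e[1].times)
        assert not np.array_equal(e[1].times, e[2].times)

    def test_across_ensemble_mean_near_stationary(self, id_model):
        e = sk.run_ensemble(
            id_model, sk.SolverSettings(end=2000, seed=19, n_trajectories=30)
        )
        means = [sk.moments(tr, "mRNA", burn_in=0.2).mean for tr in e]
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - 50.0) < 3 * se + 0.5
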