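"""Waiting times, time-weighted distributions, moments, ACF, regridding."""

import numpy as np
import pytest
from scipy import stats

import ssakit as sk
from ssakit.analysis import (
    AnalysisError,
    all_waiting_times,
    gridded_distribution,
    total_variation,
)
from ssakit.model import parse_mdl

from conftest import make_trajectory


class TestWaitingTimes:
    def test_definition_on_constructed_input(self):
        # channel 1 fires at t = 1.0, 1.7, 3.2 → intervals [0.7, 1.5]
        tr = make_trajectory(
            times=[0.0, 1.0, 1.4, 1.7, 3.2],
            states=[0, 1, 2, 3, 4],
            fired=[-1, 1, 0, 1, 1],
        )
        assert sk.event_waiting_times(tr, 1) == pytest.approx([0.7, 1.5])

    def test_single_firing_gives_empty_list(self):
        tr = make_trajectory(times=[0.0, 2.0], states=[0, 1], fired=[-1, 0])
        assert len(sk.event_waiting_times(tr, 0)) == 0

    def test_unknown_channel(self, id_long):
        with pytest.raises(KeyError):
            sk.event_waiting_times(id_long, "Rnope")
        with pytest.raises(KeyError):
            sk.event_waiting_times(id_long, 7)

    def test_constant_propensity_channel_is_poisson_process(self, id_long):
        """Zero-order synthesis at 10/min has Exponential(10) waiting times."""
        wt = sk.event_waiting_times(id_long, "Rsyn")
        res = stats.kstest(wt, stats.expon(scale=1 / 10.0).cdf)
        assert res.pvalue > 0.001

    def test_counts_invariant(self, id_long):
        """Σ_channel (firings − 1) = Σ_channel len(intervals)."""
        wts = all_waiting_times(id_long)
        for j, name in enumerate(id_long.reaction_names):
            firings = int((id_long.fired == j).sum())
            assert len(wts[name]) == firings - 1
            assert np.all(wts[name] > 0)


class TestSpeciesDistribution:
    def test_constant_state_gives_point_mass(self):
        tr = make_trajectory(times=[0.0, 1.0, 5.0], states=[7, 7, 7], fired=[-1, 0, 0])
        d = sk.species_distribution(tr, 0)
        assert d.support.tolist() == [7.0]
        assert d.probabilities.tolist() == [1.0]

    def test_hand_computed_holding_weights(self):
        # value 0 holds 1.0 time unit, value 1 holds 3.0 → p = (0.25, 0.75)
        tr = make_trajectory(times=[0.0, 1.0, 4.0], states=[0, 1, 1], fired=[-1, 0, 0])
        d = sk.species_distribution(tr, 0)
        assert d.probabilities == pytest.approx([0.25, 0.75])

    def test_zero_duration_rejected(self):
        tr = make_trajectory(times=[0.0], states=[3], fired=[-1])
        with pytest.raises(AnalysisError):
            sk.species_distribution(tr, 0)

    def test_probabilities_sum_to_one(self, id_long):
        d = sk.species_distribution(id_long, "mRNA", burn_in=0.1)
        assert abs(d.probabilities.sum() - 1.0) < 1e-9

    def test_close_to_poisson_law(self, id_long):
        d = sk.species_distribution(id_long, "mRNA", burn_in=0.1)
        sup, pmf = sk.analytic_poisson(50.0, 200)
        assert total_variation(d, (sup, pmf)) < 0.05

    def test_burn_in_validation(self, id_long):
        with pytest.raises(AnalysisError):
            sk.species_distribution(id_long, "mRNA", burn_in=1.0)


class TestPropensityDistribution:
    def test_zero_order_channel_is_point_mass_at_constant(self, id_long):
        d = sk.propensity_distribution(id_long, "Rsyn")
        assert d.support.tolist() == [10.0]
        assert d.probabilities.tolist() == [1.0]

    def test_first_order_channel_is_scaled_species_distribution(self, id_long):
        """Degradation propensity = kd·n: same shape, support × 0.2."""
        dp = sk.propensity_distribution(id_long, "Rdeg", burn_in=0.1)
        ds = sk.species_distribution(id_long, "mRNA", burn_in=0.1).scaled(0.2)
        assert dp.support == pytest.approx(ds.support)
        assert dp.probabilities == pytest.approx(ds.probabilities)

    def test_absorbed_at_zero_gives_point_mass_zero(self):
        m = parse_mdl("R1: A > $pool, 5.0\nA = 1\n")
        tr = sk.simulate_direct(m, sk.SolverSettings(end=100.0, mode="time", seed=1))
        d = sk.propensity_distribution(tr, "R1")
        # almost all holding time sits at propensity 0 after absorption
        assert d.support[0] == 0.0 and d.probabilities[0] > 0.9


class TestMoments:
    def test_constant_trajectory(self):
        tr = make_trajectory(times=[0.0, 1.0, 5.0], states=[7, 7, 7], fired=[-1, 0, 0])
        m = sk.moments(tr, 0)
        assert m.mean == 7.0 and m.std == 0.0 and m.fano == 0.0

    def test_fano_flagged_undefined_at_zero_mean(self):
        tr = make_trajectory(times=[0.0, 1.0], states=[0, 0], fired=[-1, 0])
        assert sk.moments(tr, 0).fano is None

    def test_mean_matches_distribution_mean_exactly(self, id_long):
        """Single weighting path: moments and distribution agree to 1e-12."""
        mom = sk.moments(id_long, "mRNA", burn_in=0.1)
        dist = sk.species_distribution(id_long, "mRNA", burn_in=0.1)
        assert abs(mom.mean - dist.mean()) < 1e-12

    def test_immigration_death_poisson_moments(self, id_long):
        m = sk.moments(id_long, "mRNA", burn_in=0.1)
        assert abs(m.mean - 50.0) < 1.5
        assert abs(m.fano - 1.0) < 0.08


class TestAutocorrelation:
    def test_lag_zero_is_one(self, id_long):
        assert sk.autocorrelation(id_long, "mRNA", [0.0], grid_dt=0.5)[0] == 1.0

    def test_exponential_decay_for_birth_death(self, id_long):
        """Linear birth-death ACF is exp(−kd·τ)."""
        lags = [1.0, 2.5, 5.0, 10.0]
        acf = sk.autocorrelation(id_long, "mRNA", lags, grid_dt=0.1)
        expected = sk.analytic_acf(0.2, np.array(lags))
        assert np.all(np.abs(acf - expected) < 0.05)

    def test_white_noise_decorrelates(self):
        rng = np.random.default_rng(0)
        n = 4000
        times = np.arange(n, dtype=float)
        states = rng.poisson(50, size=n)
        tr = make_trajectory(times=times, states=states, fired=[-1] + [0] * (n - 1))
        acf = sk.autocorrelation(tr, 0, [50.0], grid_dt=1.0)
        assert abs(acf[0]) < 3 / np.sqrt(n)

    def test_lag_beyond_duration_rejected(self, id_long):
        with pytest.raises(AnalysisError):
            sk.autocorrelation(id_long, "mRNA", [10 * id_long.duration], grid_dt=1.0)

    def test_short_trajectory_warns(self):
        tr = make_trajectory(times=[0.0, 1.0, 10.0], states=[1, 2, 3], fired=[-1, 0, 0])
        with pytest.warns(RuntimeWarning, match="10×"):
            sk.autocorrelation(tr, 0, [5.0], grid_dt=0.5)


class TestRegrid:
    def test_zero_order_hold_semantics(self):
        tr = make_trajectory(
            times=[0.0, 5.0, 10.0], states=[1, 9, 9], fired=[-1, 0, -2]
        )
        grid, states = sk.regrid_fixed_interval(tr, 3)
        assert grid.tolist() == [0.0, 5.0, 10.0]
        assert states[:, 0].tolist() == [1, 9, 9]

    def test_two_points_are_endpoints(self, id_long):
        grid, states = sk.regrid_fixed_interval(id_long, 2)
        assert grid[0] == id_long.t0 and grid[-1] == id_long.t_end
        assert states[0, 0] == id_long.states[0, 0]
        assert states[-1, 0] == id_long.states[-1, 0]

    def test_gridded_mean_converges_to_time_weighted_mean(self, id_long):
        """Fixed-interval mean error shrinks as the grid refines."""
        ref = sk.moments(id_long, "mRNA").mean
        errs = []
        for n in [10**2, 10**3, 10**4, 10**5]:
            _, states = sk.regrid_fixed_interval(id_long, n)
            errs.append(abs(states[:, 0].mean() - ref))
        assert errs[-1] < errs[0] / 3  # average monotone decrease

    def test_invalid_inputs(self, id_long):
        with pytest.raises(AnalysisError):
            sk.regrid_fixed_interval(id_long, 1)


class TestAverageTrajectories:
    def test_identical_trajectories_have_zero_sd(self, id_model):
        tr = sk.simulate_direct(id_model, sk.SolverSettings(end=100, seed=2))
        grid = np.linspace(0, tr.t_end, 20)
        mean, sd = sk.average_trajectories([tr, tr, tr], "mRNA", grid)
        assert np.all(sd == 0.0)

    def test_two_trajectories_average_is_midpoint(self, id_model):
        a = sk.simulate_direct(id_model, sk.SolverSettings(end=100, seed=3))
        b = sk.simulate_direct(id_model, sk.SolverSettings(end=100, seed=4))
        grid = np.linspace(0, min(a.t_end, b.t_end), 15)
        mean, _ = sk.average_trajectories([a, b], "mRNA", grid)
        sa = a.sample_at(grid)[:, 0]
        sb = b.sample_at(grid)[:, 0]
        assert mean == pytest.approx((sa + sb) / 2.0)

    def test_single_enzyme_mean_product_curve(self):
        """Ensemble mean P(t) follows the two-state turnover closed form."""
        m = sk.build_fixture("single_enzyme").model
        ens = sk.run_ensemble(
            m, sk.SolverSettings(end=50.0, mode="time", seed=5, n_trajectories=100)
        )
        grid = np.linspace(5.0, 50.0, 10)
        mean, sd = sk.average_trajectories(ens, "P", grid)
        # E→ES rate 1, ES→E total 1.5: stationary bound fraction 0.4,
        # E[P(t)] = k2 (0.4 t − 0.16 (1 − e^{−2.5 t}))
        expected = 0.4 * grid - 0.16 * (1 - np.exp(-2.5 * grid))
        se = sd / np.sqrt(len(ens))
        assert np.all(np.abs(mean - expected) < 3 * se + 0.05)

    def test_mismatched_models_rejected(self, id_model, two_state_bursty):
        a = sk.simulate_direct(id_model, sk.SolverSettings(end=10, seed=6))
        b = sk.simulate_direct(two_state_bursty, sk.SolverSettings(end=10, seed=6))
        with pytest.raises(AnalysisError):
            sk.average_trajectories([a, b], 0, np.array([0.0, 1.0]))


class TestWaitingTimePdf:
    def test_exponential_log_density_slope(self):
        rng = np.random.default_rng(8)
        sample = rng.exponential(1 / 10.0, size=20000)
        edges, density = sk.waiting_time_pdf(sample, bins=20)
        centers = 0.5 * (edges[:-1] + edges[1:])
        pos = density > 0
        slope = np.polyfit(centers[pos], np.log(density[pos]), 1)[0]
        assert slope == pytest.approx(-10.0, rel=0.1)

    def test_single_bin_integrates_to_one(self):
        edges, density = sk.waiting_time_pdf(np.array([1.0, 2.0, 3.0]), bins=1)
        assert density[0] * (edges[1] - edges[0]) == pytest.approx(1.0)

    def test_log_bins(self):
        rng = np.random.default_rng(9)
        sample = rng.exponential(1.0, size=1000)
        edges, density = sk.waiting_time_pdf(sample, bins=15, scale="log")
        assert np.sum(density * np.diff(edges)) == pytest.approx(1.0)

    def test_empty_rejected_and_small_warns(self):
        with pytest.raises(AnalysisError):
            sk.waiting_time_pdf(np.array([]))
        with pytest.warns(RuntimeWarning):
            sk.waiting_time_pdf(np.array([1.0, 2.0]), bins=2)


class TestExplicitVsGridded:
    def test_equal_count_grid_less_accurate_than_explicit(self, two_state_bursty):
        """Fixed-interval snapshots at one sample per event lose accuracy
        relative to the holding-time-weighted explicit estimate."""
        tr = sk.simulate_direct(
            two_state_bursty, sk.SolverSettings(end=10**5, seed=11)
        )
        cme = sk.cme_stationary(
            two_state_bursty, {"Goff": 1, "Gon": 1, "mRNA": 100}
        )
        ref = cme.marginal("mRNA")
        tv_explicit = total_variation(
            sk.species_distribution(tr, "mRNA", burn_in=0.1), ref
        )
        tv_grid = total_variation(
            gridded_distribution(tr, "mRNA", tr.n_events, burn_in=0.1), ref
        )
        assert tv_explicit < tv_grid
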