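"""Coalescent HMM: discretization, likelihood oracle, EM behaviour,
calibration and trajectory handling."""

import itertools

import numpy as np
import pandas as pd
import pytest

from paleoterrapin import demography, smc
from paleoterrapin._kernels import forward_backward_counts, posterior_marginals
from paleoterrapin.demography import (
    CalibrationParams,
    DemographicTrajectory,
    calibrate,
    mean_pairwise_distance,
    minmax_normalize,
    normalize_and_average,
    scale_to_years,
)
from paleoterrapin.discretize import TimeDiscretization, expand_pattern, parse_pattern
from paleoterrapin.hetstats import BIN_HET, BIN_HOM, BIN_MISSING, HetBinTrack
from paleoterrapin.smc import (
    SMCModel,
    bootstrap,
    emission_matrix,
    fit_smc,
    prior_distribution,
    transition_matrix,
)


def brute_force_loglik(obs, P, E, pi):
    """Exhaustive sum over all hidden paths — the likelihood oracle."""
    K = P.shape[0]
    total = 0.0
    for path in itertools.product(range(K), repeat=len(obs)):
        p = pi[path[0]] * E[path[0], obs[0]]
        for t in range(1, len(obs)):
            p *= P[path[t - 1], path[t]] * E[path[t], obs[t]]
        total += p
    return np.log(total)


class TestPattern:
    def test_study_pattern_expansion(self):
        counts = expand_pattern("2 + 2 + 25*2 + 4 + 6", 64)
        assert counts == [2, 2] + [2] * 25 + [4, 6]
        assert sum(counts) == 64
        assert len(counts) == 29

    def test_singleton_pattern(self):
        # "m*a" is m free intervals of a atomic intervals each
        assert expand_pattern("64*1", 64) == [1] * 64
        assert expand_pattern("1*64", 64) == [64]

    def test_sum_mismatch_rejected(self):
        with pytest.raises(ValueError):
            expand_pattern("2+2", 64)

    def test_boundaries_increase_from_zero(self, default_disc):
        b = default_disc.boundaries
        assert b[0] == 0
        assert np.all(np.diff(b[:-1]) > 0)
        assert np.isinf(b[-1])

    def test_free_left_edges_align_with_groups(self, default_disc):
        edges = default_disc.free_left_edges()
        assert len(edges) == default_disc.n_free
        assert edges[0] == 0


class TestHMMComponents:
    def test_transition_rows_are_distributions(self, default_disc):
        lam = np.linspace(0.5, 2.0, default_disc.n_free)
        P = transition_matrix(default_disc, lam, rho=0.03)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert P.min() >= 0

    def test_prior_is_distribution(self, default_disc):
        pi = prior_distribution(default_disc, np.ones(default_disc.n_free))
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(pi > 0)

    def test_emission_increases_with_time(self, tiny_disc):
        E = emission_matrix(tiny_disc, np.ones(3), theta=0.3)
        assert np.all(np.diff(E[:, 1]) > 0)  # deeper TMRCA, more het
        assert np.allclose(E[:, 2], 1.0)

    def test_forward_matches_exhaustive_enumeration(self, tiny_disc):
        """Scaled forward recursion equals the brute-force path sum."""
        P = transition_matrix(tiny_disc, np.array([1.3, 0.7, 1.1]), rho=0.25)
        E = emission_matrix(tiny_disc, np.array([1.3, 0.7, 1.1]), theta=0.4)
        pi = prior_distribution(tiny_disc, np.array([1.3, 0.7, 1.1]))
        obs = np.array([0, 1, 0, 0, 2, 1, 0, 1, 0, 0], dtype=np.int8)
        ll, *_ = forward_backward_counts(obs, P, E, pi)
        oracle = brute_force_loglik(obs, P, E, pi)
        assert ll == pytest.approx(oracle, rel=1e-10)

    def test_posteriors_sum_to_one(self, tiny_disc):
        lam = np.array([1.0, 0.9, 1.2])
        P = transition_matrix(tiny_disc, lam, rho=0.2)
        E = emission_matrix(tiny_disc, lam, theta=0.3)
        pi = prior_distribution(tiny_disc, lam)
        obs = np.array([0, 1, 2, 0, 1, 0], dtype=np.int8)
        _, gamma = posterior_marginals(obs, P, E, pi)
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-10)

    def test_numba_and_numpy_kernels_agree(self, default_disc):
        from paleoterrapin._kernels import HAVE_NUMBA, _fb_nb, _fb_py

        if not HAVE_NUMBA:
            pytest.skip("numba unavailable")
        lam = np.ones(default_disc.n_free)
        P = transition_matrix(default_disc, lam, rho=0.05)
        E = emission_matrix(default_disc, lam, theta=0.04)
        pi = prior_distribution(default_disc, lam)
        rng = np.random.default_rng(0)
        obs = rng.choice([0, 0, 0, 1, 2], size=500).astype(np.int8)
        ll_a, ce_a, A_a, g_a = _fb_py(obs, P, E, pi)
        ll_b, ce_b, A_b, g_b = _fb_nb(obs, np.ascontiguousarray(P), np.ascontiguousarray(E), pi)
        assert ll_a == pytest.approx(ll_b, rel=1e-12)
        assert np.allclose(ce_a, ce_b, atol=1e-9)
        assert np.allclose(A_a, A_b, atol=1e-9)


class TestFit:
    def test_em_loglik_monotone(self, constant_ne_sim, default_disc):
        fit = fit_smc(constant_ne_sim.het_track, default_disc, n_em_iters=6)
        ll = np.array(fit.loglik_history)
        assert np.all(np.diff(ll) >= -1e-8 * np.abs(ll[:-1]))

    def test_zero_het_track_flagged_degenerate(self, default_disc):
        track = HetBinTrack(bins={"s": np.full(5000, BIN_HOM, dtype=np.int8)})
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_smc(track, default_disc, n_em_iters=3)
        assert fit.degenerate

    def test_all_missing_track_rejected(self, default_disc):
        track = HetBinTrack(bins={"s": np.full(100, BIN_MISSING, dtype=np.int8)})
        with pytest.raises(ValueError):
            fit_smc(track, default_disc)

    def test_theta_recovered_on_constant_ne(self, constant_ne_sim, default_disc):
        fit = fit_smc(constant_ne_sim.het_track, default_disc, n_em_iters=6)
        assert fit.model.theta == pytest.approx(4 * 10_000 * 1e-8 * 100, rel=0.2)


class TestFitReport:
    def test_report_layout(self, tmp_path, constant_ne_sim, default_disc):
        from paleoterrapin.smc import write_fit_report

        fit = fit_smc(constant_ne_sim.het_track, default_disc, n_em_iters=2)
        p = tmp_path / "fit.txt"
        write_fit_report(fit, p)
        lines = p.read_text().splitlines()
        assert any(l.startswith("TR\t") for l in lines)
        assert sum(l.startswith("RS\t") for l in lines) == default_disc.n_atomic
        assert lines[-1].startswith("//")


class TestBootstrap:
    def test_zero_reps_empty(self, constant_ne_sim, default_disc):
        assert bootstrap(constant_ne_sim.het_track, default_disc, n_reps=0) == []

    def test_seeded_resampling_deterministic(self, constant_ne_sim, default_disc):
        kw = dict(n_reps=2, segment_size_bp=2e5, seed=9, n_em_iters=2)
        a = bootstrap(constant_ne_sim.het_track, default_disc, **kw)
        b = bootstrap(constant_ne_sim.het_track, default_disc, **kw)
        for x, y in zip(a, b):
            assert np.array_equal(x.ne, y.ne)

    def test_scaling_commutes_with_bootstrap(self, constant_ne_sim, default_disc):
        calib = calibrate(d=0.012, T=3e7, alpha=12, L=30)
        reps = bootstrap(constant_ne_sim.het_track, default_disc, n_reps=2,
                         segment_size_bp=2e5, seed=4, n_em_iters=2)
        scaled_each = [scale_to_years(r, calib) for r in reps]
        traj = fit_smc(constant_ne_sim.het_track, default_disc, n_em_iters=2).trajectory
        traj.bootstrap = reps
        scaled_whole = scale_to_years(traj, calib)
        # replicates scale with their own theta, identically either way
        for a, b in zip(scaled_each, scaled_whole.bootstrap):
            assert np.allclose(a.times, b.times) and np.allclose(a.ne, b.ne)


class TestCalibration:
    def test_generation_time_formula(self):
        assert calibrate(d=0.01, T=1e7, alpha=12, L=30).g == 27

    def test_mutation_rate_arithmetic(self):
        c = calibrate(d=0.012, T=3e7, alpha=12, L=30)
        assert c.mu_per_gen == pytest.approx(5.4e-9)
        assert c.mu_per_year == pytest.approx(2.0e-10)

    def test_turtle_like_inputs_give_slow_per_year_rates(self):
        """Typical chelonian distances/divergences give per-year rates within
        the span reported for the clade (2.62e-10 to 7.83e-10)."""
        rates = [calibrate(d=d, T=T, alpha=15, L=30).mu_per_year
                 for d, T in [(0.02, 3e7), (0.012, 2e7), (0.045, 3e7)]]
        assert all(2.62e-10 <= r <= 7.83e-10 for r in rates)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            calibrate(d=0, T=1, alpha=1, L=1)

    def test_mean_pairwise_distance(self):
        assert mean_pairwise_distance([0.01, 0.02]) == pytest.approx(0.015)


class TestTrajectory:
    def make(self):
        return DemographicTrajectory(
            times=np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0]),
            ne=np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]),
            theta_per_bin=0.04,
            bin_size=100,
        )

    def test_scaling_linearity_in_generation_time(self):
        traj = self.make()
        c1 = calibrate(d=0.012, T=3e7, alpha=12, L=30)   # g = 27
        c2 = calibrate(d=0.024, T=3e7, alpha=39, L=30)   # g = 54, same mu/site/gen? no
        y1 = scale_to_years(traj, c1)
        # doubling g with mu fixed doubles times and leaves Ne unchanged
        c_double = CalibrationParams(d=c1.d, T=c1.T, alpha=c1.alpha + 27, L=c1.L)
        n0 = traj.theta_per_bin / (4 * c1.mu_per_gen * traj.bin_size)
        y2 = scale_to_years(traj, c_double, n0=n0)
        assert np.allclose(y2.times, 2 * y1.times)
        assert np.allclose(y2.ne, y1.ne)

    def test_scale_round_trip(self):
        traj = self.make()
        calib = calibrate(d=0.012, T=3e7, alpha=12, L=30)
        y = scale_to_years(traj, calib)
        n0 = traj.theta_per_bin / (4 * calib.mu_per_gen * traj.bin_size)
        assert np.allclose(y.times / (2 * n0 * calib.g), traj.times)
        assert np.allclose(y.ne / n0, traj.ne)

    def test_mean_ne_drops_four_most_recent(self):
        traj = self.make()
        assert traj.mean_ne() == pytest.approx(np.mean([5.0, 6.0]))
        with pytest.raises(ValueError):
            traj.mean_ne(exclude_recent=6)

    def test_value_at_steps(self):
        traj = self.make()
        assert traj.value_at(0.5) == 1.0
        assert traj.value_at(5.5) == 6.0


class TestNormalization:
    def test_minmax_example(self):
        assert np.allclose(minmax_normalize([2, 4, 6]), [0, 0.5, 1])

    def test_constant_series_warns_and_centers(self):
        with pytest.warns(UserWarning):
            out = minmax_normalize([3, 3, 3])
        assert np.allclose(out, 0.5)

    def test_single_species_group_mean_is_own_curve(self):
        traj = DemographicTrajectory(
            times=np.array([1e3, 1e5, 1e6]), ne=np.array([5e3, 2e4, 1e4]), units="years"
        )
        out = normalize_and_average({"sp": traj}, time_window=(1e4, 1e7))
        grid = out["time"].to_numpy()
        expect = minmax_normalize(traj.value_at(grid))
        assert np.allclose(out["mean_ne_norm"], expect)

    def test_max_mode_bounded_by_one(self):
        traj = DemographicTrajectory(
            times=np.array([1e3, 1e5]), ne=np.array([5e3, 2e4]), units="years"
        )
        out = normalize_and_average({"sp": traj}, mode="max")
        assert out["mean_ne_norm"].max() == pytest.approx(1.0)
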