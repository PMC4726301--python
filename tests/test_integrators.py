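"""Correlated-increment generation and stochastic Heun integration."""

import numpy as np
import pytest
from scipy import stats

from depotsim.fokker_planck import NoiseParams, default_grid, stationary_distribution
from depotsim.integrators import (
    PAPER_SCALE,
    IntegrationBlowupError,
    SimulationConfig,
    correlated_increments,
    run_ensemble,
    step_full,
    step_reduced,
)
from depotsim.model_core import ModelParams, quasistationary_depot


def _analytic_cdf(params, noise):
    sol = stationary_distribution(default_grid(), params, noise)
    cdf = np.concatenate(
        ([0.0], np.cumsum(0.5 * (sol.Q_st[1:] + sol.Q_st[:-1]) * np.diff(sol.grid)))
    )
    cdf /= cdf[-1]
    return lambda x: np.interp(x, sol.grid, cdf)


class TestCorrelatedIncrements:
    def test_covariance_recovery(self, rng):
        """Sample covariance of 1e5 pairs matches 2*M*dt within 4 SE."""
        n = NoiseParams(M1=0.5, M2=0.05, mu=0.5)
        dt = 0.01
        dw = correlated_increments(100_000, dt, n, rng)
        cov = np.cov(dw.T)
        target = 2 * dt * np.array([[n.M1, n.M12], [n.M12, n.M2]])
        # SE of a covariance entry ~ sqrt(2/n) * scale
        for i in range(2):
            for j in range(2):
                se = np.sqrt(2.0 / len(dw)) * np.sqrt(target[i, i] * target[j, j])
                assert abs(cov[i, j] - target[i, j]) < 4 * se

    def test_independent_when_uncorrelated(self, rng):
        dw = correlated_increments(100_000, 0.01, NoiseParams(0.5, 0.05, 0.0), rng)
        r = np.corrcoef(dw.T)[0, 1]
        assert abs(r) < 4 / np.sqrt(len(dw))

    def test_rank_one_at_perfect_correlation(self, rng):
        dw = correlated_increments(10_000, 0.01, NoiseParams(0.5, 0.05, 1.0), rng)
        r = np.corrcoef(dw.T)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_monte_carlo_convergence_rate(self):
        """Covariance error shrinks roughly as 1/sqrt(n) across sizes."""
        n = NoiseParams(M1=0.5, M2=0.05, mu=0.3)
        errs = []
        for size in (1_000, 100_000):
            rng = np.random.default_rng(7)
            dw = correlated_increments(size, 0.01, n, rng)
            cov = np.cov(dw.T)
            target = 2 * 0.01 * np.array([[n.M1, n.M12], [n.M12, n.M2]])
            errs.append(np.abs(cov - target).max() / target.max())
        assert errs[1] < errs[0] / 3  # expected factor 10, generous margin

    def test_null_multiplicative_with_perfect_correlation_rejected(self, rng):
        with pytest.raises(ValueError, match="undefined"):
            correlated_increments(10, 0.01, NoiseParams(0.0, 0.05, 1.0), rng)


class TestDeterministicLimits:
    def test_reduced_stationary_at_stable_speed(self, paper_params):
        """With no noise, v(0) = v+ stays at v+ (fixed point of f)."""
        n0 = NoiseParams(0.0, 0.0, 0.0)
        x, v = np.zeros(1), np.full(1, 0.3)
        for _ in range(1000):
            x, v = step_reduced((x, v), 0.01, paper_params, n0, np.zeros((1, 2)))
        assert v[0] == pytest.approx(0.3, abs=1e-10)

    def test_reduced_rest_state_is_invariant(self, paper_params):
        n0 = NoiseParams(0.0, 0.0, 0.0)
        x, v = np.zeros(1), np.zeros(1)
        for _ in range(100):
            x, v = step_reduced((x, v), 0.01, paper_params, n0, np.zeros((1, 2)))
        assert v[0] == 0.0

    def test_full_fixed_point_is_stationary(self, paper_params):
        """(v+, e_qs(v+)) is a fixed point of the coupled noiseless flow."""
        n0 = NoiseParams(0.0, 0.0, 0.0)
        v = np.full(1, 0.3)
        e = np.asarray(quasistationary_depot(v, paper_params))
        x = np.zeros(1)
        for _ in range(1000):
            (x, v, e), _ = step_full((x, v, e), 0.01, paper_params, n0,
                                     np.zeros((1, 2)))
        assert v[0] == pytest.approx(0.3, abs=1e-8)
        assert e[0] == pytest.approx(20.0, abs=1e-6)

    def test_depot_relaxation_matches_linear_ode(self):
        """At frozen v = 0 the depot relaxes as
        e_qs + (e0 - e_qs) exp(-c t); Heun at dt = 1e-3 tracks the closed
        form to 1e-4."""
        p = ModelParams(gamma0=20.0, q=2.0, c=0.5, d2=1.0)
        n0 = NoiseParams(0.0, 0.0, 0.0)
        dt, n_steps = 1e-3, 10_000
        e0 = 1.0
        x, v, e = np.zeros(1), np.zeros(1), np.full(1, e0)
        for _ in range(n_steps):
            (x, v, e), _ = step_full((x, v, e), dt, p, n0, np.zeros((1, 2)))
        t = n_steps * dt
        e_qs = p.q / p.c
        expected = e_qs + (e0 - e_qs) * np.exp(-p.c * t)
        assert e[0] == pytest.approx(expected, rel=1e-4)

    def test_depot_clamped_at_zero(self):
        """Overdamped depot steps clamp at zero and are counted."""
        p = ModelParams(gamma0=1.0, q=0.01, c=150.0, d2=1.0)
        n0 = NoiseParams(0.0, 0.0, 0.0)
        state = (np.zeros(1), np.zeros(1), np.full(1, 5.0))
        (x, v, e), clamps = step_full(state, 0.01, p, n0, np.zeros((1, 2)))
        assert clamps > 0
        assert e[0] >= 0.0


class TestEnsembles:
    def test_same_seed_bit_identical(self, paper_params):
        cfg = SimulationConfig(dt=0.01, n_steps=200, n_traj=8, burn_in_steps=50,
                               seed=42, variant="full")
        n = NoiseParams(0.5, 0.05, 0.3)
        a = run_ensemble(cfg, paper_params, n)
        b = run_ensemble(cfg, paper_params, n)
        assert np.array_equal(a.v, b.v) and np.array_equal(a.x, b.x)
        assert np.array_equal(a.e, b.e)

    def test_different_seeds_differ(self, paper_params):
        n = NoiseParams(0.5, 0.05, 0.3)
        mk = lambda s: SimulationConfig(dt=0.01, n_steps=100, n_traj=4,  # noqa: E731
                                        burn_in_steps=10, seed=s)
        a = run_ensemble(mk(1), paper_params, n)
        b = run_ensemble(mk(2), paper_params, n)
        assert not np.any(a.v[:, 1:] == b.v[:, 1:])

    def test_reference_protocol_constants(self):
        assert PAPER_SCALE == {"dt": 0.01, "n_steps": 100_000, "n_traj": 500}

    def test_shapes_and_time_grid(self, paper_params):
        cfg = SimulationConfig(dt=0.01, n_steps=100, n_traj=5, burn_in_steps=10,
                               variant="full", store_every=2)
        ens = run_ensemble(cfg, paper_params, NoiseParams(0.1, 0.05, 0.0))
        assert ens.v.shape == (5, 51)
        assert ens.e.shape == (5, 51)
        assert np.all(ens.e >= 0)
        np.testing.assert_allclose(np.diff(ens.times), 0.02)

    def test_blowup_reported_with_context(self, paper_params):
        cfg = SimulationConfig(dt=10.0, n_steps=100, n_traj=3, burn_in_steps=1,
                               seed=3, variant="reduced")
        with pytest.raises(IntegrationBlowupError) as exc:
            run_ensemble(cfg, paper_params, NoiseParams(0.5, 0.05, 0.0))
        assert exc.value.step >= 1
        assert len(exc.value.trajectories) >= 1

    def test_clamp_fraction_negligible_at_reference_parameters(self, paper_params):
        cfg = SimulationConfig(dt=0.01, n_steps=5000, n_traj=50,
                               burn_in_steps=1000, seed=9, variant="full")
        ens = run_ensemble(cfg, paper_params, NoiseParams(0.5, 0.05, 0.5))
        assert ens.clamp_count / (cfg.n_steps * cfg.n_traj) < 1e-4


class TestStationaryConsistency:
    def test_reduced_preserves_stationary_law(self, paper_params, reference_noise):
        """A stationary-initialized reduced ensemble stays distributed as
        Q_st (Kolmogorov-Smirnov distance below 0.05)."""
        cfg = SimulationConfig(dt=0.01, n_steps=6000, n_traj=100,
                               burn_in_steps=1000, seed=17,
                               variant="reduced", v_init="stationary")
        ens = run_ensemble(cfg, paper_params, reference_noise)
        samples = ens.v[:, ens.retained_slice()].ravel()
        ks = stats.ks_1samp(samples, _analytic_cdf(paper_params, reference_noise))
        assert ks.statistic < 0.05

    def test_weak_convergence_in_dt(self, paper_params, reference_noise):
        """Distributional error of the Heun scheme shrinks with dt (KS to
        the analytic stationary law, matched physical horizon)."""
        cdf = _analytic_cdf(paper_params, reference_noise)
        ks_by_dt = {}
        for dt, n_steps in ((0.02, 3000), (0.005, 12_000)):
            cfg = SimulationConfig(dt=dt, n_steps=n_steps, n_traj=100,
                                   burn_in_steps=n_steps // 6, seed=23,
                                   variant="reduced", v_init="stationary")
            ens = run_ensemble(cfg, paper_params, reference_noise)
            samples = ens.v[:, ens.retained_slice()].ravel()
            ks_by_dt[dt] = stats.ks_1samp(samples, cdf).statistic
        assert ks_by_dt[0.005] < ks_by_dt[0.02]

    def test_equivalent_matches_reduced_histogram(self, paper_params,
                                                  reference_noise):
        """The single-noise Langevin equation reproduces the reduced
        two-noise stationary histogram (two-sample KS, thinned samples)."""
        mk = lambda seed, var: SimulationConfig(  # noqa: E731
            dt=0.01, n_steps=10_000, n_traj=150, burn_in_steps=2000,
            seed=seed, variant=var, v_init="stationary")
        a = run_ensemble(mk(71, "reduced"), paper_params, reference_noise)
        b = run_ensemble(mk(72, "equivalent"), paper_params, reference_noise)
        thin = 500  # ~5 well-relaxation times between retained samples
        va = a.v[:, a.retained_slice()][:, ::thin].ravel()
        vb = b.v[:, b.retained_slice()][:, ::thin].ravel()
        assert stats.ks_2samp(va, vb).pvalue > 0.01

    def test_perfect_correlation_never_crosses_noise_root(self, paper_params):
        """At mu = 1 the noise vanishes at v = sqrt(M2/M1); trajectories in
        the occupied well below the root stay below it."""
        n = NoiseParams(0.5, 0.05, 1.0)
        root = np.sqrt(n.M2 / n.M1)
        for variant in ("reduced", "equivalent"):
            cfg = SimulationConfig(dt=0.01, n_steps=10_000, n_traj=30,
                                   burn_in_steps=1000, seed=31,
                                   variant=variant, v_init="stationary")
            ens = run_ensemble(cfg, paper_params, n)
            assert ens.v.max() < root

    def test_full_matches_reduced_when_depot_is_fast(self):
        """Adiabatic elimination is quantitative when the depot relaxation
        rate c + d2 v^2 is large next to the velocity relaxation near the
        wells; full and reduced histograms then agree (KS < 0.07)."""
        p = ModelParams(gamma0=2.0, q=2.0, c=5.0, d2=20.0)
        n = NoiseParams(0.05, 0.3, 0.0)
        mk = lambda seed, var: SimulationConfig(  # noqa: E731
            dt=0.002, n_steps=40_000, n_traj=80, burn_in_steps=8000,
            seed=seed, variant=var)
        vf = run_ensemble(mk(53, "full"), p, n)
        vr = run_ensemble(mk(54, "reduced"), p, n)
        a = vf.v[:, vf.retained_slice()][:, ::400].ravel()
        b = vr.v[:, vr.retained_slice()][:, ::400].ravel()
        assert stats.ks_2samp(a, b).statistic < 0.07
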