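"""Smoluchowski first-passage solver, diffusivity models and oracles."""

import numpy as np
import pytest

from npcvoid.pmf import PMFProfile
from npcvoid.transport import (DiffusivityProfile, bd_oracle_mfpt,
                               diffusivity_profile, free_diffusion_fpt_density,
                               mfpt_exact, solve_fpt, stokes_einstein_d0,
                               transition_rates)


def flat_rates(z0=-200.0, z1=200.0, d=2.0, D0=100.0):
    z = np.arange(z0, z1 + 1e-9, d)
    dp = DiffusivityProfile.constant(z, D0)
    return transition_rates(dp, np.zeros_like(z), d=d)


class TestDiffusivityModels:
    def test_constant_area_gives_bulk(self):
        z = np.linspace(-50, 50, 101)
        for model in ("reguera_rubi", "zwanzig"):
            dp = diffusivity_profile(z, np.full_like(z, 400.0), 50.0, model)
            assert np.allclose(dp.D, 50.0)

    def test_linear_width_slopes(self):
        # w(z) = w0 + z (slope 1): Reguera-Rubi D0/sqrt(2); Zwanzig D0/1.5
        z = np.linspace(0, 50, 201)
        w = 100.0 + z
        area = np.pi * w**2
        rr = diffusivity_profile(z, area, 60.0, "reguera_rubi")
        zw = diffusivity_profile(z, area, 60.0, "zwanzig")
        inner = slice(2, -2)
        assert np.allclose(rr.D[inner], 60.0 / np.sqrt(2.0), rtol=1e-6)
        assert np.allclose(zw.D[inner], 60.0 / 1.5, rtol=1e-6)

    def test_pointwise_formula_oracle(self):
        rng = np.random.default_rng(14)
        z = np.linspace(-100, 100, 201)
        w = 50.0 + 10.0 * np.sin(z / 30.0) + rng.normal(0, 0.1, z.shape)
        area = np.pi * w**2
        s = np.gradient(np.sqrt(area / np.pi), z)
        rr = diffusivity_profile(z, area, 10.0, "reguera_rubi")
        zw = diffusivity_profile(z, area, 10.0, "zwanzig")
        assert np.allclose(rr.D, 10.0 / np.sqrt(1 + s**2))
        assert np.allclose(zw.D, 10.0 / (1 + 0.5 * s**2))
        # sqrt(1+s^2) <= 1 + s^2/2, so the Zwanzig correction slows diffusion
        # at least as much as Reguera-Rubi at every point
        assert np.all(rr.D >= zw.D - 1e-12)

    def test_w_squared_pi_equals_area(self):
        z = np.linspace(0, 10, 11)
        area = np.linspace(100, 400, 11)
        dp = diffusivity_profile(z, area, 5.0)
        assert np.allclose(dp.w**2 * np.pi, area)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            diffusivity_profile([0, 1], [10.0, -1.0], 5.0)

    def test_stokes_einstein_scale(self):
        # ~25 A protein diffuses ~1e4 A^2/us in water
        assert stokes_einstein_d0(24.47) == pytest.approx(1e4, rel=0.01)


class TestTransitionRates:
    def test_flat_rates_value(self):
        r = flat_rates(d=2.0, D0=100.0)
        assert np.allclose(r.k_up[1:], 100.0 / 4.0)
        assert np.allclose(r.k_dn[1:], 100.0 / 4.0)
        assert r.k_up[0] == r.k_dn[0] == 0.0  # reflecting convention

    def test_detailed_balance(self):
        rng = np.random.default_rng(3)
        z = np.arange(0, 50.0, 1.0)
        V = rng.uniform(0, 3, len(z))
        dp = DiffusivityProfile.constant(z, 10.0)
        r = transition_rates(dp, V, d=1.0)
        ratio = r.k_up[1:] / r.k_dn[1:]
        assert np.allclose(ratio, np.exp(-(V[2:] - V[1:-1])))

    def test_hard_wall_isolated(self):
        z = np.arange(0, 10.0, 1.0)
        V = np.zeros_like(z)
        V[5] = np.inf
        dp = DiffusivityProfile.constant(z, 10.0)
        r = transition_rates(dp, V, d=1.0)
        assert r.k_up[4] == r.k_dn[4] == 0.0
        assert r.k_up[5] == r.k_dn[5] == 0.0

    def test_grid_mismatch_rejected(self):
        z = np.arange(0, 10.0, 1.0)
        dp = DiffusivityProfile.constant(z, 10.0)
        with pytest.raises(ValueError):
            transition_rates(dp, np.zeros(5), d=1.0)


class TestSolver:
    def test_flat_pmf_closed_form_coarse(self):
        # tau = (L^2 - x0^2) / 2D, x0 measured from the reflecting wall
        r = flat_rates(z0=-200, z1=200, d=1.0, D0=100.0)
        res = solve_fpt(r, z_start=-100.0)
        closed = (400.0**2 - 100.0**2) / 200.0
        assert res.mfpt == pytest.approx(closed, rel=0.01)
        assert res.residual < 1e-3
        assert res.converged

    def test_exact_solve_matches_euler(self):
        rng = np.random.default_rng(8)
        z = np.arange(-60, 60.0 + 1e-9, 1.0)
        V = 1.5 * np.exp(-(z**2) / 400.0) + 0.3 * np.sin(z / 9.0)
        dp = DiffusivityProfile.constant(z, 80.0)
        r = transition_rates(dp, V, d=1.0)
        tau_e = mfpt_exact(r, -40.0)
        res = solve_fpt(r, -40.0)
        assert res.mfpt == pytest.approx(tau_e, rel=5e-3)

    def test_mass_conservation_flag(self):
        r = flat_rates(d=2.0)
        res = solve_fpt(r, z_start=-100.0)
        total = res.absorbed_mass() + res.residual
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_doubling_d0_halves_tau_exactly(self):
        z = np.arange(-50, 50.0 + 1e-9, 1.0)
        V = np.exp(-(z**2) / 200.0)
        t1 = mfpt_exact(transition_rates(
            DiffusivityProfile.constant(z, 40.0), V, d=1.0), -30.0)
        t2 = mfpt_exact(transition_rates(
            DiffusivityProfile.constant(z, 80.0), V, d=1.0), -30.0)
        assert t1 / t2 == pytest.approx(2.0, rel=1e-9)

    def test_grid_refinement_convergence(self):
        # production-size domain: halving d changes tau by < 0.5% (the only
        # O(d) term is the half-node offset of the no-flux wall, negligible
        # relative to an 800 A domain)
        taus = []
        for d in (2.0, 1.0):
            z = np.arange(-600.0, 200.0 + 1e-9, d)
            V = 1.2 * np.exp(-(z**2) / 500.0)
            r = transition_rates(DiffusivityProfile.constant(z, 100.0), V, d=d)
            taus.append(mfpt_exact(r, -200.0))
        assert abs(taus[1] - taus[0]) / taus[1] < 0.005

    def test_diffusion_model_swap_bounded(self):
        """Switching Reguera-Rubi for Zwanzig changes tau only modestly."""
        z = np.arange(-80, 80 + 1e-9, 1.0)
        w = 60.0 - 30.0 * np.exp(-(z**2) / (2 * 25.0**2))
        area = np.pi * w**2
        F = -np.log(area / area[0])
        taus = {}
        for model in ("reguera_rubi", "zwanzig"):
            dp = diffusivity_profile(z, area, 100.0, model)
            taus[model] = mfpt_exact(transition_rates(dp, F, d=1.0), -60.0)
        ratio = taus["zwanzig"] / taus["reguera_rubi"]
        assert 1.0 - 1e-9 < ratio  # Zwanzig slows diffusion at least as much
        assert abs(np.log(ratio)) < 0.3

    def test_arrhenius_scaling_over_barrier_sweep(self):
        """Kramers limit: tau grows as exp(V0) across a 2 kT sweep of a high
        plateau barrier; the log-slope is within 5% of unity."""
        d, D = 2.0, 100.0
        z = np.arange(-50.0, 50.0 + 1e-9, d)
        # flat-topped barrier: the plateau reaches the nominal height so the
        # Kramers exponent is not diluted by the edge profile
        shape = 0.5 * (np.tanh((z + 15.0) / 3.0) - np.tanh((z - 15.0) / 3.0))
        taus = []
        heights = [8.0, 9.0, 10.0]
        for V0 in heights:
            r = transition_rates(DiffusivityProfile.constant(z, D),
                                 V0 * shape, d=d)
            taus.append(solve_fpt(r, z_start=-40.0).mfpt)
        slope = np.polyfit(heights, np.log(taus), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_unstable_dt_reduced_with_warning(self):
        r = flat_rates(d=2.0)
        with pytest.warns(UserWarning, match="stability"):
            res = solve_fpt(r, z_start=-100.0, dt=1.0)
        assert res.mfpt == pytest.approx(1500.0 * 0.5 / 100.0 * 100.0, rel=0.05)

    def test_hard_wall_between_start_and_absorber(self):
        z = np.arange(-20, 20.0 + 1e-9, 1.0)
        V = np.zeros_like(z)
        V[30] = np.inf
        r = transition_rates(DiffusivityProfile.constant(z, 10.0), V, d=1.0)
        assert mfpt_exact(r, -10.0) == np.inf


class TestFreeDiffusionDensity:
    def test_mode_location(self):
        # d ln P / dt = 0 at t* = l^2 / (6 D)
        t = np.linspace(1e-3, 2000, 400_000)
        P = free_diffusion_fpt_density(400.0, 100.0, t)
        t_star = t[np.argmax(P)]
        assert t_star == pytest.approx(400.0**2 / 600.0, rel=1e-3)
        assert t_star == pytest.approx(266.7, rel=1e-2)

    def test_normalization(self):
        # the t^{-3/2} tail needs a logarithmic grid to integrate to 1e-4
        t = np.logspace(-4, 14, 40_000)
        P = free_diffusion_fpt_density(400.0, 100.0, t)
        assert np.trapezoid(P, t) == pytest.approx(1.0, abs=1e-4)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            free_diffusion_fpt_density(-1.0, 100.0, [1.0])


class TestBDOracle:
    def test_flat_pmf_matches_closed_form(self):
        z = np.arange(-100, 100.0 + 1e-9, 1.0)
        pmf = PMFProfile(z=z, F=np.zeros_like(z))
        dp = DiffusivityProfile.constant(z, 100.0)
        mean, sem = bd_oracle_mfpt(pmf, dp, n_walkers=5000, rng_seed=1,
                                   z_start=-50.0)
        closed = (200.0**2 - 50.0**2) / 200.0
        assert abs(mean - closed) < 2 * sem + 1.0

    def test_seed_reproducibility(self):
        z = np.arange(-50, 50.0 + 1e-9, 1.0)
        pmf = PMFProfile(z=z, F=np.zeros_like(z))
        dp = DiffusivityProfile.constant(z, 50.0)
        a = bd_oracle_mfpt(pmf, dp, n_walkers=500, rng_seed=7, z_start=-25.0)
        b = bd_oracle_mfpt(pmf, dp, n_walkers=500, rng_seed=7, z_start=-25.0)
        assert a == b

    def test_gaussian_well_matches_solver(self):
        z = np.arange(-80, 80.0 + 1e-9, 1.0)
        F = -1.5 * np.exp(-(z**2) / (2 * 15.0**2))
        pmf = PMFProfile(z=z, F=F)
        dp = DiffusivityProfile.constant(z, 100.0)
        tau = mfpt_exact(transition_rates(dp, F, d=1.0), -50.0)
        mean, sem = bd_oracle_mfpt(pmf, dp, n_walkers=4000, rng_seed=3,
                                   z_start=-50.0)
        assert abs(mean - tau) < 2 * sem + 0.02 * tau
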