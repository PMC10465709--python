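"""Core PFC dynamics: free energy, chemical potential, dispersion relation,
semi-implicit stepping, conservation and Lyapunov properties."""

import numpy as np
import pytest
from scipy import fft

from fibrilpfc.grid import GridSpec, PhaseField
from fibrilpfc.grf import GRFParams, sample_grf
from fibrilpfc.pfc import (
    PFCParams,
    Stepper,
    chemical_potential,
    dispersion_rate,
    free_energy,
    one_mode_spacing,
    run,
    step,
)


def uniform_field(grid: GridSpec, value: float) -> PhaseField:
    return PhaseField(np.full(grid.shape, value), grid)


class TestFreeEnergy:
    def test_uniform_state_closed_form(self):
        # F = A [ (q*^4 - r) phi0^2 / 2 + phi0^4 / 4 ]; unit area via 32 px of 1/32
        grid = GridSpec(32, 32, dx=1 / 32)
        params = PFCParams(r=0.8, phi0=0.4, qstar=1.0, dt=0.1)
        f = free_energy(uniform_field(grid, 0.4), None, params)
        assert f == pytest.approx(0.0224, rel=1e-12)

    def test_zero_field_zero_energy(self):
        grid = GridSpec(32, 32)
        params = PFCParams(r=0.8, phi0=0.0, dt=0.1)
        assert free_energy(uniform_field(grid, 0.0), None, params) == 0.0

    def test_single_mode_closed_form(self):
        # phi = a cos(q* x) on a commensurate periodic box:
        # F = A [ -r a^2/4 + 3 a^4/32 ]  (gradient term vanishes at k = q*)
        n, a, r = 64, 0.3, 0.8
        dx = 2 * np.pi / n  # one wavelength across the box at q* = 1
        grid = GridSpec(n, n, dx=dx)
        x = np.arange(n) * dx
        vals = np.tile(a * np.cos(x), (n, 1))
        params = PFCParams(r=r, phi0=0.0, qstar=1.0, dt=0.1)
        area = (n * dx) ** 2
        expect = area * (-r * a**2 / 4.0 + 3.0 * a**4 / 32.0)
        assert free_energy(PhaseField(vals, grid), None, params) == pytest.approx(
            expect, rel=1e-10
        )


class TestChemicalPotential:
    def test_uniform_state(self):
        grid = GridSpec(32, 32)
        params = PFCParams(r=0.8, phi0=0.4, dt=0.1)
        mu = chemical_potential(uniform_field(grid, 0.4), params)
        expect = (1.0 - 0.8) * 0.4 + 0.4**3
        assert np.allclose(mu, expect, atol=1e-12)

    def test_zero_field(self):
        grid = GridSpec(32, 32)
        params = PFCParams(r=0.8, phi0=0.0, dt=0.1)
        assert np.allclose(
            chemical_potential(uniform_field(grid, 0.0), params), 0.0
        )

    def test_resonant_mode_linear_part(self):
        # phi = cos(q* x): [(q*^2+lap)^2 - r] phi = -r cos(q* x)
        n = 64
        dx = 2 * np.pi / n
        grid = GridSpec(n, n, dx=dx)
        x = np.arange(n) * dx
        vals = np.tile(np.cos(x), (n, 1)) * 1e-3  # small so cubic is negligible
        params = PFCParams(r=0.8, phi0=0.0, qstar=1.0, dt=0.1)
        mu = chemical_potential(PhaseField(vals, grid), params)
        assert np.allclose(mu, -0.8 * vals, atol=1e-9)


class TestDispersion:
    def test_zero_mode_conserved(self):
        params = PFCParams(r=0.8, phi0=0.4, dt=0.1)
        assert dispersion_rate(0.0, params) == 0.0

    def test_value_at_qstar(self):
        params = PFCParams(r=0.8, phi0=0.4, qstar=1.0, dt=0.1)
        # sigma(q*) = q*^2 (r - 3 phi0^2) = 0.8 - 0.48 = 0.32
        assert dispersion_rate(1.0, params) == pytest.approx(0.32, rel=1e-12)

    def test_all_modes_stable_below_threshold(self):
        params = PFCParams(r=0.1, phi0=0.4, dt=0.1)  # r < 3 phi0^2 = 0.48
        k = np.linspace(0.0, 3.0, 500)
        assert (dispersion_rate(k, params) <= 1e-12).all()

    def test_measured_growth_rates_match_dispersion(self):
        """Log-amplitude growth of seeded single modes matches sigma(k) to 2%."""
        n, phi0, r = 64, 0.4, 0.8
        grid = GridSpec(n, n, dx=1.0)
        params = PFCParams(r=r, phi0=phi0, dt=0.02, dx_model=1.0)
        x = np.arange(n)
        for mode in (6, 8, 10, 12):  # k = 2 pi m / 64 around q* = 1
            k = 2 * np.pi * mode / n
            sigma = dispersion_rate(k, params)
            amp0 = 1e-4
            vals = phi0 + amp0 * np.cos(k * x)[None, :].repeat(n, axis=0)
            field = PhaseField(vals.copy(), grid)
            stepper = Stepper(grid, None, params)
            v = field.values
            n_steps = 100
            for _ in range(n_steps):
                v = stepper.step_values(v)
            amp1 = 2 * np.abs(np.fft.fft(v[0] - v[0].mean())[mode]) / n
            measured = np.log(amp1 / amp0) / (n_steps * params.dt)
            assert measured == pytest.approx(sigma, rel=0.02, abs=5e-4)


class TestStep:
    def test_uniform_state_is_fixed_point(self):
        grid = GridSpec(32, 32)
        params = PFCParams(r=0.8, phi0=0.4, dt=0.2)
        f0 = uniform_field(grid, 0.4)
        f1 = step(f0, None, params)
        assert np.allclose(f1.values, 0.4, atol=1e-13)
        assert f1.time == pytest.approx(0.2)

    def test_mass_conserved_to_rounding_over_many_steps(self):
        grid = GridSpec(64, 64)
        params = PFCParams(r=0.8, phi0=0.4, dt=0.2, dx_model=1.0)
        ic = sample_grf(grid, None, GRFParams(phi0=0.4, m2=0.01, lam=0.0, seed=2))
        stepper = Stepper(grid, None, params)
        v = ic.values
        mean0 = v.mean()
        for _ in range(10_000):
            v = stepper.step_values(v)
        assert abs(v.mean() - mean0) / abs(mean0) <= 1e-10

    def test_unstable_dt_rejected(self):
        grid = GridSpec(64, 64)
        with pytest.raises(ValueError, match="unstable"):
            Stepper(grid, None, PFCParams(r=0.8, phi0=0.4, dt=5.0, dx_model=1.0))

    def test_blow_up_reported_with_time(self):
        grid = GridSpec(32, 32)
        params = PFCParams(r=0.8, phi0=0.4, dt=0.2)
        bad = PhaseField(np.full(grid.shape, 1e200), grid, time=3.0)
        with pytest.raises(FloatingPointError, match="t="):
            step(bad, None, params)


class TestRun:
    def test_subcritical_returns_to_uniform(self):
        # r = 0.1 < 3 phi0^2 = 0.48: all modes decay, field flattens
        grid = GridSpec(64, 64)
        params = PFCParams(r=0.1, phi0=0.4, dt=0.2, t_end=200.0, save_stride=100,
                           dx_model=1.0)
        ic = sample_grf(grid, None, GRFParams(phi0=0.4, m2=1e-4, lam=0.0, seed=3))
        traj = run(ic, None, params, keep_snapshots=False)
        assert traj.final.values.std() < 1e-4

    def test_free_energy_monotone_on_periodic_run(self):
        grid = GridSpec(64, 64)
        params = PFCParams(r=0.8, phi0=0.4, dt=0.2, t_end=200.0, save_stride=10,
                           dx_model=1.209)
        ic = sample_grf(grid, None, GRFParams(phi0=0.4, m2=0.01, lam=0.0, seed=4))
        traj = run(ic, None, params, keep_snapshots=False)
        fe = traj.series.free_energy
        increases = np.diff(fe)
        scale = np.abs(fe).max()
        assert (increases <= 1e-6 * scale).all()

    def test_same_seed_reproduces_trajectory(self):
        grid = GridSpec(48, 48)
        params = PFCParams(r=0.8, phi0=0.4, dt=0.2, t_end=20.0, save_stride=50,
                           dx_model=1.209)
        ic = sample_grf(grid, None, GRFParams(phi0=0.4, m2=0.01, lam=0.0, seed=5))
        t1 = run(ic, None, params)
        t2 = run(ic, None, params)
        assert np.array_equal(t1.final.values, t2.final.values)

    def test_semi_implicit_matches_tiny_dt_explicit_integrator(self):
        """Independent explicit-Euler reference on a 64^2 periodic run to t=1."""
        n = 64
        grid = GridSpec(n, n, dx=1.0)
        params = PFCParams(r=0.8, phi0=0.4, dt=1e-3, dx_model=1.0)
        ic = sample_grf(grid, None, GRFParams(phi0=0.4, m2=1e-4, lam=2.0, seed=6))

        # explicit reference: phi' = -k^2 mu_hat, mu from its definition
        kx = 2 * np.pi * fft.fftfreq(n)
        k2 = kx[None, :] ** 2 + kx[:, None] ** 2
        sym = (1.0 - k2) ** 2 - params.r
        dt_e = 2e-4
        v = ic.values.copy()
        for _ in range(int(round(1.0 / dt_e))):
            mu_hat = sym * fft.fft2(v) + fft.fft2(v**3)
            v = np.real(fft.ifft2(fft.fft2(v) - dt_e * k2 * mu_hat))
        reference = v

        stepper = Stepper(grid, None, params)
        w = ic.values.copy()
        for _ in range(int(round(1.0 / params.dt))):
            w = stepper.step_values(w)
        assert np.max(np.abs(w - reference)) <= 1e-4

    def test_equilibrium_spacing_near_one_mode_value(self, periodic_equilibrium):
        """Median nearest-neighbor distance within 5% of 4 pi / (sqrt(3) q*)."""
        from fibrilpfc.defects import defect_report
        from fibrilpfc.points import detect_fibrils

        grid, params, traj = periodic_equilibrium
        h = params.spacing(grid)
        expect_px = one_mode_spacing(params.qstar) / h
        fib = detect_fibrils(traj.final, None, spacing=expect_px * grid.dx)
        assert fib.n > 50
        report = defect_report(fib)
        assert report.median_edge_length() == pytest.approx(
            expect_px * grid.dx, rel=0.05
        )


class TestMaskedRun:
    def test_pattern_initiates_at_boundary_and_propagates_inward(self):
        """Mean distance-to-boundary of crystallized pixels increases in time."""
        from fibrilpfc import pipeline
        from fibrilpfc.observables import concentration

        mask, traj = pipeline.run_study(
            301, 17, keep_snapshots=True, t_end=60.0, save_stride=25
        )
        dist = mask.signed_distance_px
        means = []
        for snap in traj.snapshots:
            cry = mask.inside & (concentration(snap) >= 0.5)
            if cry.sum() > 20:
                means.append(dist[cry].mean())
        assert len(means) >= 4
        # increasing front position: late mean distance clearly above early
        assert means[-1] > means[0]
        assert np.polyfit(range(len(means)), means, 1)[0] > 0

    def test_in_mask_mean_conserved(self):
        from fibrilpfc import pipeline

        mask, traj = pipeline.run_study(302, 18, t_end=100.0)
        final = traj.final
        drift = abs(final.values[mask.inside].mean() - 0.4)
        assert drift <= 1e-3

    def test_masked_free_energy_near_monotone(self):
        """Boundary treatment keeps FE decrease monotone to ~1e-3 relative."""
        from fibrilpfc import pipeline

        mask, traj = pipeline.run_study(303, 19, t_end=300.0)
        fe = traj.series.free_energy
        increases = np.diff(fe)
        assert increases.max() <= 5e-3 * np.abs(fe).max()
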