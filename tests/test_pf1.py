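"""Binary orientation-field model: free-energy pieces, variational
stepping, conservation/Lyapunov structure, and the moving window."""

import numpy as np
import pytest

from biominpf.grids import FieldState2D, Grid2D
from biominpf.pf1 import (NoiseParams, anisotropy_s, bulk_free_energy_density,
                          double_well_g, front_height, interpolation_p,
                          maybe_shift_window, orientation_energy_density,
                          shift_window, stable_dt, step_pf1,
                          total_free_energy)
from biominpf.scales import MobilityParams

from conftest import C_ZERO_DRIVE, make_pf1_params, seeded_state


class TestInterpolation:
    @pytest.mark.parametrize("phi,expected", [
        (0.0, 0.0), (1.0, 1.0), (0.5, 0.5), (0.25, 0.103515625)])
    def test_values(self, phi, expected):
        assert interpolation_p(phi) == pytest.approx(expected, abs=1e-15)

    def test_flat_ends(self):
        eps = 1e-7
        assert interpolation_p(eps) / eps < 1e-5
        assert (1.0 - interpolation_p(1.0 - eps)) / eps < 1e-5


class TestBulkFreeEnergy:
    def test_phase_endpoints(self, pf1_params):
        c = 0.3
        f0 = bulk_free_energy_density(0.0, c, pf1_params)
        f1 = bulk_free_energy_density(1.0, c, pf1_params)
        entropy = c * np.log(c) + (1 - c) * np.log(1 - c)
        assert f0 == pytest.approx(entropy, rel=1e-12)
        drive = (1 - c) * pf1_params.dg_A + c * pf1_params.dg_B
        assert f1 - f0 == pytest.approx(drive, rel=1e-12)

    def test_driving_force_signs(self, pf1_params):
        # mineral-rich mother phase drives crystallization, organic-rich resists
        assert (bulk_free_energy_density(1.0, 0.1, pf1_params)
                < bulk_free_energy_density(0.0, 0.1, pf1_params))
        assert (bulk_free_energy_density(1.0, 0.9, pf1_params)
                > bulk_free_energy_density(0.0, 0.9, pf1_params))

    def test_barrier_mixing_linear_in_c(self, pf1_params):
        # at the double-well maximum the barrier is the c-weighted mean
        g = double_well_g(0.5)
        vals = []
        for c in (0.0, 0.5, 1.0):
            f = bulk_free_energy_density(0.5, c, pf1_params)
            # strip entropy+drive to isolate w(c) g(phi)
            f0 = bulk_free_energy_density(0.0, c, pf1_params)
            drive = interpolation_p(0.5) * ((1 - c) * pf1_params.dg_A + c * pf1_params.dg_B)
            vals.append((f - f0 - drive) / g)
        assert vals[1] == pytest.approx(0.5 * (vals[0] + vals[2]), rel=1e-10)

    def test_log_floor_handles_out_of_range(self, pf1_params):
        assert np.isfinite(bulk_free_energy_density(0.5, -0.1, pf1_params))
        assert np.isfinite(bulk_free_energy_density(0.5, 1.2, pf1_params))


class TestOrientationEnergy:
    def test_uniform_theta_zero(self, pf1_params):
        e = orientation_energy_density(np.zeros(5), np.zeros(5),
                                       np.ones(5), pf1_params, eta=1e-3)
        assert np.all(e == 0.0)

    def test_linear_in_H(self):
        p1 = make_pf1_params(H_ori=0.5)
        p2 = make_pf1_params(H_ori=1.0)
        gy, gx = np.full(4, 0.3), np.full(4, -0.2)
        e1 = orientation_energy_density(gy, gx, 0.8, p1, eta=1e-3)
        e2 = orientation_energy_density(gy, gx, 0.8, p2, eta=1e-3)
        assert np.allclose(e2, 2 * e1)

    def test_suppressed_in_mother_phase(self, pf1_params):
        e = orientation_energy_density(np.ones(3), np.ones(3),
                                       np.zeros(3), pf1_params, eta=1e-3)
        assert np.all(e == 0.0)

    def test_two_domain_quadrature_oracle(self, pf1_params):
        # 1D profile with a smooth theta ramp inside solid; integrated energy
        # must match direct quadrature of H * p(phi) * |dtheta/dx|
        n = 200
        dx = 6.25e-3
        x = (np.arange(n) + 0.5) * dx
        theta = 0.25 / (1.0 + np.exp(-(x - x.mean()) / (5 * dx)))
        dth = np.gradient(theta, dx)
        eta = 1e-6 / dx
        dens = orientation_energy_density(np.zeros(n), dth, np.ones(n),
                                          pf1_params, eta)
        direct = pf1_params.H_ori * np.sqrt(dth**2 + eta**2) - pf1_params.H_ori * eta
        assert np.trapezoid(dens, dx=dx) == pytest.approx(
            np.trapezoid(direct, dx=dx), rel=1e-10)


class TestAnisotropy:
    def test_isotropic_limit(self):
        s = anisotropy_s(np.ones(4), np.ones(4), 0.3, s0=0.0, k=6)
        assert np.all(s == 1.0)

    def test_printed_formula_value(self):
        # normal along +x (nu = 0), theta = 0, s0 = 0.1 -> s = 1.1
        s = anisotropy_s(np.zeros(1), np.ones(1), np.zeros(1), s0=0.1, k=6, dx=1.0)
        assert s[0] == pytest.approx(1.1)

    def test_theta_circularity(self):
        gy, gx = np.full(8, 0.4), np.full(8, 1.0)
        th = np.linspace(0, 1, 8, endpoint=False)
        s1 = anisotropy_s(gy, gx, th, s0=0.07, k=6, dx=1.0)
        s2 = anisotropy_s(gy, gx, th + 1.0, s0=0.07, k=6, dx=1.0)
        assert np.allclose(s1, s2)

    def test_undefined_normal_returns_one(self):
        s = anisotropy_s(np.zeros(3), np.zeros(3), 0.2, s0=0.1, k=6, dx=1.0)
        assert np.all(s == 1.0)


class TestTotalFreeEnergy:
    def test_uniform_solid_equals_area_times_bulk(self, pf1_params, small_grid):
        c0 = 0.3
        st = FieldState2D(np.ones(small_grid.shape), np.full(small_grid.shape, c0),
                          np.full(small_grid.shape, 0.2))
        E = total_free_energy(st, pf1_params, small_grid)
        area = small_grid.nx * small_grid.ny * small_grid.dx**2
        f_C = bulk_free_energy_density(1.0, c0, pf1_params)
        assert E == pytest.approx(area * f_C, rel=1e-10)

    def test_planar_interface_excess_matches_analytic_gamma(self, pf1_params):
        # relaxed 1D profile: excess energy per unit length ~ sqrt(2 B eps^2)/6
        grid = Grid2D(8, 160, boundary={"left": "periodic", "right": "periodic",
                                        "bottom": "noflux", "top": "noflux"})
        c0 = C_ZERO_DRIVE
        params = make_pf1_params(mobility=MobilityParams(3.75, 0.0, 0.0, 0.0, 0.0))
        y = (np.arange(grid.ny) + 0.5) * grid.dx
        ell = np.sqrt(2 * params.eps_phi_sq / (0.5 * (params.w_A + params.w_B)))
        phi = 1.0 / (1.0 + np.exp((y - y.mean()) / ell))
        st = FieldState2D(phi[:, None] * np.ones((1, 8)),
                          np.full(grid.shape, c0), np.zeros(grid.shape))
        dt = stable_dt(params, grid)
        for _ in range(1500):
            st = step_pf1(st, params, grid, dt)
        E = total_free_energy(st, params, grid)
        # subtract bulk contributions (equal f at both ends: zero driving)
        area = grid.nx * grid.ny * grid.dx**2
        f_bulk = bulk_free_energy_density(0.0, c0, params)
        w_eff = (1 - c0) * params.w_A + c0 * params.w_B
        gamma_hat = np.sqrt(2 * (w_eff / 4) * params.eps_phi_sq) / 6
        excess_per_len = (E - area * f_bulk) / (grid.nx * grid.dx)
        assert excess_per_len == pytest.approx(gamma_hat, rel=0.05)


class TestStepping:
    def test_zero_mobilities_leave_fields_unchanged(self, small_grid):
        params = make_pf1_params(mobility=MobilityParams(0.0, 0.0, 0.0, 0.0, 0.0))
        st = seeded_state(small_grid)
        new = step_pf1(st, params, small_grid, 1e-6)
        assert np.array_equal(new.phi, st.phi)
        assert np.array_equal(new.c, st.c)
        assert np.array_equal(new.theta, st.theta)
        assert new.t == pytest.approx(1e-6)

    def test_uniform_single_phase_is_stationary(self, pf1_params, small_grid):
        st = FieldState2D(np.zeros(small_grid.shape),
                          np.full(small_grid.shape, 0.4),
                          np.full(small_grid.shape, 0.7))
        dt = stable_dt(pf1_params, small_grid)
        new = step_pf1(st, pf1_params, small_grid, dt)
        assert np.abs(new.phi - st.phi).max() < 1e-12
        assert np.abs(new.c - st.c).max() < 1e-12

    def test_dt_guard_refuses_and_override_works(self, pf1_params, small_grid):
        st = seeded_state(small_grid)
        dt = 2.0 * stable_dt(pf1_params, small_grid)
        with pytest.raises(ValueError, match="stability guard"):
            step_pf1(st, pf1_params, small_grid, dt)
        step_pf1(st, pf1_params, small_grid, dt, allow_unstable_dt=True)

    def test_solute_conservation_long_run(self, pf1_params, small_grid):
        st = seeded_state(small_grid, c0=0.3)
        total0 = st.c.sum()
        dt = stable_dt(pf1_params, small_grid)
        for _ in range(10_000):
            st = step_pf1(st, pf1_params, small_grid, dt, check=False)
        st.validate()
        assert abs(st.c.sum() - total0) / total0 < 1e-10

    def test_free_energy_non_increasing(self, pf1_params, small_grid):
        st = seeded_state(small_grid, c0=0.35)
        dt = stable_dt(pf1_params, small_grid)
        E = total_free_energy(st, pf1_params, small_grid)
        for k in range(400):
            st = step_pf1(st, pf1_params, small_grid, dt)
            if k % 20 == 0:
                E_new = total_free_energy(st, pf1_params, small_grid)
                assert E_new <= E + 1e-10 * abs(E)
                E = E_new

    def test_isotropy_limit_theta_shift_invariance(self, small_grid):
        # dyadic orientations + exact 1/4 shift keep the circular arithmetic
        # free of round-off, so trajectories must agree bit-for-bit
        params = make_pf1_params(s0=0.0)
        st = seeded_state(small_grid, seed=5)
        rng = np.random.default_rng(11)
        st.theta = rng.integers(0, 1024, size=small_grid.shape) / 1024.0
        shifted = st.copy()
        shifted.theta = (shifted.theta + 0.25) % 1.0
        dt = stable_dt(params, small_grid)
        a = step_pf1(st, params, small_grid, dt)
        b = step_pf1(shifted, params, small_grid, dt)
        assert np.array_equal(a.phi, b.phi)
        assert np.array_equal(a.c, b.c)
        assert np.array_equal((b.theta - 0.25) % 1.0, a.theta % 1.0) or \
            np.allclose((b.theta - a.theta) % 1.0, 0.25, atol=1e-12)

    def test_equilibrium_profile_matches_closed_form(self):
        # width of the relaxed 1D interface within 5% of sqrt(2 eps^2 / w)
        grid = Grid2D(8, 160, boundary={"left": "periodic", "right": "periodic",
                                        "bottom": "noflux", "top": "noflux"})
        params = make_pf1_params(mobility=MobilityParams(3.75, 0.0, 0.0, 0.0, 0.0))
        y = (np.arange(grid.ny) + 0.5) * grid.dx
        w_eff = (1 - C_ZERO_DRIVE) * params.w_A + C_ZERO_DRIVE * params.w_B
        ell_exact = np.sqrt(2 * params.eps_phi_sq / w_eff)
        # start from a deliberately wrong width; relaxation must restore it
        phi0 = 1.0 / (1.0 + np.exp((y - y.mean()) / (2.0 * ell_exact)))
        st = FieldState2D(phi0[:, None] * np.ones((1, 8)),
                          np.full(grid.shape, C_ZERO_DRIVE), np.zeros(grid.shape))
        dt = stable_dt(params, grid)
        for _ in range(4000):
            st = step_pf1(st, params, grid, dt)
        prof = st.phi[:, 0]
        # fit logistic width from the 25%/75% crossing separation
        y25 = np.interp(0.25, prof[::-1], y[::-1])
        y75 = np.interp(0.75, prof[::-1], y[::-1])
        ell_fit = (y25 - y75) / (2.0 * np.log(3.0))
        assert ell_fit == pytest.approx(ell_exact, rel=0.05)

    def test_noise_variance_scales_with_amplitude_squared(self, small_grid):
        st = FieldState2D(np.full(small_grid.shape, 0.5),
                          np.full(small_grid.shape, 0.4),
                          np.full(small_grid.shape, 0.2))
        dt = 1e-6
        vars_ = []
        for amp in (0.001, 0.002):
            params = make_pf1_params(noise=NoiseParams(amp_phi=amp))
            new = step_pf1(st, params, small_grid, dt,
                           np.random.default_rng(1), check=False)
            base = step_pf1(st, make_pf1_params(), small_grid, dt)
            vars_.append(np.var(new.phi - base.phi))
        assert vars_[1] / vars_[0] == pytest.approx(4.0, rel=1e-6)

    def test_front_advances_and_converges_under_refinement(self):
        # supersaturated 1D growth: velocity within 10% of half-resolution rerun
        def velocity(dx_factor):
            ny = int(120 * dx_factor)
            dx = 6.25e-3 / dx_factor
            grid = Grid2D(8, ny, dx=dx,
                          boundary={"left": "periodic", "right": "periodic",
                                    "bottom": "noflux", "top": "noflux"})
            params = make_pf1_params()
            y = (np.arange(ny) + 0.5) * dx
            ell = np.sqrt(2 * params.eps_phi_sq / params.w_A)
            phi = (1.0 / (1.0 + np.exp((y - 0.1) / ell)))[:, None] * np.ones((1, 8))
            st = FieldState2D(phi, np.full(grid.shape, 0.25), np.zeros(grid.shape))
            dt = 0.9 * stable_dt(params, grid)
            h0 = front_height(st.phi, dx=dx)
            n = int(2.4e-3 / dt)
            for _ in range(n):
                st = step_pf1(st, params, grid, dt, check=False)
            return (front_height(st.phi, dx=dx) - h0) / st.t

        v1 = velocity(1.0)
        v2 = velocity(2.0)
        assert v1 > 0
        assert v2 == pytest.approx(v1, rel=0.10)


class TestMovingWindow:
    def test_shift_updates_offset_and_fills_far_field(self, small_grid, pf1_params):
        st = seeded_state(small_grid, slab_rows=40)
        new = shift_window(st, small_grid, rows=8, far_field_c=0.45)
        assert new.frame_offset == 8
        assert np.all(new.phi[-8:] == 0.0)
        assert np.all(new.c[-8:] == 0.45)
        assert np.array_equal(new.phi[:-8], st.phi[8:])

    def test_no_shift_below_trigger(self, small_grid):
        st = seeded_state(small_grid, slab_rows=10)
        new = maybe_shift_window(st, small_grid, far_field_c=0.4)
        assert new.frame_offset == 0
        assert np.array_equal(new.phi, st.phi)

    def test_all_liquid_no_shift(self, small_grid):
        st = FieldState2D(np.zeros(small_grid.shape),
                          np.full(small_grid.shape, 0.4),
                          np.zeros(small_grid.shape))
        new = maybe_shift_window(st, small_grid, far_field_c=0.4)
        assert new.frame_offset == 0
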