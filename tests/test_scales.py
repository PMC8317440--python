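"""Estimator and dimensionless-coefficient tests.

Reference values: direct arithmetic evaluation of the closed-form
relations (Turnbull, Stokes-Einstein, diffusion length, gamma ~ T), plus
the tabulated thermodynamic state of the binary mollusk-shell model.
"""

import numpy as np
import pytest

from biominpf import scales as sc


@pytest.fixture
def aq_scales():
    return sc.PhysicalScales(gamma_A=0.150, gamma_B=0.118, delta=4.15e-8,
                             xi=2.1e-6, v_m=26.7e-6, D_cM=1e-9,
                             T_A=329.3, T_B=258.8)


class TestSquareGradientCoefficient:
    def test_reference_evaluation(self):
        eps2, w = sc.square_gradient_coefficient(0.150, 4.15e-8, 329.3)
        assert eps2 == pytest.approx(1.604e-10, rel=1e-3)
        assert w == pytest.approx(9.31e4, rel=1e-2)

    def test_linearity_and_scaling(self):
        eps2, w = sc.square_gradient_coefficient(0.0, 1e-8, 300.0)
        assert eps2 == 0.0 and w == 0.0
        e1, w1 = sc.square_gradient_coefficient(0.1, 1e-8, 300.0)
        e2, w2 = sc.square_gradient_coefficient(0.1, 2e-8, 300.0)
        assert e2 == pytest.approx(2 * e1) and w2 == pytest.approx(w1 / 2)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            sc.square_gradient_coefficient(0.1, 0.0, 300.0)
        with pytest.raises(ValueError):
            sc.square_gradient_coefficient(-0.1, 1e-8, 300.0)


class TestMobilities:
    def test_mother_phase_self_map_is_unity(self, aq_scales):
        mob = sc.dimensionless_mobilities(
            aq_scales, M_phi=1e-7, D_cC=1e-29, M_thetaM=1e-3, M_thetaC=1e-23,
            eps_phi_sq=1.6e-10, H=1.0, T=329.3)
        assert mob.m_cM == 1.0
        assert mob.m_cC / mob.m_cM == pytest.approx(1e-20)

    def test_zero_physical_mobilities_map_to_zero(self, aq_scales):
        mob = sc.dimensionless_mobilities(
            aq_scales, M_phi=0.0, D_cC=0.0, M_thetaM=0.0, M_thetaC=0.0,
            eps_phi_sq=1.6e-10, H=1.0, T=329.3)
        assert mob.m_phi == mob.m_cC == mob.m_thetaM == mob.m_thetaC == 0.0

    def test_round_trip_identity(self, aq_scales):
        mob = sc.MobilityParams(3.75, 1.0, 1e-14, 120.0, 120e-14)
        phys = sc.physical_mobilities(aq_scales, mob, eps_phi_sq=1.6e-10,
                                      H=1.0, T=329.3)
        back = sc.dimensionless_mobilities(
            aq_scales, M_phi=phys["M_phi"], D_cC=phys["D_cC"],
            M_thetaM=phys["M_thetaM"], M_thetaC=phys["M_thetaC"],
            eps_phi_sq=1.6e-10, H=1.0, T=329.3)
        for name in ("m_phi", "m_cM", "m_cC", "m_thetaM", "m_thetaC"):
            assert getattr(back, name) == pytest.approx(getattr(mob, name), rel=1e-12)

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            sc.MobilityParams(1.0, 1.0, 2.0, 1.0, 0.5)  # crystal faster than mother


class TestPhaseInterpolatedMobility:
    @pytest.mark.parametrize("phi,expected", [(1.0, 0.0), (0.0, 1.0), (0.5, 0.5)])
    def test_endpoints_and_midpoint(self, phi, expected):
        assert sc.phase_interpolated_mobility(0.0, 1.0, phi) == pytest.approx(expected)

    def test_clamping_and_monotonicity(self):
        assert sc.phase_interpolated_mobility(0.0, 1.0, 1.7) == 0.0
        phis = np.linspace(0, 1, 50)
        vals = sc.phase_interpolated_mobility(0.0, 1.0, phis)
        assert np.all(np.diff(vals) <= 1e-12)


class TestTurnbull:
    def test_acc_aragonite_estimate(self):
        # enthalpy difference ACC -> crystal with the aragonite molar volume
        gamma = sc.turnbull_interfacial_energy(
            sc.TURNBULL_ALPHA_MD, sc.ACC_ARAGONITE_TRANSFORMATION_ENTHALPY,
            sc.ARAGONITE_MOLAR_VOLUME)
        assert gamma == pytest.approx(0.087, rel=0.02)

    def test_degenerate_inputs(self):
        assert sc.turnbull_interfacial_energy(0.55, 0.0, 3e-5) == 0.0
        one = sc.turnbull_interfacial_energy(1.0, 1.0, 3e-5)
        assert sc.turnbull_interfacial_energy(1.0, 2.0, 3e-5) == pytest.approx(2 * one)
        with pytest.raises(ValueError):
            sc.turnbull_interfacial_energy(0.0, 1.0, 1.0)


class TestStokesEinsteinAndDiffusionLength:
    def test_hacc_particle_diffusivity(self):
        D = sc.stokes_einstein_diffusivity(150e-9, 300.0, 1e-3)
        assert D == pytest.approx(1.465e-12, rel=1e-3)

    def test_radius_scaling_and_zero_T(self):
        D1 = sc.stokes_einstein_diffusivity(1e-7, 300.0, 1e-3)
        D2 = sc.stokes_einstein_diffusivity(2e-7, 300.0, 1e-3)
        assert D1 == pytest.approx(2 * D2)
        assert sc.stokes_einstein_diffusivity(1e-7, 0.0, 1e-3) == 0.0

    def test_fast_coral_diffusion_length(self):
        D = sc.stokes_einstein_diffusivity(150e-9, 300.0, 1e-3)
        v = sc.growth_rate_to_si(37.0)
        assert sc.diffusion_length(D, v) == pytest.approx(0.12e-3, rel=0.05)

    def test_diffusion_length_edges(self):
        assert sc.diffusion_length(0.0, 1e-9) == 0.0
        assert sc.diffusion_length(1e-9, 1e-9) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            sc.diffusion_length(1e-9, 0.0)


class TestGammaTemperatureScaling:
    def test_reproduces_derived_interface_energies(self):
        # organic interfaces follow from gamma ~ T_trans with T_B/T_A = 0.786
        assert sc.gamma_temperature_scaling(0.150, 0.786) * 1e3 == pytest.approx(118, rel=0.01)
        assert sc.gamma_temperature_scaling(0.087, 0.786) * 1e3 == pytest.approx(68, rel=0.01)
        assert sc.gamma_temperature_scaling(0.1, 1.0) == pytest.approx(0.1)


class TestGrowthRateConversion:
    @pytest.mark.parametrize("cm_yr,expected", [(1.0, 3.2e-10), (37.0, 1.2e-8)])
    def test_coral_range(self, cm_yr, expected):
        # reference values are printed to two significant figures
        assert sc.growth_rate_to_si(cm_yr) == pytest.approx(expected, rel=0.05)

    def test_zero(self):
        assert sc.growth_rate_to_si(0.0) == 0.0


class TestRegimeClassifier:
    def test_ion_by_ion_is_deeply_diffusive(self):
        x, label = sc.classify_growth_regime(1e-9, 1e-10, 1e-9)
        assert x == pytest.approx(1e-10) and label == "diffusive"

    def test_diffusionless_boundary(self):
        x, label = sc.classify_growth_regime(1e-9, 1e-10, 1e-19)
        assert x == pytest.approx(1.0) and label == "diffusionless"

    def test_half_open_window_edges(self):
        _, label = sc.classify_growth_regime(1.0, 1e-4, 1.0)  # x exactly lower edge
        assert label == "transition"
        _, label = sc.classify_growth_regime(1.0, 1e-2, 1.0, convention="narrow")
        assert label == "transition"


class TestDrivingForce:
    def test_reference_state_exact(self):
        th = sc.ThermoParamsPF1()
        assert sc.driving_force_at_temperature(th, 0.0) == (th.dg_A, th.dg_B)

    def test_back_derived_enthalpy(self):
        th = sc.ThermoParamsPF1()
        assert th.dH_A == pytest.approx(-0.1184 / (0.911 - 1.0), rel=1e-12)
        assert th.dH_A == pytest.approx(1.330, rel=1e-3)

    def test_linearity(self):
        th = sc.ThermoParamsPF1()
        a = sc.driving_force_at_temperature(th, -0.02)
        b = sc.driving_force_at_temperature(th, 0.02)
        mid = sc.driving_force_at_temperature(th, 0.0)
        assert mid[0] == pytest.approx(0.5 * (a[0] + b[0]), rel=1e-12)
        assert mid[1] == pytest.approx(0.5 * (a[1] + b[1]), rel=1e-12)

    def test_recomputation_matches_tabulated(self):
        # internal consistency of the linear law at the reference state
        th = sc.ThermoParamsPF1()
        assert th.dH_A * (th.T_r - 1.0) == pytest.approx(th.dg_A, abs=1e-12)
        assert th.dH_B * (th.T_r / th.T_rB - 1.0) == pytest.approx(th.dg_B, abs=1e-12)


class TestDimensionlessCoefficients:
    def test_width_identity_and_positivity(self, aq_scales):
        co = sc.dimensionless_coefficients(aq_scales)
        # eps^2 / w_i = (delta/xi)^2 by construction of the coefficient pair
        delta_hat = aq_scales.delta / aq_scales.xi
        assert co.eps_phi_sq / co.w_A == pytest.approx(delta_hat**2, rel=1e-2)
        # gamma ~ T makes the *dimensionless* interfacial energies coincide
        assert co.gamma_A > 0
        assert co.gamma_B == pytest.approx(co.gamma_A, rel=0.01)

    def test_time_unit(self, aq_scales):
        assert aq_scales.time_unit == pytest.approx(4.41e-3, rel=1e-3)
        assert aq_scales.velocity_to_si(1.0) == pytest.approx(1e-9 / 2.1e-6)

    def test_invalid_scales_rejected(self):
        with pytest.raises(ValueError):
            sc.PhysicalScales(gamma_A=0.1, gamma_B=0.1, delta=-1.0, xi=1e-6,
                              v_m=3e-5, D_cM=1e-9, T_A=300, T_B=250)
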