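"""Dimensional materials data, dimensionless model coefficients, and
closed-form materials-parameter estimators.

The simulation models work in dimensionless form: lengths are measured in a
mesoscale unit ``xi``, time in ``xi**2 / D_cM`` (diffusive scaling with the
mother-phase chemical diffusion coefficient), and free-energy densities in
``R*T/v_m``.  This module holds the dimensional inputs (interfacial free
energies, interface thickness, molar volume, diffusivities, transition
temperatures) and converts them into the dimensionless coefficients the
phase-field models consume.  It also implements the small closed-form
estimators used to bracket the physics: Turnbull's interfacial-energy
relation, Stokes-Einstein particle diffusivity, diffusion lengths, and the
diffusive/diffusionless growth-regime classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "K_BOLTZMANN",
    "N_AVOGADRO",
    "R_GAS",
    "JULIAN_YEAR_S",
    "ARAGONITE_MOLAR_VOLUME",
    "ACC_ARAGONITE_TRANSFORMATION_ENTHALPY",
    "TURNBULL_ALPHA_MD",
    "PhysicalScales",
    "ThermoParamsPF1",
    "MobilityParams",
    "square_gradient_coefficient",
    "dimensionless_mobilities",
    "physical_mobilities",
    "phase_interpolated_mobility",
    "turnbull_interfacial_energy",
    "stokes_einstein_diffusivity",
    "diffusion_length",
    "gamma_temperature_scaling",
    "growth_rate_to_si",
    "classify_growth_regime",
    "driving_force_at_temperature",
    "DimensionlessCoefficients",
    "dimensionless_coefficients",
]

K_BOLTZMANN = 1.380649e-23  # J/K
N_AVOGADRO = 6.02214076e23  # 1/mol
R_GAS = 8.31446261815324  # J/(mol K)

#: Julian year in seconds; used for cm/year -> m/s growth-rate conversions.
JULIAN_YEAR_S = 3.1557e7

#: Molar volume of aragonite (M = 100.09 g/mol, rho = 2.93 g/cm^3), m^3/mol.
#: This is the crystal-phase molar volume entering Turnbull's relation.
ARAGONITE_MOLAR_VOLUME = 34.2e-6

#: Calorimetric enthalpy difference between ACC and crystalline CC, J/mol.
ACC_ARAGONITE_TRANSFORMATION_ENTHALPY = 14300.0

#: Turnbull coefficient for the ACC -> crystal transition (MD-derived).
TURNBULL_ALPHA_MD = 0.55

_SQRT2 = math.sqrt(2.0)


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0.0) or not math.isfinite(value):
            raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class PhysicalScales:
    """Dimensional quantities used to (de/re)dimensionalize a model.

    Parameters
    ----------
    gamma_A, gamma_B:
        Interfacial free energies of the mineral-mother and organic-mother
        interfaces (J/m^2).
    delta:
        Crystal-mother interface thickness (m).
    xi:
        Simulation length unit (m); one grid cell is ``dx * xi``.
    v_m:
        Average molar volume of the components (m^3/mol).
    D_cM:
        Chemical diffusion coefficient of the mother phase (m^2/s); sets the
        time unit ``xi**2 / D_cM``.
    T_A, T_B:
        Transition temperatures of the pure components (K); component A is
        the mineral (CC), component B the organic constituent.
    """

    gamma_A: float
    gamma_B: float
    delta: float
    xi: float
    v_m: float
    D_cM: float
    T_A: float
    T_B: float
    R_gas: float = R_GAS

    def __post_init__(self) -> None:
        _require_positive(
            gamma_A=self.gamma_A, gamma_B=self.gamma_B, delta=self.delta,
            xi=self.xi, v_m=self.v_m, D_cM=self.D_cM, T_A=self.T_A,
            T_B=self.T_B, R_gas=self.R_gas,
        )

    @property
    def time_unit(self) -> float:
        """Dimensional duration of one dimensionless time unit (s)."""
        return self.xi**2 / self.D_cM

    def velocity_to_si(self, v_dimensionless: float) -> float:
        """Convert a dimensionless front velocity to m/s (``v * D_cM / xi``)."""
        return v_dimensionless * self.D_cM / self.xi

    def length_to_si(self, length_dimensionless: float) -> float:
        return length_dimensionless * self.xi


@dataclass(frozen=True)
class ThermoParamsPF1:
    """Ideal-solution thermodynamic state of the binary (CC + organic) model.

    ``dg_A`` and ``dg_B`` are the dimensionless crystallization driving
    forces Delta_G_i/RT of the pure components at reduced temperature
    ``T_r = T/T_A``; the linear law Delta_G_i = Delta_H_i (T - T_i)/T_i
    connects them to the (back-derived) dimensionless enthalpies ``dH_i``.
    """

    T_r: float = 0.911
    T_rB: float = 0.786
    dg_A: float = -0.1184
    dg_B: float = 0.1554

    def __post_init__(self) -> None:
        _require_positive(T_r=self.T_r, T_rB=self.T_rB)

    @property
    def dH_A(self) -> float:
        """Dimensionless transformation enthalpy of the mineral component."""
        return self.dg_A / (self.T_r - 1.0)

    @property
    def dH_B(self) -> float:
        """Dimensionless transformation enthalpy of the organic component."""
        return self.dg_B / (self.T_r / self.T_rB - 1.0)


@dataclass(frozen=True)
class MobilityParams:
    """Dimensionless mobilities of the phase, concentration and orientation
    fields; mother-phase chemical mobility is the reference (== 1)."""

    m_phi: float
    m_cM: float
    m_cC: float
    m_thetaM: float
    m_thetaC: float

    def __post_init__(self) -> None:
        for name in ("m_phi", "m_cM", "m_cC", "m_thetaM", "m_thetaC"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.m_cC > self.m_cM:
            raise ValueError("crystal chemical mobility exceeds mother-phase value")
        if self.m_thetaC > self.m_thetaM:
            raise ValueError("crystal orientational mobility exceeds mother-phase value")


def square_gradient_coefficient(gamma: float, delta: float, T: float) -> tuple[float, float]:
    """Square-gradient coefficient and double-well height for one component.

    ``eps_phi^2 = (12/sqrt(2)) * gamma * delta / T`` and
    ``w = (12/sqrt(2)) * gamma / (delta * T)`` (SI), the combination for
    which a relaxed interface of 10-90% width ~ ``delta`` carries excess
    free energy ``gamma``.

    Returns ``(eps_phi_sq, w)``.  ``gamma`` may be zero (both vanish);
    ``delta`` and ``T`` must be positive.
    """
    if gamma < 0:
        raise ValueError(f"gamma must be >= 0, got {gamma!r}")
    _require_positive(delta=delta, T=T)
    pref = 12.0 / _SQRT2
    return pref * gamma * delta / T, pref * gamma / (delta * T)


def dimensionless_mobilities(
    scales: PhysicalScales,
    *,
    M_phi: float,
    D_cC: float,
    M_thetaM: float,
    M_thetaC: float,
    eps_phi_sq: float,
    H: float,
    T: float,
) -> MobilityParams:
    """Map physical mobilities/diffusivities to the dimensionless set.

    ``m_phi = M_phi * eps_phi^2 * T / D_cM``, ``m_c = D_c / D_cM`` (the
    composition prefactor ``(v_m/RT) c(1-c)`` is applied inside the flux at
    run time, so a chemical mobility corresponding to ``D_cM`` maps to 1),
    and ``m_theta = M_theta * xi * H * T / D_cM``.
    """
    _require_positive(D_cM=scales.D_cM)
    m_phi = M_phi * eps_phi_sq * T / scales.D_cM
    m_cM = 1.0
    m_cC = D_cC / scales.D_cM
    m_thetaM = M_thetaM * scales.xi * H * T / scales.D_cM
    m_thetaC = M_thetaC * scales.xi * H * T / scales.D_cM
    return MobilityParams(m_phi, m_cM, m_cC, m_thetaM, m_thetaC)


def physical_mobilities(
    scales: PhysicalScales,
    mob: MobilityParams,
    *,
    eps_phi_sq: float,
    H: float,
    T: float,
) -> dict[str, float]:
    """Inverse of :func:`dimensionless_mobilities` (round-trip identity)."""
    D = scales.D_cM
    return {
        "M_phi": mob.m_phi * D / (eps_phi_sq * T),
        "D_cM": mob.m_cM * D,
        "D_cC": mob.m_cC * D,
        "M_thetaM": mob.m_thetaM * D / (scales.xi * H * T),
        "M_thetaC": mob.m_thetaC * D / (scales.xi * H * T),
    }


def interpolation_p(phi):
    """Quintic interpolant p(phi) = phi^3 (10 - 15 phi + 6 phi^2).

    Anchors p(0)=0, p(1)=1 with vanishing first derivatives, so bulk phases
    are not shifted by the interpolation.
    """
    phi = np.asarray(phi, dtype=float) if not np.isscalar(phi) else phi
    return phi**3 * (10.0 - 15.0 * phi + 6.0 * phi**2)


def phase_interpolated_mobility(M_C, M_M, phi):
    """Phase-dependent mobility M = M_C + [1 - p(phi)] (M_M - M_C).

    ``phi`` is clamped to [0, 1]; returns the crystal value at phi=1 and the
    mother-phase value at phi=0.
    """
    phi_c = np.clip(phi, 0.0, 1.0)
    return M_C + (1.0 - interpolation_p(phi_c)) * (M_M - M_C)


def turnbull_interfacial_energy(alpha: float, deltaH: float, v_mc: float) -> float:
    """Turnbull's estimate gamma = alpha * deltaH / (N0 * v_mc^2)^(1/3) (J/m^2).

    ``deltaH`` is the molar heat of transformation (J/mol) and ``v_mc`` the
    molar volume of the crystalline phase (m^3/mol).  ``deltaH = 0`` returns 0.
    """
    if deltaH < 0:
        raise ValueError(f"deltaH must be >= 0, got {deltaH!r}")
    _require_positive(alpha=alpha, v_mc=v_mc)
    return alpha * deltaH / (N_AVOGADRO * v_mc**2) ** (1.0 / 3.0)


def stokes_einstein_diffusivity(R_p: float, T: float, eta: float) -> float:
    """Stokes-Einstein diffusivity D = k_B T / (6 pi R_p eta) (m^2/s).

    ``T = 0`` returns 0; particle radius and viscosity must be positive.
    """
    if T < 0:
        raise ValueError(f"T must be >= 0, got {T!r}")
    _require_positive(R_p=R_p, eta=eta)
    return K_BOLTZMANN * T / (6.0 * math.pi * R_p * eta)


def diffusion_length(D: float, v: float) -> float:
    """Diffusion length l_D = D / v (m); growth rate ``v`` must be positive."""
    if D < 0:
        raise ValueError(f"D must be >= 0, got {D!r}")
    _require_positive(v=v)
    return D / v


def gamma_temperature_scaling(gamma_ref: float, T_ratio: float) -> float:
    """Scale an interfacial free energy by a transition-temperature ratio.

    For materials of comparable transformation entropy the interfacial free
    energy is proportional to the transition temperature, so the second
    component's gamma follows from the first as ``gamma_ref * T_ratio``.
    """
    _require_positive(gamma_ref=gamma_ref, T_ratio=T_ratio)
    return gamma_ref * T_ratio


def growth_rate_to_si(rate_cm_per_year: float) -> float:
    """Convert a growth rate from cm/year to m/s (Julian year)."""
    if rate_cm_per_year < 0:
        raise ValueError(f"rate must be >= 0, got {rate_cm_per_year!r}")
    return rate_cm_per_year * 1e-2 / JULIAN_YEAR_S


#: (lower, upper) bounds of the diffusive->diffusionless transition window
#: of the Peclet-like number d*v/D; two conventions are in circulation.
REGIME_WINDOWS = {"wide": (1e-4, 1.0), "narrow": (1e-2, 10.0)}


def classify_growth_regime(d: float, v: float, D: float, convention: str = "wide"):
    """Classify growth as diffusive / transition / diffusionless.

    The dimensionless number ``d*v/D`` (interface thickness x velocity over
    mother-phase diffusivity) is compared with a transition window; labels
    use the half-open convention [lower, upper).  Returns ``(x, label)``.
    """
    _require_positive(d=d, v=v, D=D)
    try:
        lo, hi = REGIME_WINDOWS[convention]
    except KeyError:
        raise ValueError(f"unknown convention {convention!r}; use 'wide' or 'narrow'") from None
    x = d * v / D
    if x < lo:
        label = "diffusive"
    elif x < hi:
        label = "transition"
    else:
        label = "diffusionless"
    return x, label


def driving_force_at_temperature(thermo: ThermoParamsPF1, dT_rel: float) -> tuple[float, float]:
    """Driving forces (dg_A, dg_B) at reduced temperature ``T_r + dT_rel``.

    Uses the linear law Delta_G_i = Delta_H_i (T - T_i)/T_i with the
    enthalpies back-derived from the reference state, so ``dT_rel = 0``
    returns the tabulated values exactly.
    """
    T_r = thermo.T_r + dT_rel
    if not (0.0 < T_r):
        raise ValueError(f"shifted reduced temperature must stay positive, got {T_r!r}")
    dg_A = thermo.dH_A * (T_r - 1.0)
    dg_B = thermo.dH_B * (T_r / thermo.T_rB - 1.0)
    return dg_A, dg_B


@dataclass(frozen=True)
class DimensionlessCoefficients:
    """Dimensionless free-energy coefficients derived from a PhysicalScales.

    ``eps_phi_sq`` multiplies ``(1/2) s^2 |grad phi|^2``; ``w_A``/``w_B``
    are the double-well heights entering ``w(c) g(phi)`` with
    ``g = phi^2 (1-phi)^2 / 4``; ``gamma_A``/``gamma_B`` are the resulting
    dimensionless interfacial free energies; ``delta`` the dimensionless
    interface thickness.
    """

    eps_phi_sq: float
    w_A: float
    w_B: float
    gamma_A: float
    gamma_B: float
    delta: float


def dimensionless_coefficients(scales: PhysicalScales) -> DimensionlessCoefficients:
    """Build dimensionless square-gradient/double-well coefficients.

    Free-energy densities are measured in RT/v_m and lengths in ``xi``.
    Each component contributes eps_i^2 = (12/sqrt2) gamma_i delta / T_i and
    w_i = (12/sqrt2) gamma_i / (delta T_i); with gamma proportional to
    T_trans the per-component eps_i^2 coincide and the model uses their
    mean.  The pairing guarantees eps^2 / w_i = delta^2, so the relaxed
    interface width equals delta for either component.
    """
    eps2 = []
    w = []
    for gamma, T_i in ((scales.gamma_A, scales.T_A), (scales.gamma_B, scales.T_B)):
        e2, wi = square_gradient_coefficient(gamma, scales.delta, T_i)
        eps2.append(e2 * scales.v_m / (scales.R_gas * scales.xi**2))
        w.append(wi * scales.v_m / scales.R_gas)
    eps_hat = 0.5 * (eps2[0] + eps2[1])
    gam = [math.sqrt(2.0 * (wi / 4.0) * eps_hat) / 6.0 for wi in w]
    return DimensionlessCoefficients(
        eps_phi_sq=eps_hat,
        w_A=w[0],
        w_B=w[1],
        gamma_A=gam[0],
        gamma_B=gam[1],
        delta=scales.delta / scales.xi,
    )
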