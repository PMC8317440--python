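"""Eutectic two-solid extension of the binary orientation-field model (2D).

Two crystalline solution phases (a mineral-rich alpha and an organic-rich
beta, compositions ``c_alpha < c_beta``) grow simultaneously from the
mother phase.  Relative to the base model this adds

* regular-solution bulk thermodynamics: an interaction term
  ``omega c (1-c)`` with phase-interpolated coefficient
  (``omega_M`` in the mother phase, ``omega_C`` in the solid) whose solid
  branch is concave enough to demix into alpha/beta;
* a concentration square-gradient term ``(eps_c^2/2)|grad c|^2`` with
  ``eps_c^2 = 2 eps_phi^2``, which penalizes sharp composition bands;
* a composition-gated orientational free energy

      H p(phi) [ h(c) F1(|grad theta|) + (1 - h(c)) F2(|grad theta|) ]

  with ``F1(x) = x`` (classic grain-boundary branch, active inside either
  solid phase where ``h = 1``) and ``F2(x) = a + b |cos(2 m pi d x)|``
  whose periodic minima select a fixed misorientation across solid-solid
  phase boundaries (where c crosses the alpha/beta midpoint and ``h = 0``).

Equations of motion are derived exactly as in the base model; the stepping
kernel is shared, so pinning ``h`` to the F1 branch with ``omega = 0`` and
``eps_c^2 = 0`` reproduces the base model trajectory identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .grids import FieldState2D, Grid2D
from .pf1 import (PF1Params, _step2d, double_well_g, interpolation_p,
                  interpolation_p_prime, _safe_c)

__all__ = [
    "PF2Params",
    "h_weight",
    "regular_solution_bulk",
    "common_tangent_compositions",
    "orientation_energy_pf2",
    "step_pf2",
]


def h_weight(c, c_alpha: float, c_beta: float):
    """Composition gate h(c) = (1/2){1 + cos[2 pi (c - c_a)/(c_b - c_a)]}.

    Equals 1 at both solid compositions and 0 at their midpoint; outside
    [c_alpha, c_beta] the argument is clamped so the gate stays at 1 rather
    than oscillating (the F2 branch only concerns solid-solid boundaries).
    """
    if c_alpha == c_beta:
        raise ValueError("c_alpha and c_beta must differ")
    x = (np.clip(c, min(c_alpha, c_beta), max(c_alpha, c_beta)) - c_alpha) / (c_beta - c_alpha)
    return 0.5 * (1.0 + np.cos(2.0 * np.pi * x))


def _h_weight_prime(c, c_alpha: float, c_beta: float):
    span = c_beta - c_alpha
    x = (np.asarray(c) - c_alpha) / span
    inside = (x > 0.0) & (x < 1.0)
    return np.where(inside, -np.pi * np.sin(2.0 * np.pi * x) / span, 0.0)


def regular_solution_bulk(c, omega: float, dg_A: float, dg_B: float):
    """Regular-solution free energy density (dimensionless, per RT/v_m).

    Ideal mixing entropy + omega c(1-c) interaction + linear driving-force
    terms (1-c) dg_A + c dg_B.  Concentrations are floored inside the
    logarithms as in the base model.
    """
    cs = _safe_c(np.asarray(c, dtype=float))
    return (cs * np.log(cs) + (1.0 - cs) * np.log(1.0 - cs)
            + omega * cs * (1.0 - cs) + (1.0 - cs) * dg_A + cs * dg_B)


def common_tangent_compositions(omega: float, tol: float = 1e-10) -> tuple[float, float]:
    """Coexisting compositions of the regular solution by common tangent.

    For ``f = c ln c + (1-c) ln(1-c) + omega c(1-c)`` (linear terms do not
    shift the double-tangent compositions) the construction is symmetric
    about c = 1/2; the binodal satisfies ln(c/(1-c)) + omega(1-2c) = 0.
    Requires omega > 2 (otherwise the solid curve is convex and no
    two-phase region exists).
    """
    if omega <= 2.0:
        raise ValueError(f"no miscibility gap for omega = {omega} <= 2")
    f = lambda c: math.log(c / (1.0 - c)) + omega * (1.0 - 2.0 * c)
    c_alpha = brentq(f, 1e-12, 0.5 - 1e-9, xtol=tol)
    return c_alpha, 1.0 - c_alpha


@dataclass(frozen=True)
class PF2Params:
    """Parameters of the eutectic model: a base parameter set plus the
    two-solid extensions.

    ``h_mode`` selects the reading of the F1/F2 combination: "blend"
    (h F1 + (1-h) F2, default) or "f1" (gate pinned to the F1 branch, used
    for reduction checks).
    """

    base: PF1Params
    eps_c_sq: float
    c_alpha: float
    c_beta: float
    omega_M: float = 2.0510
    omega_C: float = 3.6335
    a: float = 0.3
    b: float = 0.7
    m_sym: int = 2
    d: float = 3 * 6.25e-3
    h_mode: str = "blend"
    _allow_eps_override: bool = False

    def __post_init__(self) -> None:
        if not self._allow_eps_override:
            if not math.isclose(self.eps_c_sq, 2.0 * self.base.eps_phi_sq,
                                rel_tol=0.0, abs_tol=0.0):
                raise ValueError("eps_c_sq must equal 2 * eps_phi_sq exactly")
        if not (0.0 < self.c_alpha < self.c_beta < 1.0):
            raise ValueError("require 0 < c_alpha < c_beta < 1")
        if self.h_mode not in ("blend", "f1"):
            raise ValueError(f"unknown h_mode {self.h_mode!r}")

    @classmethod
    def from_base(cls, base: PF1Params, *, omega_M: float = 2.0510,
                  omega_C: float = 3.6335, a: float = 0.3, b: float = 0.7,
                  m_sym: int = 2, d: float | None = None,
                  dx: float = 6.25e-3) -> "PF2Params":
        """Build with eps_c^2 = 2 eps_phi^2 and alpha/beta compositions from
        the common-tangent construction on the solid free-energy curve."""
        c_a, c_b = common_tangent_compositions(omega_C)
        return cls(base=base, eps_c_sq=2.0 * base.eps_phi_sq, c_alpha=c_a,
                   c_beta=c_b, omega_M=omega_M, omega_C=omega_C, a=a, b=b,
                   m_sym=m_sym, d=(3 * dx if d is None else d))

    @classmethod
    def pf1_reduction(cls, base: PF1Params) -> "PF2Params":
        """Degenerate parameter set whose trajectories coincide with the
        base model: gate pinned to F1, omega = 0, no concentration
        square-gradient term (validation use)."""
        return cls(base=base, eps_c_sq=0.0, c_alpha=0.25, c_beta=0.75,
                   omega_M=0.0, omega_C=0.0, h_mode="f1",
                   _allow_eps_override=True)


def _gate(pf2: PF2Params, cs):
    if pf2.h_mode == "f1":
        return 1.0
    return h_weight(cs, pf2.c_alpha, pf2.c_beta)


def _F2(pf2: PF2Params, x):
    return pf2.a + pf2.b * np.abs(np.cos(2.0 * pf2.m_sym * np.pi * pf2.d * x))


def _F2_prime(pf2: PF2Params, x):
    arg = 2.0 * pf2.m_sym * np.pi * pf2.d * x
    return -pf2.b * 2.0 * pf2.m_sym * np.pi * pf2.d * np.sin(arg) * np.sign(np.cos(arg))


def pf2_bulk_energy(phi, c, base: PF1Params, pf2: PF2Params):
    cs = _safe_c(np.asarray(c, dtype=float))
    p = interpolation_p(np.clip(phi, 0.0, 1.0))
    w_c = (1.0 - cs) * base.w_A + cs * base.w_B
    omega_mix = (1.0 - p) * pf2.omega_M + p * pf2.omega_C
    drive = (1.0 - cs) * base.dg_A + cs * base.dg_B
    entropy = cs * np.log(cs) + (1.0 - cs) * np.log(1.0 - cs)
    return (w_c * double_well_g(phi) + entropy + omega_mix * cs * (1.0 - cs)
            + p * drive)


def pf2_dfdphi(phi, cs, base: PF1Params, pf2: PF2Params):
    from .pf1 import _double_well_g_prime
    w_c = (1.0 - cs) * base.w_A + cs * base.w_B
    drive = (1.0 - cs) * base.dg_A + cs * base.dg_B
    pp = interpolation_p_prime(phi)
    return (w_c * _double_well_g_prime(phi)
            + pp * (drive + (pf2.omega_C - pf2.omega_M) * cs * (1.0 - cs)))


def pf2_dfdc(phi, cs, p_phi, base: PF1Params, pf2: PF2Params, tmag, eta):
    omega_mix = (1.0 - p_phi) * pf2.omega_M + p_phi * pf2.omega_C
    mu = (np.log(cs) - np.log(1.0 - cs)
          + double_well_g(phi) * (base.w_B - base.w_A)
          + omega_mix * (1.0 - 2.0 * cs)
          + p_phi * (base.dg_B - base.dg_A))
    if pf2.h_mode != "f1":
        F1 = tmag - eta
        hp = _h_weight_prime(cs, pf2.c_alpha, pf2.c_beta)
        mu = mu + base.H_ori * p_phi * hp * (F1 - _F2(pf2, F1))
    return mu


def pf2_orientation_energy(ty, tx, phi, c, base: PF1Params, pf2: PF2Params, eta):
    tmag = np.sqrt(tx**2 + ty**2 + eta**2)
    F1 = tmag - eta
    h = _gate(pf2, _safe_c(np.asarray(c, dtype=float)))
    p = interpolation_p(np.clip(phi, 0.0, 1.0))
    return base.H_ori * p * (h * F1 + (1.0 - h) * _F2(pf2, F1))


def pf2_orientation_dphi(tmag, eta, phi, cs, base: PF1Params, pf2: PF2Params):
    F1 = tmag - eta
    h = _gate(pf2, cs)
    pp = interpolation_p_prime(phi)
    return base.H_ori * pp * (h * F1 + (1.0 - h) * _F2(pf2, F1))


def pf2_theta_face_coefficient(c_face, mag_face, pf2: PF2Params):
    """Scalar multiplier of the unit-vector orientation flux at a face,
    blending the F1 branch (slope 1) with the F2 branch (periodic slope)."""
    h = _gate(pf2, c_face)
    if isinstance(h, float) and h == 1.0:
        return 1.0
    return h * 1.0 + (1.0 - h) * _F2_prime(pf2, mag_face)


def orientation_energy_pf2(theta_grad_y, theta_grad_x, c, phi,
                           base: PF1Params, pf2: PF2Params, eta: float):
    """Public wrapper over the blended orientational free energy density."""
    return pf2_orientation_energy(theta_grad_y, theta_grad_x, phi, c, base, pf2, eta)


def step_pf2(state: FieldState2D, params: PF2Params, grid: Grid2D, dt: float,
             rng: np.random.Generator | None = None, *,
             allow_unstable_dt: bool = False, check: bool = True,
             source_c: float | None = None) -> FieldState2D:
    """One forward-Euler step of the eutectic model (shared kernel with the
    base model; see that stepper for contracts)."""
    return _step2d(state, params.base, grid, dt, rng, pf2=params,
                   allow_unstable_dt=allow_unstable_dt, check=check,
                   source_c=source_c)
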