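"""Binary orientation-field phase-field model (2D).

The model couples a structural order parameter ``phi`` (0 = mother phase,
1 = crystal), the concentration ``c`` of the organic component of a binary
ideal solution (mineral fraction ``1 - c``), and a scalar crystallographic
orientation ``theta`` (circular on [0, 1)).  The free energy functional is

    F = Int dV [ (eps_phi^2/2) s(nu, theta)^2 |grad phi|^2 + f(phi, c)
                 + H p(phi) |grad theta| ]

with the bulk density

    f = w(c) g(phi) + p(phi) [ (1-c) dg_A + c dg_B ]
        + c ln c + (1-c) ln(1-c),

where ``g(phi) = phi^2 (1-phi)^2 / 4`` is the double well,
``w(c) = (1-c) w_A + c w_B`` its composition-weighted height,
``p(phi) = phi^3 (10 - 15 phi + 6 phi^2)`` the interpolant, ``dg_A``/``dg_B``
the dimensionless pure-component driving forces, and
``s = 1 + s0 cos(k nu - 2 pi theta)`` an optional k-fold anisotropy of the
interface energy (``nu`` = interface-normal angle).  All quantities are
dimensionless: lengths in ``xi``, time in ``xi^2/D_cM``, energies in RT/v_m.

Equations of motion are variational: ``phi`` and ``theta`` relax
(nonconserved, mobilities ``m_phi/eps_phi^2`` and ``m_theta(phi)/H``), the
concentration obeys a conservative flux law
``dc/dt = div( m_c(phi) c (1-c) grad(dF/dc) )`` discretized in face-flux
form so the total solute content is conserved to round-off under no-flux
boundaries.  Gaussian noise (nonconserved fields) and divergence-of-flux
noise (concentration) with mobility-proportional variance represent thermal
fluctuations.  Time stepping is forward Euler on a uniform grid.

The scalar orientation field restricts this model to 2D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._fd import pad2, central_gradient, face_diffs, div_faces, face_average
from .grids import FieldState2D, Grid2D
from .scales import MobilityParams, ThermoParamsPF1, interpolation_p

__all__ = [
    "NoiseParams",
    "PF1Params",
    "interpolation_p",
    "interpolation_p_prime",
    "double_well_g",
    "bulk_free_energy_density",
    "orientation_energy_density",
    "anisotropy_s",
    "total_free_energy",
    "step_pf1",
    "stable_dt",
    "front_height",
    "shift_window",
    "maybe_shift_window",
]

LOG_FLOOR = 1e-12  # floor inside ideal-solution logarithms
GRAD_PHI_EPS = 1e-8  # |grad phi| (per dx) below which the normal is undefined


@dataclass(frozen=True)
class NoiseParams:
    """Amplitudes of the Langevin forcings added to the EOMs.

    Injected standard deviations scale as amp * sqrt(2 * mobility * dt) / dx
    (fluctuation-dissipation proportionality to the respective mobility);
    the concentration noise enters as the divergence of random face fluxes,
    which preserves the total solute content exactly.
    """

    amp_phi: float = 0.0
    amp_c: float = 0.0
    amp_theta: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.amp_phi, self.amp_c, self.amp_theta) < 0:
            raise ValueError("noise amplitudes must be >= 0")

    @property
    def any_active(self) -> bool:
        return (self.amp_phi > 0) or (self.amp_c > 0) or (self.amp_theta > 0)


@dataclass(frozen=True)
class PF1Params:
    """Dimensionless coefficients of the binary orientation-field model."""

    eps_phi_sq: float
    w_A: float
    w_B: float
    mobility: MobilityParams
    dg_A: float = -0.1184
    dg_B: float = 0.1554
    thermo: ThermoParamsPF1 = field(default_factory=ThermoParamsPF1)
    H_ori: float = 1.0
    s0: float = 0.05
    k_fold: int = 6
    kinetic_aniso: bool = False
    noise: NoiseParams = field(default_factory=NoiseParams)

    def __post_init__(self) -> None:
        if not (0.0 <= self.s0 < 1.0):
            raise ValueError("s0 must be in [0, 1)")
        if self.k_fold < 1 or int(self.k_fold) != self.k_fold:
            raise ValueError("k_fold must be a positive integer")
        if self.eps_phi_sq <= 0 or self.w_A < 0 or self.w_B < 0 or self.H_ori < 0:
            raise ValueError("eps_phi_sq must be > 0; w_A, w_B, H_ori >= 0")

    def with_driving(self, dg_A: float, dg_B: float) -> "PF1Params":
        return replace(self, dg_A=dg_A, dg_B=dg_B)


def interpolation_p_prime(phi):
    """Derivative p'(phi) = 30 phi^2 (1-phi)^2."""
    return 30.0 * phi**2 * (1.0 - phi) ** 2


def double_well_g(phi):
    """Double well g(phi) = phi^2 (1-phi)^2 / 4 (minima at 0 and 1)."""
    return 0.25 * phi**2 * (1.0 - phi) ** 2


def _double_well_g_prime(phi):
    return 0.5 * phi * (1.0 - phi) * (1.0 - 2.0 * phi)


def _safe_c(c):
    return np.clip(c, LOG_FLOOR, 1.0 - LOG_FLOOR)


def bulk_free_energy_density(phi, c, params: PF1Params):
    """Bulk free energy density f(phi, c) of the ideal-solution model.

    Interpolates between mother phase (phi=0) and crystal (phi=1); the
    double-well barrier height is the composition-weighted ``w(c)``.
    Concentrations outside (0, 1) are floored inside the logarithms.
    """
    cs = _safe_c(np.asarray(c, dtype=float))
    w_c = (1.0 - cs) * params.w_A + cs * params.w_B
    drive = (1.0 - cs) * params.dg_A + cs * params.dg_B
    entropy = cs * np.log(cs) + (1.0 - cs) * np.log(1.0 - cs)
    return w_c * double_well_g(phi) + interpolation_p(phi) * drive + entropy


def orientation_energy_density(theta_grad_y, theta_grad_x, phi, params: PF1Params,
                               eta: float):
    """Orientation free energy density H p(phi) (|grad theta|_reg - eta).

    The regularization sqrt(|grad theta|^2 + eta^2) - eta removes the
    singularity at vanishing gradient while keeping spatially uniform
    orientation exactly energy-free.  The p(phi) coupling suppresses
    orientational stiffness in the mother phase, where theta fluctuates
    freely (short-range order only).
    """
    mag = np.sqrt(theta_grad_x**2 + theta_grad_y**2 + eta**2) - eta
    return params.H_ori * interpolation_p(np.clip(phi, 0.0, 1.0)) * mag


def anisotropy_s(phi_grad_y, phi_grad_x, theta, s0: float, k: int,
                 dx: float | None = None):
    """Interfacial anisotropy s = 1 + s0 cos(k nu - 2 pi theta).

    ``nu = atan2(phi_y, phi_x)`` is the interface-normal angle (radians in
    the laboratory frame); where |grad phi| is below threshold the normal is
    undefined and s = 1 is returned.  Invariant under theta -> theta + 1.
    """
    if s0 == 0.0:
        return np.ones(np.broadcast(phi_grad_x, phi_grad_y).shape)
    nu = np.arctan2(phi_grad_y, phi_grad_x)
    s = 1.0 + s0 * np.cos(k * nu - 2.0 * np.pi * np.asarray(theta))
    thresh = GRAD_PHI_EPS / (dx if dx else 1.0)
    mag2 = phi_grad_x**2 + phi_grad_y**2
    return np.where(mag2 < thresh**2, 1.0, s)


def total_free_energy(state: FieldState2D, params: PF1Params, grid: Grid2D,
                      pf2=None) -> float:
    """Total dimensionless free energy (sum over cells x cell area).

    Gradient terms use central differences consistent with the stepping
    stencils; wall cells are excluded.  ``pf2`` optionally supplies the
    eutectic extensions (concentration gradient term, F1/F2 orientation
    blend, regular-solution bulk) so both models share one accounting.
    """
    if state.phi.shape != grid.shape:
        raise ValueError("state/grid shape mismatch")
    dx = grid.dx
    eta = 1e-6 / dx
    phi_p = pad2(state.phi, grid.periodic_x)
    th_p = pad2(state.theta, grid.periodic_x)
    gy, gx = central_gradient(phi_p, dx)
    ty, tx = central_gradient(th_p, dx, circular=True)
    s = anisotropy_s(gy, gx, state.theta, params.s0, params.k_fold, dx)
    grad_e = 0.5 * params.eps_phi_sq * s**2 * (gx**2 + gy**2)
    if pf2 is None:
        bulk = bulk_free_energy_density(state.phi, state.c, params)
        ori = orientation_energy_density(ty, tx, state.phi, params, eta)
        extra = 0.0
    else:
        from .pf2 import pf2_bulk_energy, pf2_orientation_energy  # local: avoid cycle
        bulk = pf2_bulk_energy(state.phi, state.c, params, pf2)
        ori = pf2_orientation_energy(ty, tx, state.phi, state.c, params, pf2, eta)
        cp = pad2(state.c, grid.periodic_x)
        cy, cx = central_gradient(cp, dx)
        extra = 0.5 * pf2.eps_c_sq * (cx**2 + cy**2)
    dens = grad_e + bulk + ori + extra
    if grid.wall_mask is not None:
        dens = np.where(grid.wall_mask, 0.0, dens)
    return float(dens.sum() * dx * dx)


def stable_dt(params: PF1Params, grid: Grid2D) -> float:
    """Forward-Euler time-step guard 0.4 dx^2 / (2 D_max).

    D_max counts the phase-field pseudo-diffusivity m_phi (1+s0)^2 and the
    chemical diffusivities; the bounded-flux orientation term does not add a
    linear diffusivity and is excluded.
    """
    m = params.mobility
    D_max = max(m.m_phi * (1.0 + params.s0) ** 2, m.m_cM, m.m_cC, 1e-300)
    return 0.4 * grid.dx**2 / (2.0 * D_max)


def _mobility_field(m_C: float, m_M: float, p_phi):
    # p(phi) may overshoot 1 by an ulp; clamp so mobilities stay >= 0
    return np.maximum(m_C + (1.0 - p_phi) * (m_M - m_C), 0.0)


def _contact_angle_ghost_adjust(phi_p, c_edge, params, grid, wall_angle_deg, dx):
    """Overwrite the bottom ghost row so the wall enforces a contact angle.

    Equilibrium interface slope |grad phi| = sqrt(w/(2 eps^2)) phi (1-phi);
    the ghost value phi_in - 2 dx cos(psi) |grad phi|_eq realises a contact
    angle psi between the crystal-mother interface and the wall (measured
    through the crystal).
    """
    psi = math.radians(wall_angle_deg)
    w_c = (1.0 - c_edge) * params.w_A + c_edge * params.w_B
    slope = np.sqrt(w_c / (2.0 * params.eps_phi_sq))
    ph = phi_p[1, 1:-1]
    phi_p[0, 1:-1] = ph + dx * math.cos(psi) * slope * ph * (1.0 - ph)
    return phi_p


def step_pf1(state: FieldState2D, params: PF1Params, grid: Grid2D, dt: float,
             rng: np.random.Generator | None = None, *,
             allow_unstable_dt: bool = False, check: bool = True,
             source_c: float | None = None) -> FieldState2D:
    """Advance the state by one forward-Euler step; returns a new state.

    ``source_c`` sets the Dirichlet concentration on a "source" top edge.
    With all noise amplitudes zero and no-flux boundaries the total solute
    content is conserved to round-off and the free energy is non-increasing.
    Raises if dt exceeds the stability guard (override with
    ``allow_unstable_dt``) or if fields go non-finite.
    """
    return _step2d(state, params, grid, dt, rng, pf2=None,
                   allow_unstable_dt=allow_unstable_dt, check=check,
                   source_c=source_c)


def _step2d(state, params: PF1Params, grid: Grid2D, dt, rng, *, pf2,
            allow_unstable_dt=False, check=True, source_c=None):
    guard = stable_dt(params, grid)
    if pf2 is not None and pf2.eps_c_sq > 0 and params.mobility.m_cM > 0:
        # biharmonic bound from the concentration square-gradient term
        guard = min(guard, 0.4 * grid.dx**4 /
                    (16.0 * pf2.eps_c_sq * 0.25 * params.mobility.m_cM))
    if dt > guard * (1.0 + 1e-12) and not allow_unstable_dt:
        raise ValueError(
            f"dt={dt:g} exceeds stability guard {guard:g}; pass allow_unstable_dt=True "
            "to override")
    dx = grid.dx
    eta = 1e-6 / dx
    mob = params.mobility
    eps2 = params.eps_phi_sq
    phi, c, theta = state.phi, state.c, state.theta
    wall = grid.wall_mask
    noise = params.noise
    use_noise = noise.any_active and rng is not None

    top_is_source = grid.boundary.get("top") == "source"
    bottom_wall_angle = grid.contact_angle_deg if grid.boundary.get("bottom") == "wall" else None

    p_phi = interpolation_p(np.clip(phi, 0.0, 1.0))
    pp_phi = interpolation_p_prime(phi)
    cs = _safe_c(c)
    w_c = (1.0 - cs) * params.w_A + cs * params.w_B

    # --- padded fields -----------------------------------------------------
    phi_p = pad2(phi, grid.periodic_x, top_value=(0.0 if top_is_source else None))
    if bottom_wall_angle is not None:
        phi_p = _contact_angle_ghost_adjust(phi_p, cs[0, :], params, grid,
                                            bottom_wall_angle, dx)
    th_p = pad2(theta, grid.periodic_x)
    c_p = pad2(c, grid.periodic_x)

    # --- geometry: gradients, anisotropy ----------------------------------
    gy, gx = central_gradient(phi_p, dx)
    ty, tx = central_gradient(th_p, dx, circular=True)
    tmag = np.sqrt(tx**2 + ty**2 + eta**2)

    if params.s0 > 0.0:
        nu = np.arctan2(gy, gx)
        q = params.k_fold * nu - 2.0 * np.pi * theta
        mag2 = gx**2 + gy**2
        defined = mag2 >= (GRAD_PHI_EPS / dx) ** 2
        s_arr = np.where(defined, 1.0 + params.s0 * np.cos(q), 1.0)
        s_q = np.where(defined, -params.s0 * params.k_fold * np.sin(q), 0.0)
        if wall is not None:
            s_arr = np.where(wall, 1.0, s_arr)
            s_q = np.where(wall, 0.0, s_q)
    else:
        s_arr = None
        s_q = None

    # --- phi equation ------------------------------------------------------
    # isotropic part of the gradient flux in face form
    dphi_e, dphi_n = face_diffs(phi_p, dx)
    if s_arr is not None:
        s2_p = pad2(s_arr**2, grid.periodic_x)
        s2_e, s2_n = face_average(s2_p)
    else:
        s2_e = s2_n = 1.0
    Fe = eps2 * s2_e * dphi_e
    Fn = eps2 * s2_n * dphi_n
    open_e = open_n = None
    if wall is not None:
        wall_p = pad2(wall.astype(float), grid.periodic_x)
        we, wn = face_average(wall_p)
        open_e = we < 0.25  # face open iff neither side is wall
        open_n = wn < 0.25
        Fe = np.where(open_e, Fe, 0.0)
        Fn = np.where(open_n, Fn, 0.0)
    lap_term = div_faces(Fe, Fn, dx)

    aniso_div = 0.0
    if s_arr is not None:
        # rotation term -div( eps^2 s s_nu (-phi_y, phi_x) )
        Ax = -eps2 * s_arr * s_q * gy
        Ay = eps2 * s_arr * s_q * gx
        Axp = pad2(Ax, grid.periodic_x)
        Ayp = pad2(Ay, grid.periodic_x)
        aniso_div = ((Axp[1:-1, 2:] - Axp[1:-1, :-2]) +
                     (Ayp[2:, 1:-1] - Ayp[:-2, 1:-1])) / (2.0 * dx)

    if pf2 is None:
        drive = (1.0 - cs) * params.dg_A + cs * params.dg_B
        dfdphi = w_c * _double_well_g_prime(phi) + pp_phi * drive
        ori_dphi = params.H_ori * pp_phi * (tmag - eta)
    else:
        from .pf2 import pf2_dfdphi, pf2_orientation_dphi
        dfdphi = pf2_dfdphi(phi, cs, params, pf2)
        ori_dphi = pf2_orientation_dphi(tmag, eta, phi, cs, params, pf2)

    M_phi = mob.m_phi / eps2
    if params.kinetic_aniso and s_arr is not None:
        M_phi = M_phi * s_arr**2
    dphi = dt * M_phi * (lap_term + aniso_div - dfdphi - ori_dphi)
    if use_noise and noise.amp_phi > 0:
        sig = noise.amp_phi * np.sqrt(2.0 * (mob.m_phi / eps2) * dt) / dx
        dphi = dphi + sig * rng.standard_normal(phi.shape)

    # --- c equation (conservative face-flux form) --------------------------
    lap_c = 0.0
    if pf2 is not None and pf2.eps_c_sq != 0.0:
        lap_c = (c_p[1:-1, 2:] + c_p[1:-1, :-2] + c_p[2:, 1:-1] + c_p[:-2, 1:-1]
                 - 4.0 * c) / dx**2
    if pf2 is None:
        mu = (np.log(cs) - np.log(1.0 - cs)
              + double_well_g(phi) * (params.w_B - params.w_A)
              + p_phi * (params.dg_B - params.dg_A))
    else:
        from .pf2 import pf2_dfdc
        mu = pf2_dfdc(phi, cs, p_phi, params, pf2, tmag, eta)
    if pf2 is not None and pf2.eps_c_sq != 0.0:
        mu = mu - pf2.eps_c_sq * lap_c

    m_c = _mobility_field(mob.m_cC, mob.m_cM, p_phi)
    Mcell = m_c * cs * (1.0 - cs)
    if wall is not None:
        Mcell = np.where(wall, 0.0, Mcell)
    M_p = pad2(Mcell, grid.periodic_x)
    Me, Mn = face_average(M_p)
    mu_p = pad2(mu, grid.periodic_x)
    dmu_e, dmu_n = face_diffs(mu_p, dx)
    Je = Me * dmu_e
    Jn = Mn * dmu_n
    if wall is not None:
        Je = np.where(open_e, Je, 0.0)
        Jn = np.where(open_n, Jn, 0.0)
    if top_is_source and source_c is not None:
        # feeding boundary: linearized Dirichlet flux through the top faces
        m_top = Mcell[-1, :] / (cs[-1, :] * (1.0 - cs[-1, :]))
        Jn[-1, :] = m_top * 2.0 * (source_c - c[-1, :]) / dx
    dc = dt * div_faces(Je, Jn, dx)
    if use_noise and noise.amp_c > 0:
        sig_e = noise.amp_c * np.sqrt(2.0 * np.maximum(Me, 0.0) * dt) / dx
        sig_n = noise.amp_c * np.sqrt(2.0 * np.maximum(Mn, 0.0) * dt) / dx
        Ze = sig_e * rng.standard_normal(Je.shape)
        Zn = sig_n * rng.standard_normal(Jn.shape)
        Ze[:, 0] = 0.0 if not grid.periodic_x else Ze[:, 0]
        if not grid.periodic_x:
            Ze[:, -1] = 0.0
        Zn[0, :] = 0.0
        Zn[-1, :] = 0.0
        if wall is not None:
            Ze = np.where(open_e, Ze, 0.0)
            Zn = np.where(open_n, Zn, 0.0)
        dc = dc + (Ze[:, 1:] - Ze[:, :-1] + Zn[1:, :] - Zn[:-1, :])

    # --- theta equation (bounded-flux TV relaxation) -----------------------
    m_th = _mobility_field(mob.m_thetaC, mob.m_thetaM, p_phi)
    dth_e, dth_n = face_diffs(th_p, dx, circular=True)
    # face-local regularization keeps the unit-vector flux bounded (|u| <= 1)
    mag_e = np.sqrt(dth_e**2 + eta**2)
    mag_n = np.sqrt(dth_n**2 + eta**2)
    pw = np.where(wall, 0.0, p_phi) if wall is not None else p_phi
    p_p = pad2(pw, grid.periodic_x)
    pe, pn = face_average(p_p)
    if pf2 is None:
        Te = pe * dth_e / mag_e
        Tn = pn * dth_n / mag_n
    else:
        from .pf2 import pf2_theta_face_coefficient
        cs_p = pad2(cs, grid.periodic_x)
        ce, cn = face_average(cs_p)
        Te = pe * pf2_theta_face_coefficient(ce, mag_e, pf2) * dth_e / mag_e
        Tn = pn * pf2_theta_face_coefficient(cn, mag_n, pf2) * dth_n / mag_n
    if wall is not None:
        Te = np.where(open_e, Te, 0.0)
        Tn = np.where(open_n, Tn, 0.0)
    dtheta = dt * m_th * div_faces(Te, Tn, dx)
    if s_arr is not None:
        torque = (eps2 / params.H_ori) * s_arr * (2.0 * np.pi * params.s0 *
                                                  np.sin(q)) * (gx**2 + gy**2)
        dtheta = dtheta - dt * m_th * torque
    if use_noise and noise.amp_theta > 0:
        sig = noise.amp_theta * np.sqrt(2.0 * m_th * dt) / dx
        dtheta = dtheta + sig * rng.standard_normal(theta.shape)

    # --- assemble ----------------------------------------------------------
    phi_new = phi + dphi
    c_new = c + dc
    theta_new = theta + dtheta
    theta_new = theta_new - np.floor(theta_new)
    # tiny negative values round up to exactly 1.0 after the wrap
    theta_new = np.where(theta_new >= 1.0, 0.0, theta_new)
    if wall is not None:
        phi_new = np.where(wall, phi, phi_new)
        c_new = np.where(wall, c, c_new)
        theta_new = np.where(wall, theta, theta_new)

    new = FieldState2D(phi_new, c_new, theta_new, t=state.t + dt,
                       frame_offset=state.frame_offset)
    if check:
        new.validate(c_clip=1e-6 if not use_noise else 1e-2)
    return new


def front_height(phi: np.ndarray, level: float = 0.5, dx: float = 1.0) -> float:
    """Mean over columns of the highest level-crossing of phi (dimensionless).

    Columns without a crossing are excluded; raises if no column crosses.
    """
    ny, nx = phi.shape
    above = phi > level
    heights = []
    for i in range(nx):
        col = above[:, i]
        if not col.any():
            continue
        j = np.max(np.nonzero(col)[0])
        if j + 1 < ny:
            # linear interpolation of the crossing between j and j+1
            f = (phi[j, i] - level) / max(phi[j, i] - phi[j + 1, i], 1e-30)
            heights.append((j + 0.5 + f) * dx)
        else:
            heights.append((j + 0.5) * dx)
    if not heights:
        raise ValueError("no level crossing found in any column")
    return float(np.mean(heights))


def shift_window(state: FieldState2D, grid: Grid2D, rows: int,
                 far_field_c, rng: np.random.Generator | None = None,
                 far_field_phi: float = 0.0) -> FieldState2D:
    """Shift fields down by ``rows`` (moving window following the front).

    Incoming top rows are filled with mother phase: phi = far_field_phi,
    c from ``far_field_c`` (a callable of the absolute dimensionless height,
    or a constant), theta random uniform (liquid has no orientational order)
    or 0 when no rng is given.  ``frame_offset`` increments by ``rows``.
    """
    if rows <= 0:
        return state
    ny, nx = state.phi.shape
    if rows >= ny:
        raise ValueError("cannot shift by a full domain height")
    new = state.copy()
    for name in ("phi", "c", "theta"):
        a = getattr(new, name)
        a[:-rows, :] = a[rows:, :]
    new.frame_offset = state.frame_offset + rows
    y_new = (np.arange(ny - rows, ny) + new.frame_offset + 0.5) * grid.dx
    if callable(far_field_c):
        c_fill = np.asarray(far_field_c(y_new), dtype=float)[:, None]
    else:
        c_fill = float(far_field_c)
    new.phi[-rows:, :] = far_field_phi
    new.c[-rows:, :] = c_fill
    if rng is not None:
        new.theta[-rows:, :] = rng.random((rows, nx))
    else:
        new.theta[-rows:, :] = 0.0
    return new


def maybe_shift_window(state: FieldState2D, grid: Grid2D, far_field_c,
                       rng: np.random.Generator | None = None,
                       trigger_fraction: float = 0.75,
                       block_rows: int | None = None) -> FieldState2D:
    """Apply :func:`shift_window` when the front passes ``trigger_fraction``
    of the domain height; block size defaults to ny // 8."""
    try:
        h = front_height(state.phi, dx=1.0)
    except ValueError:
        return state
    ny = state.phi.shape[0]
    if h < trigger_fraction * ny:
        return state
    rows = block_rows if block_rows is not None else max(1, ny // 8)
    return shift_window(state, grid, rows, far_field_c, rng)
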