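"""Ternary phase-field model of two-solid (eutectic-like) growth in 3D.

A single order parameter ``phi`` distinguishes liquid/amorphous mother
phase (0) from solid (1); the composition is a ternary simplex
``c = (c1, c2, c3)`` (mineral, organic, water) with ``sum c_i = 1``.  The
free energy is

    F = Int dV [ (eps_phi^2/2)|grad phi|^2 + w g(phi)
                 + p(phi) f_S(c) + (1 - p(phi)) f_L(c)
                 + (eps_c^2/2) sum_i |grad c_i|^2 ]

with a regular-solution solid ``f_S = sum c_i ln c_i +
sum_{i<j} Omega_ij c_i c_j`` and an ideal-solution liquid
``f_L = sum c_i ln c_i + sum_i d_i c_i`` whose linear offsets ``d_i``
supply the crystallization driving force.  A sufficiently repulsive
``Omega_12`` makes the solid demix into a mineral-rich alpha and an
organic-rich beta phase, so a planar front at suitable compositions grows
coupled two-solid lamellae; diffusion of the dilute third component can
destabilize the pattern into helical (screw-dislocation-like) defects
appearing in pairs of opposite chirality.

Composition dynamics is a conservative flux law with the simplex-
preserving 3x3 mobility matrix (diagonal 1, off-diagonal -1/2, rows and
columns summing to zero) and a ``(1 - p(phi))`` interpolant that switches
diffusion off in the bulk solid.  All quantities are dimensionless and
generic (qualitative model); time stepping is forward Euler on a uniform
3D grid, periodic in x and y, growth along +z with an optional moving
frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import FieldState3D
from .scales import interpolation_p

__all__ = [
    "PF3Params",
    "solid_free_energy",
    "liquid_free_energy",
    "step_pf3",
    "stable_dt_pf3",
    "moving_frame_shift",
    "front_height_3d",
]

LOG_FLOOR = 1e-12

#: simplex-conserving mobility structure (diagonal 1, off-diagonal -1/2);
#: the default parameter set scales it by 4 so that demixing diffusion
#: outruns interface attachment at desk-scale grids.
DEFAULT_MOBILITY_MATRIX = np.array([
    [1.0, -0.5, -0.5],
    [-0.5, 1.0, -0.5],
    [-0.5, -0.5, 1.0],
])


def _default_omega() -> np.ndarray:
    # binary interaction coefficients: strong 1-2 repulsion (alpha/beta
    # demixing), moderate water-solid repulsion (water rejected on freezing)
    return np.array([
        [0.0, 3.0, 2.0],
        [3.0, 0.0, 2.0],
        [2.0, 2.0, 0.0],
    ])


@dataclass(frozen=True)
class PF3Params:
    """Dimensionless coefficients of the ternary model.

    Defaults are generic (the source computations keep their materials
    data unpublished) and are balanced so that, at the reference
    composition, solid demixing is faster than front propagation: liquid
    driving just above the demixed-solid threshold, slow attachment
    kinetics (m_phi = 0.5), chemical mobilities x4, and a reduced
    composition-gradient penalty (eps_c^2 = 0.5) so solid-solid
    boundaries stay resolvable without stiffening the time step.
    """

    w: float = 1.0
    eps_phi_sq: float = 2.0
    eps_c_sq: float = 0.5
    m_phi: float = 0.5
    omega: np.ndarray = field(default_factory=_default_omega)
    drive: tuple[float, float, float] = (0.8, 0.8, 0.0)
    mobility_matrix: np.ndarray = field(
        default_factory=lambda: 4.0 * DEFAULT_MOBILITY_MATRIX)
    far_field: tuple[float, float, float] = (0.43, 0.55, 0.02)
    dx: float = 1.0

    def __post_init__(self) -> None:
        om = np.asarray(self.omega, dtype=float)
        if om.shape != (3, 3) or not np.allclose(om, om.T) or np.abs(np.diag(om)).max() > 0:
            raise ValueError("omega must be symmetric 3x3 with zero diagonal")
        M = np.asarray(self.mobility_matrix, dtype=float)
        if M.shape != (3, 3) or np.abs(M.sum(axis=1)).max() > 1e-14:
            raise ValueError("mobility_matrix rows must sum to 0 (simplex conservation)")
        if abs(sum(self.far_field) - 1.0) > 1e-12:
            raise ValueError("far_field composition must sum to 1")
        if min(self.w, self.eps_phi_sq, self.m_phi, self.dx) <= 0 or self.eps_c_sq < 0:
            raise ValueError("w, eps_phi_sq, m_phi, dx must be positive")


def _check_simplex(comp, tol=1e-9):
    comp = np.asarray(comp, dtype=float)
    if np.abs(comp.sum(axis=0) - 1.0).max() > tol:
        raise ValueError("composition off the simplex beyond tolerance")
    return comp


def solid_free_energy(comp, omega) -> np.ndarray:
    """Regular-solution solid free energy density (units RT/v_m).

    ``comp`` is (3, ...) on the simplex; ``omega`` the symmetric binary
    interaction matrix.  f_S = sum_i c_i ln c_i + sum_{i<j} Omega_ij c_i c_j.
    """
    c = _check_simplex(comp)
    cs = np.clip(c, LOG_FLOOR, 1.0)
    entropy = (cs * np.log(cs)).sum(axis=0)
    om = np.asarray(omega, dtype=float)
    inter = sum(om[i, j] * c[i] * c[j] for i in range(3) for j in range(i + 1, 3))
    return entropy + inter


def liquid_free_energy(comp, drive=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Ideal-solution liquid free energy density plus driving offsets d_i."""
    c = _check_simplex(comp)
    cs = np.clip(c, LOG_FLOOR, 1.0)
    entropy = (cs * np.log(cs)).sum(axis=0)
    return entropy + sum(d * ci for d, ci in zip(drive, c))


def _pad3(a, top_value=None):
    """Pad [nz, ny, nx]: periodic in x and y, edge (no-flux) in z; an
    optional Dirichlet value at the top z face."""
    p = np.pad(a, ((1, 1), (0, 0), (0, 0)), mode="edge")
    p = np.pad(p, ((0, 0), (1, 1), (1, 1)), mode="wrap")
    if top_value is not None:
        p[-1, 1:-1, 1:-1] = 2.0 * np.asarray(top_value) - a[-1]
    return p


def _lap3(p, dx):
    return (p[2:, 1:-1, 1:-1] + p[:-2, 1:-1, 1:-1]
            + p[1:-1, 2:, 1:-1] + p[1:-1, :-2, 1:-1]
            + p[1:-1, 1:-1, 2:] + p[1:-1, 1:-1, :-2]
            - 6.0 * p[1:-1, 1:-1, 1:-1]) / dx**2


def stable_dt_pf3(params: PF3Params) -> float:
    """Forward-Euler guard for the 3D seven-point stencil.

    Combines the diffusive bound 0.4 dx^2/(6 D_max) with a biharmonic
    bound for the concentration square-gradient term (fourth-order
    operator from eps_c^2 inside the chemical potential).
    """
    D_phi = params.m_phi * params.eps_phi_sq
    D_c = float(np.abs(np.asarray(params.mobility_matrix)).max())
    dt = 0.4 * params.dx**2 / (6.0 * max(D_phi, D_c))
    if params.eps_c_sq > 0:
        dt = min(dt, 0.4 * params.dx**4 / (48.0 * D_c * params.eps_c_sq))
    return dt


def _chemical_potentials(phi_pad, comp, params: PF3Params, dx):
    """mu_j = p df_S/dc_j + (1-p) df_L/dc_j - eps_c^2 lap c_j at cells."""
    phi = phi_pad[1:-1, 1:-1, 1:-1]
    p = interpolation_p(np.clip(phi, 0.0, 1.0))
    cs = np.clip(comp, LOG_FLOOR, 1.0)
    om = np.asarray(params.omega)
    mus = []
    for j in range(3):
        dfS = np.log(cs[j]) + 1.0 + sum(om[j, k] * comp[k] for k in range(3) if k != j)
        dfL = np.log(cs[j]) + 1.0 + params.drive[j]
        mu = p * dfS + (1.0 - p) * dfL
        if params.eps_c_sq > 0:
            mu = mu - params.eps_c_sq * _lap3(_pad3(comp[j]), dx)
        mus.append(mu)
    return p, mus


def step_pf3(state: FieldState3D, params: PF3Params, dt: float,
             rng: np.random.Generator | None = None, *,
             allow_unstable_dt: bool = False, check: bool = True) -> FieldState3D:
    """One forward-Euler step; phi nonconserved, compositions conserved.

    The composition flux of component i is
    ``J_i = (1 - p(phi)) sum_j M_ij c_j grad mu_j`` in face form, so the
    simplex sum is preserved identically (column sums of M vanish) and
    each component's total content is conserved under the no-flux/periodic
    boundaries.  No noise is applied by default (the helical instability is
    deterministic); ``rng`` is accepted for interface symmetry.
    """
    guard = stable_dt_pf3(params)
    if dt > guard * (1 + 1e-12) and not allow_unstable_dt:
        raise ValueError(f"dt={dt:g} exceeds stability guard {guard:g}")
    dx = params.dx
    phi, comp = state.phi, state.comp
    phi_pad = _pad3(phi)
    p, mus = _chemical_potentials(phi_pad, comp, params, dx)

    # phi equation
    cs = np.clip(comp, LOG_FLOOR, 1.0)
    om = np.asarray(params.omega)
    entropy = (cs * np.log(cs)).sum(axis=0)
    fS = entropy + sum(om[i, j] * comp[i] * comp[j]
                       for i in range(3) for j in range(i + 1, 3))
    fL = entropy + sum(d * ci for d, ci in zip(params.drive, comp))
    # nonlinear forces evaluated on the clipped order parameter: transient
    # overshoots outside [0, 1] then feel only the restoring Laplacian
    phic = np.clip(phi, 0.0, 1.0)
    g_prime = 0.5 * phic * (1.0 - phic) * (1.0 - 2.0 * phic)
    p_prime = 30.0 * phic**2 * (1.0 - phic) ** 2
    dphi = dt * params.m_phi * (params.eps_phi_sq * _lap3(phi_pad, dx)
                                - params.w * g_prime - p_prime * (fS - fL))

    # composition equations: face fluxes along z, y, x
    Dphi_cell = 1.0 - p  # diffusion off in bulk solid
    Dpad = _pad3(Dphi_cell)
    M = np.asarray(params.mobility_matrix)
    # weighted gradients (c_j grad mu_j) per face, premultiplied by D at face
    flux_terms = []
    for j in range(3):
        q = _pad3(mus[j])
        cj = np.clip(comp[j], 0.0, 1.0)
        w = _pad3(cj * (1.0 - cj) * Dphi_cell)  # degenerate at the simplex edges
        gz = (q[1:, 1:-1, 1:-1] - q[:-1, 1:-1, 1:-1]) / dx
        gy = (q[1:-1, 1:, 1:-1] - q[1:-1, :-1, 1:-1]) / dx
        gx = (q[1:-1, 1:-1, 1:] - q[1:-1, 1:-1, :-1]) / dx
        wz = 0.5 * (w[1:, 1:-1, 1:-1] + w[:-1, 1:-1, 1:-1])
        wy = 0.5 * (w[1:-1, 1:, 1:-1] + w[1:-1, :-1, 1:-1])
        wx = 0.5 * (w[1:-1, 1:-1, 1:] + w[1:-1, 1:-1, :-1])
        flux_terms.append((wz * gz, wy * gy, wx * gx))

    comp_new = np.empty_like(comp)
    for i in range(3):
        Jz = sum(M[i, j] * flux_terms[j][0] for j in range(3))
        Jy = sum(M[i, j] * flux_terms[j][1] for j in range(3))
        Jx = sum(M[i, j] * flux_terms[j][2] for j in range(3))
        div = ((Jz[1:] - Jz[:-1]) + (Jy[:, 1:] - Jy[:, :-1])
               + (Jx[:, :, 1:] - Jx[:, :, :-1])) / dx
        comp_new[i] = comp[i] + dt * div

    new = FieldState3D(phi + dphi, comp_new, t=state.t + dt,
                       frame_offset=state.frame_offset)
    if check:
        new.validate(simplex_tol=1e-9)
    return new


def front_height_3d(phi: np.ndarray, level: float = 0.5) -> float:
    """Mean height (cells) of the highest z level-crossing over columns."""
    above = phi > level
    any_col = above.any(axis=0)
    if not any_col.any():
        raise ValueError("no solid found")
    nz = phi.shape[0]
    idx = nz - 1 - np.argmax(above[::-1], axis=0)
    return float(idx[any_col].mean())


def moving_frame_shift(state: FieldState3D, params: PF3Params,
                       trigger_fraction: float = 0.6,
                       block: int | None = None) -> FieldState3D:
    """Shift the frame down along z once the front passes the trigger.

    Incoming top layers are filled with liquid at the far-field
    composition; ``frame_offset`` increments; a static all-liquid state is
    returned unchanged.
    """
    try:
        h = front_height_3d(state.phi)
    except ValueError:
        return state
    nz = state.phi.shape[0]
    if h < trigger_fraction * nz:
        return state
    rows = block if block is not None else max(1, nz // 8)
    new = state.copy()
    new.phi[:-rows] = new.phi[rows:]
    new.comp[:, :-rows] = new.comp[:, rows:]
    new.phi[-rows:] = 0.0
    for i in range(3):
        new.comp[i, -rows:] = params.far_field[i]
    new.frame_offset = state.frame_offset + rows
    return new
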