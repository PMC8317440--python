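"""Scenario builders: initial/boundary conditions for the studied systems.

Four systems are covered, all on 2D grids with growth along +y:

* shell (base model): heterogeneous nucleation on the periostracum wall,
  exponential supersaturation profile across the extrapallial space,
  mechanism switch between ion-by-ion and amorphous-precursor routes;
* shell (eutectic model): volumetric heterogeneous nucleation with
  exponentially decaying site density and a mantle source boundary whose
  emitted concentration decays exponentially in time;
* columnar nacre: preexisting horizontal organic membranes with aligned
  holes (mineral bridges) inserted "by hand" as wall cells of pixelwise
  random orientation, with a prescribed contact angle;
* coral corallite: confined channel fed from a nutrient source boundary,
  temperature offsets entering through the linear driving-force law,
  operated far from the diffusionless regime (d v / D << 1).

Builders are deterministic given (config, seed).  Route materials data
(interface energies, diffusivities, dimensionless mobilities and
thermodynamics for both mechanisms) ship as YAML resources.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

from .grids import FieldState2D, Grid2D
from .pf1 import NoiseParams, PF1Params, maybe_shift_window, stable_dt, step_pf1
from .pf2 import PF2Params, step_pf2
from .scales import (MobilityParams, PhysicalScales, ThermoParamsPF1,
                     classify_growth_regime, dimensionless_coefficients,
                     driving_force_at_temperature)

__all__ = [
    "NucleationSpec",
    "MembraneSpec",
    "ScenarioConfig",
    "load_route",
    "route_scales",
    "route_pf1_params",
    "exponential_supersaturation_profile",
    "sample_volumetric_sites",
    "build_shell_pf1",
    "build_shell_pf2",
    "build_columnar_nacre",
    "build_coral_corallite",
    "coral_sweep_config",
    "run_coral_to_height",
    "run_scenario",
]

MECHANISMS = ("ion_by_ion", "acc_precursor")
_ROUTE_FILES = {"ion_by_ion": "aq_sol_to_CCC.yaml", "acc_precursor": "ACC_to_CCC.yaml"}


def load_route(mechanism: str) -> dict:
    """Load the transcribed materials/mobility tables for one route."""
    if mechanism not in _ROUTE_FILES:
        raise ValueError(f"mechanism must be one of {MECHANISMS}, got {mechanism!r}")
    with resources.files("biominpf.data").joinpath(_ROUTE_FILES[mechanism]).open() as fh:
        return yaml.safe_load(fh)


def route_scales(route: dict) -> PhysicalScales:
    s = route["scales"]
    th = route["thermo_pf1"]
    T_A = s["T_ref"] / th["T_r"]
    return PhysicalScales(gamma_A=s["gamma_A"], gamma_B=s["gamma_B"],
                          delta=s["delta"], xi=s["xi"], v_m=s["v_m"],
                          D_cM=s["D_cM"], T_A=T_A, T_B=T_A * th["T_rB"])


def route_pf1_params(route: dict, *, dT_kelvin: float = 0.0,
                     noise: NoiseParams | None = None, s0: float = 0.05,
                     k_fold: int = 6, H_ori: float | None = None,
                     kinetic_aniso: bool = False) -> tuple[PF1Params, PhysicalScales]:
    """Build base-model parameters for a route, optionally shifted in
    temperature by ``dT_kelvin`` via the linear driving-force law.

    The grain-boundary energy scale ``H_ori`` defaults to the dimensionless
    crystal-mother interfacial free energy, placing high-angle boundary
    energies at (not far above) the solid-liquid interface energy.
    """
    scales = route_scales(route)
    co = dimensionless_coefficients(scales)
    if H_ori is None:
        H_ori = co.gamma_A
    th = route["thermo_pf1"]
    thermo = ThermoParamsPF1(T_r=th["T_r"], T_rB=th["T_rB"],
                             dg_A=th["dg_A"], dg_B=th["dg_B"])
    dT_rel = dT_kelvin / scales.T_A
    dg_A, dg_B = driving_force_at_temperature(thermo, dT_rel)
    mo = route["mobilities_pf1"]
    mob = MobilityParams(m_phi=mo["m_phi"], m_cM=mo["m_cM"], m_cC=mo["m_cC"],
                         m_thetaM=mo["m_thetaM"], m_thetaC=mo["m_thetaC"])
    params = PF1Params(eps_phi_sq=co.eps_phi_sq, w_A=co.w_A, w_B=co.w_B,
                       mobility=mob, dg_A=dg_A, dg_B=dg_B, thermo=thermo,
                       H_ori=H_ori, s0=s0, k_fold=k_fold,
                       kinetic_aniso=kinetic_aniso,
                       noise=noise or NoiseParams())
    return params, scales


@dataclass(frozen=True)
class NucleationSpec:
    """Heterogeneous-nucleation recipe.

    mode "wall_seeds": ``n_sites`` semicircular nuclei of ``seed_radius``
    cells on the bottom wall.  mode "volumetric_sites": Poisson-sampled
    point nuclei whose areal density decays exponentially with distance
    from the wall over ``site_density_scale`` (dimensionless length);
    ``n_sites`` is the expected total count.  Orientations are uniform on
    [0, 1).
    """

    mode: str = "wall_seeds"
    n_sites: int = 24
    seed_radius: int = 3
    site_density_scale: float = 0.3

    def __post_init__(self) -> None:
        if self.mode not in ("wall_seeds", "volumetric_sites"):
            raise ValueError(f"unknown nucleation mode {self.mode!r}")
        if self.n_sites < 1 or self.seed_radius < 1 or self.site_density_scale <= 0:
            raise ValueError("nucleation spec values must be positive")


@dataclass(frozen=True)
class MembraneSpec:
    """Preexisting horizontal organic membranes with aligned holes.

    ``spacing``/``thickness`` in cells; ``holes`` is a list of
    (center_x_cells, width_cells) applied to every membrane (aligned
    holes = mineral bridges); ``contact_angle`` in degrees.
    """

    spacing: int = 40
    thickness: int = 3
    holes: tuple = ((32, 20),)
    contact_angle: float = 100.0

    def __post_init__(self) -> None:
        if not (0.0 < self.contact_angle < 180.0):
            raise ValueError("contact angle must be in (0, 180) degrees")
        if self.spacing <= self.thickness:
            raise ValueError("membrane spacing must exceed thickness")
        spans = sorted((c - w / 2, c + w / 2) for c, w in self.holes)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError("overlapping holes")


@dataclass(frozen=True)
class ScenarioConfig:
    """Recipe for one studied system."""

    model: str = "PF1"
    system: str = "shell"           # shell | nacre | coral
    mechanism: str = "acc_precursor"
    nx: int = 128
    ny: int = 256
    c_min: float = 0.20
    c_max: float = 0.42
    L: float | None = None          # extrapallial thickness; default 0.8 x height
    nucleation: NucleationSpec = field(default_factory=NucleationSpec)
    membranes: MembraneSpec | None = None
    dT: float = 0.0                 # K, temperature offset (coral sweeps)
    seed: int = 0
    steps: int = 4000
    snapshot_every: int = 500
    noise: NoiseParams = field(default_factory=lambda: NoiseParams(amp_theta=0.01))
    s0: float = 0.05
    source_decay_time: float | None = None  # mantle-source time constant (PF2)

    def __post_init__(self) -> None:
        if not (0.0 <= self.c_min < self.c_max <= 1.0):
            raise ValueError("require 0 <= c_min < c_max <= 1")
        if self.model not in ("PF1", "PF2"):
            raise ValueError("2D scenarios support models PF1 and PF2")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.system not in ("shell", "nacre", "coral"):
            raise ValueError(f"unknown system {self.system!r}")
        if self.system == "nacre" and self.membranes is None:
            raise ValueError("nacre system needs a MembraneSpec")

    @property
    def domain_height(self) -> float:
        return self.ny * 6.25e-3

    def profile_L(self) -> float:
        return self.L if self.L is not None else 0.8 * self.domain_height


def exponential_supersaturation_profile(x, c_min: float, c_max: float, L: float):
    """Organic-content profile c(x) = c_min + (c_max - c_min)(1 - e^{-9x/L}).

    ``x`` is the distance from the periostracum; the organic fraction rises
    (CC supersaturation falls) away from the wall, saturating toward
    ``c_max`` over the extrapallial thickness ``L``.
    """
    if L <= 0:
        raise ValueError("L must be positive")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("distance x must be >= 0")
    return c_min + (c_max - c_min) * (1.0 - np.exp(-9.0 * x / L))


def _seeded_bottom(state: FieldState2D, grid: Grid2D, spec: NucleationSpec,
                   rng: np.random.Generator) -> None:
    """Place semicircular wall nuclei with random orientations (in place)."""
    nx = grid.nx
    xs = rng.choice(nx, size=min(spec.n_sites, nx), replace=False)
    oris = rng.random(len(xs))
    r = spec.seed_radius
    X, Y = np.meshgrid(np.arange(nx), np.arange(grid.ny))
    for x0, th in zip(xs, oris):
        dx_ = np.minimum(np.abs(X - x0), nx - np.abs(X - x0)) if grid.periodic_x \
            else np.abs(X - x0)
        mask = (dx_**2 + Y**2) <= r**2
        state.phi[mask] = 1.0
        state.theta[mask] = th


def sample_volumetric_sites(grid: Grid2D, spec: NucleationSpec,
                            rng: np.random.Generator):
    """Poisson-sample nucleation sites with exponentially decaying areal
    density away from the wall (decay length ``site_density_scale``,
    dimensionless); returns (y, x, orientation) arrays in dimensionless
    coordinates (truncated-exponential inverse-CDF sampling in y)."""
    n = rng.poisson(spec.n_sites)
    H = grid.ny * grid.dx
    lam = spec.site_density_scale
    u = rng.random(n)
    y = -lam * np.log1p(-u * (1.0 - math.exp(-H / lam)))
    x = rng.random(n) * grid.nx * grid.dx
    oris = rng.random(n)
    return y, x, oris


def _volumetric_sites(state: FieldState2D, grid: Grid2D, spec: NucleationSpec,
                      rng: np.random.Generator) -> np.ndarray:
    """Apply sampled point nuclei to the state in place; returns (y, x)
    cell indices of the sites."""
    y, x, oris = sample_volumetric_sites(grid, spec, rng)
    iy = np.minimum((y / grid.dx).astype(int), grid.ny - 1)
    ix = np.minimum((x / grid.dx).astype(int), grid.nx - 1)
    r = spec.seed_radius
    X, Y = np.meshgrid(np.arange(grid.nx), np.arange(grid.ny))
    for yy, xx, th in zip(iy, ix, oris):
        dx_ = np.minimum(np.abs(X - xx), grid.nx - np.abs(X - xx)) if grid.periodic_x \
            else np.abs(X - xx)
        mask = (dx_**2 + (Y - yy)**2) <= r**2
        state.phi[mask] = 1.0
        state.theta[mask] = th
    return np.stack([iy, ix], axis=1) if len(iy) else np.empty((0, 2), dtype=int)


def _blank_state(grid: Grid2D, c0, rng: np.random.Generator) -> FieldState2D:
    phi = np.zeros(grid.shape)
    c = np.broadcast_to(np.asarray(c0, dtype=float), grid.shape).copy()
    theta = rng.random(grid.shape)
    return FieldState2D(phi, c, theta)


def build_shell_pf1(config: ScenarioConfig):
    """Shell formation, base model: wall nucleation + exponential profile.

    The mechanism selects the mobility row and the (gamma, v_m) pair of the
    route tables; the concentration profile rises from c_min at the
    periostracum (y=0) toward c_max across the extrapallial thickness L.
    Returns (state, grid, params, scales).
    """
    if config.model != "PF1":
        raise ValueError("build_shell_pf1 requires model PF1")
    route = load_route(config.mechanism)
    params, scales = route_pf1_params(route, noise=config.noise, s0=config.s0)
    dx = route["numerics"]["dx"]
    grid = Grid2D(config.nx, config.ny, dx=dx, boundary={
        "left": "periodic", "right": "periodic", "bottom": "wall", "top": "noflux"})
    rng = np.random.default_rng(config.seed)
    y = grid.y_coords()
    prof = exponential_supersaturation_profile(y, config.c_min, config.c_max,
                                               config.profile_L())
    state = _blank_state(grid, prof[:, None], rng)
    _seeded_bottom(state, grid, config.nucleation, rng)
    return state, grid, params, scales


def _pf2_params_for_route(route: dict, config: ScenarioConfig) -> tuple[PF2Params, PhysicalScales]:
    scales = route_scales(route)
    co = dimensionless_coefficients(scales)
    th2 = route["thermo_pf2"]
    mo = route["mobilities_pf2"]
    mob = MobilityParams(m_phi=mo["m_phi"], m_cM=mo["m_cM"], m_cC=mo["m_cC"],
                         m_thetaM=mo["m_thetaM"], m_thetaC=mo["m_thetaC"])
    base = PF1Params(eps_phi_sq=co.eps_phi_sq, w_A=co.w_A, w_B=co.w_B,
                     mobility=mob, dg_A=th2["dg_A"], dg_B=th2["dg_B"],
                     s0=config.s0, noise=config.noise)
    pf2 = PF2Params.from_base(base, omega_M=th2["omega_M"], omega_C=th2["omega_C"],
                              dx=route["numerics"]["dx"])
    return pf2, scales


def build_shell_pf2(config: ScenarioConfig):
    """Shell formation, eutectic model: volumetric nucleation + mantle source.

    Nucleation sites are Poisson-sampled with exponentially decaying
    density away from the periostracum; the top edge is a source whose
    emitted mineral content decays exponentially in time (handled by the
    runner via the returned ``source_c`` callable).  Returns
    (state, grid, params, scales, source_c).
    """
    if config.model != "PF2":
        raise ValueError("build_shell_pf2 requires model PF2")
    route = load_route(config.mechanism)
    pf2, scales = _pf2_params_for_route(route, config)
    dx = route["numerics"]["dx"]
    grid = Grid2D(config.nx, config.ny, dx=dx, boundary={
        "left": "periodic", "right": "periodic", "bottom": "noflux", "top": "source"})
    rng = np.random.default_rng(config.seed)
    state = _blank_state(grid, config.c_min, rng)
    _volumetric_sites(state, grid, replace(config.nucleation, mode="volumetric_sites"),
                      rng)
    tau = config.source_decay_time or (0.25 * config.steps * 4.75e-6)

    def source_c(t: float) -> float:
        # mantle emits a mixture whose mineral content (1 - c) decays
        # exponentially in time -> organic content rises toward c_max
        return config.c_max - (config.c_max - config.c_min) * math.exp(-t / tau)

    return state, grid, pf2, scales, source_c


def build_columnar_nacre(config: ScenarioConfig):
    """Columnar nacre: growth between preexisting organic membranes.

    Membrane rows become wall cells with pixelwise random (amorphous)
    orientation; aligned holes act as mineral bridges; the membrane
    surfaces prescribe the configured contact angle.  A single seed layer
    sits below the lowest membrane.  Returns (state, grid, params, scales).
    """
    if config.membranes is None:
        raise ValueError("columnar nacre scenario needs a MembraneSpec")
    mem = config.membranes
    route = load_route(config.mechanism)
    params, scales = route_pf1_params(route, noise=config.noise, s0=config.s0,
                                      kinetic_aniso=True)
    dx = route["numerics"]["dx"]
    rng = np.random.default_rng(config.seed)
    wall = np.zeros((config.ny, config.nx), dtype=bool)
    first = mem.spacing
    for y0 in range(first, config.ny - mem.thickness, mem.spacing):
        wall[y0:y0 + mem.thickness, :] = True
        for cx, wdt in mem.holes:
            x0 = int(cx - wdt // 2)
            wall[y0:y0 + mem.thickness, max(0, x0):min(config.nx, x0 + int(wdt))] = False
    grid = Grid2D(config.nx, config.ny, dx=dx, boundary={
        "left": "periodic", "right": "periodic", "bottom": "wall", "top": "noflux"},
        wall_mask=wall, contact_angle_deg=mem.contact_angle)
    state = _blank_state(grid, 0.5 * (config.c_min + config.c_max), rng)
    _seeded_bottom(state, grid, config.nucleation, rng)
    # membranes: inert organic walls, amorphous = random pixelwise orientation
    state.phi[wall] = 1.0
    state.c[wall] = 1.0
    state.theta[wall] = rng.random(wall.sum())
    return state, grid, params, scales


def build_coral_corallite(config: ScenarioConfig):
    """Coral corallite: confined channel fed from a nutrient source.

    The corallite top (existing skeleton) is a flat base slab of
    block-wise random orientation; the calcifying fluid above it carries a
    uniform particle concentration ``(c_min + c_max)/2`` close to the
    zero-driving composition, so growth is slow and diffusion-controlled
    (d v / D << 1) rather than trapping-dominated.  The temperature offset
    ``dT`` (K) shifts the driving force via the linear law and modulates
    the growth-front-nucleation rate.  The builder estimates d v/D and
    warns (not raises) outside the diffusion-controlled regime.  Returns
    (state, grid, params, scales, source_c).
    """
    route = load_route(config.mechanism)
    params, scales = route_pf1_params(route, dT_kelvin=config.dT,
                                      noise=config.noise, s0=config.s0)
    dx = route["numerics"]["dx"]
    grid = Grid2D(config.nx, config.ny, dx=dx, boundary={
        "left": "noflux", "right": "noflux", "bottom": "wall", "top": "source"})
    rng = np.random.default_rng(config.seed)
    # nutrient-rich boundary layer over the skeleton: strong driving at the
    # base (the existing corallite never redissolves), weak driving in the
    # bulk calcifying fluid so growth stays diffusion-controlled there
    y = grid.y_coords()
    L_coral = config.L if config.L is not None else 0.15 * grid.ny * grid.dx
    prof = exponential_supersaturation_profile(y, config.c_min, config.c_max,
                                               L_coral)
    state = _blank_state(grid, prof[:, None], rng)
    # liquid orientation with a short correlation length: pixelwise-random
    # theta would impose a static orientational barrier ~H p'|grad theta|
    # that exceeds the weak coral driving force and melts the base
    from scipy.ndimage import gaussian_filter
    th = gaussian_filter(rng.random(grid.shape), 3.0, mode="wrap")
    rng_span = th.max() - th.min()
    state.theta = (th - th.min()) / (rng_span if rng_span > 0 else 1.0)
    base_rows = config.nucleation.seed_radius
    block = max(4, grid.nx // max(config.nucleation.n_sites, 1))
    n_blocks = -(-grid.nx // block)
    base_theta = np.repeat(rng.random(n_blocks), block)[:grid.nx]
    state.phi[:base_rows, :] = 1.0
    state.theta[:base_rows, :] = base_theta[None, :]
    c0 = config.c_max
    # regime estimate: kinetic-limited bound v ~ m_phi |dg| / gamma_hat
    co = dimensionless_coefficients(scales)
    drive = abs((1.0 - c0) * params.dg_A + c0 * params.dg_B)
    v_hat = params.mobility.m_phi * drive / max(co.gamma_A, 1e-30)
    x, label = classify_growth_regime(scales.delta,
                                      scales.velocity_to_si(v_hat), scales.D_cM)
    if x >= 0.1:
        import warnings
        warnings.warn(f"coral scenario dv/D = {x:.3g} not << 1 ({label})",
                      stacklevel=2)
    return state, grid, params, scales, (lambda t: c0)


def coral_sweep_config(dT: float, seed: int, *, nx: int = 80, ny: int = 128,
                       steps: int = 8000) -> ScenarioConfig:
    """Study conditions of the coral temperature sweep.

    The calcifying fluid sits at organic fraction 0.35, well below the
    zero-driving composition 0.4324 but weak enough that growth stays far
    from the diffusionless regime across dT in [-3, +2] K; the orientation
    noise amplitude keeps growth-front nucleation active without
    overwhelming interfacial alignment.
    """
    return ScenarioConfig(system="coral", mechanism="ion_by_ion", nx=nx, ny=ny,
                          dT=dT, seed=seed, steps=steps, snapshot_every=steps,
                          c_min=0.30, c_max=0.35,
                          noise=NoiseParams(amp_theta=0.005),
                          nucleation=NucleationSpec(n_sites=8, seed_radius=4))


def run_coral_to_height(config: ScenarioConfig, target_rows: int = 70,
                        max_steps: int = 16000):
    """Run a coral scenario until the front reaches ``target_rows`` (or
    ``max_steps``); comparing sweep points at equal grown height removes
    the trivial dependence of area fractions on how far each run got.
    Returns (state, grid, params, scales)."""
    state, grid, params, scales, src = build_coral_corallite(config)
    dt = min(4.75e-6, stable_dt(params, grid))
    rng = np.random.default_rng(config.seed + 1)
    from .pf1 import front_height
    steps = 0
    while steps < max_steps:
        state = step_pf1(state, params, grid, dt, rng, source_c=src(state.t),
                         check=False)
        steps += 1
        if steps % 500 == 0:
            try:
                if front_height(state.phi, dx=1.0) >= target_rows:
                    break
            except ValueError:
                pass
    state.validate(c_clip=1e-2)
    return state, grid, params, scales


def run_scenario(config: ScenarioConfig, *, dt: float | None = None,
                 moving_window: bool = False, progress: bool = False):
    """Build and run a scenario; returns (snapshots, grid, params, scales).

    Snapshot cadence follows ``config.snapshot_every``; the time step
    defaults to min(reference table value, stability guard).  With
    ``moving_window`` the frame follows the front and incoming rows are
    refilled from the far-field profile.
    """
    source_c = None
    if config.model == "PF2":
        state, grid, params, scales, source_c = build_shell_pf2(config)
        base = params.base
        stepper = lambda st, d, rng, sc: step_pf2(st, params, grid, d, rng, source_c=sc)
    elif config.system == "nacre":
        state, grid, params, scales = build_columnar_nacre(config)
        base = params
        stepper = lambda st, d, rng, sc: step_pf1(st, params, grid, d, rng)
    elif config.system == "coral":
        state, grid, params, scales, source_c = build_coral_corallite(config)
        base = params
        stepper = lambda st, d, rng, sc: step_pf1(st, params, grid, d, rng, source_c=sc)
    else:
        state, grid, params, scales = build_shell_pf1(config)
        base = params
        stepper = lambda st, d, rng, sc: step_pf1(st, params, grid, d, rng)
    rng = np.random.default_rng(config.seed + 1)
    guard = stable_dt(base, grid)
    if config.model == "PF2" and params.eps_c_sq > 0:
        guard = min(guard, 0.4 * grid.dx**4 /
                    (16.0 * params.eps_c_sq * 0.25 * base.mobility.m_cM))
    dt_used = dt if dt is not None else min(4.75e-6, guard)
    y_top = grid.ny * grid.dx
    prof = lambda y: exponential_supersaturation_profile(
        np.minimum(y, 50.0 * config.profile_L()), config.c_min, config.c_max,
        config.profile_L())
    snaps = [state.copy()]
    for n in range(1, config.steps + 1):
        sc = source_c(state.t) if source_c is not None else None
        state = stepper(state, dt_used, rng, sc)
        if moving_window:
            state = maybe_shift_window(state, grid, prof, rng)
        if n % config.snapshot_every == 0 or n == config.steps:
            snaps.append(state.copy())
            if progress:
                print(f"step {n}/{config.steps} t={state.t:.3e}")
    return snaps, grid, params, scales
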