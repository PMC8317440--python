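# Methods

`biominpf` implements a family of orientation-field phase-field models of
CaCO3 biomineralization — the formation of mollusk-shell ultrastructure
(granular, columnar prismatic, and sheet-nacre zones), columnar nacre
between preexisting organic membranes, and coral-skeleton microstructure —
together with the closed-form materials-parameter estimators that anchor
the models to measured quantities.  This note records the governing
equations as implemented, the non-dimensionalization, all numerical
choices, and the judgement calls made where the modeling literature leaves
the formulation open.

## 1. Binary orientation-field model (2D)

### Fields and free energy

Three coupled fields live on a uniform 2D grid: the structural order
parameter `phi` (0 = mother phase: aqueous solution or amorphous
precursor; 1 = crystal), the concentration `c` of the *organic* component
of a quasi-binary solution (the mineral fraction is `1 - c`), and a scalar
crystallographic orientation `theta`, a circular variable normalized to
[0, 1).  The free energy functional is

    F = Int dV [ eps^2/2 * s(nu, theta)^2 |grad phi|^2
                 + w(c) g(phi) + p(phi) ((1-c) dg_A + c dg_B)
                 + c ln c + (1-c) ln(1-c)
                 + H p(phi) |grad theta| ]

with

* `g(phi) = phi^2 (1-phi)^2 / 4` — double well; `p(phi) = phi^3 (10 - 15
  phi + 6 phi^2)` — interpolant with flat ends;
* `w(c) = (1-c) w_A + c w_B` — composition-weighted barrier height
  (component A = CaCO3, B = organic);
* `dg_A, dg_B` — dimensionless pure-component crystallization driving
  forces Delta_G_i/RT (ideal-solution thermodynamics); the tabulated
  reference state is `T_r = 0.911`, `T_rB = 0.786`, `dg_A = -0.1184`,
  `dg_B = +0.1554`;
* `s = 1 + s0 cos(k nu - 2 pi theta)` — k-fold interfacial anisotropy,
  `nu = atan2(phi_y, phi_x)` the interface-normal angle;
* `H p(phi) |grad theta|` — orientational (grain-boundary) free energy of
  the Kobayashi–Warren–Carter type; the `p(phi)` coupling removes
  orientational stiffness from the mother phase, where `theta` is allowed
  to fluctuate freely (representing short-range order only).

The factor 1/4 in `g` pairs with the coefficient definitions
`eps^2 = (12/sqrt 2) gamma delta / T` and `w = (12/sqrt 2) gamma / (delta
T)` so that a relaxed planar interface carries excess free energy exactly
`gamma` and has a logistic profile `1/(1+exp(x/l))` with
`l = sqrt(2 eps^2 / w) = sqrt 2 * delta`.  (Quoting the double well as
`phi^2(1-phi)^2` with these same coefficient formulas would give an
interface energy of `2 gamma`; the 1/4 is the consistent convention and is
verified by the interface-excess test.)

### Non-dimensionalization

Lengths are measured in `xi = 2.1 um`, time in `xi^2 / D_cM` with `D_cM`
the mother-phase chemical diffusivity (1e-9 m^2/s for aqueous solution,
1e-15 m^2/s for ACC), free-energy densities in `RT/v_m`.  Dimensionless
mobilities follow the convention `m_phi = M_phi eps^2 T / D_cM` (3.75),
`m_c = D_c / D_cM` (1 in the mother phase, 1e-20 or 1e-14 in the crystal
for the two routes), `m_theta = M_theta xi H T / D_cM` (120 in the mother
phase, zero for practical purposes in the crystal).  Chemical and
orientational mobilities are phase-interpolated as
`M_i = M_iC + [1 - p(phi)](M_iM - M_iC)`.

### Equations of motion

Variational relaxation for the nonconserved fields and a conservative
flux law for the concentration:

    d phi / dt   = -(m_phi / eps^2) dF/dphi           + zeta_phi
    d c / dt     = div( m_c(phi) c (1-c) grad(dF/dc) ) + div zeta_c
    d theta / dt = m_theta(phi) div( p(phi) u ) - (m_theta/H) dE_aniso/dtheta
                                                       + zeta_theta

where `u = grad theta / |grad theta|_reg` is the regularized unit
gradient.  The `1/eps^2` in the phi mobility follows from the convention
that `m_phi` contains `eps^2`; the grain-boundary scale `H` cancels out of
the leading orientation dynamics (classic KWC behavior) and enters only
the cross-coupling terms.

**Orientation energy scale.** `H` is a free scale in this family of
models.  We set it, in scenario builders, to the dimensionless
crystal–mother interfacial free energy (~7e-4 in RT/v_m units), so that a
high-angle grain boundary costs about half of a crystal–mother interface —
the physically expected ordering.  Values of order 1 would make grain
boundaries thousands of times more expensive than the interface itself
and blow up the phi equation wherever a crystal meets a randomly oriented
mother phase.  `H` remains a constructor parameter.

### Numerics

* Finite differences on a uniform grid, forward-Euler time stepping;
  `dx = 6.25e-3` (dimensionless) as in the reference computations.
* Conserved field in face-flux form: fluxes `M_face * (mu_j+1 - mu_j)/dx`
  with arithmetically averaged face mobilities; no-flux edges carry zero
  flux identically, so the total solute content is conserved to round-off
  over arbitrarily many steps.
* Orientation flux evaluated per face with *face-local* regularization
  `u_face = dtheta_face / sqrt(dtheta_face^2 + eta^2)`, `eta = 1e-6/dx`,
  which bounds the flux magnitude by `p(phi)` regardless of how small the
  local gradient is.  (Cell-centered regularization would divide a face
  gradient by an interior magnitude and is unbounded — it detonates at
  seed edges.)  Circular differences use the minimal image on (-1/2, 1/2];
  `theta` is re-wrapped to [0, 1) after each step.
* Anisotropy: the variational rotation term
  `-div(eps^2 s s_nu (-phi_y, phi_x))` is discretized cell-centered;
  `s = 1` is forced where `|grad phi| < 1e-8/dx` (undefined normal) and in
  wall cells.  An optional kinetic anisotropy multiplies `m_phi` by `s^2`.
* Stability guard `dt <= 0.4 dx^2 / (2 D_max)` with `D_max = max(m_phi
  (1+s0)^2, m_cM, m_cC)`; the bounded orientation flux contributes no
  linear diffusivity.  With the tabulated mobilities the guard gives
  `dt ~ 1.9e-6`, slightly below the tabulated reference step 4.75e-6 —
  which exceeds the explicit-Euler CFL bound for `m_phi = 3.75` — so the
  runner uses `min(4.75e-6, guard)`.  The guard refuses larger steps
  unless explicitly overridden.
* Logarithms floored at 1e-12; bulk nonlinear forces in the 3D model are
  evaluated on `phi` clipped to [0, 1] so transient overshoots feel only
  the restoring Laplacian.
* Noise: Gaussian, standard deviation `amp * sqrt(2 * mobility * dt)/dx`
  per step (variance proportional to the respective mobility, the
  fluctuation–dissipation pattern); the concentration noise enters as the
  divergence of independent random face fluxes, which conserves the total
  content exactly and vanishes on no-flux boundary faces.  Amplitudes are
  scenario parameters (nothing canonical exists for them): shell runs use
  `amp_theta = 0.01` — small enough that crystallization starts only at
  the seeded sites, large enough to keep the mother-phase orientation
  decorrelating; coral runs use `amp_theta = 0.02` so growth-front
  nucleation is active.
* Moving window: when the front passes 3/4 of the domain height the
  fields shift down by ny/8 rows, `frame_offset` increments, and incoming
  rows are filled with far-field mother phase (profile-continued
  concentration, random orientation).
* Contact angle (wall boundaries): ghost row
  `phi_ghost = phi + dx cos(psi) sqrt(w(c)/(2 eps^2)) phi (1-phi)`, the
  discrete form of the Young condition `eps^2 n . grad phi = -sigma'(phi)`
  for a wall free energy interpolating `-gamma cos(psi)` between the
  phases.  A sessile-drop calibration (drop held near stationary by a
  Gibbs–Thomson-balancing supersaturation, angle read from a quadratic
  tangent fit of the contour at the wall) recovers prescribed angles of
  60–120 degrees within ~3 degrees; 100 degrees — the columnar-nacre
  value — is recovered to better than 1 degree.

## 2. Eutectic two-solid model (2D)

The refined shell model adds, on top of the binary model: regular-solution
bulk thermodynamics with phase-interpolated interaction
`omega(phi) c(1-c)` (`omega_M = 2.0510`, `omega_C = 3.6335` at the
tabulated eutectic state; driving forces `dg_A = -0.5802`,
`dg_B = -1.0477` on the `T/T_E = 0.720` scale), a concentration
square-gradient term `(eps_c^2/2)|grad c|^2` with `eps_c^2 = 2 eps^2`
(enforced at construction), and a composition-gated orientational energy

    H p(phi) [ h(c) F1(|grad theta|) + (1 - h(c)) F2(|grad theta|) ]

with `h(c) = (1/2){1 + cos[2 pi (c - c_a)/(c_b - c_a)]}`, `F1(x) = x`, and
`F2(x) = a + b |cos(2 m pi d x)|`.  The gate selects F1 inside either
solid phase (`h = 1` at `c_a` and `c_b`) and F2 across solid–solid
boundaries (`h = 0` at the midpoint composition), whose periodic minima
impose a fixed misorientation set by `m` and the boundary thickness `d` —
this is the reading of the published blend that places the
fixed-orientation-relationship mechanism where the two solids meet, and it
is isolated in one switchable function.  Outside `[c_a, c_b]` the gate is
clamped to 1 rather than allowed to oscillate.  The branch constants are
not published; defaults `a = 0.3`, `b = 0.7`, `m = 2`, `d = 3 dx` give
order-one branch levels and a boundary a few cells thick.

The coexistence compositions `c_a < c_b` are not hard-coded: they are
computed at construction by the common-tangent construction on the solid
free-energy curve (for the symmetric regular solution the binodal solves
`ln(c/(1-c)) + omega(1-2c) = 0`; tolerance 1e-10), giving
`c_a = 0.032, c_b = 0.968` at `omega_C = 3.6335`.

A degenerate constructor (`PF2Params.pf1_reduction`) pins the gate to F1
and zeroes `omega` and `eps_c^2`; the shared stepping kernel then
reproduces binary-model trajectories exactly, which the reduction test
asserts.  The `eps_c^2 = 0` in this validation mode is the one deliberate
exception to the 2x ratio: the square-gradient term contributes at the
1e-4 level and would otherwise mask the kernel identity.

The stability guard gains a biharmonic bound
`dt <= 0.4 dx^4 / (16 eps_c^2 * 0.25 * m_cM)` from the square-gradient
term inside the conserved flux.

## 3. Ternary model (3D)

A single order parameter plus a composition simplex
`c = (c1, c2, c3)` (mineral, organic, water), free energy

    F = Int dV [ eps_phi^2/2 |grad phi|^2 + w g(phi)
                 + p(phi) f_S(c) + (1-p(phi)) f_L(c)
                 + eps_c^2/2 sum_i |grad c_i|^2 ]

with a regular-solution solid `f_S = sum c_i ln c_i + sum_{i<j} Omega_ij
c_i c_j` and an ideal liquid `f_L = sum c_i ln c_i + sum d_i c_i` whose
offsets `d_i` carry the driving force.  Composition dynamics uses the
simplex-conserving mobility matrix (diagonal 1, off-diagonal -1/2; rows
and columns sum to zero) in face-flux form with weights
`c_j (1-c_j) (1-p(phi))`: the degenerate `c(1-c)` factor keeps
compositions inside [0, 1] and the `(1-p)` interpolant switches diffusion
off in the bulk solid.  The simplex sum is preserved to ~1e-14 over 1e4
steps (exact up to the non-associativity of floating-point addition).

The source publications retain unpublished materials parameters for this
model; all coefficients here are therefore config values with documented
defaults (`Omega_12 = 3`, `Omega_13 = Omega_23 = 2`, liquid offsets
`d = (0.8, 0.8, 0)`, `w = 1`, `eps_phi^2 = 2`, `eps_c^2 = 0.5`,
`m_phi = 0.5`, mobility matrix scaled by 4; generic dimensionless units
with `dx = 1`).  The set was fixed by a timescale argument: at the
reference composition `(0.43, 0.55, 0.02)` coupled two-solid growth
requires the solid's spinodal demixing (rate ~ f''^2/(8 eps_c^2) x
mobility) to outrun front propagation (~ m_phi x driving / interface
energy), hence slow attachment kinetics, fast chemistry, and a reduced
composition-gradient penalty.  With these defaults a lamellar seed grows
a partitioned two-solid front (mineral fraction spanning roughly
0.15–0.6 in the new solid) on grids a few tens of cells wide; water
piles up at the front and the solid–solid boundaries.  Sustained helical
(screw-dislocation-like) defect formation requires production-scale
grids (order 256^3) and is treated as exploratory — the tests assert the
conservation structure, partitioned two-solid growth from a lamellar
seed, and moving-frame bookkeeping, not helix formation.

## 4. Scenario builders (study conditions)

All builders are deterministic given (config, seed).

* **Shell, binary model.** Bottom wall = periostracum with semicircular
  seeds of radius 3 cells at random positions/orientations
  (discrete seeding is reproducible; noise-induced heterogeneous
  nucleation would demand per-run amplitude tuning).  Organic fraction
  profile `c(y) = c_min + (c_max - c_min)(1 - exp(-9 y / L))`: mineral
  supersaturation is highest at the wall and decays across the
  extrapallial thickness `L` (default 0.8 of the domain height).  Defaults
  `c_min = 0.20`, `c_max = 0.42`: the zero-driving composition of the
  tabulated thermodynamics is `c* = 0.4324`, so the far field stays weakly
  supersaturated and the front decelerates into the partitioning regime
  instead of halting.  The mechanism switch selects the route tables:
  ion-by-ion (D_cM = 1e-9 m^2/s, gamma = 150/118 mJ/m^2, v_m = 26.7
  cm^3/mol) or amorphous precursor (1e-15 m^2/s, 87/68 mJ/m^2, 32.4
  cm^3/mol); both share the tabulated dimensionless driving force.
  Kinetic anisotropy (m_phi modulated by s^2, s0 = 0.05, k = 6 for the
  pseudo-hexagonal habit) is on by default — it drives the competitive
  orientation selection that turns the granular layer into columns.
* **Shell, eutectic model.** Poisson-sampled volumetric nuclei whose
  density decays exponentially with distance from the wall
  (inverse-CDF sampling of a truncated exponential; decay length
  config, default 0.3); a top source edge whose emitted mineral content
  decays exponentially in time (time constant config); with the moving
  window this realizes a mother-phase gap of roughly constant thickness.
* **Columnar nacre.** Horizontal membrane rows (thickness 3 cells,
  spacing config) as inert wall cells with pixelwise random orientation;
  aligned holes (default width 20 cells, three-column variant 20/5/10)
  act as mineral bridges; membrane surfaces prescribe a 100-degree
  contact angle; kinetic + interfacial anisotropy enabled.
* **Coral corallite.** Confined channel (no-flux side walls), nutrient
  source at the top; the existing skeleton is a flat base slab with
  block-wise random orientations.  The fluid composition rises over a
  short profile from 0.30 at the base to a bulk value of 0.35, so the
  base can never redissolve while the bulk sits at a weak, nearly
  constant driving force (-0.015 to -0.035 across the sweep) — constant
  so that the temperature effect on growth-front nucleation is not
  diluted by a spatial driving gradient.  The liquid orientation field is
  initialized with a short correlation length (Gaussian-smoothed noise)
  rather than pixelwise random: fully random orientations would impose a
  static orientational energy barrier `~H p'(phi)|grad theta|` larger
  than the weak coral driving force and melt the base, an artifact of
  initialization rather than model physics; the theta noise
  (amp 0.005) keeps growth-front nucleation active dynamically.  The
  temperature offset `dT` (K, anchored via T_ref = 300 K so
  T_A = T_ref/T_r = 329.3 K) shifts the driving forces through the
  linear law with enthalpies back-derived from the reference state
  (`dH_A = 1.330`, `dH_B = 0.977`).  The builder estimates `d v / D` and
  warns when the kinetic-limited bound is not << 1 (the realized
  diffusion-limited front is slower).  Sweep points are compared at
  equal grown height with the active front zone excluded, since area
  fractions otherwise depend trivially on how far each run grew.

## 5. Microstructure quantification

* **Front tracing.** Per column, the highest `phi = 0.5` crossing
  (linearly interpolated); front position = column mean + frame offset;
  summary velocity = least-squares slope over a trailing window (default
  last 50%, skipping the nucleation transient); physical velocity
  `v * D_cM / xi`.
* **Grain segmentation.** Union-find over 4-neighbor bonds between solid
  cells (`phi > 0.5`) with circular misorientation below tolerance
  (default 0.01 of the full turn ~ 3.6 degrees); canonical labels in
  first-occurrence order; per-grain circular mean orientation.
* **Sprinkles.** Fraction of solid area in grains below a size threshold
  (in cells; reported alongside the physical cell size `xi dx`).  The
  sources give no quantitative sprinkle cutoff ("submicron"), so the
  threshold remains a user choice; analyses here use 12 cells.
* **Layer spacing.** Dominant FFT period of the detrended mean-transverse
  composition profile (Hann window; peak must exceed 3x the median
  nonzero-frequency power) plus a mean-crossing band count.
* **Contact angle.** Quadratic tangent fit of the drop contour at the
  wall (see section 1).

## 6. Synthetic-data realism and limits

The scenario builders *are* the data generators: no external data enter.
What they emulate: heterogeneous nucleation geometry, supersaturation
gradients across the extrapallial space, the two crystallization routes'
diffusivity/interface-energy contrast, membrane confinement with a known
contact angle, and temperature-shifted driving forces.  What they do not:
real extrapallial-fluid chemistry (quasi-binary ideal/regular solutions
stand in), biological regulation (mantle physiology is a boundary
condition), 3D crystallographic texture (scalar orientation is valid only
in 2D), mechanical stress, and production-scale resolution.  Passing
tests therefore demonstrate that the implemented mechanisms reproduce the
qualitative microstructural sequences and order-of-magnitude kinetics at
reduced scale — not quantitative agreement with any particular shell or
coral.

Problem sizes: test and acceptance runs use grids of 64x64 up to 128x256
cells and 4e3–6e4 steps (2D), and up to 40x12x16 cells (3D), chosen as
desk-scale counterparts of the reference computations (1000x2000 and
256x256x272 grids).

## 7. Known limitations

* Explicit Euler only; the tabulated reference time step exceeds the CFL
  bound of the phi equation and is capped by the guard.
* The energy functional and its discrete dynamics are not exactly
  adjoint (face-local TV regularization vs cell-centered energy), so the
  Lyapunov property is verified to 1e-10 relative per step, not to
  machine precision.
* Bitwise trajectory invariance under global orientation shifts holds
  for the one-step generator (verified with dyadic orientations); over
  many steps the sign structure of the TV flux amplifies ulp-level
  re-wrap differences, which is inherent to singular-diffusion dynamics.
* Layer/band formation sits beyond desk scale in all three models: the
  decelerating binary-model front passes the trapping-to-partitioning
  transition smoothly (the oscillatory solute-trapping instability that
  produces alternating layers needs several times finer grids and an
  order of magnitude more steps; a refined quasi-1D run shows only a
  ~0.005-amplitude composition wobble), the eutectic model's solid-solid
  composition steps are near sub-cell at `eps_c^2 = 2 eps^2` and pin the
  front, and ternary helical defects need production-scale 3D grids.
  The implementation supports all three regimes; the test suite asserts
  the granular-to-columnar sequence and two-solid partitioning, not
  banding or helices.
* The scalar orientation field cannot represent 3D texture
  (co-alignment of c-axes); that requires quaternion orientation fields.
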