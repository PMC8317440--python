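import numpy as np
import pytest

from biominpf.grids import FieldState2D, Grid2D
from biominpf.pf1 import PF1Params
from biominpf.scales import MobilityParams, PhysicalScales, dimensionless_coefficients

#: dimensionless organic fraction at which the binary driving force vanishes
C_ZERO_DRIVE = 0.1184 / (0.1184 + 0.1554)


def acc_route_scales() -> PhysicalScales:
    return PhysicalScales(gamma_A=0.087, gamma_B=0.068, delta=4.15e-8,
                          xi=2.1e-6, v_m=32.4e-6, D_cM=1e-15,
                          T_A=329.3, T_B=258.8)


def make_pf1_params(**over) -> PF1Params:
    """Reference binary-model parameter set (amorphous-precursor route),
    orientation energy at the interfacial-energy scale, no anisotropy or
    noise unless overridden."""
    co = dimensionless_coefficients(acc_route_scales())
    kw = dict(eps_phi_sq=co.eps_phi_sq, w_A=co.w_A, w_B=co.w_B,
              mobility=MobilityParams(3.75, 1.0, 1e-14, 120.0, 120e-14),
              H_ori=co.gamma_A, s0=0.0)
    kw.update(over)
    return PF1Params(**kw)


@pytest.fixture
def pf1_params() -> PF1Params:
    return make_pf1_params()


@pytest.fixture
def small_grid() -> Grid2D:
    return Grid2D(32, 48, boundary={"left": "periodic", "right": "periodic",
                                    "bottom": "noflux", "top": "noflux"})


def seeded_state(grid: Grid2D, seed: int = 0, slab_rows: int = 10,
                 c0: float = 0.3) -> FieldState2D:
    """Solid slab at the bottom, mother phase above, random orientations in
    the mother phase, uniform orientation in the slab."""
    rng = np.random.default_rng(seed)
    phi = np.zeros(grid.shape)
    phi[:slab_rows, :] = 1.0
    theta = rng.random(grid.shape)
    theta[:slab_rows, :] = 0.25
    c = np.full(grid.shape, c0)
    return FieldState2D(phi, c, theta)
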