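"""Finite-difference helpers shared by the 2D models.

All operators act on cell-centered arrays indexed [y, x]; ghost cells are
added explicitly so boundary conditions stay in one place.  Orientation
differences are taken with the minimal-image convention on the unit circle
(theta is circular on [0, 1)).
"""

from __future__ import annotations

import numpy as np

__all__ = ["pad2", "wrap_diff", "central_gradient", "face_diffs", "div_faces"]


def pad2(a: np.ndarray, periodic_x: bool, *, top_value: np.ndarray | float | None = None,
         bottom_value: np.ndarray | float | None = None) -> np.ndarray:
    """Pad a [ny, nx] array with one ghost cell per side.

    x: periodic wrap or edge replication (zero normal derivative).
    y: edge replication, unless a Dirichlet face value is given, in which
    case the ghost is linearly extrapolated so the face takes that value.
    """
    mode = "wrap" if periodic_x else "edge"
    p = np.pad(a, ((1, 1), (1, 1)), mode="edge")
    if periodic_x:
        p[1:-1, 0] = a[:, -1]
        p[1:-1, -1] = a[:, 0]
    if top_value is not None:
        p[-1, 1:-1] = 2.0 * top_value - a[-1, :]
    if bottom_value is not None:
        p[0, 1:-1] = 2.0 * bottom_value - a[0, :]
    # corners never enter 5-point stencils; leave as copied edges
    return p


def wrap_diff(d: np.ndarray) -> np.ndarray:
    """Wrap circular-variable differences to (-0.5, 0.5]."""
    return d - np.round(d)


def central_gradient(p: np.ndarray, dx: float, circular: bool = False):
    """Cell-centered gradient from a padded array; returns (d/dy, d/dx)."""
    dy = p[2:, 1:-1] - p[:-2, 1:-1]
    dxx = p[1:-1, 2:] - p[1:-1, :-2]
    if circular:
        dy = wrap_diff(dy)
        dxx = wrap_diff(dxx)
    return dy / (2.0 * dx), dxx / (2.0 * dx)


def face_diffs(p: np.ndarray, dx: float, circular: bool = False):
    """Forward differences at the east and north faces of each cell.

    Returns (de, dn) with shape [ny, nx+1]-like slices folded to [ny, nx]+1
    handled by the caller; here we return differences between cell i and its
    +x / +y neighbor for all interior faces including boundary ghosts:
    de[j, i] = p[j, i+1] - p[j, i] over the padded row, shape [ny, nx+1];
    dn analogous with shape [ny+1, nx].
    """
    de = p[1:-1, 1:] - p[1:-1, :-1]        # [ny, nx+1]
    dn = p[1:, 1:-1] - p[:-1, 1:-1]        # [ny+1, nx]
    if circular:
        de = wrap_diff(de)
        dn = wrap_diff(dn)
    return de / dx, dn / dx


def div_faces(Fe: np.ndarray, Fn: np.ndarray, dx: float) -> np.ndarray:
    """Divergence from east-face [ny, nx+1] and north-face [ny+1, nx] fluxes."""
    return (Fe[:, 1:] - Fe[:, :-1] + Fn[1:, :] - Fn[:-1, :]) / dx


def face_average(p: np.ndarray):
    """Arithmetic face averages of a padded cell field: (east [ny, nx+1],
    north [ny+1, nx])."""
    ae = 0.5 * (p[1:-1, 1:] + p[1:-1, :-1])
    an = 0.5 * (p[1:, 1:-1] + p[:-1, 1:-1])
    return ae, an
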