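"""Grids and field-state containers for the 2D and 3D models.

Arrays are indexed ``[y, x]`` (2D) or ``[z, y, x]`` (3D) with the growth
direction along the last-but-one axis being +y (2D) / +z (3D); index 0 sits
at the nucleating wall.  Cells are cell-centered with spacing ``dx`` in
dimensionless units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Grid2D", "FieldState2D", "FieldState3D", "BOUNDARY_KINDS"]

BOUNDARY_KINDS = ("periodic", "noflux", "wall", "source")


@dataclass(frozen=True)
class Grid2D:
    """Uniform rectangular 2D grid.

    ``boundary`` maps edge names ("left", "right", "bottom", "top") to a
    condition tag: "periodic" (left/right only, both sides), "noflux",
    "wall" (no-flux with optional contact-angle prescription on phi), or
    "source" (Dirichlet concentration feeding edge, top only).
    ``wall_mask`` marks inert obstacle cells (organic membranes); their
    fields are pinned and no flux crosses their faces.
    """

    nx: int
    ny: int
    dx: float = 6.25e-3
    boundary: dict = field(default_factory=lambda: {
        "left": "periodic", "right": "periodic", "bottom": "wall", "top": "noflux",
    })
    wall_mask: np.ndarray | None = None
    contact_angle_deg: float | None = None

    def __post_init__(self) -> None:
        if self.nx < 8 or self.ny < 8:
            raise ValueError("grid must be at least 8x8 cells")
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        for edge, kind in self.boundary.items():
            if kind not in BOUNDARY_KINDS:
                raise ValueError(f"unknown boundary kind {kind!r} on edge {edge!r}")
        px = self.boundary.get("left") == "periodic"
        if px != (self.boundary.get("right") == "periodic"):
            raise ValueError("periodic boundary must be set on both left and right")
        if self.wall_mask is not None:
            if self.wall_mask.shape != (self.ny, self.nx):
                raise ValueError("wall_mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def periodic_x(self) -> bool:
        return self.boundary.get("left") == "periodic"

    def y_coords(self, frame_offset: int = 0) -> np.ndarray:
        """Cell-center y coordinates (dimensionless), frame-offset corrected."""
        return (np.arange(self.ny) + frame_offset + 0.5) * self.dx


@dataclass
class FieldState2D:
    """Coupled fields of the 2D models.

    phi : structural order parameter, 0 = mother phase, 1 = crystal.
    c : concentration of the organic component B (mineral fraction = 1 - c).
    theta : crystallographic orientation, circular on [0, 1).
    t : dimensionless time; frame_offset : rows shed by the moving window.
    """

    phi: np.ndarray
    c: np.ndarray
    theta: np.ndarray
    t: float = 0.0
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if not (self.phi.shape == self.c.shape == self.theta.shape):
            raise ValueError("phi, c, theta must share one shape")
        self.phi = np.ascontiguousarray(self.phi, dtype=np.float64)
        self.c = np.ascontiguousarray(self.c, dtype=np.float64)
        self.theta = np.ascontiguousarray(self.theta, dtype=np.float64)

    def copy(self) -> "FieldState2D":
        return FieldState2D(self.phi.copy(), self.c.copy(), self.theta.copy(),
                            self.t, self.frame_offset)

    def validate(self, c_clip: float = 1e-6) -> None:
        """Raise if a field left its admissible range (NaN/Inf guard)."""
        for name in ("phi", "c", "theta"):
            a = getattr(self, name)
            if not np.isfinite(a).all():
                raise FloatingPointError(f"non-finite values in {name} at t={self.t}")
        if self.c.min() < -c_clip or self.c.max() > 1.0 + c_clip:
            raise FloatingPointError(
                f"c outside [{-c_clip}, {1 + c_clip}]: min={self.c.min()}, max={self.c.max()}")
        if self.theta.min() < 0.0 or self.theta.max() >= 1.0:
            raise FloatingPointError("theta not wrapped to [0, 1)")


@dataclass
class FieldState3D:
    """Order parameter and ternary composition fields of the 3D model.

    ``comp`` has shape (3, nz, ny, nx) and satisfies sum_i c_i = 1 pointwise.
    """

    phi: np.ndarray
    comp: np.ndarray
    t: float = 0.0
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.comp.shape != (3,) + self.phi.shape:
            raise ValueError("comp must have shape (3,) + phi.shape")
        self.phi = np.ascontiguousarray(self.phi, dtype=np.float64)
        self.comp = np.ascontiguousarray(self.comp, dtype=np.float64)

    def copy(self) -> "FieldState3D":
        return FieldState3D(self.phi.copy(), self.comp.copy(), self.t, self.frame_offset)

    def validate(self, simplex_tol: float = 1e-9) -> None:
        if not (np.isfinite(self.phi).all() and np.isfinite(self.comp).all()):
            raise FloatingPointError(f"non-finite values at t={self.t}")
        drift = np.abs(self.comp.sum(axis=0) - 1.0).max()
        if drift > simplex_tol:
            raise FloatingPointError(f"composition simplex drift {drift:g} > {simplex_tol:g}")
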