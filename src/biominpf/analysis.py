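"""Quantification of simulated microstructures.

Front positions/velocities from snapshot sequences, grain segmentation on
the orientation field, sprinkle (small-crystallite) statistics, and layer
spacing of banded structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import Grid2D
from .pf1 import front_height
from .scales import PhysicalScales

__all__ = [
    "FrontTrace",
    "GrainMap",
    "front_trace",
    "segment_grains",
    "sprinkle_fraction",
    "layer_wavelength",
    "orientation_diversity_profile",
    "measure_contact_angle",
]


@dataclass
class FrontTrace:
    """Front position/velocity time series (frame-offset corrected)."""

    times: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    velocity: float
    physical_velocity: float | None = None

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class GrainMap:
    """Segmented grains: integer labels (0 = mother phase), per-grain mean
    orientation and size in cells."""

    labels: np.ndarray
    grain_orientations: np.ndarray
    grain_sizes: np.ndarray

    @property
    def n_grains(self) -> int:
        return len(self.grain_sizes)


def front_trace(snapshots, level: float = 0.5,
                scales: PhysicalScales | None = None,
                grid: Grid2D | None = None,
                fit_window: float = 0.5) -> FrontTrace:
    """Trace the solidification front through a snapshot sequence.

    Front height = mean over columns of the highest ``level`` crossing of
    phi, corrected by each state's ``frame_offset`` so moving-window runs
    report absolute positions.  The summary velocity is the least-squares
    slope over the trailing ``fit_window`` fraction of the samples
    (skipping the nucleation transient); ``physical_velocity`` (m/s) is
    attached when ``scales`` is given (v * D_cM / xi).
    """
    snapshots = list(snapshots)
    if len(snapshots) < 2:
        raise ValueError("need at least two snapshots")
    dx = grid.dx if grid is not None else 1.0
    times, pos = [], []
    for st in snapshots:
        try:
            h = front_height(st.phi, level=level, dx=dx)
        except ValueError:
            continue
        times.append(st.t)
        pos.append(h + st.frame_offset * dx)
    if len(times) < 2:
        raise ValueError("front not detectable in enough snapshots")
    times = np.asarray(times)
    pos = np.asarray(pos)
    vel = np.gradient(pos, times)
    n = len(times)
    i0 = min(n - 2, int(np.floor(n * (1.0 - fit_window))))
    slope = float(np.polyfit(times[i0:], pos[i0:], 1)[0])
    phys = scales.velocity_to_si(slope) if scales is not None else None
    return FrontTrace(times, pos, vel, slope, phys)


def _circular_distance(a, b):
    d = np.abs(a - b)
    return np.minimum(d, 1.0 - d)


def segment_grains(theta: np.ndarray, phi: np.ndarray,
                   misorientation_tol: float = 0.01,
                   solid_level: float = 0.5,
                   periodic_x: bool = False) -> GrainMap:
    """Connected-component grain segmentation on the orientation field.

    Adjacent solid cells (phi > solid_level, 4-connectivity) belong to the
    same grain iff their circular orientation distance is below
    ``misorientation_tol`` (fraction of the full turn).  Labels are
    canonical (1..N in order of first occurrence, row-major); label 0 is
    the mother phase.  Mean orientation per grain is the circular mean.
    """
    solid = phi > solid_level
    ny, nx = theta.shape
    labels = np.zeros((ny, nx), dtype=np.int32)
    # union-find over bonds that satisfy both solidity and misorientation
    idx = np.arange(ny * nx).reshape(ny, nx)
    parent = np.arange(ny * nx)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    def bond(ia, ib, ok):
        for a, b in zip(ia[ok], ib[ok]):
            union(a, b)

    ok_y = solid[1:, :] & solid[:-1, :] & (
        _circular_distance(theta[1:, :], theta[:-1, :]) < misorientation_tol)
    bond(idx[1:, :].ravel(), idx[:-1, :].ravel(), ok_y.ravel())
    ok_x = solid[:, 1:] & solid[:, :-1] & (
        _circular_distance(theta[:, 1:], theta[:, :-1]) < misorientation_tol)
    bond(idx[:, 1:].ravel(), idx[:, :-1].ravel(), ok_x.ravel())
    if periodic_x:
        ok_w = solid[:, 0] & solid[:, -1] & (
            _circular_distance(theta[:, 0], theta[:, -1]) < misorientation_tol)
        bond(idx[:, 0].ravel(), idx[:, -1].ravel(), ok_w.ravel())

    roots = np.array([find(a) for a in idx.ravel()]).reshape(ny, nx)
    order: dict[int, int] = {}
    flat_roots = roots.ravel()
    flat_solid = solid.ravel()
    lab = np.zeros(ny * nx, dtype=np.int32)
    for i in range(ny * nx):
        if not flat_solid[i]:
            continue
        r = flat_roots[i]
        if r not in order:
            order[r] = len(order) + 1
        lab[i] = order[r]
    labels = lab.reshape(ny, nx)

    n = len(order)
    sizes = np.zeros(n, dtype=np.int64)
    oris = np.zeros(n)
    if n:
        sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
        ang = 2.0 * np.pi * theta
        sin_sum = ndimage.sum_labels(np.sin(ang), labels, index=np.arange(1, n + 1))
        cos_sum = ndimage.sum_labels(np.cos(ang), labels, index=np.arange(1, n + 1))
        oris = (np.arctan2(sin_sum, cos_sum) / (2.0 * np.pi)) % 1.0
    return GrainMap(labels, oris, sizes)


def sprinkle_fraction(grains: GrainMap, size_threshold: int) -> tuple[float, int]:
    """Fraction of solid area in grains smaller than ``size_threshold``
    cells, and the count of such grains."""
    if grains.n_grains == 0:
        raise ValueError("empty grain map")
    small = grains.grain_sizes < size_threshold
    total = grains.grain_sizes.sum()
    return float(grains.grain_sizes[small].sum() / total), int(small.sum())


def layer_wavelength(c_profile: np.ndarray, dx: float = 1.0,
                     snr_threshold: float = 3.0):
    """Dominant spatial period of a (mean-transverse) composition profile.

    Detrends the profile, locates the strongest FFT peak, and counts bands
    via mean-level crossings.  Returns ``(wavelength, band_count)`` in the
    same units as ``dx``, or ``(None, 0)`` when no periodic component
    stands above the noise floor (peak power < snr_threshold x median
    nonzero-frequency power, or an essentially uniform profile).
    """
    x = np.asarray(c_profile, dtype=float)
    n = len(x)
    if n < 8:
        raise ValueError("profile too short")
    if np.ptp(x) < 1e-12:
        return None, 0
    detrended = x - np.polyval(np.polyfit(np.arange(n), x, 1), np.arange(n))
    power = np.abs(np.fft.rfft(detrended * np.hanning(n))) ** 2
    power[0] = 0.0
    k = int(np.argmax(power))
    noise = np.median(power[1:][power[1:] > 0]) if (power[1:] > 0).any() else 0.0
    if k == 0 or (noise > 0 and power[k] < snr_threshold * noise):
        return None, 0
    wavelength = n * dx / k
    centered = detrended - detrended.mean()
    crossings = np.count_nonzero(np.diff(np.sign(centered)) != 0)
    return float(wavelength), int(max(crossings // 2, 0))


def measure_contact_angle(phi: np.ndarray, level: float = 0.5,
                          fit_rows: int = 12) -> float:
    """Contact angle (degrees) of a sessile solid drop on the bottom wall.

    Extracts the right-hand phi = level contour x(y) per row (rightmost
    crossing), fits a quadratic in the first ``fit_rows`` rows above the
    wall, and evaluates the tangent at y = 0; the angle is measured through
    the drop (solid on the left).  The quadratic absorbs the drop's surface
    curvature, which a straight-line fit would fold into the angle.
    """
    ny, nx = phi.shape
    xs, ys = [], []
    for j in range(min(fit_rows, ny)):
        row = phi[j]
        above = row > level
        if not above.any():
            continue
        i = int(np.max(np.nonzero(above)[0]))
        if i + 1 >= nx:
            continue
        f = (row[i] - level) / max(row[i] - row[i + 1], 1e-30)
        xs.append(i + 0.5 + f)
        ys.append(j + 0.5)
    if len(xs) < 6:
        raise ValueError("too few contour points for the tangent fit")
    coef = np.polyfit(np.asarray(ys), np.asarray(xs), 2)
    return float(90.0 + np.degrees(np.arctan(coef[1])))


def orientation_diversity_profile(theta: np.ndarray, phi: np.ndarray,
                                  labels: np.ndarray | None = None,
                                  solid_level: float = 0.5) -> np.ndarray:
    """Per-row count of distinct grains (orientation diversity vs height).

    Rows without solid cells report 0.  Uses a provided grain labeling or
    computes one with defaults; competitive (columnar) growth shows up as a
    decreasing profile.
    """
    if labels is None:
        labels = segment_grains(theta, phi, solid_level=solid_level).labels
    out = np.zeros(theta.shape[0], dtype=np.int64)
    for j in range(theta.shape[0]):
        row = labels[j]
        out[j] = len(np.unique(row[row > 0]))
    return out
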