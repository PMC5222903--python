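"""Dense hill-of-vision surfaces and total-variation smoothness metrics.

An examination is interpolated onto a uniform N x N lattice spanning +/-90
degrees (default N = 501, spacing 0.36 deg).  Before interpolation the data
are augmented with 72 zero-dB boundary points on a 120-deg circle so the
surface decays outside the measured field.  Smoothness is summarized by the
first- and second-order isotropic total variation

    TV1(h) = sqrt( mean_{(i,j) in Omega} |grad_x h|^2 + |grad_y h|^2 )
    TV2(h) = sqrt( mean_{(i,j) in Omega} |grad_xx h|^2 + |grad_yy h|^2 )

over the mask Omega of lattice points inside the convex hull of the original
(non-augmented) test grid.  The finite differences use forward/central
stencils with wrap-around at the last index; because the default hull
half-width (~67.5 deg) is well inside the +/-90 deg lattice, the wrapped
cells never intersect Omega and the convention is inert in practice.

Matrix orientation: values[i, j] is the surface at (x_i, y_j), i.e. axis 0
indexes x ascending and axis 1 indexes y ascending.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay

from .exceptions import InsufficientDataError
from .interpolate import InterpolatorSpec, fit

__all__ = [
    "DenseSurface",
    "SmoothnessMetrics",
    "augment_boundary",
    "dense_resample",
    "fdiff_first",
    "fdiff_second",
    "tv1",
    "tv2",
    "compute_smoothness",
]

log = logging.getLogger(__name__)


@dataclass
class DenseSurface:
    """Interpolated hill of vision on a uniform lattice."""

    values: np.ndarray   # (Nx, Ny) dB, [i, j] = h(x_i, y_j)
    extent: float        # half-width: lattice spans [-extent, +extent] each axis
    spacing: float       # lattice step, degrees
    mask: np.ndarray     # (Nx, Ny) bool, True inside the test-grid hull
    method: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def axis(self) -> np.ndarray:
        return np.linspace(-self.extent, self.extent, self.values.shape[0])


@dataclass(frozen=True)
class SmoothnessMetrics:
    tv1: float  # dB per cell
    tv2: float  # dB per cell^2


def augment_boundary(
    points, n_boundary: int = 72, radius: float = 120.0, value: float = 0.0
) -> np.ndarray:
    """Append zero-sensitivity boundary points on a peripheral circle.

    ``n_boundary`` points are placed counterclockwise at equal angular
    spacing starting at angle 0, each at ``radius`` degrees from the origin
    with sensitivity ``value``.  A boundary point that coincides with a data
    point is shifted by half an angular step (logged).
    """
    pts = np.asarray(points, dtype=float)
    ecc = np.hypot(pts[:, 0], pts[:, 1])
    if radius < ecc.max():
        raise ValueError("boundary radius must cover the grid's max eccentricity")
    step = 2.0 * np.pi / n_boundary
    theta = np.arange(n_boundary) * step
    ring = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.full(n_boundary, value)]
    )
    # collision with existing data: shift the offending point by half a step
    d = np.hypot(
        ring[:, None, 0] - pts[None, :, 0], ring[:, None, 1] - pts[None, :, 1]
    )
    clash = np.nonzero(d.min(axis=1) < 1e-9)[0]
    for i in clash:
        t = theta[i] + 0.5 * step
        ring[i, 0] = radius * np.cos(t)
        ring[i, 1] = radius * np.sin(t)
        log.info("boundary point %d coincided with a data point; shifted by half a step", i)
    return np.vstack([pts, ring])


def dense_resample(
    spec: InterpolatorSpec,
    points,
    n: int = 501,
    extent: float = 90.0,
    hull_points=None,
) -> DenseSurface:
    """Interpolate (augmented) examination points onto the uniform lattice.

    ``hull_points`` are the original (non-augmented) test-grid locations
    defining the mask Omega; they default to the x, y of ``points`` (pass the
    bare grid when interpolating boundary-augmented data).
    """
    pts = np.asarray(points, dtype=float)
    model = fit(spec, pts)
    ax = np.linspace(-extent, extent, n)
    X, Y = np.meshgrid(ax, ax, indexing="ij")  # [i, j] -> (x_i, y_j)
    queries = np.column_stack([X.ravel(), Y.ravel()])
    values = model.predict(queries).reshape(n, n)
    hp = np.asarray(hull_points, dtype=float) if hull_points is not None else pts[:, :2]
    mask = Delaunay(hp).find_simplex(queries).reshape(n, n) >= 0
    return DenseSurface(
        values=values,
        extent=extent,
        spacing=2.0 * extent / (n - 1),
        mask=mask,
        method=spec.method,
    )


def _as_values(surface) -> np.ndarray:
    return surface.values if isinstance(surface, DenseSurface) else np.asarray(surface, float)


def fdiff_first(surface) -> tuple[np.ndarray, np.ndarray]:
    """Forward first differences with wrap-around at the last index."""
    h = _as_values(surface)
    gx = np.roll(h, -1, axis=0) - h  # at i = Nx: h[0, j] - h[Nx-1, j]
    gy = np.roll(h, -1, axis=1) - h
    return gx, gy


def fdiff_second(surface) -> tuple[np.ndarray, np.ndarray]:
    """Central second differences with wrap-around at both ends."""
    h = _as_values(surface)
    gxx = np.roll(h, 1, axis=0) - 2.0 * h + np.roll(h, -1, axis=0)
    gyy = np.roll(h, 1, axis=1) - 2.0 * h + np.roll(h, -1, axis=1)
    return gxx, gyy


def _masked_rms(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None) -> float:
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    if not mask.any():
        raise InsufficientDataError("empty mask Omega")
    return float(np.sqrt(np.mean(a[mask] ** 2 + b[mask] ** 2)))


def tv1(surface, mask=None) -> float:
    """First-order isotropic total variation over the mask (dB per cell)."""
    h = _as_values(surface)
    if mask is None and isinstance(surface, DenseSurface):
        mask = surface.mask
    gx, gy = fdiff_first(h)
    return _masked_rms(gx, gy, mask)


def tv2(surface, mask=None) -> float:
    """Second-order isotropic total variation over the mask (dB per cell^2)."""
    h = _as_values(surface)
    if mask is None and isinstance(surface, DenseSurface):
        mask = surface.mask
    gxx, gyy = fdiff_second(h)
    return _masked_rms(gxx, gyy, mask)


def compute_smoothness(surface: DenseSurface) -> SmoothnessMetrics:
    return SmoothnessMetrics(tv1=tv1(surface), tv2=tv2(surface))
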