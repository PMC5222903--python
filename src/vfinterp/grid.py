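"""Perimetric test-grid geometry.

The default grid emulates a full-field static perimetry pattern: 164 test
locations arranged on radial spokes over concentric (elliptical) rings,
binocularly symmetric, centrally condensed, spanning 135 deg horizontally and
125 deg vertically.  Coordinates are visual-field degrees with x positive
toward the subject's right and y positive superior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from functools import cached_property
from typing import Sequence

import numpy as np
from scipy.spatial import Delaunay, QhullError
from scipy.spatial.distance import pdist
from shapely.geometry import Polygon

from .exceptions import (
    DegenerateGeometryError,
    GridConstructionError,
    InsufficientDataError,
)

__all__ = [
    "Eye",
    "TestGrid",
    "BlindSpotSpec",
    "generate_test_grid",
    "delaunay",
    "voronoi_cells",
    "mean_pairwise_separation",
    "blind_spot_filter",
]

#: geometric tolerance for collinearity / duplicate detection (deg^2)
GEOM_TOL = 1e-9

#: Frozen default ring layout: (ring radius along x in degrees, point count).
#: Counts are even (mirror symmetry) and the outermost count is divisible by 4
#: so the ring places points on both axes, pinning the 135 x 125 deg extents
#: exactly (y is compressed by 125/135).  Radii grow super-linearly to give
#: the central condensation typical of radial perimetry grids.
DEFAULT_RING_LAYOUT: tuple[tuple[float, int], ...] = (
    (2.0, 4),
    (5.0, 8),
    (8.0, 10),
    (12.0, 12),
    (17.0, 14),
    (24.0, 18),
    (32.0, 22),
    (42.0, 24),
    (54.0, 28),
    (67.5, 24),
)

#: vertical compression factor: 125 deg vertical extent over 135 horizontal
Y_SCALE = 125.0 / 135.0


class Eye(str, Enum):
    """Laterality: OD = right eye, OS = left eye."""

    OD = "OD"
    OS = "OS"


@dataclass(frozen=True)
class BlindSpotSpec:
    """Anatomical exclusion region around the optic-disc projection.

    The physiologic blind spot sits ~15 deg temporal and slightly inferior.
    Temporal means +x for OD and -x for OS, so the OS center is the mirror
    image of the OD center.
    """

    center_od: tuple[float, float] = (15.0, -1.5)
    exclusion_radius: float = 6.0

    def __post_init__(self) -> None:
        if self.exclusion_radius <= 0:
            raise ValueError("exclusion_radius must be > 0")
        if self.center_od[0] <= 0:
            raise ValueError("OD blind-spot center must have positive x")

    def center(self, eye: Eye) -> tuple[float, float]:
        cx, cy = self.center_od
        return (cx, cy) if Eye(eye) is Eye.OD else (-cx, cy)


def delaunay(locations: np.ndarray) -> np.ndarray:
    """Delaunay triangulation; returns (n_tri, 3) vertex-index triples.

    Raises :class:`DegenerateGeometryError` for <3 points or collinear input.
    """
    pts = np.asarray(locations, dtype=float)
    if len(pts) < 3:
        raise DegenerateGeometryError("need at least 3 points to triangulate")
    try:
        tri = Delaunay(pts)
    except QhullError as exc:  # collinear / duplicate degenerate input
        raise DegenerateGeometryError(f"degenerate point set: {exc}") from exc
    if tri.simplices.size == 0:
        raise DegenerateGeometryError("all points collinear")
    return tri.simplices


def voronoi_cells(
    locations: np.ndarray, clip_polygon: Sequence[tuple[float, float]]
) -> list[Polygon]:
    """Bounded Voronoi cells clipped to a convex polygon.

    Each cell is the intersection of the clip polygon with the half-planes
    toward its Delaunay neighbors, which is exact for a Voronoi tessellation.
    Returns one shapely polygon per input location.
    """
    pts = np.asarray(locations, dtype=float)
    if len(np.unique(np.round(pts / max(GEOM_TOL, 1e-12)), axis=0)) != len(pts):
        raise DegenerateGeometryError("duplicate points in Voronoi input")
    clip = Polygon(clip_polygon)
    tri = Delaunay(pts)
    indptr, indices = tri.vertex_neighbor_vertices
    span = max(clip.bounds[2] - clip.bounds[0], clip.bounds[3] - clip.bounds[1])
    big = 10.0 * span + 10.0
    cells: list[Polygon] = []
    for i, p in enumerate(pts):
        cell = clip
        for j in indices[indptr[i] : indptr[i + 1]]:
            q = pts[j]
            mid = 0.5 * (p + q)
            n = q - p
            n = n / np.hypot(*n)
            t = np.array([-n[1], n[0]])
            half = Polygon(
                [
                    mid + t * big,
                    mid - t * big,
                    mid - t * big - n * big,
                    mid + t * big - n * big,
                ]
            )
            cell = cell.intersection(half)
        cells.append(cell)
    return cells


def mean_pairwise_separation(locations: np.ndarray) -> float:
    """Mean Euclidean distance over all unordered point pairs (degrees)."""
    pts = np.asarray(locations, dtype=float)
    if len(pts) < 2:
        raise InsufficientDataError("need at least 2 points")
    return float(pdist(pts).mean())


@dataclass
class TestGrid:
    """A perimetric sampling pattern with its derived geometry."""

    locations: np.ndarray  # (N, 2) degrees
    eye: Eye

    def __post_init__(self) -> None:
        self.locations = np.asarray(self.locations, dtype=float)
        self.eye = Eye(self.eye)

    @property
    def n_points(self) -> int:
        return len(self.locations)

    @cached_property
    def triangulation(self) -> np.ndarray:
        return delaunay(self.locations)

    @cached_property
    def _delaunay(self) -> Delaunay:
        return Delaunay(self.locations)

    @cached_property
    def hull(self) -> np.ndarray:
        """Convex-hull vertices in counterclockwise order, (m, 2) degrees."""
        from scipy.spatial import ConvexHull

        h = ConvexHull(self.locations)
        return self.locations[h.vertices]

    @cached_property
    def voronoi(self) -> list[Polygon]:
        """Voronoi cells clipped to the convex hull."""
        return voronoi_cells(self.locations, self.hull)

    def mean_separation(self) -> float:
        return mean_pairwise_separation(self.locations)

    def contains(self, queries: np.ndarray) -> np.ndarray:
        """Closed-hull membership for an array of (x, y) queries."""
        q = np.atleast_2d(np.asarray(queries, dtype=float))
        return self._delaunay.find_simplex(q) >= 0

    def mirrored(self) -> "TestGrid":
        other = Eye.OS if self.eye is Eye.OD else Eye.OD
        loc = self.locations.copy()
        loc[:, 0] *= -1.0
        return TestGrid(loc, other)


def generate_test_grid(eye: Eye | str = Eye.OD, n_points: int = 164) -> TestGrid:
    """Construct the default radial perimetry grid.

    Deterministic: points lie on concentric elliptical rings (y compressed by
    125/135) at equally spaced spoke angles starting at 0 deg.  The default
    164-point layout is frozen; other sizes are built by proportionally
    rescaling the ring point counts while keeping every count even (so the
    pattern stays mirror-symmetric).
    """
    eye = Eye(eye)
    if n_points < 4:
        raise GridConstructionError("need at least 4 points for a symmetric grid")
    if n_points % 2:
        raise GridConstructionError("n_points must be even for mirror symmetry")

    if n_points == 164:
        layout = DEFAULT_RING_LAYOUT
    else:
        layout = _rescale_layout(n_points)

    pts = []
    for radius, count in layout:
        # build the closed upper half-ring and reflect it, so (x, y)/(x, -y)
        # pairs are bitwise identical in x (exact mirror determinism)
        theta = np.arange(count // 2 + 1) * (2.0 * np.pi / count)
        upper = np.column_stack([radius * np.cos(theta), radius * np.sin(theta) * Y_SCALE])
        lower = upper[1:-1].copy()
        lower[:, 1] *= -1.0
        pts.append(np.vstack([upper, lower]))
    locations = np.vstack(pts)
    # exact mirror symmetry: snap tiny trig residue so x -> -x is bitwise clean
    locations[np.abs(locations) < 1e-12] = 0.0
    if eye is Eye.OS:
        locations[:, 0] *= -1.0
    return TestGrid(locations, eye)


def _rescale_layout(n_points: int) -> tuple[tuple[float, int], ...]:
    """Scale the default ring counts to an arbitrary even total >= 4."""
    base = np.array([c for _, c in DEFAULT_RING_LAYOUT], dtype=float)
    radii = [r for r, _ in DEFAULT_RING_LAYOUT]
    frac = base / base.sum()
    counts = np.maximum(2, 2 * np.round(frac * n_points / 2.0)).astype(int)
    rings = min(len(radii), max(1, n_points // 4))
    counts, radii = counts[-rings:], radii[-rings:]
    # adjust outermost rings by +-2 until the total matches exactly
    i = len(counts) - 1
    while counts.sum() != n_points:
        step = 2 if counts.sum() < n_points else -2
        if counts[i] + step >= 2:
            counts[i] += step
        i = (i - 1) % len(counts)
    return tuple((r, int(c)) for r, c in zip(radii, counts))


def blind_spot_filter(exam, spec: BlindSpotSpec):
    """Split an examination's points into kept and blind-spot-excluded.

    Returns ``(filtered_exam, excluded_indices)`` where the filtered
    examination drops every point within ``spec.exclusion_radius`` of the
    eye-appropriate blind-spot center.
    """
    center = np.asarray(spec.center(exam.eye))
    d = np.hypot(*(exam.locations - center).T)
    excluded = np.nonzero(d <= spec.exclusion_radius)[0]
    kept = np.nonzero(d > spec.exclusion_radius)[0]
    return exam.subset(kept), excluded


def blind_spot_mask(locations: np.ndarray, eye: Eye | str, spec: BlindSpotSpec) -> np.ndarray:
    """Boolean mask, True where a location is OUTSIDE the blind-spot region."""
    center = np.asarray(spec.center(Eye(eye)))
    d = np.hypot(*(np.asarray(locations, float) - center).T)
    return d > spec.exclusion_radius
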