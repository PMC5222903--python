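"""Sibson natural-neighbor interpolation.

Weights are the Voronoi areas a query point "steals" from its neighbors when
inserted into the tessellation.  Rather than rebuilding polygons per query,
the stolen areas are accumulated per Bowyer-Watson cavity triangle: inserting
q destroys every triangle whose circumcircle contains q, and within each such
triangle (a, b, c) the area q takes from vertex a is the signed area of the
triangle formed by circumcenter(q, a, b), the destroyed triangle's
circumcenter, and circumcenter(q, a, c).  Summed over the cavity this equals
the exact area-stealing decomposition (verified against a half-plane
construction in the test suite).

Sibson weights are nonnegative, sum to 1, and give the interpolant linear
precision and C1 continuity away from the data sites.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import Delaunay

__all__ = ["NaturalNeighborInterpolator", "sibson_weights"]

_EPS = 1e-12


def _circumcenters(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Vectorized circumcenters of triangles given as (n,2) vertex arrays.

    Degenerate (collinear) triples yield non-finite rows; callers detect and
    retry under a perturbation.
    """
    d = 2.0 * (
        a[:, 0] * (b[:, 1] - c[:, 1])
        + b[:, 0] * (c[:, 1] - a[:, 1])
        + c[:, 0] * (a[:, 1] - b[:, 1])
    )
    a2 = (a * a).sum(1)
    b2 = (b * b).sum(1)
    c2 = (c * c).sum(1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ux = (a2 * (b[:, 1] - c[:, 1]) + b2 * (c[:, 1] - a[:, 1]) + c2 * (a[:, 1] - b[:, 1])) / d
        uy = (a2 * (c[:, 0] - b[:, 0]) + b2 * (a[:, 0] - c[:, 0]) + c2 * (b[:, 0] - a[:, 0])) / d
    return np.column_stack([ux, uy])


def _circumcenter_q(q: np.ndarray, p: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Circumcenters of (q, p_i, r_i) for a fixed q and (n,2) arrays p, r."""
    qq = np.broadcast_to(q, p.shape)
    return _circumcenters(qq, p, r)


class NaturalNeighborInterpolator:
    """Fit once on scattered (x, y, z); evaluate Sibson weights per query."""

    def __init__(self, points: np.ndarray, values: np.ndarray):
        self.points = np.asarray(points, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self.tri = Delaunay(self.points)
        simp = self.tri.simplices
        a, b, c = (self.points[simp[:, k]] for k in range(3))
        # enforce CCW orientation per simplex for consistent signed areas
        cross = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (
            c[:, 0] - a[:, 0]
        )
        flip = cross < 0
        simp = simp.copy()
        simp[flip] = simp[flip][:, [0, 2, 1]]
        self.simplices = simp
        a, b, c = (self.points[simp[:, k]] for k in range(3))
        self.centers = _circumcenters(a, b, c)
        self.radii2 = ((a - self.centers) ** 2).sum(1)
        from scipy.spatial import cKDTree

        self._tree = cKDTree(self.points)
        ptp = np.ptp(self.points, axis=0)
        self._scale = float(max(ptp[0], ptp[1]) / 240.0)  # ~1 on a perimetric grid

    def weights(self, q: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
        """Sibson weights at a single query.

        Returns ``(indices, weights)`` or ``None`` when q falls outside the
        convex hull of the data.  A query within ``1e-9`` deg of a data site
        returns that site with weight 1 (the interpolant's exact limit).

        Queries exactly collinear with a data-point pair (common on
        structured grids) make a circumcenter degenerate; such queries are
        retried under a deterministic sub-1e-6-deg perturbation, which
        changes a C1 interpolant by far less than the measurement scale.
        """
        q = np.asarray(q, dtype=float)
        d2 = ((self.points - q) ** 2).sum(1)
        hit = int(np.argmin(d2))
        if d2[hit] < 1e-18:
            return np.array([hit]), np.array([1.0])
        for shift in ((0.0, 0.0), (8.3e-8, 5.1e-8), (-6.1e-7, 9.7e-7)):
            qs = q + np.asarray(shift)
            res = self._weights_at(qs, int(self.tri.find_simplex(qs[None, :])[0]))
            if res is not None and np.isfinite(res[1]).all():
                return res
        return None  # outside hull (or irrecoverably degenerate)

    def _weights_at(self, q: np.ndarray, containing: int) -> tuple[np.ndarray, np.ndarray] | None:
        if containing < 0:
            return None
        qd2 = ((q - self.centers) ** 2).sum(1)
        cavity = np.nonzero(qd2 < self.radii2 * (1.0 - _EPS))[0]
        if containing not in cavity:
            cavity = np.append(cavity, containing)

        simp = self.simplices[cavity].T  # (3, m): row k = k-th vertex per triangle
        centers = self.centers[cavity]
        # per cavity triangle, per vertex: stolen-area contribution.  The
        # three vertex rotations are stacked into single vectorized calls.
        P = self.points
        vi = simp.ravel()
        vj = simp[[1, 2, 0]].ravel()
        vk = simp[[2, 0, 1]].ravel()

        def accumulate(Pd, qd, cen):
            cij = _circumcenter_q(qd, Pd[vi], Pd[vj])
            cik = _circumcenter_q(qd, Pd[vi], Pd[vk])
            cen3 = np.tile(cen, (3, 1))
            u = cen3 - cij
            v = cik - cij
            area = 0.5 * (u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])
            mag = float(max(np.abs(cij).max(initial=0.0), np.abs(cik).max(initial=0.0)))
            return np.bincount(vi, weights=area.astype(float), minlength=len(Pd)), mag

        contrib, mag = accumulate(P, q, centers)
        # double-precision area error ~ mag^2 * eps; 3e5 keeps it below 1e-5
        # of a typical cell area on a degree-scaled grid
        if not np.isfinite(mag) or mag > 3e5 * max(self._scale, 1.0):
            # q nearly collinear with a point pair: the huge circumcenters
            # cancel catastrophically in double precision; redo in extended
            # precision where the residual error is negligible
            contrib2, mag2 = accumulate(
                P.astype(np.longdouble), q.astype(np.longdouble),
                centers.astype(np.longdouble),
            )
            if np.isfinite(mag2):
                contrib = contrib2
        total = contrib.sum()
        if not np.isfinite(total) or total <= 0:  # degenerate (e.g. collinear/cocircular)
            # fall back to barycentric weights in the containing simplex
            s = self.tri.simplices[containing]
            T = self.tri.transform[containing]
            bary = T[:2] @ (q - T[2])
            w = np.append(bary, 1.0 - bary.sum())
            return s, np.clip(w, 0.0, None) / max(np.clip(w, 0.0, None).sum(), _EPS)
        if not np.isfinite(contrib).all():
            return np.arange(1), np.array([np.nan])  # caller retries perturbed
        idx = np.nonzero(np.abs(contrib) > 1e-14 * abs(total))[0]
        w = np.clip(contrib[idx], 0.0, None)
        return idx, w / w.sum()

    def __call__(self, queries: np.ndarray) -> np.ndarray:
        """Interpolate at (m, 2) queries; NaN outside the convex hull."""
        qs = np.atleast_2d(np.asarray(queries, dtype=float))
        out = np.full(len(qs), np.nan)
        simplex = self.tri.find_simplex(qs)  # batched hull/containment test
        dmin, nearest = self._tree.query(qs)
        for i, q in enumerate(qs):
            if dmin[i] < 1e-9:
                out[i] = self.values[nearest[i]]
                continue
            if simplex[i] < 0:
                continue
            res = self._weights_at(q, int(simplex[i]))
            if res is None or not np.isfinite(res[1]).all():
                res = self.weights(q)  # perturbation retry path
            if res is not None:
                idx, w = res
                out[i] = float(w @ self.values[idx])
        return out


def sibson_weights(points: np.ndarray, q: np.ndarray):
    """One-shot Sibson weights of q among ``points`` (None outside hull)."""
    interp = NaturalNeighborInterpolator(points, np.zeros(len(points)))
    return interp.weights(np.asarray(q, dtype=float))
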