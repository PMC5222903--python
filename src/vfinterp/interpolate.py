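"""The nine scattered-data interpolators.

All methods are pure interpolators: they reproduce the training data exactly
at the training sites.  Methods and their fixed parameters:

======  =====================================================================
NN      nearest neighbor (ties broken by lowest training index)
Lin     barycentric linear over the Delaunay triangulation
Cub     C1 Clough-Tocher piecewise cubic over the Delaunay triangulation
NatN    Sibson natural neighbor (Voronoi area stealing)
IDW     Shepard inverse distance weighting, power 2, all points
IDW2    localized Shepard: only points within a cutoff radius (default: the
        mean pairwise separation of the training locations)
RBFlin  radial basis function with linear kernel phi(r) = r, unaugmented
RBFtps  thin-plate spline phi(r) = r^2 log r with affine augmentation
Krig    ordinary Kriging with an exponential semivariogram fitted per data set
======  =====================================================================

Lin/Cub/NatN are undefined outside the training convex hull; such queries are
resolved by the spec's ``fallback`` ("nearest" substitutes the nearest
training value and is flagged, "missing" yields NaN).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import linalg
from scipy.interpolate import CloughTocher2DInterpolator, LinearNDInterpolator
from scipy.optimize import curve_fit
from scipy.spatial import Delaunay, QhullError
from scipy.spatial.distance import cdist, pdist

from .exceptions import (
    DegenerateGeometryError,
    InsufficientDataError,
    InsufficientStructureError,
    SolverFailureError,
)
from .grid import mean_pairwise_separation
from .natural import NaturalNeighborInterpolator

__all__ = [
    "METHODS",
    "InterpolatorSpec",
    "FittedInterpolator",
    "fit",
    "rbf_kernel",
    "idw2_neighborhood",
    "empirical_semivariogram",
    "fit_exponential_variogram",
    "exponential_variogram",
    "ordinary_kriging_predict",
    "VariogramFit",
]

METHODS: tuple[str, ...] = (
    "NN", "Lin", "Cub", "NatN", "IDW", "IDW2", "RBFlin", "RBFtps", "Krig",
)

_TRIANGULATED = {"Lin", "Cub", "NatN"}
_COINCIDENT_TOL = 1e-9  # deg: query treated as sitting on a training site
_JITTER = 1e-10
_RESID_TOL = 1e-6


@dataclass(frozen=True)
class InterpolatorSpec:
    """Method selector plus the fixed, standardized parameters."""

    method: str
    idw_power: float = 2.0
    idw2_radius: float | None = None  # None -> mean pairwise separation
    kriging_model: str = "exponential"
    fallback: Literal["nearest", "missing"] = "nearest"
    rbf_augment: bool | None = None  # None -> kernel default (tps yes, lin no)
    variogram_bins: int = 12
    #: "zero" fixes the Kriging nugget at 0 so the predictor is a pure
    #: interpolator (an exponential covariance has no nugget term); "fit"
    #: estimates it, which turns Kriging into a noise-filtering smoother
    krig_nugget: Literal["zero", "fit"] = "zero"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.idw_power <= 0:
            raise ValueError("idw_power must be > 0")
        if self.idw2_radius is not None and self.idw2_radius <= 0:
            raise ValueError("idw2_radius must be > 0")
        if self.kriging_model != "exponential":
            raise ValueError("only the exponential variogram model is supported")


def rbf_kernel(kind: Literal["linear", "tps"], r) -> np.ndarray | float:
    """RBF kernels: linear phi(r) = r; thin-plate spline phi(r) = r^2 log r.

    The thin-plate value at r = 0 is the limit 0.  Negative radii raise.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(arr < 0):
        raise ValueError("kernel radius must be nonnegative")
    if kind == "linear":
        out = arr.copy()
    elif kind == "tps":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(arr > 0, arr * arr * np.log(np.where(arr > 0, arr, 1.0)), 0.0)
    else:
        raise ValueError(f"unknown kernel {kind!r}")
    return out if out.ndim else float(out)


@dataclass
class VariogramFit:
    """Exponential semivariogram gamma(h) = nugget + (sill-nugget)(1-e^{-h/range})."""

    nugget: float
    sill: float
    range_: float
    fallback: bool = False  # True when the documented fallback path was taken

    def __call__(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        psill = self.sill - self.nugget
        g = self.nugget + psill * (1.0 - np.exp(-h / max(self.range_, 1e-12)))
        return np.where(h > 0, g, 0.0)


def exponential_variogram(h, nugget: float, sill: float, range_: float):
    """Model curve used for fitting (gamma at h > 0; gamma(0) = 0)."""
    return VariogramFit(nugget, sill, range_)(h)


def empirical_semivariogram(points, n_bins: int = 12):
    """Binned empirical semivariogram of an (x, y, z) point set.

    Equal-width lag bins span (0, max_distance/2]; each bin reports the mean
    lag of its pairs, gamma = half the mean squared value difference, and the
    pair count.  Empty bins are omitted.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise InsufficientDataError("need at least 2 points")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    lags = pdist(pts[:, :2])
    if np.ptp(lags) < 1e-12 and len(np.unique(np.round(lags, 9))) == 1 and len(lags) > 1:
        raise InsufficientStructureError("all pairwise lags identical")
    sqdiff = 0.5 * pdist(pts[:, 2:3], metric="sqeuclidean")
    hmax = lags.max() / 2.0
    edges = np.linspace(0.0, hmax, n_bins + 1)
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (lags > lo) & (lags <= hi)
        if not sel.any():
            continue
        out.append((float(lags[sel].mean()), float(sqdiff[sel].mean()), int(sel.sum())))
    return out


def fit_exponential_variogram(
    empirical,
    sample_variance: float | None = None,
    fix_nugget_zero: bool = False,
) -> VariogramFit:
    """Weighted least-squares fit of the exponential model to binned gamma.

    Weights are the bin pair counts.  Constraints: nugget >= 0,
    sill >= nugget, range > 0.  ``fix_nugget_zero`` pins the nugget at 0
    (the pure-interpolation convention for Kriging).  If fewer than 3 usable
    bins exist or the optimizer fails, the documented fallback is returned
    and flagged: nugget 0, sill = sample variance (or the count-weighted
    mean gamma when no variance is supplied), range = mean lag / 3.
    """
    emp = [(float(h), float(g), int(c)) for h, g, c in empirical]
    lag = np.array([e[0] for e in emp])
    gam = np.array([e[1] for e in emp])
    cnt = np.array([e[2] for e in emp], dtype=float)

    def _fallback() -> VariogramFit:
        sill = sample_variance if sample_variance is not None else (
            float((gam * cnt).sum() / cnt.sum()) if len(gam) else 0.0
        )
        rng = float(lag.mean() / 3.0) if len(lag) else 1.0
        return VariogramFit(0.0, max(sill, 0.0), max(rng, 1e-6), fallback=True)

    if len(emp) < 3:
        return _fallback()

    gmax = max(gam.max(), 1e-12)

    if fix_nugget_zero:
        def model(h, psill, rng):
            return psill * (1.0 - np.exp(-h / rng))

        p0 = (gmax, max(lag.max() / 3.0, 1e-3))
        bounds = ([0.0, 1e-6], [np.inf, np.inf])
    else:
        def model(h, nugget, psill, rng):
            return nugget + psill * (1.0 - np.exp(-h / rng))

        p0 = (
            max(min(gam[0], gmax / 2), 0.0),
            max(gmax - gam[0], gmax / 10),
            max(lag.max() / 3.0, 1e-3),
        )
        bounds = ([0.0, 0.0, 1e-6], [np.inf, np.inf, np.inf])
    try:
        popt, _ = curve_fit(
            model, lag, gam, p0=p0,
            sigma=1.0 / np.sqrt(cnt), absolute_sigma=False,
            bounds=bounds, maxfev=20000,
        )
    except (RuntimeError, ValueError):
        return _fallback()
    if fix_nugget_zero:
        psill, rng = map(float, popt)
        return VariogramFit(0.0, psill, rng, fallback=False)
    nugget, psill, rng = map(float, popt)
    return VariogramFit(nugget, nugget + psill, rng, fallback=False)


@dataclass
class FittedInterpolator:
    """A trained interpolator; call :meth:`predict` on (x, y) queries."""

    spec: InterpolatorSpec
    xy: np.ndarray          # (N, 2) training locations, degrees
    z: np.ndarray           # (N,) training sensitivities, dB
    state: dict = field(default_factory=dict, repr=False)

    # -- queries ----------------------------------------------------------
    def predict(self, queries) -> np.ndarray:
        values, _ = self.predict_flagged(queries)
        return values

    def predict_flagged(self, queries) -> tuple[np.ndarray, np.ndarray]:
        """Predictions plus a boolean mask of fallback-resolved queries."""
        q = np.asarray(queries, dtype=float)
        if q.size == 0:
            return np.empty(0), np.zeros(0, dtype=bool)
        q = np.atleast_2d(q)
        method = self.spec.method
        fb = np.zeros(len(q), dtype=bool)

        if method == "NN":
            values = self.z[self._nearest_index(q)]
        elif method in ("Lin", "Cub"):
            values = np.asarray(self.state["interp"](q), dtype=float)
        elif method == "NatN":
            values = self.state["interp"](q)
        elif method in ("IDW", "IDW2"):
            values, fb = self._shepard(q)
        elif method in ("RBFlin", "RBFtps"):
            values = self._rbf_eval(q)
        elif method == "Krig":
            values = self._krig_eval(q)
        else:  # pragma: no cover
            raise AssertionError(method)

        missing = ~np.isfinite(values)
        if missing.any():
            fb = fb | missing
            if self.spec.fallback == "nearest":
                nn = self._nearest_index(q[missing])
                values = values.copy()
                values[missing] = self.z[nn]
        return values, fb

    # -- method internals -------------------------------------------------
    def _nearest_index(self, q: np.ndarray) -> np.ndarray:
        d2 = cdist(q, self.xy, metric="sqeuclidean")
        return np.argmin(d2, axis=1)  # first minimum -> lowest-index tie-break

    def _shepard(self, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = cdist(q, self.xy)
        exact_row, exact_col = np.nonzero(d < _COINCIDENT_TOL)
        with np.errstate(divide="ignore"):
            w = d ** (-self.spec.idw_power)
        fb = np.zeros(len(q), dtype=bool)
        if self.spec.method == "IDW2":
            radius = self.state["idw2_radius"]
            w = np.where(d <= radius, w, 0.0)
            empty = ~(w.sum(axis=1) > 0)
            if empty.any():
                # no point within the cutoff: fall back to the nearest point
                fb |= empty
                nn = self._nearest_index(q[empty])
                w[empty] = 0.0
                w[np.nonzero(empty)[0], nn] = 1.0
        w[~np.isfinite(w)] = 0.0
        values = (w @ self.z) / w.sum(axis=1)
        values[exact_row] = self.z[exact_col]  # removable singularity
        fb[exact_row] = False
        return values, fb

    def _rbf_eval(self, q: np.ndarray) -> np.ndarray:
        kind = self.state["kernel"]
        K = rbf_kernel(kind, cdist(q, self.xy))
        values = K @ self.state["weights"]
        if self.state["augmented"]:
            a = self.state["poly_coef"]
            values = values + a[0] + q @ a[1:]
        return values

    def _krig_eval(self, q: np.ndarray) -> np.ndarray:
        gamma: VariogramFit = self.state["variogram"]
        n = len(self.xy)
        d = cdist(q, self.xy)
        B = np.empty((n + 1, len(q)))
        B[:n] = gamma(d).T
        B[n] = 1.0
        sol = linalg.lu_solve(self.state["lu"], B)
        values = sol[:n].T @ self.z
        # pure-interpolation convention: coincident queries return the datum
        # even when the fitted nugget is positive
        exact_row, exact_col = np.nonzero(d < _COINCIDENT_TOL)
        values[exact_row] = self.z[exact_col]
        return values

    def kriging_weights(self, query) -> np.ndarray:
        """Ordinary-Kriging weights (sum to 1) for a single query."""
        if self.spec.method != "Krig":
            raise ValueError("kriging_weights requires a Krig model")
        q = np.atleast_2d(np.asarray(query, dtype=float))
        gamma: VariogramFit = self.state["variogram"]
        n = len(self.xy)
        b = np.empty(n + 1)
        b[:n] = gamma(cdist(q, self.xy)[0])
        b[n] = 1.0
        return linalg.lu_solve(self.state["lu"], b)[:n]


def fit(spec: InterpolatorSpec, points) -> FittedInterpolator:
    """Train an interpolator on (x, y, z) triplets."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (N, 3) triplets of (x, y, z)")
    xy, z = pts[:, :2], pts[:, 2]
    if len(np.unique(np.round(xy / 1e-9), axis=0)) != len(xy):
        raise DegenerateGeometryError("duplicate training locations")
    method = spec.method
    if method in _TRIANGULATED:
        if len(xy) < 3:
            raise InsufficientDataError(f"{method} needs >= 3 points")
    elif len(xy) < 2:
        raise InsufficientDataError(f"{method} needs >= 2 points")

    state: dict = {}
    if method in ("Lin", "Cub", "NatN"):
        try:
            tri = Delaunay(xy)
        except QhullError as exc:
            raise DegenerateGeometryError(f"{method}: degenerate geometry: {exc}") from exc
        if tri.simplices.size == 0:
            raise DegenerateGeometryError(f"{method}: collinear training points")
        if method == "Lin":
            state["interp"] = LinearNDInterpolator(tri, z)
        elif method == "Cub":
            state["interp"] = CloughTocher2DInterpolator(tri, z)
        else:
            state["interp"] = NaturalNeighborInterpolator(xy, z)
    elif method == "IDW2":
        state["idw2_radius"] = (
            spec.idw2_radius if spec.idw2_radius is not None
            else mean_pairwise_separation(xy)
        )
    elif method in ("RBFlin", "RBFtps"):
        state.update(_fit_rbf(spec, xy, z))
    elif method == "Krig":
        state.update(_fit_kriging(spec, xy, z))

    return FittedInterpolator(spec=spec, xy=xy, z=z, state=state)


def _solve_with_jitter(A: np.ndarray, b: np.ndarray, method: str) -> np.ndarray:
    """Dense solve with one diagonal-jitter retry; validates the residual."""
    for jitter in (0.0, _JITTER):
        M = A if jitter == 0.0 else A + jitter * np.eye(len(A))
        try:
            x = linalg.solve(M, b)
        except linalg.LinAlgError:
            continue
        resid = np.linalg.norm(A @ x - b)
        scale = max(np.linalg.norm(b), 1.0)
        if np.isfinite(x).all() and resid / scale < _RESID_TOL:
            return x
    raise SolverFailureError(f"{method}: linear system singular after regularization")


def _fit_rbf(spec: InterpolatorSpec, xy: np.ndarray, z: np.ndarray) -> dict:
    kind = "linear" if spec.method == "RBFlin" else "tps"
    augment = spec.rbf_augment if spec.rbf_augment is not None else (kind == "tps")
    K = rbf_kernel(kind, cdist(xy, xy))
    n = len(xy)
    if augment:
        # affine augmentation with orthogonality side conditions; required for
        # the conditionally positive definite (order 2) thin-plate kernel
        P = np.column_stack([np.ones(n), xy])
        A = np.zeros((n + 3, n + 3))
        A[:n, :n] = K
        A[:n, n:] = P
        A[n:, :n] = P.T
        b = np.concatenate([z, np.zeros(3)])
        sol = _solve_with_jitter(A, b, spec.method)
        return {"kernel": kind, "weights": sol[:n], "poly_coef": sol[n:], "augmented": True}
    sol = _solve_with_jitter(K, z, spec.method)
    return {"kernel": kind, "weights": sol, "poly_coef": None, "augmented": False}


def _fit_kriging(spec: InterpolatorSpec, xy: np.ndarray, z: np.ndarray) -> dict:
    pts = np.column_stack([xy, z])
    if len(xy) >= 10:
        try:
            emp = empirical_semivariogram(pts, n_bins=spec.variogram_bins)
            gamma = fit_exponential_variogram(
                emp,
                sample_variance=float(np.var(z)),
                fix_nugget_zero=spec.krig_nugget == "zero",
            )
        except InsufficientStructureError:
            gamma = VariogramFit(0.0, float(np.var(z)), 1.0, fallback=True)
    else:
        lags = pdist(xy)
        gamma = VariogramFit(
            0.0, float(np.var(z)), max(float(lags.mean() / 3.0), 1e-6), fallback=True
        )
    n = len(xy)
    G = gamma(cdist(xy, xy))
    np.fill_diagonal(G, 0.0)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    try:
        lu = linalg.lu_factor(A)
        ok = np.isfinite(lu[0]).all() and np.abs(np.diag(lu[0])).min() > 1e-13
    except linalg.LinAlgError:
        ok = False
    if not ok:
        A[:n, :n] += _JITTER * np.eye(n)
        try:
            lu = linalg.lu_factor(A)
        except linalg.LinAlgError as exc:
            raise SolverFailureError("Krig: system singular after jitter retry") from exc
    return {"variogram": gamma, "lu": lu}


def idw2_neighborhood(model: FittedInterpolator, query) -> np.ndarray:
    """Indices of training points within the IDW2 cutoff radius of a query."""
    if model.spec.method != "IDW2":
        raise ValueError("idw2_neighborhood requires an IDW2 model")
    q = np.atleast_2d(np.asarray(query, dtype=float))
    d = cdist(q, model.xy)[0]
    return np.nonzero(d <= model.state["idw2_radius"])[0]


def ordinary_kriging_predict(model: FittedInterpolator, query) -> float:
    """Ordinary-Kriging prediction at a single query point."""
    if model.spec.method != "Krig":
        raise ValueError("ordinary_kriging_predict requires a Krig model")
    return float(model.predict(np.atleast_2d(np.asarray(query, dtype=float)))[0])
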