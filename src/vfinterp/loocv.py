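"""Leave-one-out cross-validation against replicate-averaged truth.

For each eye, a "truth" field is the per-location mean sensitivity over that
eye's replicate examinations.  For one examination and one interpolator, each
grid location k is predicted from the other N-1 measured points and the
modified residual e_k = zhat_k - ztilde_k compares the prediction with the
truth value rather than the held-out measurement, isolating the ability to
recover the underlying sensitivity from noisy neighbors.

Accuracy is summarized by MAE, RMSE and Willmott's modified index of
agreement d1, all evaluated over the N_b locations that survive blind-spot
exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg
from scipy.interpolate import CloughTocher2DInterpolator, LinearNDInterpolator
from scipy.spatial import Delaunay
from scipy.spatial.distance import cdist

from .exceptions import AlignmentError, InsufficientDataError, VfinterpError
from .grid import BlindSpotSpec, Eye, blind_spot_mask
from .interpolate import (
    FittedInterpolator,
    InterpolatorSpec,
    VariogramFit,
    _fit_kriging,
    fit,
    rbf_kernel,
)
from .natural import NaturalNeighborInterpolator

__all__ = [
    "Examination",
    "TruthField",
    "ResidualSet",
    "AccuracyMetrics",
    "average_truth",
    "loocv_predictions",
    "loocv_residuals",
    "mae",
    "rmse",
    "willmott_d1",
    "compute_accuracy",
]


@dataclass
class Examination:
    """One eye's test session: identity plus the measured point cloud."""

    subject_id: str
    group: str  # "normal" | "patient"
    eye: Eye
    replicate_index: int
    locations: np.ndarray  # (N, 2) degrees
    z: np.ndarray          # (N,) sensitivities, dB
    reliability_pass: bool = True

    def __post_init__(self) -> None:
        self.locations = np.asarray(self.locations, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.eye = Eye(self.eye)
        if self.group not in ("normal", "patient"):
            raise ValueError(f"group must be normal|patient, got {self.group!r}")
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be >= 1")
        if np.any(self.z < 0):
            raise ValueError("sensitivities must be >= 0 dB")
        if len(self.locations) != len(self.z):
            raise ValueError("locations and z length mismatch")

    @property
    def points(self) -> np.ndarray:
        """(N, 3) triplets (x, y, z)."""
        return np.column_stack([self.locations, self.z])

    @property
    def key(self) -> tuple:
        return (self.subject_id, self.group, self.eye.value, self.replicate_index)

    def canonical_order(self) -> np.ndarray:
        """Index order sorting locations lexicographically by (x, then y).

        Coordinates are compared at the 1e-6 deg file precision so the order
        survives a CSV round trip.
        """
        loc = np.round(self.locations, 6)
        return np.lexsort((loc[:, 1], loc[:, 0]))

    def subset(self, indices) -> "Examination":
        idx = np.asarray(indices, dtype=int)
        return Examination(
            self.subject_id, self.group, self.eye, self.replicate_index,
            self.locations[idx], self.z[idx], self.reliability_pass,
        )


@dataclass
class TruthField:
    """Per-eye, per-location mean sensitivity over replicate exams."""

    subject_id: str
    eye: Eye
    locations: np.ndarray  # (N, 2)
    values: np.ndarray     # (N,) dB
    n_exams: int

    def __post_init__(self) -> None:
        self.locations = np.asarray(self.locations, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.eye = Eye(self.eye)
        if self.n_exams < 1:
            raise ValueError("n_exams must be >= 1")
        if len(self.locations) != len(self.values):
            raise ValueError("locations/values length mismatch")


@dataclass
class ResidualSet:
    """Modified LOOCV residuals for one (examination, method) pair."""

    residuals: np.ndarray   # (N,) zhat - ztilde
    predicted: np.ndarray   # (N,) zhat
    kept_mask: np.ndarray   # (N,) bool; False at blind-spot exclusions
    truth_values: np.ndarray | None = None  # (N,) ztilde aligned to residuals
    fallback_count: int = 0

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())


@dataclass(frozen=True)
class AccuracyMetrics:
    mae: float
    rmse: float
    d1: float


def _align_indices(a_loc: np.ndarray, b_loc: np.ndarray) -> np.ndarray:
    """Index array ``idx`` with b_loc[idx] == a_loc (at file precision)."""
    if a_loc.shape != b_loc.shape:
        raise AlignmentError("location sets differ in size")
    ar = np.round(a_loc, 6)
    br = np.round(b_loc, 6)
    a_ord = np.lexsort((ar[:, 1], ar[:, 0]))
    b_ord = np.lexsort((br[:, 1], br[:, 0]))
    if not np.allclose(a_loc[a_ord], b_loc[b_ord], atol=1e-5):
        raise AlignmentError("location sets do not match")
    idx = np.empty(len(a_loc), dtype=int)
    idx[a_ord] = b_ord
    return idx


def average_truth(exams: list[Examination]) -> TruthField:
    """Mean sensitivity per location over one eye's examinations."""
    if not exams:
        raise InsufficientDataError("need at least one examination")
    ref = exams[0]
    total = ref.z.astype(float).copy()
    for ex in exams[1:]:
        if ex.eye != ref.eye or ex.subject_id != ref.subject_id:
            raise AlignmentError("examinations are not all from the same eye")
        idx = _align_indices(ref.locations, ex.locations)
        total += ex.z[idx]
    return TruthField(
        ref.subject_id, ref.eye, ref.locations.copy(), total / len(exams), len(exams)
    )


# ---------------------------------------------------------------------------
# leave-one-out predictions
# ---------------------------------------------------------------------------

def loocv_predictions(
    points: np.ndarray, spec: InterpolatorSpec, fast: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Predict each point from the other N-1 under the given method.

    Returns ``(zhat, fallback_mask)``.  ``fast=True`` uses vectorized /
    factorization-reusing paths that are algebraically identical to refitting
    per fold (the naive path, ``fast=False``, is retained as an oracle).
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    # parameters that the study defines per-examination are resolved once on
    # the full point set and shared by every fold: the IDW2 cutoff radius
    # (mean separation of the test grid) and the Kriging variogram
    if spec.method == "IDW2" and spec.idw2_radius is None:
        from .grid import mean_pairwise_separation

        spec = replace(spec, idw2_radius=mean_pairwise_separation(pts[:, :2]))
    gamma = None
    if spec.method == "Krig":
        gamma = _fit_kriging(spec, pts[:, :2], pts[:, 2])["variogram"]
    if n < 4:
        # too small for meaningful specialization; always go naive
        fast = False
    if not fast:
        return _loocv_naive(pts, spec, gamma)
    method = spec.method
    if method == "NN":
        return _loocv_nn(pts), np.zeros(n, bool)
    if method in ("IDW", "IDW2"):
        return _loocv_shepard(pts, spec)
    if method in ("RBFlin", "RBFtps"):
        return _loocv_rbf(pts, spec), np.zeros(n, bool)
    if method == "Krig":
        return _loocv_krig(pts, spec, gamma), np.zeros(n, bool)
    return _loocv_triangulated(pts, spec)


def _loocv_naive(
    pts: np.ndarray, spec: InterpolatorSpec, gamma: VariogramFit | None = None
) -> tuple[np.ndarray, np.ndarray]:
    n = len(pts)
    zhat = np.empty(n)
    fb = np.zeros(n, bool)
    for k in range(n):
        keep = np.arange(n) != k
        try:
            model = fit(spec, pts[keep])
            if gamma is not None:
                model = _with_variogram(model, gamma)
        except VfinterpError as exc:
            raise VfinterpError(f"LOOCV fold {k} failed for {spec.method}: {exc}") from exc
        vals, flags = model.predict_flagged(pts[k, :2][None, :])
        zhat[k] = vals[0]
        fb[k] = bool(flags[0])
    return zhat, fb


def _with_variogram(model: FittedInterpolator, gamma: VariogramFit) -> FittedInterpolator:
    """Rebuild a Krig model's system around an externally fitted variogram."""
    n = len(model.xy)
    G = gamma(cdist(model.xy, model.xy))
    np.fill_diagonal(G, 0.0)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    try:
        lu = linalg.lu_factor(A)
    except linalg.LinAlgError:
        A[:n, :n] += 1e-10 * np.eye(n)
        lu = linalg.lu_factor(A)
    model.state = {"variogram": gamma, "lu": lu}
    return model


def _loocv_nn(pts: np.ndarray) -> np.ndarray:
    d2 = cdist(pts[:, :2], pts[:, :2], metric="sqeuclidean")
    np.fill_diagonal(d2, np.inf)
    return pts[np.argmin(d2, axis=1), 2]


def _loocv_shepard(pts: np.ndarray, spec: InterpolatorSpec) -> tuple[np.ndarray, np.ndarray]:
    xy, z = pts[:, :2], pts[:, 2]
    d = cdist(xy, xy)
    with np.errstate(divide="ignore"):
        w = d ** (-spec.idw_power)
    np.fill_diagonal(w, 0.0)
    fb = np.zeros(len(pts), bool)
    if spec.method == "IDW2":
        radius = spec.idw2_radius  # resolved on the full grid by the caller
        w = np.where(d <= radius, w, 0.0)
        np.fill_diagonal(w, 0.0)
        empty = ~(w.sum(1) > 0)
        if empty.any():
            fb |= empty
            d2 = d.copy()
            np.fill_diagonal(d2, np.inf)
            nn = np.argmin(d2[empty], axis=1)
            w[empty] = 0.0
            w[np.nonzero(empty)[0], nn] = 1.0
    return (w @ z) / w.sum(1), fb


def _loocv_rbf(pts: np.ndarray, spec: InterpolatorSpec) -> np.ndarray:
    xy, z = pts[:, :2], pts[:, 2]
    n = len(pts)
    kind = "linear" if spec.method == "RBFlin" else "tps"
    augment = spec.rbf_augment if spec.rbf_augment is not None else (kind == "tps")
    K = rbf_kernel(kind, cdist(xy, xy))
    P = np.column_stack([np.ones(n), xy])
    zhat = np.empty(n)
    idx = np.arange(n)
    for k in range(n):
        keep = idx != k
        Kk = K[np.ix_(keep, keep)]
        if augment:
            m = n - 1
            A = np.zeros((m + 3, m + 3))
            A[:m, :m] = Kk
            A[:m, m:] = P[keep]
            A[m:, :m] = P[keep].T
            b = np.concatenate([z[keep], np.zeros(3)])
            sol = _solve(A, b)
            zhat[k] = K[k, keep] @ sol[:m] + P[k] @ sol[m:]
        else:
            sol = _solve(Kk, z[keep])
            zhat[k] = K[k, keep] @ sol
    return zhat


def _loocv_krig(pts: np.ndarray, spec: InterpolatorSpec, gamma: VariogramFit) -> np.ndarray:
    xy, z = pts[:, :2], pts[:, 2]
    n = len(pts)
    # variogram fitted once per examination (the full data set), reused across folds
    G = gamma(cdist(xy, xy))
    np.fill_diagonal(G, 0.0)
    zhat = np.empty(n)
    idx = np.arange(n)
    for k in range(n):
        keep = idx != k
        m = n - 1
        A = np.zeros((m + 1, m + 1))
        A[:m, :m] = G[np.ix_(keep, keep)]
        A[:m, m] = 1.0
        A[m, :m] = 1.0
        b = np.concatenate([G[keep, k], [1.0]])
        sol = _solve(A, b)
        zhat[k] = sol[:m] @ z[keep]
    return zhat


def _solve(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    try:
        x = linalg.solve(A, b)
        if np.isfinite(x).all():
            return x
    except linalg.LinAlgError:
        pass
    return linalg.solve(A + 1e-10 * np.eye(len(A)), b)


def _loocv_triangulated(pts: np.ndarray, spec: InterpolatorSpec) -> tuple[np.ndarray, np.ndarray]:
    xy, z = pts[:, :2], pts[:, 2]
    n = len(pts)
    zhat = np.empty(n)
    fb = np.zeros(n, bool)
    idx = np.arange(n)
    for k in range(n):
        keep = idx != k
        sub_xy, sub_z = xy[keep], z[keep]
        tri = Delaunay(sub_xy)
        if spec.method == "Lin":
            val = float(LinearNDInterpolator(tri, sub_z)(xy[k][None, :])[0])
        elif spec.method == "Cub":
            val = float(CloughTocher2DInterpolator(tri, sub_z)(xy[k][None, :])[0])
        else:  # NatN
            val = float(NaturalNeighborInterpolator(sub_xy, sub_z)(xy[k][None, :])[0])
        if not np.isfinite(val):
            fb[k] = True
            if spec.fallback == "nearest":
                d2 = ((sub_xy - xy[k]) ** 2).sum(1)
                val = float(sub_z[np.argmin(d2)])
            else:
                val = np.nan
        zhat[k] = val
    return zhat, fb


def loocv_residuals(
    exam: Examination,
    truth: TruthField,
    spec: InterpolatorSpec,
    blind_spot: BlindSpotSpec | None = None,
    fast: bool = True,
) -> ResidualSet:
    """Modified LOOCV residuals of one examination against its truth field.

    Blind-spot locations stay in the interpolation inputs but are flagged out
    of the kept mask so they never enter the accuracy metrics.
    """
    idx = _align_indices(exam.locations, truth.locations)
    truth_vals = truth.values[idx]
    zhat, fb = loocv_predictions(exam.points, spec, fast=fast)
    kept = (
        blind_spot_mask(exam.locations, exam.eye, blind_spot)
        if blind_spot is not None
        else np.ones(len(exam.locations), dtype=bool)
    )
    return ResidualSet(
        residuals=zhat - truth_vals,
        predicted=zhat,
        kept_mask=kept,
        truth_values=truth_vals,
        fallback_count=int(fb.sum()),
    )


# ---------------------------------------------------------------------------
# accuracy metrics
# ---------------------------------------------------------------------------

def _kept_residuals(residuals) -> np.ndarray:
    if isinstance(residuals, ResidualSet):
        e = residuals.residuals[residuals.kept_mask]
    else:
        e = np.asarray(residuals, dtype=float)
    if e.size == 0:
        raise InsufficientDataError("no kept residuals")
    return e


def mae(residuals) -> float:
    """Mean absolute error over the kept locations (dB)."""
    return float(np.mean(np.abs(_kept_residuals(residuals))))


def rmse(residuals) -> float:
    """Root-mean-square error over the kept locations (dB)."""
    return float(np.sqrt(np.mean(_kept_residuals(residuals) ** 2)))


def willmott_d1(predicted, truth_values, kept_mask=None) -> float:
    """Willmott's modified index of agreement d1 in [0, 1] (1 = perfect).

    d1 = 1 - sum|zhat - ztilde| / sum(|ztilde - zbar| + |zhat - zbar|), with
    zbar the mean truth over the kept locations.  A zero denominator (all
    values identical and perfectly predicted) returns 1 by convention.
    """
    zhat = np.asarray(predicted, dtype=float)
    zt = np.asarray(truth_values, dtype=float)
    if kept_mask is not None:
        kept = np.asarray(kept_mask, dtype=bool)
        zhat, zt = zhat[kept], zt[kept]
    if zhat.size == 0:
        raise InsufficientDataError("no kept locations")
    zbar = zt.mean()
    denom = np.sum(np.abs(zt - zbar) + np.abs(zhat - zbar))
    if denom == 0.0:
        return 1.0
    return float(1.0 - np.sum(np.abs(zhat - zt)) / denom)


def compute_accuracy(rs: ResidualSet, truth_values: np.ndarray | None = None) -> AccuracyMetrics:
    """MAE, RMSE and d1 for one residual set against aligned truth values."""
    zt = truth_values if truth_values is not None else rs.truth_values
    if zt is None:
        raise ValueError("truth values required (none stored on the ResidualSet)")
    return AccuracyMetrics(
        mae=mae(rs),
        rmse=rmse(rs),
        d1=willmott_d1(rs.predicted, np.asarray(zt, dtype=float), rs.kept_mask),
    )
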