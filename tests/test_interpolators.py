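"""Interpolator contracts: exactness, precision, bounds, continuity."""

import numpy as np
import pytest

import vfinterp as vf
from vfinterp.exceptions import DegenerateGeometryError, InsufficientDataError
from vfinterp.interpolate import idw2_neighborhood, rbf_kernel

from conftest import random_points

ALL = vf.METHODS
LINEAR_PRECISION = ("Lin", "NatN", "Cub", "RBFtps")


def _affine_cloud(rng, n=25, span=40.0, coef=(5.0, 0.3, -0.2)):
    xy = rng.uniform(-span, span, (n, 2))
    a, b, c = coef
    z = a + b * xy[:, 0] + c * xy[:, 1]
    return np.column_stack([xy, z])


class TestExactness:
    @pytest.mark.parametrize("method", ALL)
    def test_constant_three_points(self, method):
        if method in ("Lin", "Cub", "NatN"):
            pts = [(0, 0, 7), (10, 0, 7), (0, 10, 7)]
        else:
            pts = [(0, 0, 7), (10, 0, 7), (0, 10, 7)]
        model = vf.fit(vf.InterpolatorSpec(method=method), pts)
        got = model.predict([(0, 0), (10, 0), (0, 10)])
        assert np.allclose(got, 7.0, atol=1e-6)

    @pytest.mark.parametrize("method", ALL)
    def test_training_sites_reproduced(self, method, rng):
        pts = random_points(rng, 30)
        model = vf.fit(vf.InterpolatorSpec(method=method), pts)
        got = model.predict(pts[:, :2])
        assert np.allclose(got, pts[:, 2], atol=1e-6), method

    def test_rbflin_two_point_hand_solve(self):
        # kernel matrix [[0,1],[1,0]] -> weights (1, 0) reproduce the data
        model = vf.fit(vf.InterpolatorSpec(method="RBFlin"), [(0, 0, 0), (1, 0, 1)])
        assert np.allclose(model.state["weights"], [1.0, 0.0])
        assert np.allclose(model.predict([(0, 0), (1, 0)]), [0.0, 1.0], atol=1e-12)


class TestPredictContracts:
    def test_lin_barycentric_hand_example(self):
        model = vf.fit(vf.InterpolatorSpec(method="Lin"), [(0, 0, 0), (1, 0, 1), (0, 1, 2)])
        assert model.predict([(0.25, 0.25)])[0] == pytest.approx(0.75, abs=1e-12)

    def test_idw_equidistant_symmetry(self):
        model = vf.fit(vf.InterpolatorSpec(method="IDW"), [(0, 0, 10), (2, 0, 20)])
        assert model.predict([(1, 0)])[0] == pytest.approx(15.0, abs=1e-12)

    def test_idw_shepard_weights_by_hand(self):
        # weights 1/1^2 and 1/2^2 -> (0*1 + 12*0.25) / 1.25 = 2.4
        model = vf.fit(vf.InterpolatorSpec(method="IDW"), [(0, 0, 0), (3, 0, 12)])
        assert model.predict([(1, 0)])[0] == pytest.approx(2.4, abs=1e-12)

    def test_nn_tie_broken_by_lowest_index(self):
        model = vf.fit(
            vf.InterpolatorSpec(method="NN"), [(0, 0, 5), (2, 0, 9), (1, 1, 7)]
        )
        # query (1, 0) is equidistant from points 0 and 1 -> lowest index wins
        assert model.predict([(1, 0)])[0] == 5.0

    def test_empty_query_list(self):
        model = vf.fit(vf.InterpolatorSpec(method="NN"), [(0, 0, 1), (1, 1, 2)])
        assert model.predict(np.empty((0, 2))).size == 0

    @pytest.mark.parametrize("method", ["Lin", "Cub", "NatN"])
    def test_out_of_hull_fallback_modes(self, method, rng):
        pts = random_points(rng, 15, span=10)
        far = [(50.0, 50.0)]
        nearest_model = vf.fit(vf.InterpolatorSpec(method=method, fallback="nearest"), pts)
        vals, flags = nearest_model.predict_flagged(far)
        d = np.hypot(pts[:, 0] - 50, pts[:, 1] - 50)
        assert vals[0] == pts[np.argmin(d), 2]
        assert flags[0]
        missing_model = vf.fit(vf.InterpolatorSpec(method=method, fallback="missing"), pts)
        assert np.isnan(missing_model.predict(far)[0])


class TestRbfKernel:
    def test_linear_kernel_is_identity(self):
        assert rbf_kernel("linear", 2.0) == 2.0

    @pytest.mark.parametrize("r,expected", [(1.0, 0.0), (0.0, 0.0), (2.0, 4 * np.log(2))])
    def test_tps_values(self, r, expected):
        assert rbf_kernel("tps", r) == pytest.approx(expected, abs=1e-12)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            rbf_kernel("linear", -1.0)


class TestIdw2:
    def test_neighborhood_matches_brute_force(self, rng):
        pts = random_points(rng, 25)
        model = vf.fit(vf.InterpolatorSpec(method="IDW2", idw2_radius=30.0), pts)
        q = (5.0, -3.0)
        got = set(idw2_neighborhood(model, q))
        brute = {
            i for i, p in enumerate(pts[:, :2]) if np.hypot(*(p - np.array(q))) <= 30.0
        }
        assert got == brute

    def test_coincident_query_included(self, small_cloud):
        model = vf.fit(vf.InterpolatorSpec(method="IDW2"), small_cloud)
        assert 0 in idw2_neighborhood(model, small_cloud[0, :2])

    def test_large_radius_equals_global_idw(self, small_cloud, rng):
        diameter = 1e4
        idw2 = vf.fit(vf.InterpolatorSpec(method="IDW2", idw2_radius=diameter), small_cloud)
        idw = vf.fit(vf.InterpolatorSpec(method="IDW"), small_cloud)
        q = rng.uniform(-60, 60, (40, 2))
        assert np.array_equal(idw2.predict(q), idw.predict(q))

    def test_empty_neighborhood_falls_back_to_nearest(self, small_cloud):
        model = vf.fit(vf.InterpolatorSpec(method="IDW2", idw2_radius=1.0), small_cloud)
        q = [(500.0, 500.0)]
        vals, flags = model.predict_flagged(q)
        d = np.hypot(small_cloud[:, 0] - 500, small_cloud[:, 1] - 500)
        assert vals[0] == small_cloud[np.argmin(d), 2]
        assert flags[0]

    @pytest.mark.parametrize("method", ["IDW", "IDW2"])
    def test_predictions_bounded_by_data_range(self, method, rng):
        pts = random_points(rng, 30)
        model = vf.fit(vf.InterpolatorSpec(method=method), pts)
        q = rng.uniform(-80, 80, (200, 2))
        vals = model.predict(q)
        assert (vals >= pts[:, 2].min() - 1e-9).all()
        assert (vals <= pts[:, 2].max() + 1e-9).all()


class TestLinearPrecision:
    @pytest.mark.parametrize("method", LINEAR_PRECISION)
    def test_affine_field_reproduced_inside_hull(self, method, rng):
        pts = _affine_cloud(rng)
        model = vf.fit(vf.InterpolatorSpec(method=method), pts)
        # interior queries: convex combinations of data points
        w = rng.dirichlet(np.ones(len(pts)), size=50)
        q = w @ pts[:, :2]
        expected = 5.0 + 0.3 * q[:, 0] - 0.2 * q[:, 1]
        assert np.allclose(model.predict(q), expected, atol=1e-6), method


class TestContinuity:
    @pytest.mark.parametrize("method", ["Cub", "NatN"])
    def test_c0_across_triangle_edges(self, method, rng):
        pts = random_points(rng, 12, span=10)
        # "missing" fallback: hull-edge straddles that exit the hull yield NaN
        # and are skipped rather than polluted by the nearest-value fallback
        model = vf.fit(vf.InterpolatorSpec(method=method, fallback="missing"), pts)
        # midpoints of Delaunay edges, straddled by a 1e-6 deg step
        tri = vf.delaunay(pts[:, :2])
        edges = {tuple(sorted(e)) for t in tri for e in [(t[0], t[1]), (t[1], t[2]), (t[0], t[2])]}
        checked = 0
        for i, j in list(edges)[:10]:
            mid = 0.5 * (pts[i, :2] + pts[j, :2])
            n = pts[j, :2] - pts[i, :2]
            n = np.array([-n[1], n[0]]) / np.hypot(*n)
            a, b = model.predict([mid + 5e-7 * n, mid - 5e-7 * n])
            if np.isfinite(a) and np.isfinite(b):
                assert abs(a - b) < 1e-3
                checked += 1
        assert checked > 0


class TestNaturalNeighborWeights:
    def test_weights_match_area_stealing_brute_force(self, rng):
        """Sibson weights vs. explicit half-plane Voronoi construction."""
        from shapely.geometry import Polygon, box
        from vfinterp.natural import sibson_weights

        def cells(pts, bb):
            out = []
            for i, p in enumerate(pts):
                poly = bb
                for j, o in enumerate(pts):
                    if i == j:
                        continue
                    mid, n = (p + o) / 2, o - p
                    n = n / np.hypot(*n)
                    t = np.array([-n[1], n[0]])
                    L = 1e4
                    poly = poly.intersection(
                        Polygon([mid + t * L, mid - t * L, mid - t * L - n * L, mid + t * L - n * L])
                    )
                out.append(poly)
            return out

        for trial in range(6):
            n = int(rng.integers(5, 9))
            pts = rng.uniform(-10, 10, (n, 2))
            from scipy.spatial import Delaunay

            try:
                tri = Delaunay(pts)
            except Exception:
                continue
            q = pts[tri.simplices[0]].mean(axis=0) + rng.normal(0, 0.1, 2)
            if tri.find_simplex(q) < 0:
                continue
            res = sibson_weights(pts, q)
            assert res is not None
            idx, w = res
            assert (w >= -1e-12).all()
            assert w.sum() == pytest.approx(1.0, abs=1e-9)
            bb = box(-200, -200, 200, 200)
            c0 = cells(pts, bb)
            c1 = cells(np.vstack([pts, q]), bb)
            stolen = {i: c0[i].area - c1[i].area for i in range(n)}
            total = sum(v for v in stolen.values() if v > 0)
            for i, wi in zip(idx, w):
                assert wi == pytest.approx(max(stolen[i], 0.0) / total, abs=1e-6)

    def test_outside_hull_returns_none(self):
        from vfinterp.natural import sibson_weights

        pts = np.array([(0.0, 0.0), (1.0, 0.0), (0.0, 1.0), (1.0, 1.0)])
        assert sibson_weights(pts, (5.0, 5.0)) is None


class TestFitValidation:
    @pytest.mark.parametrize("method", ["Lin", "Cub", "NatN"])
    def test_collinear_rejected_for_triangulated(self, method):
        with pytest.raises(DegenerateGeometryError):
            vf.fit(vf.InterpolatorSpec(method=method), [(0, 0, 1), (1, 0, 2), (2, 0, 3)])

    def test_duplicate_locations_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            vf.fit(vf.InterpolatorSpec(method="IDW"), [(0, 0, 1), (0, 0, 2), (1, 1, 3)])

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            vf.fit(vf.InterpolatorSpec(method="RBFlin"), [(0, 0, 1)])

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            vf.InterpolatorSpec(method="Spline")


class TestRbfCrossCheck:
    def test_tps_agrees_with_scipy_rbfinterpolator(self, rng):
        """Independent oracle: scipy's thin-plate spline with degree-1 tail."""
        from scipy.interpolate import RBFInterpolator

        pts = random_points(rng, 25)
        ours = vf.fit(vf.InterpolatorSpec(method="RBFtps"), pts)
        theirs = RBFInterpolator(pts[:, :2], pts[:, 2], kernel="thin_plate_spline", degree=1)
        q = rng.uniform(-50, 50, (40, 2))
        assert np.allclose(ours.predict(q), theirs(q), atol=1e-6)
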