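"""Boundary augmentation, dense resampling, finite differences, TV metrics."""

import numpy as np
import pytest

import vfinterp as vf
from vfinterp.exceptions import InsufficientDataError
from vfinterp.surface import DenseSurface, fdiff_first, fdiff_second, tv1, tv2

from conftest import random_points


def _surface(values, spacing=1.0, mask=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    return DenseSurface(values=values, extent=90.0, spacing=spacing, mask=mask, method="test")


def _interior_mask(shape):
    """Mask excluding all wrap-affected rows/columns (first/last in each axis)."""
    m = np.zeros(shape, dtype=bool)
    m[1:-1, 1:-1] = True
    return m


class TestAugmentBoundary:
    def test_default_adds_72_zero_points_on_circle(self, od_grid):
        pts = np.column_stack([od_grid.locations, np.full(164, 20.0)])
        aug = vf.augment_boundary(pts)
        added = aug[164:]
        assert len(added) == 72
        assert np.allclose(np.hypot(added[:, 0], added[:, 1]), 120.0)
        assert (added[:, 2] == 0).all()

    def test_five_degree_angular_gaps(self, od_grid):
        pts = np.column_stack([od_grid.locations, np.zeros(164)])
        added = vf.augment_boundary(pts)[164:]
        ang = np.degrees(np.arctan2(added[:, 1], added[:, 0]))
        gaps = np.diff(np.sort(np.mod(ang, 360.0)))
        assert np.allclose(gaps, 5.0, atol=1e-9)

    def test_append_only(self, od_grid):
        pts = np.column_stack([od_grid.locations, np.full(164, 7.0)])
        aug = vf.augment_boundary(pts)
        assert np.array_equal(aug[:164], pts)

    def test_coincident_boundary_point_shifted(self):
        pts = np.array([(120.0, 0.0, 5.0), (0.0, 0.0, 30.0), (10.0, 10.0, 20.0)])
        aug = vf.augment_boundary(pts)
        added = aug[3:]
        d = np.hypot(added[:, 0] - 120.0, added[:, 1])
        assert d.min() > 1e-6  # clashing point was moved off the datum
        assert np.allclose(np.hypot(added[:, 0], added[:, 1]), 120.0)

    def test_radius_must_exceed_grid(self):
        pts = np.array([(150.0, 0.0, 1.0), (0.0, 0.0, 2.0)])
        with pytest.raises(ValueError):
            vf.augment_boundary(pts, radius=120.0)


class TestDenseResample:
    def test_default_lattice_geometry(self, od_grid):
        # spacing of the default 501-point lattice over +/-90 deg
        assert 2 * 90.0 / (501 - 1) == pytest.approx(0.36)
        pts = np.column_stack([od_grid.locations, np.full(164, 12.0)])
        aug = vf.augment_boundary(pts)
        surf = vf.dense_resample(
            vf.InterpolatorSpec(method="Lin"), aug, n=41, hull_points=od_grid.locations
        )
        assert surf.shape == (41, 41)
        assert surf.spacing == pytest.approx(180.0 / 40)
        # constant data: exact inside the hull mask for a convex-weight method
        assert np.allclose(surf.values[surf.mask], 12.0, atol=1e-9)

    def test_matches_per_point_predictions(self, rng):
        pts = random_points(rng, 15, span=50)
        spec = vf.InterpolatorSpec(method="Lin")
        surf = vf.dense_resample(spec, pts, n=5, extent=40.0)
        model = vf.fit(spec, pts)
        ax = np.linspace(-40, 40, 5)
        for i, x in enumerate(ax):
            for j, y in enumerate(ax):
                assert surf.values[i, j] == pytest.approx(
                    float(model.predict([(x, y)])[0]), abs=1e-9
                )

    def test_mask_uses_original_hull_not_augmented(self, od_grid):
        pts = np.column_stack([od_grid.locations, np.full(164, 10.0)])
        aug = vf.augment_boundary(pts)
        surf = vf.dense_resample(
            vf.InterpolatorSpec(method="NN"), aug, n=41, hull_points=od_grid.locations
        )
        ax = surf.axis()
        X, Y = np.meshgrid(ax, ax, indexing="ij")
        outside = np.hypot(X, Y) > 80.0  # beyond the grid but inside the 120-deg ring
        assert not surf.mask[outside].any()

    def test_default_mask_excludes_wrap_cells(self, od_grid):
        # hull half-width ~67.5 deg < 90 deg: no wrap-affected row/col in Omega
        pts = np.column_stack([od_grid.locations, np.full(164, 10.0)])
        aug = vf.augment_boundary(pts)
        surf = vf.dense_resample(
            vf.InterpolatorSpec(method="NN"), aug, n=61, hull_points=od_grid.locations
        )
        assert not surf.mask[0].any() and not surf.mask[-1].any()
        assert not surf.mask[:, 0].any() and not surf.mask[:, -1].any()


class TestFiniteDifferences:
    def test_constant_gives_zero(self):
        gx, gy = fdiff_first(np.full((6, 6), 3.0))
        assert not gx.any() and not gy.any()
        gxx, gyy = fdiff_second(np.full((6, 6), 3.0))
        assert not gxx.any() and not gyy.any()

    def test_linear_ramp_closed_form_with_wrap(self):
        n, spacing, a = 8, 0.5, 2.0
        x = np.arange(n) * spacing
        h = np.tile((a * x)[:, None], (1, n))
        gx, gy = fdiff_first(h)
        assert np.allclose(gx[:-1], a * spacing)
        # wrap row: h[0,:] - h[n-1,:]
        assert np.allclose(gx[-1], h[0] - h[-1])
        assert not gy.any()

    def test_first_differences_match_printed_stencil(self, rng):
        h = rng.normal(size=(4, 4))
        gx, gy = fdiff_first(h)
        nx, ny = h.shape
        for i in range(nx):
            for j in range(ny):
                ex = h[i + 1, j] - h[i, j] if i < nx - 1 else h[0, j] - h[i, j]
                ey = h[i, j + 1] - h[i, j] if j < ny - 1 else h[i, 0] - h[i, j]
                assert gx[i, j] == pytest.approx(ex, abs=1e-12)
                assert gy[i, j] == pytest.approx(ey, abs=1e-12)

    def test_second_differences_match_printed_stencil(self, rng):
        h = rng.normal(size=(5, 5))
        gxx, gyy = fdiff_second(h)
        nx, ny = h.shape
        for i in range(nx):
            for j in range(ny):
                im1 = h[i - 1, j] if i > 0 else h[nx - 1, j]
                ip1 = h[i + 1, j] if i < nx - 1 else h[0, j]
                assert gxx[i, j] == pytest.approx(im1 - 2 * h[i, j] + ip1, abs=1e-12)
                jm1 = h[i, j - 1] if j > 0 else h[i, ny - 1]
                jp1 = h[i, j + 1] if j < ny - 1 else h[i, 0]
                assert gyy[i, j] == pytest.approx(jm1 - 2 * h[i, j] + jp1, abs=1e-12)

    def test_quadratic_second_difference(self):
        n, spacing = 9, 0.25
        x = np.arange(n) * spacing
        h = np.tile((x ** 2)[:, None], (1, n))
        gxx, _ = fdiff_second(h)
        assert np.allclose(gxx[1:-1], 2 * spacing ** 2)


class TestTotalVariation:
    def test_constant_surface_zero(self):
        assert tv1(_surface(np.full((8, 8), 5.0))) == 0.0
        assert tv2(_surface(np.full((8, 8), 5.0))) == 0.0

    def test_ramp_tv1_closed_form(self):
        n, spacing, g = 10, 0.36, 1.7
        x = np.arange(n) * spacing
        h = np.tile((g * x)[:, None], (1, n))
        s = _surface(h, spacing=spacing, mask=_interior_mask((n, n)))
        assert tv1(s) == pytest.approx(abs(g) * spacing, rel=1e-12)

    def test_affine_surface_tv2_zero(self):
        n, spacing = 10, 0.5
        x = np.arange(n) * spacing
        h = 3.0 + 1.2 * x[:, None] - 0.7 * x[None, :]
        s = _surface(h, spacing=spacing, mask=_interior_mask((n, n)))
        assert tv2(s) == pytest.approx(0.0, abs=1e-12)

    def test_quadratic_tv2_closed_form(self):
        n, spacing = 12, 0.4
        x = np.arange(n) * spacing
        h = np.tile((x ** 2)[:, None], (1, n))
        s = _surface(h, spacing=spacing, mask=_interior_mask((n, n)))
        assert tv2(s) == pytest.approx(2 * spacing ** 2, rel=1e-12)

    def test_matches_brute_force_double_loop(self, rng):
        h = rng.normal(20, 5, (7, 7))
        mask = rng.random((7, 7)) > 0.3
        mask[2, 2] = True
        s = _surface(h, mask=mask)
        nx, ny = h.shape
        acc1 = acc2 = 0.0
        for i in range(nx):
            for j in range(ny):
                if not mask[i, j]:
                    continue
                gx = h[(i + 1) % nx, j] - h[i, j]
                gy = h[i, (j + 1) % ny] - h[i, j]
                acc1 += gx * gx + gy * gy
                gxx = h[(i - 1) % nx, j] - 2 * h[i, j] + h[(i + 1) % nx, j]
                gyy = h[i, (j - 1) % ny] - 2 * h[i, j] + h[i, (j + 1) % ny]
                acc2 += gxx * gxx + gyy * gyy
        m = mask.sum()
        assert tv1(s) == pytest.approx(np.sqrt(acc1 / m), rel=1e-10)
        assert tv2(s) == pytest.approx(np.sqrt(acc2 / m), rel=1e-10)

    def test_constant_shift_invariance(self, rng):
        h = rng.normal(size=(9, 9))
        s1, s2 = _surface(h), _surface(h + 42.0)
        assert tv1(s1) == pytest.approx(tv1(s2), rel=1e-9)
        assert tv2(s1) == pytest.approx(tv2(s2), rel=1e-9)

    def test_scaling_by_c_scales_metrics(self, rng):
        h = rng.normal(size=(9, 9))
        assert tv1(_surface(-3.0 * h)) == pytest.approx(3.0 * tv1(_surface(h)), rel=1e-9)
        assert tv2(_surface(-3.0 * h)) == pytest.approx(3.0 * tv2(_surface(h)), rel=1e-9)

    def test_empty_mask_raises(self):
        s = _surface(np.ones((4, 4)), mask=np.zeros((4, 4), dtype=bool))
        with pytest.raises(InsufficientDataError):
            tv1(s)

    def test_nn_rougher_than_rbftps(self, od_grid, rng):
        """Piecewise-constant NN surfaces carry much larger TV2 than RBFtps."""
        model = vf.HovModel(kind="rp_ring")
        ex = vf.simulate_exam(model, od_grid, 2.5, int(rng.integers(1e6)), group="patient")
        aug = vf.augment_boundary(ex.points)
        tv2s = {}
        for m in ("NN", "RBFtps"):
            surf = vf.dense_resample(
                vf.InterpolatorSpec(method=m), aug, n=61, hull_points=od_grid.locations
            )
            tv2s[m] = tv2(surf)
        assert tv2s["NN"] > tv2s["RBFtps"]
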