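"""Terrain metrics against analytic oracles on planes, spheres and channels."""

import numpy as np
import pytest
from shapely.geometry import LineString

from ridge2reef.grid import RasterGrid
from ridge2reef.terrain import (
    aggregate_mean,
    bpi,
    circular_stats,
    curvatures,
    distance_to_shore,
    rugosity,
    slope_aspect,
)


def _grid_from(f, n=15, cs=10.0):
    x = (np.arange(n) + 0.5) * cs
    X, Y = np.meshgrid(x, x)
    return RasterGrid(f(X, Y), cs)


class TestSlopeAspect:
    def test_flat_plane_zero_slope_undefined_aspect(self):
        g = _grid_from(lambda X, Y: np.full_like(X, -5.0))
        slope, aspect = slope_aspect(g)
        np.testing.assert_allclose(slope.values, 0.0, atol=1e-12)
        assert np.isnan(aspect.values).all()

    def test_inclined_plane_matches_analytic_slope_and_aspect(self):
        g = _grid_from(lambda X, Y: -0.1 * X)
        slope, aspect = slope_aspect(g)
        interior = np.s_[1:-1, 1:-1]
        np.testing.assert_allclose(slope.values[interior],
                                   np.degrees(np.arctan(0.1)), rtol=1e-9)
        # z falls toward +x, so downslope faces east (90 deg)
        np.testing.assert_allclose(aspect.values[interior], 90.0, atol=1e-9)

    def test_symmetric_bump_apex_has_zero_slope(self):
        n, cs = 21, 10.0
        g = _grid_from(lambda X, Y: -np.hypot(X - 105.0, Y - 105.0) ** 2 / 1e3,
                       n=n, cs=cs)
        slope, _ = slope_aspect(g)
        assert slope.values[10, 10] == pytest.approx(0.0, abs=1e-9)

    def test_invariance_to_constant_depth_offset(self):
        rng = np.random.default_rng(3)
        v = rng.normal(-10, 2, (12, 12))
        a = RasterGrid(v.copy(), 10.0)
        b = RasterGrid(v + 100.0, 10.0)
        sa, aa = slope_aspect(a)
        sb, ab = slope_aspect(b)
        np.testing.assert_allclose(sa.values, sb.values, rtol=1e-9)
        np.testing.assert_allclose(aa.values, ab.values, rtol=1e-9)


class TestBPI:
    def test_plane_gives_zero_interior(self):
        g = _grid_from(lambda X, Y: -0.05 * X - 0.02 * Y)
        b = bpi(g, radius=30.0)
        interior = b.values[3:-3, 3:-3]
        np.testing.assert_allclose(interior, 0.0, atol=1e-9)

    def test_pinnacle_positive_neighbors_negative(self):
        v = np.full((9, 9), -10.0)
        v[4, 4] = 0.0
        b = bpi(RasterGrid(v, 10.0), radius=10.0)
        assert b.values[4, 4] > 0
        assert b.values[4, 3] < 0

    def test_matches_brute_force_neighborhood_means(self):
        rng = np.random.default_rng(9)
        v = rng.normal(-8, 3, (9, 9))
        cs, radius = 10.0, 25.0
        b = bpi(RasterGrid(v.copy(), cs), radius)
        i, j = 4, 5
        acc = []
        for ii in range(9):
            for jj in range(9):
                if (ii, jj) != (i, j) and np.hypot(ii - i, jj - j) * cs <= radius:
                    acc.append(v[ii, jj])
        assert b.values[i, j] == pytest.approx(v[i, j] - np.mean(acc), rel=1e-9)

    def test_radius_below_cell_size_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            bpi(RasterGrid(np.zeros((5, 5)), 10.0), radius=5.0)


class TestCurvatures:
    def test_plane_has_zero_curvature(self):
        g = _grid_from(lambda X, Y: -0.1 * X + 0.03 * Y)
        plan, prof = curvatures(g)
        np.testing.assert_allclose(plan.values[1:-1, 1:-1], 0.0, atol=1e-12)
        np.testing.assert_allclose(prof.values[1:-1, 1:-1], 0.0, atol=1e-12)

    def test_sloped_parabolic_channel_axis_plan_nonzero_profile_zero(self):
        # channel z = a(x-x0)^2 + b y: on the axis the gradient points along
        # the channel, so profile curvature vanishes and plan curvature is 2a
        a, b, x0 = 0.002, -0.05, 75.0
        g = _grid_from(lambda X, Y: a * (X - x0) ** 2 + b * Y)
        plan, prof = curvatures(g)
        j_axis = 7  # column whose center x = 75
        np.testing.assert_allclose(prof.values[1:-1, j_axis], 0.0, atol=1e-12)
        np.testing.assert_allclose(plan.values[1:-1, j_axis], 2 * a, rtol=1e-9)

    def test_sphere_flank_matches_directional_derivative_oracle(self):
        # oracle: profile = -(d2z/ds2 along gradient); for the hemisphere cap
        # z = sqrt(R^2 - r^2), both curvatures are analytic and equal off-apex
        R = 500.0
        n, cs = 15, 10.0
        g = _grid_from(lambda X, Y: np.sqrt(R**2 - (X - 75) ** 2 - (Y - 75) ** 2),
                       n=n, cs=cs)
        plan, prof = curvatures(g)
        i, j = 4, 7  # flank point, gradient along -y
        x, y = (j + 0.5) * cs - 75.0, (i + 0.5) * cs - 75.0
        r2 = x**2 + y**2
        z = np.sqrt(R**2 - r2)
        # along the gradient z'' = -R^2/z^3 and profile is its negation;
        # across the gradient the second derivative is z'/r = -1/z and plan
        # reports it directly, so the two agree in magnitude near the apex
        d2z_ds2 = -(R**2) / z**3
        d2z_dt2 = -1.0 / z
        assert prof.values[i, j] == pytest.approx(-d2z_ds2, rel=0.01)
        assert plan.values[i, j] == pytest.approx(d2z_dt2, rel=0.01)
        assert abs(plan.values[i, j]) == pytest.approx(abs(prof.values[i, j]), rel=0.01)

    def test_degenerate_flat_window_returns_zero(self):
        plan, prof = curvatures(RasterGrid(np.zeros((5, 5)), 10.0))
        assert plan.values[2, 2] == 0.0 and prof.values[2, 2] == 0.0


class TestRugosity:
    def test_flat_surface_is_exactly_one(self):
        r = rugosity(RasterGrid(np.full((6, 6), -3.0), 10.0))
        np.testing.assert_allclose(r.values, 1.0, atol=1e-12)

    def test_tilted_plane_matches_sec_theta(self):
        theta = np.radians(20.0)
        g = _grid_from(lambda X, Y: np.tan(theta) * X)
        r = rugosity(g)
        np.testing.assert_allclose(r.values[1:-1, 1:-1], 1 / np.cos(theta), rtol=1e-6)

    def test_rough_surface_exceeds_smooth(self):
        rng = np.random.default_rng(1)
        smooth = RasterGrid(np.zeros((10, 10)) - 5.0, 10.0)
        rough = RasterGrid(-5.0 + rng.normal(0, 2.0, (10, 10)), 10.0)
        assert np.nanmean(rugosity(rough).values) > np.nanmean(rugosity(smooth).values)


class TestCircularStats:
    def test_constant_aspect_zero_gives_north_unit_vector(self):
        g = RasterGrid(np.zeros((7, 7)), 10.0, units="degrees")
        northness, eastness, sd = circular_stats(g, radius=20.0)
        np.testing.assert_allclose(northness.values, 1.0, atol=1e-12)
        np.testing.assert_allclose(eastness.values, 0.0, atol=1e-12)
        np.testing.assert_allclose(sd.values, 0.0, atol=1e-6)

    def test_wraparound_mean_of_350_and_10_is_north(self):
        v = np.tile(np.array([[350.0, 10.0]]), (4, 2))
        g = RasterGrid(v, 10.0, units="degrees")
        northness, eastness, _ = circular_stats(g, radius=15.0)
        # neighborhoods mixing 350 and 10 average to 0 (north), never 180
        assert np.nanmin(northness.values) > 0.98
        np.testing.assert_allclose(np.abs(eastness.values).max(), 0.0, atol=0.2)

    def test_uniform_aspects_give_small_resultant_large_sd(self):
        rng = np.random.default_rng(2)
        g = RasterGrid(rng.uniform(0, 360, (21, 21)), 10.0, units="degrees")
        northness, eastness, sd = circular_stats(g, radius=100.0)
        center = np.s_[8:13, 8:13]
        # closed form: uniform directions drive the mean resultant R-bar -> 0,
        # so sd = sqrt(-2 ln R-bar) grows large (> 1 rad for R-bar < 0.61)
        assert np.nanmean(sd.values[center]) > 1.0


class TestDistanceToShore:
    def test_straight_shoreline_distances_are_row_offsets(self):
        shore = LineString([(0, 0), (1000, 0)])
        g = RasterGrid(np.zeros((4, 6)), 50.0, (0.0, -200.0))
        d = distance_to_shore(shore, g)
        np.testing.assert_allclose(d.values[:, 2], [175.0, 125.0, 75.0, 25.0])

    def test_concave_bay_matches_brute_force_nearest_vertex(self):
        shore = LineString([(0, 0), (200, 150), (400, 0)])
        g = RasterGrid(np.zeros((5, 5)), 80.0, (0.0, -400.0))
        d = distance_to_shore(shore, g)
        dense = [shore.interpolate(s) for s in np.linspace(0, shore.length, 20001)]
        dense = np.array([[p.x, p.y] for p in dense])
        xs, ys = g.center_mesh()
        for i in range(5):
            for j in range(5):
                brute = np.min(np.hypot(dense[:, 0] - xs[i, j], dense[:, 1] - ys[i, j]))
                assert d.values[i, j] == pytest.approx(brute, abs=0.05)

    def test_empty_shoreline_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            distance_to_shore(LineString(), RasterGrid(np.zeros((3, 3)), 10.0))


class TestAggregate:
    def test_block_mean_aggregation(self):
        v = np.arange(16, dtype=float).reshape(4, 4)
        g = aggregate_mean(RasterGrid(v, 15.0), factor=2)
        assert g.cell_size == 30.0
        assert g.values[0, 0] == pytest.approx(np.mean(v[:2, :2]))
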