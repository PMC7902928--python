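import numpy as np
import pytest
import shapely
from hypothesis import given, strategies as st
from shapely.geometry import Polygon

import tincanopy as tc
from tincanopy.diffmodel import (DifferenceModel, _hull_polygon, _positive_part,
                                 below_reference_area, canopy_volume,
                                 compare_methods, difference_no_breaklines,
                                 difference_trace_all_triangles, ground_cover)
from tincanopy.surfaces import build_soil_reference, build_tin

from conftest import plane_cloud, square_plot


def _single_face_model(coords, deltas):
    v = np.column_stack([np.asarray(coords, float), np.asarray(deltas, float)])
    poly = Polygon(coords)
    return DifferenceModel("T", "no_breaklines", v, np.array([[0, 1, 2]]), poly)


def _tri_quadrature(coords, deltas, n=400):
    """Midpoint quadrature of the positive part of a linear field on a triangle."""
    a, b, c = (np.asarray(p, float) for p in coords)
    da, db, dc = deltas
    # stratified barycentric midpoints
    i, j = np.meshgrid(np.arange(n), np.arange(n))
    keep = i + j < n
    l1 = (i[keep] + 1 / 3) / n
    l2 = (j[keep] + 1 / 3) / n
    # each (i, j) cell holds two sub-triangles; sample both midpoints
    u1 = (i[keep] + 2 / 3) / n
    u2 = (j[keep] + 2 / 3) / n
    up = (i + j < n - 1)[keep]
    lam = np.concatenate([np.column_stack([l1, l2]),
                          np.column_stack([u1[up], u2[up]])])
    d = da * (1 - lam.sum(1)) + db * lam[:, 0] + dc * lam[:, 1]
    ab, ac = b - a, c - a
    area = 0.5 * abs(ab[0] * ac[1] - ab[1] * ac[0])
    cell = area / (n * n)
    return float(np.sum(np.maximum(d, 0)) * cell), float(np.sum(d > 0) * cell)


class TestDifferenceModels:
    def test_constant_offset_plane(self):
        canopy = build_tin(plane_cloud(0, 0, 10.4, n=800, seed=1))
        soil_ref = build_soil_reference(plane_cloud(0, 0, 10.0, n=400, seed=2), 0.0)
        plot = square_plot()
        for method in (difference_no_breaklines, difference_trace_all_triangles):
            diff = method(canopy, soil_ref, plot)
            np.testing.assert_allclose(diff.delta, 0.4, atol=1e-9)

    def test_identical_surfaces_zero_delta(self):
        cloud = plane_cloud(0.2, -0.1, 30.0, n=500, seed=3)
        canopy = build_tin(cloud)
        soil_ref = build_soil_reference(cloud, 0.0)
        diff = difference_no_breaklines(canopy, soil_ref, square_plot())
        np.testing.assert_allclose(diff.delta, 0.0, atol=1e-9)
        assert canopy_volume(diff) == pytest.approx(0.0, abs=1e-9)

    def test_no_breaklines_carries_interior_canopy_vertices(self, dome_field):
        sc, fd, canopy_tin, soil_ref = dome_field
        plot = fd.plots[0]
        diff = difference_no_breaklines(canopy_tin, soil_ref, plot)
        xy = canopy_tin.vertices[:, :2]
        expected = int(shapely.contains_xy(plot.polygon, xy[:, 0], xy[:, 1]).sum())
        assert len(diff.vertices) == expected  # direct count oracle
        assert len(diff.vertices) <= len(canopy_tin.vertices)

    def test_too_few_vertices_is_an_error(self):
        canopy = build_tin(plane_cloud(0, 0, 1.0, n=50, seed=4))
        soil_ref = build_soil_reference(plane_cloud(0, 0, 0.0, n=50, seed=5), 0.0)
        tiny = square_plot(size=0.01, origin=(0.495, 0.495))
        with pytest.raises(ValueError, match="no canopy surface"):
            difference_no_breaklines(canopy, soil_ref, tiny)


class TestTraceOverlay:
    def test_identical_single_triangles(self):
        cloud = tc.PointCloud([[0, 0, 1.0], [2, 0, 1.0], [0, 2, 1.0]])
        canopy = build_tin(cloud)
        soil_ref = build_soil_reference(cloud, 0.0)
        plot = tc.PlotBoundary("T", Polygon([(0, 0), (2, 0), (0, 2)]))
        diff = difference_trace_all_triangles(canopy, soil_ref, plot)
        assert diff.total_area == pytest.approx(2.0, abs=1e-9)
        np.testing.assert_allclose(diff.delta, 0.0, atol=1e-12)

    def test_crossing_meshes_conserve_area_and_integral(self):
        # canopy z = x + y on a square; soil z = 0.5 on a diamond: the two
        # triangulations cross and delta = x + y - 0.5 changes sign
        canopy = build_tin(tc.PointCloud(
            [[0, 0, 0.0], [1, 0, 1.0], [1, 1, 2.0], [0, 1, 1.0]]))
        soil = build_tin(tc.PointCloud(
            [[0.5, -0.3, 0.5], [1.3, 0.5, 0.5], [0.5, 1.3, 0.5], [-0.3, 0.5, 0.5]]),
            kind="soil_topo")
        soil_ref = soil.raised(0.0, kind="soil_reference")
        plot = square_plot()
        diff = difference_trace_all_triangles(canopy, soil_ref, plot)
        clip = plot.polygon.intersection(_hull_polygon(canopy)).intersection(
            _hull_polygon(soil_ref))
        assert len(diff.triangles) >= 4
        assert diff.total_area == pytest.approx(clip.area, rel=1e-9)
        # independent quadrature of max(0, x + y - 0.5) over the clip region
        res = 0.001
        xs = np.arange(res / 2, 1, res)
        gx, gy = np.meshgrid(xs, xs)
        inside = shapely.contains_xy(clip, gx.ravel(), gy.ravel())
        d = (gx.ravel() + gy.ravel() - 0.5)[inside]
        oracle = np.sum(d[d > 0]) * res * res
        assert canopy_volume(diff) == pytest.approx(oracle, rel=5e-3)

    def test_plot_boundary_inserts_vertices_and_clips(self):
        big = tc.PointCloud([[-1, -1, 1.0], [3, -1, 1.0], [1, 3, 1.0]])
        canopy = build_tin(big)
        soil_ref = build_soil_reference(
            tc.PointCloud([[-1, -1, 0.0], [3, -1, 0.0], [1, 3, 0.0]]), 0.0)
        plot = square_plot()
        diff = difference_trace_all_triangles(canopy, soil_ref, plot)
        clip = plot.polygon.intersection(_hull_polygon(canopy)).intersection(
            _hull_polygon(soil_ref))
        assert diff.total_area == pytest.approx(clip.area, rel=1e-9)
        # boundary vertices were created: the single input triangle had none
        on_boundary = np.isclose(diff.vertices[:, 0], 1.0) | \
            np.isclose(diff.vertices[:, 1], 1.0)
        assert on_boundary.any()

    def test_trace_densifies_the_mesh(self, dome_field):
        sc, fd, canopy_tin, soil_ref = dome_field
        plot = fd.plots[1]
        d_trace = difference_trace_all_triangles(canopy_tin, soil_ref, plot)
        d_plain = difference_no_breaklines(canopy_tin, soil_ref, plot)
        assert len(d_trace.vertices) >= len(d_plain.vertices)


class TestIntegrals:
    def test_uniform_delta_volume(self):
        m = _single_face_model([(0, 0), (2, 0), (0, 2)], [0.5, 0.5, 0.5])
        assert canopy_volume(m) == pytest.approx(1.0)
        assert ground_cover(m) == pytest.approx(2.0)

    def test_linear_prism_mean(self):
        m = _single_face_model([(0, 0), (2, 0), (0, 1)], [0, 0, 3.0])
        assert canopy_volume(m) == pytest.approx(1.0)

    def test_mixed_sign_face_matches_quadrature(self):
        coords = [(0, 0), (3, 0), (0, 2)]
        deltas = [-1.0, -1.0, 2.0]
        m = _single_face_model(coords, deltas)
        qv, qa = _tri_quadrature(coords, deltas, n=1000)
        assert canopy_volume(m) == pytest.approx(qv, rel=1e-3)
        assert ground_cover(m) == pytest.approx(qa, rel=2e-3)

    def test_positive_part_random_faces_match_quadrature(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            coords = rng.uniform(-2, 2, (3, 2))
            ab, ac = coords[1] - coords[0], coords[2] - coords[0]
            if abs(ab[0] * ac[1] - ab[1] * ac[0]) < 0.2:
                continue
            deltas = rng.uniform(-1, 1, 3)
            p = coords[None]
            area = 0.5 * abs(ab[0] * ac[1] - ab[1] * ac[0])
            vol, pos = _positive_part(np.array([area]), deltas[None])
            qv, qa = _tri_quadrature(coords, deltas, n=700)
            assert vol[0] == pytest.approx(qv, rel=3e-3, abs=1e-4)
            assert pos[0] == pytest.approx(qa, rel=5e-3, abs=1e-3)

    def test_all_zero_deltas_have_no_cover(self):
        m = _single_face_model([(0, 0), (1, 0), (0, 1)], [0.0, 0.0, 0.0])
        assert ground_cover(m) == 0.0
        assert canopy_volume(m) == 0.0

    def test_dome_cover_matches_disc_area(self):
        # one isolated dome in a large plot: cover ~ pi r^2
        spec = tc.CanopySpec()  # default full-grown dome
        sc = tc.FieldScenario(n_plots=1, plants_per_plot=1, point_density=10_000,
                              noise_sd_z=0.0, outlier_fraction=0.0, seed=33,
                              canopy_params=[spec])
        fd = tc.generate_field(sc)
        canopy_tin = build_tin(fd.canopy)
        soil_ref = build_soil_reference(fd.bare_soil, sc.ridge_height)
        diff = difference_no_breaklines(canopy_tin, soil_ref, fd.plots[0])
        assert ground_cover(diff) == pytest.approx(np.pi * spec.radius ** 2, rel=0.02)

    @given(st.lists(st.floats(-1, 1), min_size=3, max_size=3),
           st.floats(0, 0.5), st.floats(0, 0.5))
    def test_cover_non_increasing_in_threshold(self, deltas, t1, dt):
        m = _single_face_model([(0, 0), (1, 0), (0, 1)], deltas)
        assert ground_cover(m, t1) >= ground_cover(m, t1 + dt) - 1e-12

    def test_volume_translation_invariant(self):
        coords = np.array([(0.1, 0.2), (1.3, 0.4), (0.5, 1.7)])
        deltas = [-0.5, 0.3, 0.9]
        v0 = canopy_volume(_single_face_model(coords, deltas))
        v1 = canopy_volume(_single_face_model(coords + [120.0, -46.0], deltas))
        assert v1 == pytest.approx(v0, abs=1e-9)

    def test_positive_and_negative_areas_partition(self):
        m = _single_face_model([(0, 0), (2, 0), (0, 2)], [-1.0, 0.5, 1.5])
        total = m.total_area
        assert ground_cover(m) + below_reference_area(m) == pytest.approx(total, abs=1e-9)


class TestCompareMethods:
    def test_requires_three_plots(self, dome_field):
        sc, fd, canopy_tin, soil_ref = dome_field
        with pytest.raises(ValueError, match="3 plots"):
            compare_methods([(canopy_tin, soil_ref, fd.plots[0])])

    def test_zero_variance_reports_nan(self):
        cloud = plane_cloud(0, 0, 5.0, n=800, lo=-1, hi=4, seed=34)
        canopy = build_tin(cloud)
        soil_ref = build_soil_reference(cloud, 0.0)  # delta identically 0
        plots = [square_plot(f"P{i}", size=0.8, origin=(i * 1.1, 0.2))
                 for i in range(3)]
        r, va, vb = compare_methods([(canopy, soil_ref, p) for p in plots])
        assert np.isnan(r)
        np.testing.assert_allclose(va, 0.0, atol=1e-9)

    def test_three_graded_plots_rank_perfectly(self):
        sc = tc.FieldScenario(n_plots=3, point_density=700, noise_sd_z=0.005,
                              outlier_fraction=0.0, plot_margin_x=0.45, seed=35,
                              canopy_params=tc.volume_ladder_params(3, 0.01, 0.08))
        fd = tc.generate_field(sc)
        canopy_tin = build_tin(fd.canopy)
        soil_ref = build_soil_reference(fd.bare_soil, sc.ridge_height)
        r, va, vb = compare_methods([(canopy_tin, soil_ref, p) for p in fd.plots])
        assert r == pytest.approx(1.0)
        assert np.all(np.diff(va) > 0) and np.all(np.diff(vb) > 0)
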