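import numpy as np
import pytest
from shapely.geometry import Polygon

import tincanopy as tc
from tincanopy.diffmodel import canopy_volume, difference_no_breaklines
from tincanopy.metrics import (compute_metrics, hard_cap_filter,
                               height_histogram, sample_height_field,
                               sd_cleanup, validate_against_ground_truth)
from tincanopy.surfaces import build_soil_reference, build_tin

from conftest import plane_cloud, square_plot


def _field(values, plot_id="P1", res=0.01, provenance="pre_cleanup"):
    return tc.HeightField(plot_id, (0.0, 0.0), res, np.asarray(values, float),
                          provenance=provenance)


@pytest.fixture(scope="module")
def flat_diff():
    """Difference model with uniform delta 0.4 covering a small plot."""
    canopy = build_tin(plane_cloud(0, 0, 10.4, n=900, lo=-0.3, hi=0.5, seed=41))
    soil_ref = build_soil_reference(
        plane_cloud(0, 0, 10.0, n=300, lo=-0.3, hi=0.5, seed=42), 0.0)
    plot = square_plot(size=0.1)
    return difference_no_breaklines(canopy, soil_ref, plot), plot


class TestSampleHeightField:
    def test_uniform_plot_grid(self, flat_diff):
        diff, plot = flat_diff
        field = sample_height_field(diff, plot, resolution=0.01)
        assert field.values.shape == (10, 10)
        valid = field.valid_values()
        assert len(valid) > 0
        np.testing.assert_allclose(valid, 0.4, atol=1e-9)

    def test_cells_outside_polygon_missing(self, flat_diff):
        diff, _ = flat_diff
        tri_plot = tc.PlotBoundary("T", Polygon([(0, 0), (0.1, 0), (0, 0.1)]))
        field = sample_height_field(diff, tri_plot, resolution=0.01)
        # roughly half the bounding box lies outside the triangle
        assert np.isnan(field.values).sum() >= 40

    def test_resolution_bounds(self, flat_diff):
        diff, plot = flat_diff
        with pytest.raises(ValueError, match="resolution"):
            sample_height_field(diff, plot, resolution=0.5)

    def test_grid_integral_consistent_with_exact_volume(self, dome_diff):
        fd, plot, diff, field = dome_diff
        vals = field.valid_values()
        grid_volume = vals[vals > 0].sum() * field.cell_area
        assert grid_volume == pytest.approx(canopy_volume(diff), rel=0.01)


class TestHardCap:
    def test_values_above_cap_removed(self):
        field = _field([[1.3, 0.5], [1.2, 0.9]])
        capped = hard_cap_filter(field, cap=1.2)
        assert np.isnan(capped.values[0, 0])  # 1.3 strictly above the cap
        assert capped.values[1, 0] == 1.2  # exactly at the cap is retained
        assert capped.provenance == "hard_capped"

    def test_identity_when_all_below(self):
        field = _field([[0.1, 0.2], [0.3, 0.4]])
        capped = hard_cap_filter(field)
        np.testing.assert_array_equal(capped.values, field.values)


class TestSdCleanup:
    def test_single_spike_removed_at_3sd(self):
        values = np.full(100, 0.5)
        values[17] = 1.1
        field = _field(values.reshape(10, 10))
        cleaned = sd_cleanup(field, k=3)
        # oracle arithmetic: mean 0.506, sd(ddof=1) ~ 0.06, cutoff ~ 0.686
        mean, sd = values.mean(), values.std(ddof=1)
        assert 1.1 > mean + 3 * sd
        assert cleaned.n_valid == 99
        assert np.nanmax(cleaned.values) == pytest.approx(0.5)
        assert cleaned.sd_cutoff == 3

    def test_constant_field_unchanged(self):
        field = _field(np.full((5, 5), 0.3))
        cleaned = sd_cleanup(field, k=2)
        assert cleaned.n_valid == 25

    def test_stricter_cutoff_removes_superset(self):
        rng = np.random.default_rng(44)
        values = rng.lognormal(-1, 0.6, (30, 30))
        field = _field(values)
        removed = {}
        for k in (2, 2.5, 3):
            cleaned = sd_cleanup(field, k=k)
            removed[k] = set(zip(*np.where(np.isnan(cleaned.values))))
        assert removed[3] <= removed[2.5] <= removed[2]

    def test_cleanup_never_creates_values(self):
        rng = np.random.default_rng(45)
        values = rng.uniform(0, 2, (20, 20))
        values[rng.uniform(size=(20, 20)) < 0.2] = np.nan
        field = _field(values)
        for filtered in (hard_cap_filter(field), sd_cleanup(field, k=2.5)):
            was_missing = np.isnan(field.values)
            assert np.all(np.isnan(filtered.values[was_missing]))

    def test_too_few_values_error(self):
        with pytest.raises(ValueError):
            sd_cleanup(_field([[0.5, np.nan], [np.nan, np.nan]]), k=3)


class TestHistogram:
    def test_single_level(self):
        field = _field(np.full((10, 10), 0.5))
        hist = height_histogram(field, bin_width=0.02)
        assert hist.area_per_bin.sum() == pytest.approx(0.01)
        assert (hist.area_per_bin > 0).sum() == 1
        assert hist.total_area == pytest.approx(0.01)

    def test_empty_field(self):
        hist = height_histogram(_field(np.full((3, 3), np.nan)))
        assert hist.total_area == 0.0
        assert hist.area_per_bin.sum() == 0.0

    def test_two_plateaus_area_ratio(self):
        values = np.concatenate([np.full(30, 0.10), np.full(60, 0.50),
                                 np.full(10, np.nan)])
        hist = height_histogram(_field(values.reshape(10, 10)))
        occupied = hist.area_per_bin[hist.area_per_bin > 0]
        assert len(occupied) == 2
        assert occupied[1] / occupied[0] == pytest.approx(2.0)

    def test_area_conservation(self, dome_diff):
        fd, plot, diff, field = dome_diff
        hist = height_histogram(field)
        covered = (field.valid_values() > 0).sum() * field.cell_area
        assert hist.area_per_bin.sum() == pytest.approx(covered, abs=field.cell_area)

    def test_quantiles_from_known_distribution(self):
        hist = tc.HeightHistogram(np.array([0.0, 0.2, 0.4]),
                                  np.array([0.5, 0.5]), 1.0)
        assert hist.quantile(0.5) == pytest.approx(0.2)
        np.testing.assert_allclose(hist.quantile([0.25, 0.75]), [0.1, 0.3])


class TestComputeMetrics:
    def test_uniform_field(self, flat_diff):
        diff, plot = flat_diff
        field = sample_height_field(diff, plot)
        m = compute_metrics(field, diff, field, date="2018-06-20")
        assert m.max_height == pytest.approx(0.4, abs=1e-9)
        assert m.mean_height == pytest.approx(0.4, abs=1e-9)
        assert m.pct_points_removed == 0.0

    def test_removed_percentage_arithmetic(self):
        pre = _field(np.full((100, 100), 0.5))
        post_vals = np.full((100, 100), 0.5)
        post_vals.ravel()[:100] = np.nan
        post = _field(post_vals, provenance="sd_cleaned")
        m = compute_metrics(post, _dummy_diff(), pre)
        assert m.pct_points_removed == pytest.approx(1.0)

    def test_no_canopy_flagged(self):
        empty = _field(np.full((4, 4), np.nan))
        m = compute_metrics(empty, _dummy_diff(), empty)
        assert m.no_canopy and m.max_height == 0.0

    def test_dome_metrics_match_generator_truth(self, dome_diff):
        fd, plot, diff, field = dome_diff
        truth = fd.truth.per_plot[plot.plot_id]
        m = compute_metrics(field, diff, field)
        assert m.max_height == pytest.approx(truth.true_max_height, abs=0.01)
        assert m.volume_m3 == pytest.approx(truth.true_volume, rel=0.03)


def _dummy_diff():
    from tincanopy.diffmodel import DifferenceModel

    v = np.array([[0, 0, 0.0], [1, 0, 0.0], [0, 1, 0.0]])
    return DifferenceModel("P1", "no_breaklines", v, np.array([[0, 1, 2]]),
                           Polygon([(0, 0), (1, 0), (0, 1)]))


class TestSpikeFlagging:
    def test_lone_spike_flagged_canopy_kept(self):
        rng = np.random.default_rng(55)
        xy = rng.uniform(0, 2, (500, 2))
        z = 0.3 + rng.normal(0, 0.02, 500)
        z[7] = 1.6  # a weed / reconstruction error towering over neighbors
        from tincanopy.metrics import flag_isolated_spikes

        flags = flag_isolated_spikes(tc.PointCloud(np.column_stack([xy, z])))
        assert flags[7]
        assert flags.sum() == 1

    def test_dense_tall_canopy_not_flagged(self):
        # a tall but spatially coherent canopy region is kept
        rng = np.random.default_rng(56)
        xy = rng.uniform(0, 1, (400, 2))
        z = np.where(xy[:, 0] > 0.5, 0.9, 0.2)
        from tincanopy.metrics import flag_isolated_spikes

        assert not flag_isolated_spikes(tc.PointCloud(np.column_stack([xy, z]))).any()


class TestGroundTruthValidation:
    def _metrics(self, heights, dates=None):
        return [tc.CanopyMetrics(plot_id=f"P{i}", date=(dates or "d")[0] if False else "d",
                                 max_height=h, mean_height=h * 0.8,
                                 ground_cover_m2=1.0, volume_m3=h)
                for i, h in enumerate(heights)]

    def _truth(self, heights):
        return [tc.GroundTruthRecord(plot_id=f"P{i}", date="d", max_height_field=h)
                for i, h in enumerate(heights)]

    def test_identity_recovers_unit_slope(self):
        h = np.linspace(0.2, 0.8, 10)
        s = validate_against_ground_truth(self._metrics(h), self._truth(h))
        assert s.slope == pytest.approx(1.0, abs=1e-9)
        assert s.r2_adj == pytest.approx(1.0, abs=1e-9)
        assert s.spearman_r == pytest.approx(1.0)

    def test_known_slope_recovered_under_noise(self):
        rng = np.random.default_rng(46)
        field_h = rng.uniform(0.2, 0.9, 100)
        uav_h = 0.85 * field_h + rng.normal(0, 0.02, 100)
        s = validate_against_ground_truth(self._metrics(uav_h), self._truth(field_h))
        # 95% CI half-width for the OLS slope at this noise level is ~0.02
        assert s.slope == pytest.approx(0.85, abs=0.03)
        assert s.n == 100 and s.p_value < 0.01

    def test_constant_truth_undefined(self):
        h = np.full(5, 0.5)
        s = validate_against_ground_truth(self._metrics(h), self._truth(h))
        assert np.isnan(s.r2_adj)

    def test_no_matches_error(self):
        with pytest.raises(ValueError):
            validate_against_ground_truth(self._metrics([1, 2, 3]), [])
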