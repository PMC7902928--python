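import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from shapely.geometry import Polygon

import tincanopy as tc
from tincanopy.surfaces import build_soil_reference, build_tin

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def plane_cloud(a: float, b: float, c: float, n: int = 600,
                lo: float = -0.5, hi: float = 1.5, seed: int = 0) -> tc.PointCloud:
    """Random cloud sampling the plane z = a x + b y + c."""
    rng = np.random.default_rng(seed)
    xy = rng.uniform(lo, hi, (n, 2))
    z = a * xy[:, 0] + b * xy[:, 1] + c
    return tc.PointCloud(np.column_stack([xy, z]))


def square_plot(plot_id: str = "P1", size: float = 1.0,
                origin: tuple[float, float] = (0.0, 0.0)) -> tc.PlotBoundary:
    x0, y0 = origin
    return tc.PlotBoundary(plot_id, Polygon(
        [(x0, y0), (x0 + size, y0), (x0 + size, y0 + size), (x0, y0 + size)]))


@pytest.fixture(scope="session")
def dome_field():
    """Noise-free two-plot cap-dome field with surfaces already built."""
    sc = tc.FieldScenario(
        n_plots=2, point_density=2500, noise_sd_z=0.0, outlier_fraction=0.0,
        plot_margin_x=0.45, seed=101,
        canopy_params=[tc.CanopySpec("dome", 0.35, 0.40),
                       tc.CanopySpec("dome", 0.25, 0.30)])
    fd = tc.generate_field(sc)
    canopy_tin = build_tin(fd.canopy, kind="canopy")
    soil_ref = build_soil_reference(fd.bare_soil, sc.ridge_height)
    return sc, fd, canopy_tin, soil_ref


@pytest.fixture(scope="session")
def dome_diff(dome_field):
    """Difference model and height field for the first dome plot."""
    from tincanopy.diffmodel import difference_no_breaklines
    from tincanopy.metrics import sample_height_field

    sc, fd, canopy_tin, soil_ref = dome_field
    plot = fd.plots[0]
    diff = difference_no_breaklines(canopy_tin, soil_ref, plot)
    field = sample_height_field(diff, plot)
    return fd, plot, diff, field
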