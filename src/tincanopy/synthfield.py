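"""Synthetic ridged-field scenarios with analytic ground truth.

Emulates the geometry of a ridged potato trial — rows of soil ridges
0.90 m apart, plots of 3 plants spaced 0.35 m along the ridge, dome-,
box- or pyramid-shaped canopies — together with the properties of an
SfM-derived point cloud: the cloud samples the *upper envelope* of soil
and vegetation (nothing below the canopy is seen), carries Gaussian
vertical noise, and contains sparse tall outliers standing in for weeds
and reconstruction errors.

Every scenario also yields analytic per-plot truth (volume, cover, max
and mean height above the raised soil reference) computed in closed form
where the plant shapes are disjoint and by fine independent quadrature of
the generating surface otherwise — never via the pipeline under test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from shapely.geometry import Polygon as ShapelyPolygon

from .io import PlotBoundary, PointCloud
from .metrics import CanopyMetrics, HeightHistogram

log = logging.getLogger(__name__)

Shape = Literal["dome", "box", "pyramid"]


@dataclass
class CanopySpec:
    """One plant shape: a dome, box or square pyramid.

    ``radius`` is the footprint half-extent: the dome base radius, or the
    half-side for box and pyramid.  A dome with height <= radius is a
    spherical cap (volume pi*h*(3a^2 + h^2)/6); a taller dome is a
    hemisphere of radius a on a cylinder of height h - a, so the shape
    stays a single-valued upper envelope with an exact closed form.
    """

    shape: Shape = "dome"
    height: float = 0.35
    radius: float = 0.40

    def footprint_area(self) -> float:
        if self.height <= 0 or self.radius <= 0:
            return 0.0
        if self.shape == "dome":
            return np.pi * self.radius ** 2
        return 4.0 * self.radius ** 2

    def volume(self) -> float:
        h, a = self.height, self.radius
        if h <= 0 or a <= 0:
            return 0.0
        if self.shape == "dome":
            if h <= a:  # spherical cap
                return np.pi * h * (3 * a ** 2 + h ** 2) / 6.0
            return np.pi * a ** 2 * (h - a) + 2.0 * np.pi * a ** 3 / 3.0
        if self.shape == "box":
            return 4.0 * a ** 2 * h
        return 4.0 * a ** 2 * h / 3.0  # pyramid

    def profile(self, dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
        """Canopy height above its base at planimetric offsets from the stem."""
        h, a = self.height, self.radius
        if h <= 0 or a <= 0:
            return np.zeros(np.broadcast(dx, dy).shape)
        if self.shape == "dome":
            r2 = dx ** 2 + dy ** 2
            if h <= a:
                big_r = (a ** 2 + h ** 2) / (2.0 * h)
                z = np.sqrt(np.maximum(big_r ** 2 - r2, 0.0)) - (big_r - h)
            else:
                z = (h - a) + np.sqrt(np.maximum(a ** 2 - r2, 0.0))
            return np.where(r2 < a ** 2, np.maximum(z, 0.0), 0.0)
        d = np.maximum(np.abs(dx), np.abs(dy))
        if self.shape == "box":
            return np.where(d < a, h, 0.0)
        return np.where(d < a, h * (1.0 - d / a), 0.0)


@dataclass
class FieldScenario:
    """Layout and sampling conditions for one synthetic field.

    Defaults follow the trial geometry this generator emulates: 0.90 m
    row spacing, 3 plants per plot at 0.35 m, and a point density of
    10,000 pts/m² (one point per cm², matching ~1 cm ground sample
    distance imagery).  Noise and outlier defaults are modest values
    representative of SfM clouds; pass 0 for idealized scenarios.
    """

    n_plots: int = 4
    row_spacing: float = 0.90
    plant_spacing: float = 0.35
    plants_per_plot: int = 3
    ridge_height: float = 0.20
    ridge_profile: Literal["sinusoid", "trapezoid"] = "sinusoid"
    soil_tilt: tuple[float, float] = (0.01, -0.005)
    base_elevation: float = 50.0
    canopy_params: Sequence[CanopySpec] | None = None
    noise_sd_z: float = 0.01
    outlier_fraction: float = 0.002
    outlier_height_range: tuple[float, float] = (0.8, 1.5)
    point_density: float = 10_000.0
    bare_soil_density: float = 400.0
    plots_per_row: int = 10
    plot_margin_x: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.point_density <= 0 or self.bare_soil_density <= 0:
            raise ValueError("point densities must be positive")
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must lie in [0, 1)")
        if self.ridge_height < 0:
            raise ValueError("ridge_height must be non-negative")


@dataclass
class PlotTruth:
    true_volume: float
    true_cover: float
    true_max_height: float
    true_mean_height: float


@dataclass
class SyntheticTruth:
    per_plot: dict[str, PlotTruth]
    ridge_height: float
    soil_plane: tuple[float, float, float]  # z = c + a x + b y


@dataclass
class FieldData:
    canopy: PointCloud
    bare_soil: PointCloud
    plots: list[PlotBoundary]
    truth: SyntheticTruth
    crest_lines: list[np.ndarray] = field(default_factory=list)


# ---------------------------------------------------------------------------
# generating surfaces


class _FieldSurface:
    """Closed-form generating surface: soil plane, ridges, plant envelope."""

    def __init__(self, scenario: FieldScenario):
        self.sc = scenario
        k = scenario.plants_per_plot
        self.plot_len = (k - 1) * scenario.plant_spacing + 2 * scenario.plot_margin_x
        self.pitch_x = (k - 1) * scenario.plant_spacing + 0.90  # 90 cm between plots
        n_cols = min(scenario.plots_per_row, scenario.n_plots)
        n_rows = int(np.ceil(scenario.n_plots / n_cols))
        self.plot_centers: list[tuple[float, float]] = []
        for j in range(scenario.n_plots):
            col, row = j % n_cols, j // n_cols
            self.plot_centers.append((col * self.pitch_x, row * scenario.row_spacing))
        xs = [c[0] for c in self.plot_centers]
        ys = [c[1] for c in self.plot_centers]
        margin = 1.0 + scenario.row_spacing
        self.bounds = (min(xs) - self.plot_len / 2 - margin,
                       min(ys) - margin,
                       max(xs) + self.plot_len / 2 + margin,
                       max(ys) + margin)
        if scenario.canopy_params is not None:
            if len(scenario.canopy_params) != scenario.n_plots:
                raise ValueError("canopy_params must have one entry per plot")
            self.canopies = list(scenario.canopy_params)
        else:
            rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 17]))
            self.canopies = random_canopy_params(scenario.n_plots, rng)
        # stem positions per plot
        self.plants: list[list[tuple[float, float]]] = []
        for (cx, cy) in self.plot_centers:
            x0 = cx - (k - 1) * scenario.plant_spacing / 2.0
            self.plants.append([(x0 + i * scenario.plant_spacing, cy) for i in range(k)])
        self.n_ridge_rows = n_rows

    def plot_polygons(self) -> list[PlotBoundary]:
        out = []
        w = self.sc.row_spacing / 2.0
        for j, (cx, cy) in enumerate(self.plot_centers):
            half = self.plot_len / 2.0
            poly = ShapelyPolygon([(cx - half, cy - w), (cx + half, cy - w),
                                   (cx + half, cy + w), (cx - half, cy + w)])
            out.append(PlotBoundary(plot_id=f"P{j + 1:03d}", polygon=poly,
                                    variety=f"V{j + 1:03d}", block="B1"))
        return out

    def soil_base(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        a, b = self.sc.soil_tilt
        return self.sc.base_elevation + a * x + b * y

    def _crest_offset(self, y: np.ndarray) -> np.ndarray:
        rs = self.sc.row_spacing
        return np.mod(y + rs / 2.0, rs) - rs / 2.0

    def ridge_bump(self, y: np.ndarray) -> np.ndarray:
        """Ridge height above the soil base as a function of y (crest = max)."""
        rs, rh = self.sc.row_spacing, self.sc.ridge_height
        u = np.abs(self._crest_offset(y))
        w = 0.6 * rs
        if self.sc.ridge_profile == "sinusoid":
            bump = rh * np.cos(np.pi * u / w) ** 2
            return np.where(u < w / 2.0, bump, 0.0)
        crest_w, base_w = 0.15 * rs, 0.30 * rs  # trapezoid
        slope = rh / (base_w - crest_w)
        return np.clip((base_w - u) * slope, 0.0, rh)

    def in_furrow(self, y: np.ndarray) -> np.ndarray:
        return np.abs(self._crest_offset(y)) >= 0.31 * self.sc.row_spacing

    def delta_true(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Noise-free canopy-minus-reference height of the upper envelope."""
        delta = self.ridge_bump(y) - self.sc.ridge_height
        for spec, plants in zip(self.canopies, self.plants):
            for (px, py) in plants:
                near = (np.abs(x - px) <= spec.radius) & (np.abs(y - py) <= spec.radius)
                if np.any(near):
                    f = spec.profile(x[near] - px, y[near] - py)
                    # the plant surface only exists where its profile is
                    # positive; elsewhere the ground shows through
                    delta[near] = np.where(f > 0, np.maximum(delta[near], f),
                                           delta[near])
        return delta

    def canopy_z(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return self.soil_base(x, y) + self.sc.ridge_height + self.delta_true(x, y)

    def in_any_footprint(self, x: np.ndarray, y: np.ndarray, pad: float = 0.05) -> np.ndarray:
        hit = np.zeros(x.shape, dtype=bool)
        for spec, plants in zip(self.canopies, self.plants):
            for (px, py) in plants:
                r = spec.radius + pad
                hit |= (np.abs(x - px) <= r) & (np.abs(y - py) <= r)
        return hit

    def crest_lines(self) -> list[np.ndarray]:
        """Crest polylines on bare ridge segments (the margins beside the
        plots), where the ridge top is not hidden by canopy."""
        x0, _, x1, _ = self.bounds
        half = self.plot_len / 2.0
        xs_min = min(cx for cx, _ in self.plot_centers) - half
        xs_max = max(cx for cx, _ in self.plot_centers) + half
        lines = []
        for cy in sorted({cy for (_, cy) in self.plot_centers}):
            for a, b in ((x0 + 0.3, xs_min - 0.3), (xs_max + 0.3, x1 - 0.3)):
                if b - a >= 0.6:
                    lines.append(np.array([[a, cy], [b, cy]]))
        return lines


def random_canopy_params(n: int, rng: np.random.Generator) -> list[CanopySpec]:
    """Varied random canopies: shape uniform, h in [0.15, 0.6], r in [0.1, 0.3]."""
    shapes = np.array(["dome", "box", "pyramid"])
    return [CanopySpec(shape=str(rng.choice(shapes)),
                       height=float(rng.uniform(0.15, 0.6)),
                       radius=float(rng.uniform(0.10, 0.30))) for _ in range(n)]


def volume_ladder_params(n: int, v_min: float = 0.004, v_max: float = 0.09
                         ) -> list[CanopySpec]:
    """Canopies with distinct analytic volumes on a geometric ladder.

    Shapes cycle dome/box/pyramid; each plant's size is solved from its
    target volume at a fixed height-to-radius aspect, so consecutive plot
    volumes differ by a constant factor and ranks are unambiguous.
    """
    targets = np.geomspace(v_min, v_max, n)
    out = []
    for i, v in enumerate(targets):
        shape = ("dome", "box", "pyramid")[i % 3]
        if shape == "dome":
            c = 0.55  # r = c*h < h: capsule dome, V = pi*h^3*c^2*(1 - c/3)
            h = (v / (np.pi * c ** 2 * (1.0 - c / 3.0))) ** (1 / 3)
        elif shape == "box":
            c = 0.55
            h = (v / (4 * c ** 2)) ** (1 / 3)
        else:
            c = 0.50
            h = (3.0 * v / (4 * c ** 2)) ** (1 / 3)
        out.append(CanopySpec(shape=shape, height=float(h), radius=float(c * h)))
    return out


# ---------------------------------------------------------------------------
# truth


def _plot_truth(surface: _FieldSurface, plot: PlotBoundary, spec: CanopySpec,
                plants: list[tuple[float, float]],
                resolution: float | None = None) -> PlotTruth:
    """Analytic truth for one plot; quadrature of the generating surface.

    Closed forms are used (and cross-checked against the quadrature)
    when the plant footprints are pairwise disjoint and inside the plot;
    overlapping canopies fall back to the quadrature value.  The grid is
    at most 5 mm and refines further for small plants so the midpoint
    rule resolves the footprint boundary.
    """
    if resolution is None:
        resolution = float(min(0.005, max(0.0015, spec.radius / 50.0)))
    minx, miny, maxx, maxy = plot.polygon.bounds
    xs = np.arange(minx + resolution / 2, maxx, resolution)
    ys = np.arange(miny + resolution / 2, maxy, resolution)
    gx, gy = np.meshgrid(xs, ys)
    delta = surface.delta_true(gx.ravel(), gy.ravel())
    pos = delta > 0
    cell = resolution ** 2
    q_vol = float(delta[pos].sum() * cell)
    q_cover = float(pos.sum() * cell)
    q_max = float(delta.max()) if delta.size else 0.0

    k = len(plants)
    disjoint = all(
        max(abs(plants[i][0] - plants[j][0]), abs(plants[i][1] - plants[j][1]))
        >= 2 * spec.radius
        for i in range(k) for j in range(i + 1, k))
    contained = all(
        plot.polygon.buffer(1e-9).contains(
            ShapelyPolygon([(px - spec.radius, py - spec.radius),
                            (px + spec.radius, py - spec.radius),
                            (px + spec.radius, py + spec.radius),
                            (px - spec.radius, py + spec.radius)]))
        for (px, py) in plants)
    if disjoint and contained:
        vol = k * spec.volume()
        cover = k * spec.footprint_area()
        if abs(vol - q_vol) > 0.005 * max(vol, 1e-9):
            raise RuntimeError(
                f"plot {plot.plot_id}: closed-form volume {vol:.6f} disagrees with "
                f"quadrature {q_vol:.6f}")
    else:
        vol, cover = q_vol, q_cover
    return PlotTruth(true_volume=vol, true_cover=cover,
                     true_max_height=spec.height if spec.height > 0 else q_max,
                     true_mean_height=vol / cover if cover > 0 else 0.0)


# ---------------------------------------------------------------------------
# generation


def generate_field(scenario: FieldScenario) -> FieldData:
    """Generate one flight over a synthetic ridged field.

    Returns the canopy cloud (upper envelope + noise + outliers), the
    bare-soil cloud (furrow ground only), plot boundaries and analytic
    truth.  Deterministic given ``scenario.seed``.
    """
    surface = _FieldSurface(scenario)
    plots = surface.plot_polygons()
    for i, a in enumerate(plots):
        for b in plots[i + 1:]:
            if a.polygon.intersection(b.polygon).area > 1e-12:
                raise ValueError(f"plots {a.plot_id} and {b.plot_id} overlap")
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))
    x0, y0, x1, y1 = surface.bounds
    area = (x1 - x0) * (y1 - y0)

    n_canopy = int(round(scenario.point_density * area))
    cx = rng.uniform(x0, x1, n_canopy)
    cy = rng.uniform(y0, y1, n_canopy)
    cz = surface.canopy_z(cx, cy)
    if scenario.noise_sd_z > 0:
        cz = cz + rng.normal(0.0, scenario.noise_sd_z, n_canopy)
    if scenario.outlier_fraction > 0:
        n_out = int(scenario.outlier_fraction * n_canopy)
        idx = rng.choice(n_canopy, size=n_out, replace=False)
        lo, hi = scenario.outlier_height_range
        cz[idx] = (surface.soil_base(cx[idx], cy[idx]) + scenario.ridge_height
                   + rng.uniform(lo, hi, n_out))
    canopy = PointCloud(np.column_stack([cx, cy, cz]), source_label="synthetic-canopy")

    n_soil = int(round(scenario.bare_soil_density * area))
    sx = rng.uniform(x0, x1, n_soil)
    sy = rng.uniform(y0, y1, n_soil)
    keep = surface.in_furrow(sy) & ~surface.in_any_footprint(sx, sy)
    sx, sy = sx[keep], sy[keep]
    sz = surface.soil_base(sx, sy)
    if scenario.noise_sd_z > 0:
        sz = sz + rng.normal(0.0, scenario.noise_sd_z, len(sz))
    bare_soil = PointCloud(np.column_stack([sx, sy, sz]), source_label="synthetic-soil")

    per_plot = {
        plot.plot_id: _plot_truth(surface, plot, spec, plants)
        for plot, spec, plants in zip(plots, surface.canopies, surface.plants)
    }
    a, b = scenario.soil_tilt
    truth = SyntheticTruth(per_plot=per_plot, ridge_height=scenario.ridge_height,
                           soil_plane=(scenario.base_elevation, a, b))
    log.info("generated field: %d canopy pts, %d soil pts, %d plots",
             len(canopy), len(bare_soil), len(plots))
    return FieldData(canopy=canopy, bare_soil=bare_soil, plots=plots, truth=truth,
                     crest_lines=surface.crest_lines())


# -- season trajectories -----------------------------------------------------

#: anchor curves (season fraction -> h and r scale factors) per trajectory
_TRAJECTORIES = {
    "early_maturing": {
        "p": [0.0, 0.33, 0.66, 1.0],
        "h": [0.30, 1.00, 0.45, 0.02],
        "r": [0.40, 1.00, 0.60, 0.10],
    },
    "late_maturing": {
        "p": [0.0, 0.33, 0.66, 1.0],
        "h": [0.25, 0.55, 0.85, 1.00],
        "r": [0.30, 0.60, 0.85, 1.00],
    },
    "lodging_then_regrow": {
        "p": [0.0, 0.33, 0.66, 1.0],
        "h": [0.40, 1.00, 0.60, 0.90],
        "r": [0.50, 0.85, 1.00, 1.15],
    },
}


@dataclass
class FlightData(FieldData):
    dap: float = 0.0


def generate_season(scenario: FieldScenario,
                    trajectory: Literal["early_maturing", "late_maturing",
                                        "lodging_then_regrow"],
                    n_flights: int = 4,
                    dap_list: Sequence[float] | None = None) -> list[FlightData]:
    """A season of flights whose canopies evolve along a maturity template.

    Early-maturing canopies grow fast and collapse to near zero by the
    final flight; late-maturing ones grow monotonically; the lodging
    template drops height >= 30% at an intermediate flight while the
    footprint keeps spreading, then regrows.  Deterministic per seed.
    """
    if n_flights < 2:
        raise ValueError("need at least 2 flights")
    if trajectory not in _TRAJECTORIES:
        raise ValueError(f"unknown trajectory {trajectory!r}")
    if dap_list is None:
        dap_list = list(np.linspace(33, 117, n_flights))
    if len(dap_list) != n_flights:
        raise ValueError("dap_list length must equal n_flights")
    curve = _TRAJECTORIES[trajectory]
    base = _FieldSurface(scenario).canopies  # resolve per-plot base canopies once
    flights = []
    p = np.linspace(0.0, 1.0, n_flights)
    for i, dap in enumerate(dap_list):
        h_scale = float(np.interp(p[i], curve["p"], curve["h"]))
        r_scale = float(np.interp(p[i], curve["p"], curve["r"]))
        params = [replace(spec, height=spec.height * h_scale,
                          radius=spec.radius * r_scale) for spec in base]
        flight_sc = replace(scenario, canopy_params=params,
                            seed=scenario.seed + 1000 + i)
        fd = generate_field(flight_sc)
        flights.append(FlightData(canopy=fd.canopy, bare_soil=fd.bare_soil,
                                  plots=fd.plots, truth=fd.truth,
                                  crest_lines=fd.crest_lines, dap=float(dap)))
    return flights


# -- metric-level pattern transitions ---------------------------------------


def simulate_pattern_transition(label: str, rng: np.random.Generator,
                                noise_sd: float = 0.015,
                                n_cells: int = 2000,
                                cell_area: float = 1e-4,
                                bin_width: float = 0.02
                                ) -> tuple[CanopyMetrics, CanopyMetrics]:
    """Two-date canopy metrics embodying one growth pattern, with noise.

    Cell heights at date 1 are uniform on [0.05, 0.45] m; the pattern is
    imposed as a transform of the height distribution and covered-cell
    count, then multiplicative Gaussian noise (default 1.5%) is applied
    per cell and per summary metric.  Used to exercise the classifier
    against known generating labels.
    """
    h1 = rng.uniform(0.05, 0.45, n_cells)
    if label == "sideways_growth":
        h2 = rng.uniform(0.05, 0.45, int(1.30 * n_cells))
    elif label == "vertical_pyramid_growth":
        h2 = h1 + 0.02 + 0.28 * ((h1 - 0.05) / 0.40) ** 2
    elif label == "vertical_even_growth":
        h2 = h1 + 0.08
    elif label == "vertical_even_growth_raised_base":
        h2 = h1 + 0.25
    elif label == "lodging":
        h2 = rng.choice(h1 * 0.60, size=int(1.15 * n_cells), replace=True)
    elif label == "senescence":
        h2 = rng.choice(h1 * 0.50, size=int(0.50 * n_cells), replace=False)
    elif label == "no_change":
        h2 = h1.copy()
    else:
        raise ValueError(f"unknown pattern label {label!r}")

    def _metrics(heights: np.ndarray, date: float) -> CanopyMetrics:
        noisy = heights * (1.0 + rng.normal(0.0, noise_sd, len(heights)))
        noisy = np.maximum(noisy, 1e-4)
        n_bins = max(1, int(np.ceil(noisy.max() / bin_width)))
        edges = np.arange(n_bins + 1) * bin_width
        counts, _ = np.histogram(noisy, bins=edges)
        total = len(noisy) * cell_area
        hist = HeightHistogram(edges, counts * cell_area, total)
        jitter = 1.0 + rng.normal(0.0, noise_sd, 4)
        cover = total * jitter[0]
        return CanopyMetrics(
            plot_id="SIM", date=date,
            max_height=float(noisy.max() * jitter[1]),
            mean_height=float(noisy.mean() * jitter[2]),
            ground_cover_m2=float(cover),
            volume_m3=float(noisy.mean() * total * jitter[3]),
            histogram=hist, n_points=len(noisy))

    return _metrics(h1, 1.0), _metrics(h2, 2.0)
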