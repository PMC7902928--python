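"""Plot-level height fields, outlier cleanup and canopy metrics.

The difference model gives canopy height above the soil reference at any
point of a plot; sampling it on a regular 1-cm grid yields the plot's
height field, from which the height distribution, maximum and average
height are derived.  Cleanup is two-stage, mirroring how impossible and
improbable points are removed in practice:

1. a hard cap — every height strictly above 1.2 m is discarded, because
   potato plants do not reach that height, so anything taller is a weed or
   a reconstruction artifact;
2. a statistical cut — heights above the plot mean plus k standard
   deviations (k = 3 recommended; 2 and 2.5 are stricter alternatives that
   risk trimming real canopy) are discarded in a single pass.

The average height is robust to the residual tail; the maximum height is
not — which is why both are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import shapely
from scipy import stats

from .diffmodel import DifferenceModel, canopy_volume, ground_cover
from .io import GroundTruthRecord, PlotBoundary

log = logging.getLogger(__name__)

DEFAULT_RESOLUTION = 0.01  # m
DEFAULT_HARD_CAP = 1.2  # m; potato plants do not reach this height
DEFAULT_SD_CUTOFF = 3.0

Provenance = Literal["pre_cleanup", "hard_capped", "sd_cleaned"]


@dataclass
class HeightField:
    """Regular-grid sampling of canopy height above the reference."""

    plot_id: str
    origin: tuple[float, float]  # lower-left corner (x, y) of the grid
    resolution: float
    values: np.ndarray  # (nrows, ncols); NaN = missing; row 0 = southmost
    provenance: Provenance = "pre_cleanup"
    sd_cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        self.values = np.asarray(self.values, dtype=float)

    @property
    def cell_area(self) -> float:
        return self.resolution ** 2

    @property
    def n_valid(self) -> int:
        return int(np.isfinite(self.values).sum())

    def valid_values(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]


@dataclass
class HeightHistogram:
    """Canopy area coverage at each height level (area-weighted histogram)."""

    bin_edges: np.ndarray  # meters, strictly increasing, length n_bins + 1
    area_per_bin: np.ndarray  # m² per bin
    total_area: float  # m² of canopy-covered (height > 0) cells

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.area_per_bin = np.asarray(self.area_per_bin, dtype=float)
        if len(self.bin_edges) >= 2 and np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")

    def quantile(self, p) -> np.ndarray | float:
        """Area-weighted height quantile(s), linear within bins."""
        p_arr = np.atleast_1d(np.asarray(p, dtype=float))
        if self.total_area <= 0 or self.area_per_bin.sum() <= 0:
            out = np.zeros_like(p_arr)
            return float(out[0]) if np.isscalar(p) else out
        cum = np.concatenate([[0.0], np.cumsum(self.area_per_bin)])
        cum /= cum[-1]
        out = np.interp(p_arr, cum, self.bin_edges)
        return float(out[0]) if np.isscalar(p) else out


@dataclass
class CanopyMetrics:
    """Per-plot, per-date canopy summary."""

    plot_id: str
    date: str | float
    max_height: float
    mean_height: float
    ground_cover_m2: float
    volume_m3: float
    histogram: HeightHistogram | None = None
    pct_points_removed: float = 0.0
    sd_cutoff_used: float | None = None
    n_points: int = 0
    no_canopy: bool = False


# ---------------------------------------------------------------------------
# height field operations


def sample_height_field(diff: DifferenceModel, plot: PlotBoundary,
                        resolution: float = DEFAULT_RESOLUTION) -> HeightField:
    """Sample the face-linear delta of a difference model on a regular grid.

    The grid is anchored at the lower-left of the plot bounding box; cell
    values are the delta at the cell center, missing (NaN) where the
    center falls outside the polygon or outside the mesh.
    """
    if not (0.001 < resolution <= 0.1):
        raise ValueError("resolution must lie in (0.001, 0.1] m")
    minx, miny, maxx, maxy = plot.polygon.bounds
    ncols = max(1, int(np.ceil((maxx - minx) / resolution)))
    nrows = max(1, int(np.ceil((maxy - miny) / resolution)))
    xs = minx + (np.arange(ncols) + 0.5) * resolution
    ys = miny + (np.arange(nrows) + 0.5) * resolution
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(plot.polygon, gx.ravel(), gy.ravel()).reshape(gx.shape)
    values = np.full(gx.shape, np.nan)
    if inside.any():
        values[inside] = diff.delta_at(gx[inside], gy[inside])
    return HeightField(plot_id=plot.plot_id, origin=(minx, miny),
                       resolution=resolution, values=values,
                       provenance="pre_cleanup")


def hard_cap_filter(field: HeightField, cap: float = DEFAULT_HARD_CAP) -> HeightField:
    """Remove heights strictly above ``cap`` (default 1.2 m).

    Values exactly at the cap are retained: only points *above* the
    biologically possible maximum are impossible.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    values = field.values.copy()
    removed = int(np.nansum(values > cap))
    values[values > cap] = np.nan
    if removed:
        log.info("plot %s: hard cap %.2f m removed %d cells", field.plot_id, cap, removed)
    return replace(field, values=values, provenance="hard_capped")


def sd_cleanup(field: HeightField, k: float = DEFAULT_SD_CUTOFF) -> HeightField:
    """Remove heights above mean + k·SD of the plot height distribution.

    Single pass (the statistics are computed once, on the incoming field).
    A constant field (SD = 0) is returned unchanged.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    valid = field.valid_values()
    if len(valid) < 2:
        raise ValueError("need at least 2 values for SD cleanup")
    mean = float(valid.mean())
    sd = float(valid.std(ddof=1))
    cutoff = mean + k * sd
    values = field.values.copy()
    removed = int(np.nansum(values > cutoff))
    if sd > 0:
        values[values > cutoff] = np.nan
    log.info("plot %s: %.1f SD cutoff at %.3f m removed %d cells",
             field.plot_id, k, cutoff, removed)
    return replace(field, values=values, provenance="sd_cleaned", sd_cutoff=k)


def height_histogram(field: HeightField, bin_width: float = 0.02) -> HeightHistogram:
    """Area-coverage histogram of canopy heights (cells with value > 0)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    valid = field.valid_values()
    canopy = valid[valid > 0]
    if len(canopy) == 0:
        return HeightHistogram(np.array([0.0, bin_width]), np.array([0.0]), 0.0)
    n_bins = max(1, int(np.ceil(canopy.max() / bin_width - 1e-12)))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(canopy, bins=edges)
    # np.histogram's last bin is closed on the right, consistent with edges
    # chosen to cover the maximum value
    area = counts * field.cell_area
    return HeightHistogram(edges, area, float(len(canopy) * field.cell_area))


def compute_metrics(field: HeightField, diff: DifferenceModel,
                    pre_field: HeightField, date: str | float = "",
                    bin_width: float = 0.02) -> CanopyMetrics:
    """Assemble per-plot canopy metrics from a (cleaned) height field.

    ``pre_field`` is the pre-cleanup field on the same grid; the removed
    percentage is measured against its valid-cell count.  Ground cover and
    volume come from the exact difference-model integrals, heights from
    the grid.
    """
    if field.values.shape != pre_field.values.shape:
        raise ValueError("field and pre_field must share grid geometry")
    valid = field.valid_values()
    n_pre = pre_field.n_valid
    pct_removed = 100.0 * (n_pre - field.n_valid) / n_pre if n_pre else 0.0
    if len(valid) == 0 or not (valid > 0).any():
        log.warning("plot %s: no canopy cells; reporting zero cover", field.plot_id)
        return CanopyMetrics(
            plot_id=field.plot_id, date=date, max_height=0.0, mean_height=0.0,
            ground_cover_m2=0.0, volume_m3=0.0,
            histogram=height_histogram(field, bin_width),
            pct_points_removed=pct_removed, sd_cutoff_used=field.sd_cutoff,
            n_points=field.n_valid, no_canopy=True)
    covered = valid[valid > 0]
    return CanopyMetrics(
        plot_id=field.plot_id, date=date,
        max_height=float(valid.max()),
        mean_height=float(covered.mean()),
        ground_cover_m2=ground_cover(diff),
        volume_m3=canopy_volume(diff),
        histogram=height_histogram(field, bin_width),
        pct_points_removed=pct_removed,
        sd_cutoff_used=field.sd_cutoff,
        n_points=field.n_valid)


def flag_isolated_spikes(cloud, radius: float = 0.25,
                         max_excess: float = 0.5) -> np.ndarray:
    """Flag cloud points standing implausibly above their neighborhood.

    A point is flagged when its elevation exceeds the maximum of all other
    points within ``radius`` (planimetric) by more than ``max_excess`` —
    an automated stand-in for the manual removal of obviously impossible
    points that usually precedes surface building.  Returns a boolean
    mask (True = spike); isolated points with no neighbors are not
    flagged.
    """
    from scipy.spatial import cKDTree

    tree = cKDTree(cloud.xy)
    flags = np.zeros(len(cloud), dtype=bool)
    z = cloud.z
    for i, neighbors in enumerate(tree.query_ball_point(cloud.xy, radius)):
        others = [j for j in neighbors if j != i]
        if others and z[i] > z[others].max() + max_excess:
            flags[i] = True
    return flags


def load_metrics_table(path) -> list[CanopyMetrics]:
    """Load CanopyMetrics from a metrics CSV and its histogram sidecar.

    The sidecar written by :func:`tincanopy.io.write_metrics_table`
    (``<stem>_histograms.csv``) is picked up automatically when present;
    without it, histogram-based statistics (decile shifts) degrade to
    zeros but the scalar metrics survive the round trip.
    """
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path)
    hist_path = path.with_name(path.stem + "_histograms.csv")
    hist_map: dict[tuple[str, str], HeightHistogram] = {}
    if hist_path.exists():
        hdf = pd.read_csv(hist_path)
        for (pid, date), grp in hdf.groupby(["plot_id", "date"], sort=False):
            edges = np.append(grp["bin_low_m"].to_numpy(), grp["bin_high_m"].iloc[-1])
            area = grp["area_m2"].to_numpy()
            hist_map[(str(pid), str(date))] = HeightHistogram(edges, area, float(area.sum()))
    out = []
    for _, row in df.iterrows():
        key = (str(row["plot_id"]), str(row["date"]))
        sd_used = row.get("sd_cutoff_used")
        out.append(CanopyMetrics(
            plot_id=str(row["plot_id"]), date=row["date"],
            max_height=float(row["max_height_m"]),
            mean_height=float(row["mean_height_m"]),
            ground_cover_m2=float(row["ground_cover_m2"]),
            volume_m3=float(row["volume_m3"]),
            histogram=hist_map.get(key),
            pct_points_removed=float(row.get("pct_points_removed", 0.0)),
            sd_cutoff_used=None if pd.isna(sd_used) else float(sd_used),
            n_points=int(row.get("n_points", 0))))
    return out


# ---------------------------------------------------------------------------
# validation against proximal ground truth


@dataclass
class RegressionSummary:
    """OLS of a UAV metric on a field measurement, plus rank correlation."""

    slope: float
    intercept: float
    r2_adj: float
    p_value: float
    n: int
    spearman_r: float


def validate_against_ground_truth(metrics: Sequence[CanopyMetrics],
                                  truth: Sequence[GroundTruthRecord],
                                  height_kind: Literal["max", "mean"] = "max"
                                  ) -> RegressionSummary:
    """Regress UAV-derived heights on proximal field measurements.

    Records are matched on (plot_id, date).  Returns the OLS slope and
    intercept, adjusted R², p-value, n, and the Spearman rank correlation
    (the statistic used for LAI-style comparisons).  Degenerate inputs
    (constant truth) give NaN statistics rather than an error.
    """
    truth_map = {(t.plot_id, str(t.date)): t.max_height_field for t in truth}
    pairs = [(truth_map[(m.plot_id, str(m.date))],
              m.max_height if height_kind == "max" else m.mean_height)
             for m in metrics if (m.plot_id, str(m.date)) in truth_map]
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} matched plot-date pairs (need >= 3)")
    x, y = map(np.asarray, zip(*pairs))
    n = len(x)
    if np.ptp(x) == 0:
        return RegressionSummary(np.nan, np.nan, np.nan, np.nan, n, np.nan)
    ols = stats.linregress(x, y)
    r2 = ols.rvalue ** 2
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else np.nan
    rho, _ = stats.spearmanr(x, y)
    return RegressionSummary(float(ols.slope), float(ols.intercept),
                             float(r2_adj), float(ols.pvalue), n, float(rho))
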