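"""TIN surface models and the raised soil-reference surface.

A canopy or soil surface is represented as a triangulated irregular
network (TIN): a Delaunay triangulation of the points' planimetric (x, y)
positions whose vertices keep their observed elevations.  Elevation
anywhere inside the convex hull is obtained by barycentric-linear
interpolation within the containing triangle, which reproduces planar
fields exactly.

The soil *reference* surface — the stand-in for the unobservable ground
under the canopy of a ridged crop — is the bare-soil (furrow) TIN with
every vertex raised by the average ridge height of the block, so that
plant heights are measured from the top of the ridge the plants actually
grow on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree

from .io import PointCloud

log = logging.getLogger(__name__)

SurfaceKind = Literal["canopy", "soil_topo", "soil_reference"]


@dataclass
class RidgeSpec:
    """How the average ridge height of a block is obtained.

    ``mode="given"`` carries a field-measured (or otherwise known) scalar;
    ``mode="estimated"`` asks :func:`estimate_ridge_height` to sample the
    point cloud along user-digitized ridge crest polylines.
    """

    mode: Literal["given", "estimated"] = "given"
    ridge_height: float | None = None
    crest_lines: Sequence[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.mode == "given":
            if self.ridge_height is None or self.ridge_height < 0:
                raise ValueError("mode='given' requires ridge_height >= 0")
        elif self.mode == "estimated":
            if not self.crest_lines:
                raise ValueError("mode='estimated' requires at least one crest line")
        else:
            raise ValueError(f"unknown ridge mode {self.mode!r}")


class TINSurface:
    """A Delaunay TIN over (x, y) with linear elevation interpolation."""

    def __init__(self, vertices: np.ndarray, kind: SurfaceKind = "canopy",
                 _delaunay: Delaunay | None = None) -> None:
        self.vertices = np.asarray(vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        self.kind = kind
        if _delaunay is None:
            try:
                _delaunay = Delaunay(self.vertices[:, :2])
            except QhullError as exc:
                raise ValueError("degenerate point set: all points collinear") from exc
        self._delaunay = _delaunay
        self.triangles = _delaunay.simplices

    # -- geometry -----------------------------------------------------------

    def triangle_areas(self) -> np.ndarray:
        """Planimetric (projected) area of every triangle."""
        p = self.vertices[:, :2][self.triangles]
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        return 0.5 * np.abs(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    @property
    def hull_area(self) -> float:
        return float(self.triangle_areas().sum())

    def elevation_at(self, x, y) -> np.ndarray | float:
        """Interpolated elevation at planimetric locations.

        Returns NaN outside the convex hull ("undefined" — a value, not an
        error).  Accepts scalars or arrays; broadcasting follows numpy.
        """
        xa = np.asarray(x, dtype=float)
        ya = np.asarray(y, dtype=float)
        scalar = xa.ndim == 0 and ya.ndim == 0
        xa, ya = np.broadcast_arrays(np.atleast_1d(xa), np.atleast_1d(ya))
        pts = np.column_stack([xa.ravel(), ya.ravel()])
        out = np.full(len(pts), np.nan)
        simplex = self._delaunay.find_simplex(pts)
        ok = simplex >= 0
        if ok.any():
            T = self._delaunay.transform[simplex[ok]]
            b2 = np.einsum("nij,nj->ni", T[:, :2], pts[ok] - T[:, 2])
            bary = np.column_stack([b2, 1.0 - b2.sum(axis=1)])
            zv = self.vertices[:, 2][self._delaunay.simplices[simplex[ok]]]
            out[ok] = np.einsum("ni,ni->n", bary, zv)
        out = out.reshape(xa.shape)
        return float(out.ravel()[0]) if scalar else out

    def raised(self, dz: float, kind: SurfaceKind | None = None) -> "TINSurface":
        """A copy with every vertex elevation shifted by ``dz`` (same mesh)."""
        v = self.vertices.copy()
        v[:, 2] += dz
        return TINSurface(v, kind=kind or self.kind, _delaunay=self._delaunay)


def _collapse_duplicate_xy(points: np.ndarray, keep: str) -> np.ndarray:
    """Collapse points sharing an (x, y) location to a single vertex.

    ``keep="max"`` retains the highest z (upper-surface semantics for
    SfM canopy clouds); ``keep="mean"`` averages (soil).
    """
    xy = points[:, :2]
    _, index, inverse = np.unique(xy, axis=0, return_index=True, return_inverse=True)
    if len(index) == len(points):
        return points
    out = points[np.sort(index)].copy()
    # map group ids onto the sorted-unique order we kept
    order = np.argsort(index)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    z_agg = np.full(len(index), -np.inf if keep == "max" else 0.0)
    if keep == "max":
        np.maximum.at(z_agg, rank[inverse], points[:, 2])
    else:
        counts = np.zeros(len(index))
        np.add.at(z_agg, rank[inverse], points[:, 2])
        np.add.at(counts, rank[inverse], 1.0)
        z_agg /= counts
    out[:, 2] = z_agg
    return out


def build_tin(cloud: PointCloud, kind: SurfaceKind = "canopy") -> TINSurface:
    """Triangulate a point cloud into a TIN surface.

    Duplicate planimetric locations are collapsed before triangulation
    (max z for canopy clouds, mean z for soil), because a function surface
    admits one elevation per location.
    """
    if len(cloud) < 3:
        raise ValueError("need at least 3 points to build a TIN")
    keep = "max" if kind == "canopy" else "mean"
    points = _collapse_duplicate_xy(cloud.points, keep)
    if len(points) < 3:
        raise ValueError("degenerate point set: fewer than 3 distinct locations")
    return TINSurface(points, kind=kind)


def build_soil_reference(bare_soil: PointCloud, ridge: RidgeSpec | float,
                         soil_topo: TINSurface | None = None,
                         cloud_for_estimate: PointCloud | None = None) -> TINSurface:
    """Build the raised soil-reference surface.

    The bare-soil cloud (furrows / inter-plot ground, ridges and
    vegetation excluded by the caller) is triangulated into the soil
    topography TIN, then every vertex is raised by the average ridge
    height so the reference passes through the ridge crests the plants
    stand on.  ``ridge`` may be a scalar height in meters or a
    :class:`RidgeSpec`; estimated mode needs ``cloud_for_estimate`` (the
    full canopy/field cloud containing the ridges).
    """
    topo = soil_topo if soil_topo is not None else build_tin(bare_soil, kind="soil_topo")
    if isinstance(ridge, (int, float)):
        ridge = RidgeSpec(mode="given", ridge_height=float(ridge))
    if ridge.mode == "given":
        h = float(ridge.ridge_height)
    else:
        if cloud_for_estimate is None:
            raise ValueError("estimated ridge mode requires the full field cloud")
        h = estimate_ridge_height(cloud_for_estimate, topo, ridge.crest_lines)
    if h < 0:
        raise ValueError("ridge height must be non-negative")
    return topo.raised(h, kind="soil_reference")


def estimate_ridge_height(cloud: PointCloud, soil_topo: TINSurface,
                          crest_lines: Iterable[np.ndarray],
                          sample_step: float = 0.05,
                          search_radius: float = 0.05,
                          min_samples: int = 10) -> float:
    """Estimate the block's average ridge height from crest-line samples.

    Each crest polyline is sampled every ``sample_step`` m; at each sample
    the nearest cloud point within ``search_radius`` (planimetric) supplies
    the crest elevation, from which the soil-topography elevation at the
    same location is subtracted.  Samples with no nearby cloud point or
    outside the soil hull are skipped; the mean of the valid differences is
    returned (at least ``min_samples`` required).
    """
    tree = cKDTree(cloud.xy)
    samples: list[np.ndarray] = []
    for line in crest_lines:
        line = np.asarray(line, dtype=float)
        if line.ndim != 2 or line.shape[1] != 2 or len(line) < 2:
            raise ValueError("each crest line must be an (k>=2, 2) polyline")
        seg = np.diff(line, axis=0)
        seglen = np.hypot(seg[:, 0], seg[:, 1])
        s = np.concatenate([[0.0], np.cumsum(seglen)])
        stations = np.arange(0.0, s[-1] + 0.5 * sample_step, sample_step)
        stations = np.clip(stations, 0.0, s[-1])
        samples.append(np.column_stack([
            np.interp(stations, s, line[:, 0]),
            np.interp(stations, s, line[:, 1]),
        ]))
    pts = np.vstack(samples)
    dist, idx = tree.query(pts, distance_upper_bound=search_radius)
    found = np.isfinite(dist)
    diffs = []
    if found.any():
        crest_z = cloud.z[idx[found]]
        soil_z = soil_topo.elevation_at(pts[found, 0], pts[found, 1])
        good = np.isfinite(soil_z)
        diffs = crest_z[good] - soil_z[good]
    if len(diffs) < min_samples:
        raise ValueError(
            f"insufficient ridge evidence: {len(diffs)} valid crest samples "
            f"(need >= {min_samples})")
    est = float(np.mean(diffs))
    log.info("ridge height estimated from %d crest samples: %.3f m", len(diffs), est)
    return est
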