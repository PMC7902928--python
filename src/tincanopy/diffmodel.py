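"""Per-plot difference models between canopy and soil-reference TINs.

A difference model is a triangulated surface whose vertices carry
``delta`` = canopy elevation − soil-reference elevation at that location,
clipped to a plot polygon.  Two construction methods are provided:

``no_breaklines``
    Carries only the existing canopy vertices that fall inside the plot;
    the soil reference is interpolated at those locations.  Cheap, mesh
    density equal to the canopy cloud's.

``trace_all_triangles``
    A full planar overlay: new vertices are created wherever canopy and
    soil triangle edges cross, wherever either mesh crosses the plot
    boundary (the breakline), and wherever delta changes sign along an
    edge.  Every output face lies inside exactly one canopy triangle and
    one soil triangle, so delta is exactly linear over each face.  Much
    denser and much slower.

Canopy volume is the exact integral of max(0, delta) over the faces
(closed-form prism integration with analytic splitting at the zero
contour) and canopy ground cover is the exact planimetric area of the
super-level set {delta > threshold}; negative regions (canopy below the
raised reference — furrows, senesced or lodged areas) are reported
separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import shapely
from scipy.spatial import ConvexHull, Delaunay
from scipy.stats import spearmanr
from shapely.geometry import Polygon as ShapelyPolygon
from shapely.strtree import STRtree

from .io import PlotBoundary
from .surfaces import TINSurface

log = logging.getLogger(__name__)

def _cross2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """z-component of the cross product of 2D vectors (numpy 2 removed this)."""
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


#: planimetric snapping tolerance for the overlay (meters)
SNAP_TOL = 1e-9
#: faces below this planimetric area are dropped from integration (m^2)
MIN_FACE_AREA = 1e-10


@dataclass
class DifferenceModel:
    """Triangulated canopy-minus-reference surface clipped to one plot."""

    plot_id: str
    method: str  # "trace_all_triangles" | "no_breaklines"
    vertices: np.ndarray  # (n, 3): x, y, delta
    triangles: np.ndarray  # (m, 3) vertex indices
    clip_polygon: ShapelyPolygon

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        self._interp = None

    @property
    def delta(self) -> np.ndarray:
        return self.vertices[:, 2]

    def face_areas(self) -> np.ndarray:
        p = self.vertices[:, :2][self.triangles]
        return 0.5 * np.abs(_cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]))

    @property
    def total_area(self) -> float:
        return float(self.face_areas().sum())

    def delta_at(self, x, y):
        """Face-linear delta at planimetric locations (NaN outside the mesh)."""
        if self._interp is None:
            from matplotlib.tri import LinearTriInterpolator, Triangulation

            tri = Triangulation(self.vertices[:, 0], self.vertices[:, 1],
                                triangles=self.triangles)
            self._interp = LinearTriInterpolator(tri, self.vertices[:, 2])
        xa = np.atleast_1d(np.asarray(x, dtype=float))
        ya = np.atleast_1d(np.asarray(y, dtype=float))
        out = self._interp(xa, ya)
        return np.ma.filled(out, np.nan)


# ---------------------------------------------------------------------------
# construction helpers


def _hull_polygon(surface: TINSurface) -> ShapelyPolygon:
    hull = ConvexHull(surface.vertices[:, :2])
    return ShapelyPolygon(surface.vertices[hull.vertices, :2])


def _effective_clip(canopy: TINSurface, soil_ref: TINSurface, plot: PlotBoundary,
                    min_cover_frac: float) -> ShapelyPolygon:
    """Plot polygon clipped to both surface hulls, with a coverage check."""
    clip = plot.polygon.intersection(_hull_polygon(canopy)).intersection(
        _hull_polygon(soil_ref))
    frac = clip.area / plot.polygon.area if plot.polygon.area else 0.0
    if frac < min_cover_frac:
        raise ValueError(
            f"plot {plot.plot_id!r}: only {100 * frac:.1f}% of the plot is covered "
            f"by both surfaces (need >= {100 * min_cover_frac:.0f}%)")
    if frac < 1.0 - 1e-9:
        log.info("plot %s: %.2f%% of plot area outside surface hulls was clipped",
                 plot.plot_id, 100 * (1 - frac))
    return clip


def difference_no_breaklines(canopy: TINSurface, soil_ref: TINSurface,
                             plot: PlotBoundary,
                             min_cover_frac: float = 0.5) -> DifferenceModel:
    """Difference model from existing canopy vertices only (no new points).

    Canopy vertices strictly inside the plot polygon are kept; delta is the
    vertex elevation minus the interpolated soil-reference elevation.  The
    kept vertices are re-triangulated (Delaunay); faces whose centroid
    leaves the polygon are discarded so the mesh stays within the plot.
    """
    _effective_clip(canopy, soil_ref, plot, min_cover_frac)  # coverage guard
    xy = canopy.vertices[:, :2]
    inside = shapely.contains_xy(plot.polygon, xy[:, 0], xy[:, 1])
    kept = canopy.vertices[inside]
    if len(kept) == 0:
        raise ValueError(f"plot {plot.plot_id!r} has no canopy surface")
    soil_z = soil_ref.elevation_at(kept[:, 0], kept[:, 1])
    covered = np.isfinite(soil_z)
    n_dropped = int((~covered).sum())
    if n_dropped:
        log.info("plot %s: dropped %d vertices outside the soil-reference hull",
                 plot.plot_id, n_dropped)
    kept = kept[covered]
    if len(kept) < 3:
        raise ValueError(f"plot {plot.plot_id!r} has no canopy surface")
    delta = kept[:, 2] - soil_z[covered]
    tri = Delaunay(kept[:, :2])
    faces = tri.simplices
    centroids = kept[:, :2][faces].mean(axis=1)
    keep_face = shapely.contains_xy(plot.polygon, centroids[:, 0], centroids[:, 1])
    p = kept[:, :2][faces]
    areas = 0.5 * np.abs(_cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]))
    faces = faces[keep_face & (areas > MIN_FACE_AREA)]
    vertices = np.column_stack([kept[:, :2], delta])
    return DifferenceModel(plot.plot_id, "no_breaklines", vertices, faces, plot.polygon)


# -- planar overlay (trace all triangles) -----------------------------------


def _plane_coeffs(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Per-triangle plane z = a x + b y + c, as an (m, 3) array of (a, b, c)."""
    v = vertices[triangles]
    n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    nz = n[:, 2]
    nz = np.where(np.abs(nz) < 1e-30, 1e-30, nz)
    a = -n[:, 0] / nz
    b = -n[:, 1] / nz
    c = v[:, 0, 2] - a * v[:, 0, 0] - b * v[:, 0, 1]
    return np.column_stack([a, b, c])


def _iter_polygons(geom):
    if geom.is_empty:
        return
    if isinstance(geom, ShapelyPolygon):
        yield geom
    elif hasattr(geom, "geoms"):
        for g in geom.geoms:
            yield from _iter_polygons(g)


def _clean_ring(ring: np.ndarray) -> np.ndarray:
    """Drop consecutive near-duplicate vertices from an open ring."""
    if len(ring) == 0:
        return ring
    keep = [0]
    for i in range(1, len(ring)):
        if np.hypot(*(ring[i] - ring[keep[-1]])) > SNAP_TOL:
            keep.append(i)
    if len(keep) > 1 and np.hypot(*(ring[keep[-1]] - ring[keep[0]])) <= SNAP_TOL:
        keep.pop()
    return ring[keep]


def _ring_ccw(ring: np.ndarray) -> np.ndarray:
    x, y = ring[:, 0], ring[:, 1]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return ring if signed >= 0 else ring[::-1]


def _point_in_triangle(p, a, b, c, eps=1e-14) -> bool:
    d1 = _cross2(b - a, p - a)
    d2 = _cross2(c - b, p - b)
    d3 = _cross2(a - c, p - c)
    return d1 > eps and d2 > eps and d3 > eps


def _ear_clip(ring: np.ndarray) -> list[tuple[int, int, int]]:
    """Triangulate a simple polygon ring (CCW, no holes) by ear clipping.

    Pieces produced by the overlay are intersections of convex sets with
    the plot polygon, so they are small and usually convex; a fan fallback
    covers numerically stubborn cases.
    """
    n = len(ring)
    if n == 3:
        return [(0, 1, 2)]
    idx = list(range(n))
    tris: list[tuple[int, int, int]] = []
    i = 0
    fails = 0
    while len(idx) > 3:
        m = len(idx)
        ia, ib, ic = idx[i % m], idx[(i + 1) % m], idx[(i + 2) % m]
        a, b, c = ring[ia], ring[ib], ring[ic]
        convex = _cross2(b - a, c - b) > 1e-14
        ear = convex and not any(
            _point_in_triangle(ring[j], a, b, c) for j in idx
            if j not in (ia, ib, ic))
        if ear:
            tris.append((ia, ib, ic))
            idx.remove(ib)
            fails = 0
        else:
            i += 1
            fails += 1
            if fails > m:  # stalled (degenerate geometry): fan fallback
                first = idx[0]
                tris.extend((first, idx[k], idx[k + 1]) for k in range(1, len(idx) - 1))
                return tris
    tris.append(tuple(idx))
    return tris


def _split_at_zero(coords: np.ndarray, d: np.ndarray,
                   tol: float = 1e-12) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split one triangle at the delta zero contour (delta linear inside).

    Returns sub-triangles whose vertex deltas do not strictly straddle
    zero, inserting interpolated zero-delta vertices on crossing edges.
    """
    pos = d > tol
    neg = d < -tol
    if not (pos.any() and neg.any()):
        return [(coords, d)]
    lone = int(np.argmax(pos)) if pos.sum() == 1 else int(np.argmax(neg))
    j, k = [i for i in range(3) if i != lone]
    out: list[tuple[np.ndarray, np.ndarray]] = []
    crossings = {}
    for other in (j, k):
        if (d[lone] > tol and d[other] < -tol) or (d[lone] < -tol and d[other] > tol):
            t = d[lone] / (d[lone] - d[other])
            crossings[other] = coords[lone] + t * (coords[other] - coords[lone])
    if len(crossings) == 2:
        pj, pk = crossings[j], crossings[k]
        out.append((np.array([coords[lone], pj, pk]), np.array([d[lone], 0.0, 0.0])))
        out.append((np.array([pj, coords[j], coords[k]]), np.array([0.0, d[j], d[k]])))
        out.append((np.array([pj, coords[k], pk]), np.array([0.0, d[k], 0.0])))
    elif len(crossings) == 1:
        other = next(iter(crossings))
        third = k if other == j else j  # the (near-)zero vertex
        p = crossings[other]
        out.append((np.array([coords[lone], p, coords[third]]),
                    np.array([d[lone], 0.0, d[third]])))
        out.append((np.array([p, coords[other], coords[third]]),
                    np.array([0.0, d[other], d[third]])))
    else:  # numerically marginal: keep as-is
        out.append((coords, d))
    return out


def difference_trace_all_triangles(canopy: TINSurface, soil_ref: TINSurface,
                                   plot: PlotBoundary,
                                   min_cover_frac: float = 0.5) -> DifferenceModel:
    """Difference model by full planar overlay of the two triangulations.

    Every output face lies wholly within one canopy triangle, one soil
    triangle and the plot polygon, with extra vertices where delta changes
    sign along an edge, so delta is exactly linear over every face and the
    mesh is denser than either input.
    """
    clip = _effective_clip(canopy, soil_ref, plot, min_cover_frac)

    c_xy = canopy.vertices[:, :2]
    s_xy = soil_ref.vertices[:, :2]

    # cheap bbox prefilter: only canopy/soil triangles near the clip region
    minx, miny, maxx, maxy = clip.bounds

    def _near(xy: np.ndarray, tris: np.ndarray) -> np.ndarray:
        t = xy[tris]
        return ((t[:, :, 0].min(axis=1) <= maxx) & (t[:, :, 0].max(axis=1) >= minx)
                & (t[:, :, 1].min(axis=1) <= maxy) & (t[:, :, 1].max(axis=1) >= miny))

    c_tris = canopy.triangles[_near(c_xy, canopy.triangles)]
    s_tris = soil_ref.triangles[_near(s_xy, soil_ref.triangles)]
    if len(c_tris) == 0 or len(s_tris) == 0:
        raise ValueError(f"plot {plot.plot_id!r} has no canopy surface")
    canopy_planes = _plane_coeffs(canopy.vertices, c_tris)
    soil_planes = _plane_coeffs(soil_ref.vertices, s_tris)
    canopy_polys = shapely.polygons(shapely.linearrings(c_xy[c_tris]))
    soil_polys = shapely.polygons(shapely.linearrings(s_xy[s_tris]))
    tree = STRtree(soil_polys)
    shapely.prepare(clip)

    out_coords: list[np.ndarray] = []
    out_deltas: list[np.ndarray] = []
    candidates = tree.query(canopy_polys, predicate="intersects")
    by_canopy: dict[int, list[int]] = {}
    for ci, si in zip(*candidates):
        by_canopy.setdefault(int(ci), []).append(int(si))

    for ci, t in enumerate(canopy_polys):
        if not clip.intersects(t):
            continue
        base = t if clip.covers(t) else t.intersection(clip)
        for geom in _iter_polygons(base):
            for si in by_canopy.get(ci, ()):  # soil triangles overlapping canopy tri
                piece = geom.intersection(soil_polys[si])
                dplane = canopy_planes[ci] - soil_planes[si]
                for pg in _iter_polygons(piece):
                    if pg.area <= MIN_FACE_AREA:
                        continue
                    ring = _ring_ccw(_clean_ring(np.asarray(pg.exterior.coords)[:-1]))
                    if len(ring) < 3:
                        continue
                    for ia, ib, ic in _ear_clip(ring):
                        coords = ring[[ia, ib, ic]]
                        d = dplane[0] * coords[:, 0] + dplane[1] * coords[:, 1] + dplane[2]
                        for sub_c, sub_d in _split_at_zero(coords, d):
                            out_coords.append(sub_c)
                            out_deltas.append(sub_d)

    if not out_coords:
        raise ValueError(f"plot {plot.plot_id!r} has no canopy surface")

    # snap and merge shared vertices
    vert_index: dict[tuple[float, float], int] = {}
    vertices: list[tuple[float, float, float]] = []
    triangles: list[tuple[int, int, int]] = []
    ndec = 9  # SNAP_TOL decimal places
    for coords, deltas in zip(out_coords, out_deltas):
        ids = []
        for (x, y), d in zip(coords, deltas):
            key = (round(x, ndec), round(y, ndec))
            vid = vert_index.get(key)
            if vid is None:
                vid = len(vertices)
                vert_index[key] = vid
                vertices.append((x, y, d))
            ids.append(vid)
        if len(set(ids)) == 3:
            triangles.append(tuple(ids))

    v = np.asarray(vertices)
    f = np.asarray(triangles, dtype=int)
    p = v[:, :2][f]
    signed = 0.5 * _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    flip = signed < 0
    f[flip] = f[flip][:, ::-1]
    f = f[np.abs(signed) > MIN_FACE_AREA]
    if len(f) == 0:
        raise ValueError(f"plot {plot.plot_id!r} has no canopy surface")
    return DifferenceModel(plot.plot_id, "trace_all_triangles", v, f, plot.polygon)


# ---------------------------------------------------------------------------
# exact integration over face-linear delta


def _positive_part(areas: np.ndarray, deltas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-face integral and area of the positive part of a linear field.

    ``deltas`` is (m, 3) vertex values; returns (volume_per_face,
    positive_area_per_face).  The zero contour is handled analytically:
    with sorted vertex values d1 <= d2 <= d3 the sub-level geometry is a
    corner triangle similar to the face, giving closed forms for both the
    prism volume and the super-level area.
    """
    d = np.sort(np.asarray(deltas, dtype=float), axis=1)
    d1, d2, d3 = d[:, 0], d[:, 1], d[:, 2]
    A = np.asarray(areas, dtype=float)
    vol = np.zeros_like(A)
    pos_area = np.zeros_like(A)

    all_nonneg = d1 >= 0
    vol[all_nonneg] = A[all_nonneg] * d[all_nonneg].sum(axis=1) / 3.0
    pos_area[all_nonneg & (d3 > 0)] = A[all_nonneg & (d3 > 0)]

    one_pos = (d2 < 0) & (d3 > 0)
    if one_pos.any():
        frac = d3[one_pos] ** 2 / ((d3[one_pos] - d1[one_pos]) * (d3[one_pos] - d2[one_pos]))
        pos_area[one_pos] = A[one_pos] * frac
        vol[one_pos] = A[one_pos] * frac * d3[one_pos] / 3.0

    two_pos = (d1 < 0) & (d2 >= 0) & (d3 > 0)
    if two_pos.any():
        frac_neg = d1[two_pos] ** 2 / ((d2[two_pos] - d1[two_pos]) * (d3[two_pos] - d1[two_pos]))
        pos_area[two_pos] = A[two_pos] * (1.0 - frac_neg)
        vol[two_pos] = (A[two_pos] * d[two_pos].sum(axis=1) / 3.0
                        + A[two_pos] * frac_neg * (-d1[two_pos]) / 3.0)
    return vol, pos_area


def canopy_volume(diff: DifferenceModel) -> float:
    """Canopy volume: integral of max(0, delta) over the plot, in m³."""
    areas = diff.face_areas()
    ok = areas > MIN_FACE_AREA
    vol, _ = _positive_part(areas[ok], diff.delta[diff.triangles[ok]])
    return float(vol.sum())


def ground_cover(diff: DifferenceModel, threshold: float = 0.0) -> float:
    """Planimetric area (m²) where delta exceeds ``threshold`` (default 0)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    areas = diff.face_areas()
    ok = areas > MIN_FACE_AREA
    _, pos_area = _positive_part(areas[ok], diff.delta[diff.triangles[ok]] - threshold)
    return float(pos_area.sum())


def below_reference_area(diff: DifferenceModel) -> float:
    """Planimetric area (m²) where the canopy lies below the raised reference.

    A senescence / lodging diagnostic: the difference model is signed, and
    furrow or collapsed-canopy regions sit below the ridge-top reference.
    """
    areas = diff.face_areas()
    ok = areas > MIN_FACE_AREA
    _, neg_area = _positive_part(areas[ok], -diff.delta[diff.triangles[ok]])
    return float(neg_area.sum())


def compare_methods(plots: Sequence[tuple[TINSurface, TINSurface, PlotBoundary]]):
    """Per-plot volumes by both methods and their Spearman rank correlation.

    Returns ``(spearman_r, volumes_trace, volumes_nobreak)``.  With fewer
    than 3 plots or a zero-variance volume vector the correlation is
    undefined and reported as NaN.
    """
    if len(plots) < 3:
        raise ValueError("need at least 3 plots to compare methods")
    va, vb = [], []
    for canopy, soil_ref, plot in plots:
        va.append(canopy_volume(difference_trace_all_triangles(canopy, soil_ref, plot)))
        vb.append(canopy_volume(difference_no_breaklines(canopy, soil_ref, plot)))
    va = np.asarray(va)
    vb = np.asarray(vb)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        log.warning("zero variance in a volume vector: Spearman r undefined")
        return float("nan"), va, vb
    r, _ = spearmanr(va, vb)
    return float(r), va, vb
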