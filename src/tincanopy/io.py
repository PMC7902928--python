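"""Point-cloud, plot-boundary and metrics-table input/output.

Coordinates are assumed to arrive in a projected planar CRS in meters
(e.g. a national grid); ``crs_label`` is carried as opaque metadata and no
reprojection is ever performed.  Supported point formats are whitespace XYZ
text, ASCII PLY and a minimal binary LAS (1.x headers, point formats 0-3,
read-only).  Plot boundaries come as GeoJSON polygon features or as a CSV
of WKT strings.
"""

from __future__ import annotations

import csv
import json
import logging
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, shape
from shapely.geometry.polygon import orient
from shapely import wkt as shapely_wkt

log = logging.getLogger(__name__)

#: reject elevations beyond this magnitude as physically implausible
MAX_ABS_ELEVATION = 10_000.0


@dataclass
class PointCloud:
    """A set of 3D points (x east, y north, z elevation), all in meters."""

    points: np.ndarray  # (n, 3) float64
    crs_label: str = ""
    source_label: str = ""

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 3)
        if self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point cloud contains non-finite coordinates")
        if self.points.size and np.abs(self.points[:, 2]).max() > MAX_ABS_ELEVATION:
            raise ValueError(
                f"elevation outside plausible range (|z| > {MAX_ABS_ELEVATION} m)"
            )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def xy(self) -> np.ndarray:
        return self.points[:, :2]

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]


@dataclass
class PlotBoundary:
    """A labelled plot polygon; the ring is normalized counterclockwise."""

    plot_id: str
    polygon: Polygon
    variety: str = ""
    block: str = ""

    def __post_init__(self) -> None:
        poly = self.polygon
        if not isinstance(poly, Polygon):
            raise TypeError("polygon must be a shapely Polygon")
        if not poly.is_valid:
            raise ValueError(f"plot {self.plot_id!r}: polygon is not simple/valid")
        if poly.area <= 0:
            raise ValueError(f"plot {self.plot_id!r}: polygon has zero area")
        self.polygon = orient(poly, sign=1.0)  # CCW exterior

    @property
    def area(self) -> float:
        return self.polygon.area


@dataclass
class GroundTruthRecord:
    """One proximal field measurement of a plot on a date."""

    plot_id: str
    date: str
    max_height_field: float
    lai: float | None = None

    def __post_init__(self) -> None:
        if self.max_height_field < 0:
            raise ValueError("field-measured height must be non-negative")
        if self.lai is not None and self.lai < 0:
            raise ValueError("LAI must be non-negative when present")


# ---------------------------------------------------------------------------
# point clouds


def _read_xyz(path: Path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected 'x y z', got {body!r}")
            try:
                rows.append([float(parts[0]), float(parts[1]), float(parts[2])])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric coordinate") from exc
    return np.asarray(rows, dtype=float).reshape(-1, 3)


def _write_xyz(points: np.ndarray, path: Path) -> None:
    np.savetxt(path, points, fmt="%.6f")


def _read_ply(path: Path) -> np.ndarray:
    """Minimal ASCII PLY reader: element vertex with x, y, z properties."""
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise ValueError(f"{path}: not a PLY file")
        n_vertex = None
        props: list[str] = []
        in_vertex = False
        fmt = None
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: unexpected end of PLY header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens:
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tokens[2])
            elif tokens[0] == "property" and in_vertex:
                props.append(tokens[-1])
            elif tokens[0] == "end_header":
                break
        if fmt != "ascii":
            raise ValueError(f"{path}: only ASCII PLY is supported")
        if n_vertex is None:
            raise ValueError(f"{path}: PLY has no vertex element")
        for axis in ("x", "y", "z"):
            if axis not in props:
                raise ValueError(f"{path}: vertex element lacks property {axis!r}")
        cols = [props.index(a) for a in ("x", "y", "z")]
        data = np.empty((n_vertex, 3))
        for i in range(n_vertex):
            tokens = fh.readline().split()
            if len(tokens) < len(props):
                raise ValueError(f"{path}: vertex record {i + 1} is malformed")
            try:
                data[i] = [float(tokens[c]) for c in cols]
            except ValueError as exc:
                raise ValueError(f"{path}: vertex record {i + 1}: non-numeric value") from exc
    return data


def _write_ply(points: np.ndarray, path: Path, faces: np.ndarray | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(points)}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        if faces is not None:
            fh.write(f"element face {len(faces)}\n")
            fh.write("property list uchar int vertex_indices\n")
        fh.write("end_header\n")
        for p in points:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        if faces is not None:
            for f in faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _read_las(path: Path) -> np.ndarray:
    """Minimal LAS reader: header offsets/scales + x/y/z of point records.

    Supports uncompressed LAS 1.0-1.3 with point data formats 0-3 (x, y, z
    are the leading three int32 fields in every format).
    """
    with open(path, "rb") as fh:
        header = fh.read(227)
        if len(header) < 227 or header[:4] != b"LASF":
            raise ValueError(f"{path}: not a LAS file")
        (offset_to_points,) = struct.unpack_from("<I", header, 96)
        (point_format,) = struct.unpack_from("<B", header, 104)
        (record_len,) = struct.unpack_from("<H", header, 105)
        (n_points,) = struct.unpack_from("<I", header, 107)
        sx, sy, sz = struct.unpack_from("<3d", header, 131)
        ox, oy, oz = struct.unpack_from("<3d", header, 155)
        if point_format > 3:
            raise ValueError(f"{path}: unsupported LAS point format {point_format}")
        fh.seek(offset_to_points)
        raw = fh.read(n_points * record_len)
        if len(raw) < n_points * record_len:
            raise ValueError(f"{path}: truncated LAS point data")
    rec = np.frombuffer(raw, dtype=np.uint8).reshape(n_points, record_len)
    xyz_int = rec[:, :12].copy().view("<i4").reshape(n_points, 3).astype(float)
    return xyz_int * [sx, sy, sz] + [ox, oy, oz]


def read_point_cloud(path: str | Path, format: str | None = None,
                     crs_label: str = "", source_label: str = "") -> PointCloud:
    """Read a point cloud from ``path``.

    ``format`` is one of ``xyz``, ``ply``, ``las``; when omitted it is
    inferred from the file suffix.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "xyz"
    readers = {"xyz": _read_xyz, "txt": _read_xyz, "ply": _read_ply, "las": _read_las}
    if format not in readers:
        raise ValueError(f"unsupported point-cloud format {format!r}")
    points = readers[format](path)
    if len(points) == 0:
        raise ValueError(f"{path}: no points")
    log.info("read %d points from %s (%s)", len(points), path, format)
    return PointCloud(points, crs_label=crs_label, source_label=source_label or path.stem)


def write_point_cloud(cloud: PointCloud, path: str | Path, format: str | None = None) -> None:
    """Write a point cloud as XYZ text or ASCII PLY."""
    if len(cloud) == 0:
        raise ValueError("refusing to write an empty point cloud")
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "xyz"
    if format in ("xyz", "txt"):
        _write_xyz(cloud.points, path)
    elif format == "ply":
        _write_ply(cloud.points, path)
    else:
        raise ValueError(f"unsupported point-cloud output format {format!r}")


# ---------------------------------------------------------------------------
# plot boundaries


def _boundary_from_polygon(poly: Polygon, props: dict, where: str) -> PlotBoundary:
    plot_id = props.get("plot_id")
    if plot_id in (None, ""):
        raise ValueError(f"{where}: feature lacks required property 'plot_id'")
    if not poly.is_valid:
        raise ValueError(f"{where}: plot {plot_id!r} polygon is self-intersecting")
    return PlotBoundary(
        plot_id=str(plot_id),
        polygon=poly,
        variety=str(props.get("variety", "") or ""),
        block=str(props.get("block", "") or ""),
    )


def read_plot_boundaries(path: str | Path, format: str | None = None) -> list[PlotBoundary]:
    """Read plot polygons from a GeoJSON FeatureCollection or a WKT CSV.

    The CSV variant has columns ``plot_id, variety, block, wkt``.  Rings are
    normalized counterclockwise; duplicate ``plot_id`` values are an error.
    """
    path = Path(path)
    if format is None:
        format = "geojson" if path.suffix.lower() in (".json", ".geojson") else "wkt_csv"
    boundaries: list[PlotBoundary] = []
    if format == "geojson":
        with open(path) as fh:
            doc = json.load(fh)
        features = doc.get("features", [])
        for i, feat in enumerate(features):
            geom = shape(feat["geometry"])
            if not isinstance(geom, Polygon):
                raise ValueError(f"{path}: feature {i} is not a Polygon")
            boundaries.append(_boundary_from_polygon(geom, feat.get("properties") or {}, str(path)))
    elif format == "wkt_csv":
        with open(path, newline="") as fh:
            for i, row in enumerate(csv.DictReader(fh)):
                if "wkt" not in row:
                    raise ValueError(f"{path}: CSV lacks a 'wkt' column")
                geom = shapely_wkt.loads(row["wkt"])
                if not isinstance(geom, Polygon):
                    raise ValueError(f"{path}: row {i + 1} is not a Polygon")
                boundaries.append(_boundary_from_polygon(geom, row, str(path)))
    else:
        raise ValueError(f"unsupported boundary format {format!r}")
    seen: set[str] = set()
    for b in boundaries:
        if b.plot_id in seen:
            raise ValueError(f"{path}: duplicate plot_id {b.plot_id!r}")
        seen.add(b.plot_id)
    return boundaries


# ---------------------------------------------------------------------------
# metrics tables

METRICS_COLUMNS = [
    "plot_id", "date", "n_points", "max_height_m", "mean_height_m",
    "ground_cover_m2", "volume_m3", "sd_cutoff_used", "pct_points_removed",
]


def write_metrics_table(records: Sequence, path: str | Path,
                        histogram_path: str | Path | None = None) -> None:
    """Write per-plot canopy metrics as CSV, histograms to a sidecar CSV.

    ``records`` are objects with the attributes of
    :class:`tincanopy.metrics.CanopyMetrics`.  The sidecar (default:
    ``<path stem>_histograms.csv``) holds one row per histogram bin.
    """
    path = Path(path)
    if not records:
        log.warning("writing header-only metrics table to %s", path)
    rows = []
    hist_rows = []
    for m in records:
        rows.append({
            "plot_id": m.plot_id,
            "date": m.date,
            "n_points": m.n_points,
            "max_height_m": m.max_height,
            "mean_height_m": m.mean_height,
            "ground_cover_m2": m.ground_cover_m2,
            "volume_m3": m.volume_m3,
            "sd_cutoff_used": m.sd_cutoff_used,
            "pct_points_removed": m.pct_points_removed,
        })
        h = getattr(m, "histogram", None)
        if h is not None:
            for lo, hi, a in zip(h.bin_edges[:-1], h.bin_edges[1:], h.area_per_bin):
                hist_rows.append({"plot_id": m.plot_id, "date": m.date,
                                  "bin_low_m": lo, "bin_high_m": hi, "area_m2": a})
    pd.DataFrame(rows, columns=METRICS_COLUMNS).to_csv(path, index=False, float_format="%.10g")
    if histogram_path is None:
        histogram_path = path.with_name(path.stem + "_histograms.csv")
    pd.DataFrame(hist_rows, columns=["plot_id", "date", "bin_low_m", "bin_high_m", "area_m2"]) \
        .to_csv(histogram_path, index=False, float_format="%.10g")


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    """Read a metrics CSV produced by :func:`write_metrics_table`."""
    return pd.read_csv(path)


def read_ground_truth(path: str | Path) -> list[GroundTruthRecord]:
    """Read a CSV of proximal measurements: plot_id, date, max_height_field[, lai]."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        lai = row.get("lai")
        records.append(GroundTruthRecord(
            plot_id=str(row["plot_id"]), date=str(row["date"]),
            max_height_field=float(row["max_height_field"]),
            lai=None if lai is None or pd.isna(lai) else float(lai)))
    return records


# ---------------------------------------------------------------------------
# mesh / grid serialization helpers


def write_tin_ply(vertices: np.ndarray, triangles: np.ndarray, path: str | Path) -> None:
    """Serialize a triangulated surface (or difference model) to ASCII PLY."""
    _write_ply(np.asarray(vertices, float), Path(path), faces=np.asarray(triangles, int))


def write_height_field_asc(field, path: str | Path, nodata: float = -9999.0) -> None:
    """Write a height field as an ESRI ASCII grid for GIS inspection."""
    values = np.where(np.isnan(field.values), nodata, field.values)
    nrows, ncols = values.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\nnrows {nrows}\n")
        fh.write(f"xllcorner {field.origin[0]:.6f}\nyllcorner {field.origin[1]:.6f}\n")
        fh.write(f"cellsize {field.resolution:.6f}\nNODATA_value {nodata}\n")
        for r in range(nrows - 1, -1, -1):  # ASC grids are written top row first
            fh.write(" ".join(f"{v:.4f}" for v in values[r]) + "\n")


def write_difference_csv(diff, path: str | Path) -> None:
    """Write one row per difference-model face for auditing.

    Columns: face index, the three vertex coordinates and deltas, and the
    planimetric face area.
    """
    v = diff.vertices
    rows = []
    areas = diff.face_areas()
    for i, (tri, area) in enumerate(zip(diff.triangles, areas)):
        row = {"face": i, "area_m2": area}
        for j, vid in enumerate(tri):
            row[f"x{j}"], row[f"y{j}"], row[f"delta{j}"] = v[vid]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")


def write_histogram_csv(hist, path: str | Path) -> None:
    """Write a height histogram as CSV (bin_low_m, bin_high_m, area_m2)."""
    df = pd.DataFrame({
        "bin_low_m": hist.bin_edges[:-1],
        "bin_high_m": hist.bin_edges[1:],
        "area_m2": hist.area_per_bin,
    })
    df.to_csv(path, index=False, float_format="%.10g")
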