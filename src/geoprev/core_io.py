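"""Data model and I/O for cluster tables, covariate rasters and region polygons.

Formats are deliberately plain-text so a whole analysis can live in version
control: clusters are CSV, rasters use a small ESRI-ASCII-like dialect with a
*cell-center* upper-left origin, and regions are GeoJSON polygons.

All coordinates are geographic degrees (lon/lat).  Distances are computed
after an equirectangular projection centred on the mean data latitude
(see :func:`project_points`); this is adequate at country scale and keeps the
maths closed-form.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon

EARTH_RADIUS_KM = 6371.0

#: Sentinel region label for points not covered by any polygon.
UNASSIGNED = "UNASSIGNED"

CLUSTER_COLUMNS = (
    "cluster_id",
    "wave",
    "lon",
    "lat",
    "n_children",
    "n_underweight",
    "region_id",
)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class OutOfBoundsError(ValueError):
    """A query point falls outside a raster's extent."""


class MissingValueError(ValueError):
    """A raster query hit a nodata cell."""


@dataclass(frozen=True)
class ClusterRecord:
    """One georeferenced survey cluster.

    ``n_underweight`` / ``n_children`` are the binomial outcome pair
    (Y_j, n_j) for the cluster.
    """

    cluster_id: int
    wave: str
    lon: float
    lat: float
    n_children: int
    n_underweight: int
    region_id: str

    def __post_init__(self) -> None:
        if self.n_children < 1:
            raise ValidationError(
                f"cluster {self.cluster_id}: n_children must be >= 1, "
                f"got {self.n_children}"
            )
        if not 0 <= self.n_underweight <= self.n_children:
            raise ValidationError(
                f"cluster {self.cluster_id}: need 0 <= n_underweight <= "
                f"n_children, got {self.n_underweight}/{self.n_children}"
            )
        if not -180.0 <= self.lon <= 180.0:
            raise ValidationError(
                f"cluster {self.cluster_id}: lon {self.lon} outside [-180, 180]"
            )
        if not -90.0 <= self.lat <= 90.0:
            raise ValidationError(
                f"cluster {self.cluster_id}: lat {self.lat} outside [-90, 90]"
            )


@dataclass
class CovariateGrid:
    """A regular raster lattice holding one covariate layer.

    ``origin_lon``/``origin_lat`` locate the CENTER of the top-left cell.
    ``values`` is row-major with row 0 the northernmost row.
    """

    name: str
    origin_lon: float
    origin_lat: float
    cell_size: float
    values: np.ndarray
    nodata_flag: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if np.isnan(self.values).any():
            raise ValueError("NaN in grid values; use nodata_flag instead")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the center of cell (row, col)."""
        return (
            self.origin_lon + col * self.cell_size,
            self.origin_lat - row * self.cell_size,
        )

    def bounds(self) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max) of the cell-edge extent."""
        half = self.cell_size / 2.0
        return (
            self.origin_lon - half,
            self.origin_lat - (self.n_rows - 1) * self.cell_size - half,
            self.origin_lon + (self.n_cols - 1) * self.cell_size + half,
            self.origin_lat + half,
        )

    def nearest_cell(self, lon: float, lat: float) -> tuple[int, int]:
        """Index of the cell whose center is nearest (lon, lat).

        Ties (point equidistant between cell centers) go to the smaller
        index, i.e. ``ceil(x - 0.5)`` per axis, so the (row, col) pair is
        lexicographically smallest among the equidistant candidates.
        """
        fcol = (lon - self.origin_lon) / self.cell_size
        frow = (self.origin_lat - lat) / self.cell_size
        col = math.ceil(fcol - 0.5)
        row = math.ceil(frow - 0.5)
        return row, col


@dataclass
class RegionPolygon:
    """A named polygon: one outer ring plus optional holes, lon/lat vertices."""

    region_id: str
    rings: list[list[tuple[float, float]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ring in self.rings:
            if len(ring) < 4:
                raise ValidationError(
                    f"region {self.region_id}: ring has < 4 vertices"
                )
            if tuple(ring[0]) != tuple(ring[-1]):
                raise ValidationError(
                    f"region {self.region_id}: ring is not closed"
                )

    def to_shapely(self) -> Polygon:
        return Polygon(self.rings[0], self.rings[1:])


# ---------------------------------------------------------------------------
# cluster tables
# ---------------------------------------------------------------------------

def read_clusters(path) -> list[ClusterRecord]:
    """Read a cluster CSV into validated records, preserving row order.

    Raises :class:`SchemaError` naming any missing column and
    :class:`ValidationError` citing the 1-based data row of a bad record.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CLUSTER_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        records = []
        for i, row in enumerate(reader, start=1):
            try:
                records.append(
                    ClusterRecord(
                        cluster_id=int(row["cluster_id"]),
                        wave=str(row["wave"]),
                        lon=float(row["lon"]),
                        lat=float(row["lat"]),
                        n_children=int(row["n_children"]),
                        n_underweight=int(row["n_underweight"]),
                        region_id=str(row["region_id"]),
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"row {i}: {exc}") from exc
    _check_unique_keys(records)
    return records


def write_clusters(records: list[ClusterRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CLUSTER_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.cluster_id,
                    r.wave,
                    repr(r.lon),
                    repr(r.lat),
                    r.n_children,
                    r.n_underweight,
                    r.region_id,
                ]
            )


def _check_unique_keys(records: list[ClusterRecord]) -> None:
    seen: set[tuple[int, str]] = set()
    for r in records:
        key = (r.cluster_id, r.wave)
        if key in seen:
            raise ValidationError(f"duplicate (cluster_id, wave) pair {key}")
        seen.add(key)


# ---------------------------------------------------------------------------
# rasters (text dialect)
# ---------------------------------------------------------------------------

def read_grid(path, name: str | None = None) -> CovariateGrid:
    """Read the text raster dialect.

    Header keys: ``ncols nrows xulcenter yulcenter cellsize nodata_value``
    followed by ``nrows`` whitespace-separated value rows (row 0 north).
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    idx = 0
    needed = {"ncols", "nrows", "xulcenter", "yulcenter", "cellsize"}
    while idx < len(lines):
        parts = lines[idx].split()
        if len(parts) == 2 and parts[0].lower() in needed | {"nodata_value"}:
            header[parts[0].lower()] = float(parts[1])
            idx += 1
        else:
            break
    missing = needed - set(header)
    if missing:
        raise SchemaError(f"raster header missing: {', '.join(sorted(missing))}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    data = np.loadtxt(lines[idx:], dtype=float, ndmin=2)
    if data.shape != (n_rows, n_cols):
        raise ValidationError(
            f"raster body is {data.shape}, header says ({n_rows}, {n_cols})"
        )
    if name is None:
        import os

        name = os.path.splitext(os.path.basename(str(path)))[0]
    return CovariateGrid(
        name=name,
        origin_lon=header["xulcenter"],
        origin_lat=header["yulcenter"],
        cell_size=header["cellsize"],
        values=data,
        nodata_flag=header.get("nodata_value", -9999.0),
    )


def write_grid(grid: CovariateGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xulcenter {grid.origin_lon!r}\n")
        fh.write(f"yulcenter {grid.origin_lat!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"nodata_value {grid.nodata_flag!r}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# regions (GeoJSON)
# ---------------------------------------------------------------------------

def read_regions(path) -> list[RegionPolygon]:
    """Read polygons from a GeoJSON FeatureCollection with a region_id property."""
    with open(path) as fh:
        doc = json.load(fh)
    out = []
    for feat in doc.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon":
            raise ValidationError(
                f"unsupported geometry type {geom.get('type')!r}"
            )
        rid = str(feat.get("properties", {}).get("region_id"))
        rings = [[tuple(map(float, pt)) for pt in ring]
                 for ring in geom["coordinates"]]
        out.append(RegionPolygon(region_id=rid, rings=rings))
    return out


def write_regions(polygons: list[RegionPolygon], path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"region_id": p.region_id},
            "geometry": {
                "type": "Polygon",
                "coordinates": [[list(pt) for pt in ring] for ring in p.rings],
            },
        }
        for p in polygons
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


# ---------------------------------------------------------------------------
# spatial lookups
# ---------------------------------------------------------------------------

def extract_covariates(
    grids: list[CovariateGrid], points: list[tuple[float, float]]
) -> np.ndarray:
    """Nearest-cell covariate lookup; returns (n_points, n_grids).

    All grids must share geometry.  Column order follows the grid list.
    A nodata hit raises :class:`MissingValueError`; no silent imputation.
    """
    if not grids:
        return np.zeros((len(points), 0))
    g0 = grids[0]
    for g in grids[1:]:
        if (
            g.origin_lon != g0.origin_lon
            or g.origin_lat != g0.origin_lat
            or g.cell_size != g0.cell_size
            or g.values.shape != g0.values.shape
        ):
            raise ValueError("grids do not share origin/cell_size/dimensions")
    lon_min, lat_min, lon_max, lat_max = g0.bounds()
    out = np.empty((len(points), len(grids)))
    for i, (lon, lat) in enumerate(points):
        if not (lon_min <= lon <= lon_max and lat_min <= lat <= lat_max):
            raise OutOfBoundsError(f"point ({lon}, {lat}) outside grid extent")
        row, col = g0.nearest_cell(lon, lat)
        row = min(max(row, 0), g0.n_rows - 1)
        col = min(max(col, 0), g0.n_cols - 1)
        for j, g in enumerate(grids):
            v = g.values[row, col]
            if v == g.nodata_flag:
                raise MissingValueError(
                    f"nodata in layer {g.name!r} at point ({lon}, {lat})"
                )
            out[i, j] = v
    return out


def assign_regions(
    points: list[tuple[float, float]], polygons: list[RegionPolygon]
) -> list[str]:
    """Point-in-polygon region labels.

    Polygons are tested in region_id-sorted order; boundary points go to the
    first polygon covering them.  Points in no polygon get ``UNASSIGNED``.
    """
    ordered = sorted(polygons, key=lambda p: p.region_id)
    shapes = [(p.region_id, p.to_shapely()) for p in ordered]
    labels = []
    for lon, lat in points:
        pt = Point(lon, lat)
        for rid, shape in shapes:
            if shape.covers(pt):
                labels.append(rid)
                break
        else:
            labels.append(UNASSIGNED)
    return labels


def project_points(
    points: np.ndarray, ref_lat: float | None = None
) -> np.ndarray:
    """Equirectangular lon/lat (deg) -> planar km.

    x = R * dlon * cos(ref_lat), y = R * dlat, R = 6371 km, angles in
    radians.  ``ref_lat`` defaults to the mean latitude of the input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2) lon/lat")
    if ref_lat is None:
        ref_lat = float(np.mean(pts[:, 1]))
    rad = np.pi / 180.0
    x = EARTH_RADIUS_KM * pts[:, 0] * rad * math.cos(ref_lat * rad)
    y = EARTH_RADIUS_KM * pts[:, 1] * rad
    return np.column_stack([x, y])
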