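"""Readers and writers for the external formats the pipeline touches.

All geometry lives in a planar, metric coordinate reference system (CRS).
Geographic (longitude/latitude) input is rejected rather than silently
reprojected, because areas and volumes computed in degrees are meaningless.
The CRS itself is carried as an opaque string tag and only ever compared
for equality.

Formats
-------
* point clouds: LAS 1.2 (point format 0) or whitespace/comma delimited XYZ
  text, optionally with extra attribute columns;
* single-band rasters: GeoTIFF (ModelPixelScale + ModelTiepoint tags);
* grids: GeoJSON polygon collections, or generated in memory;
* per-cell summaries: UTF-8 CSV with a fixed, documented column order.
"""

from __future__ import annotations

import json
import math
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box, mapping, shape

__all__ = [
    "PointCloud",
    "Band",
    "RasterStack",
    "GridSpec",
    "FormatError",
    "read_point_cloud",
    "write_point_cloud",
    "read_raster_stack",
    "write_band_geotiff",
    "read_band_geotiff",
    "make_grid",
    "read_grid_geojson",
    "write_grid_geojson",
    "CELL_CSV_COLUMNS",
    "write_cell_csv",
    "read_cell_csv",
]

REFLECTANCE_BANDS = ("R", "G", "B", "N")

#: Column order of the per-cell summary CSV (stable public contract).
CELL_CSV_COLUMNS = [
    "id", "x_min", "y_min", "n_all", "n_veg", "n_vine",
    "R", "G", "B", "N", "NDVI", "Tr",
    "N_v", "NDVI_v", "Tr_v", "N_vc", "NDVI_vc", "Tr_vc",
    "h_v", "h_vc",
    "Volume_v", "SArea_v", "Area_v",
    "Volume_vc", "SArea_vc", "Area_vc",
    "f_c", "w_c", "Ts", "Tc", "flags",
]


class FormatError(ValueError):
    """Raised on malformed input files or violated format contracts."""


_GEOGRAPHIC_HINTS = ("4326", "WGS84", "WGS 84", "CRS84", "LONGLAT", "LATLON")


def _check_planar_crs(crs: str | None) -> None:
    if crs is None:
        return
    u = crs.upper()
    if any(h in u for h in _GEOGRAPHIC_HINTS) and "UTM" not in u:
        raise FormatError(
            f"geographic CRS {crs!r} rejected: a planar metric CRS is required"
        )


# ---------------------------------------------------------------------------
# point clouds
# ---------------------------------------------------------------------------

@dataclass
class PointCloud:
    """A set of 3-D points in one planar CRS with optional per-point attributes.

    Parameters
    ----------
    xyz : (n, 3) float array
        Coordinates in metres.
    attributes : pandas.DataFrame, optional
        One row per point (band values, class codes, ...).
    crs : str, optional
        Opaque CRS tag; compared for equality, never interpreted.
    """

    xyz: np.ndarray
    attributes: pd.DataFrame | None = None
    crs: str | None = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise FormatError("xyz must be an (n, 3) array")
        if self.xyz.size and not np.all(np.isfinite(self.xyz)):
            bad = int(np.flatnonzero(~np.isfinite(self.xyz).all(axis=1))[0])
            raise FormatError(f"non-finite coordinate at record {bad + 1}")
        if self.attributes is not None and len(self.attributes) != len(self.xyz):
            raise FormatError("attribute table must have one row per point")
        _check_planar_crs(self.crs)

    def __len__(self) -> int:
        return len(self.xyz)

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    def take(self, index: np.ndarray) -> "PointCloud":
        """Subset by boolean mask or integer index, preserving order."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        attrs = None
        if self.attributes is not None:
            attrs = self.attributes.iloc[index].reset_index(drop=True)
        return PointCloud(self.xyz[index], attrs, self.crs)


def _read_xyz_text(path: Path) -> PointCloud:
    rows: list[list[str]] = []
    header: list[str] | None = None
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if header is None and not _is_number(parts[0]):
                header = parts
                continue
            rows.append(parts)
    if not rows:
        raise FormatError(f"{path}: no data records")
    ncol = len(rows[0])
    data = np.empty((len(rows), ncol), dtype=np.float64)
    for i, parts in enumerate(rows):
        if len(parts) != ncol:
            raise FormatError(
                f"{path}: record {i + 1} has {len(parts)} fields, expected {ncol}"
            )
        for j, tok in enumerate(parts):
            try:
                data[i, j] = float(tok)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value {tok!r} at record {i + 1}, "
                    f"field {j + 1}"
                ) from None
    if ncol < 3:
        raise FormatError(f"{path}: need at least x y z columns, found {ncol}")
    attrs = None
    if ncol > 3:
        names = (header[3:] if header and len(header) == ncol
                 else [f"attr{k}" for k in range(ncol - 3)])
        attrs = pd.DataFrame(data[:, 3:], columns=names)
    return PointCloud(data[:, :3], attrs)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


# --- minimal LAS 1.2, point record format 0 --------------------------------
# No LAS library ships with this stack, and the subset we need (XYZ with
# fixed scaling) is a stable 227-byte header plus 20-byte records.

_LAS_HEADER_FMT = "<4sHH16sBB32s32sHHHIIBHI5I12d"
_LAS_HEADER_SIZE = struct.calcsize(_LAS_HEADER_FMT)  # 227
_LAS_POINT_DTYPE = np.dtype([
    ("X", "<i4"), ("Y", "<i4"), ("Z", "<i4"),
    ("intensity", "<u2"), ("flags", "u1"), ("classification", "u1"),
    ("scan_angle", "i1"), ("user_data", "u1"), ("point_source", "<u2"),
])


def _write_las(cloud: PointCloud, path: Path, scale: float = 1e-3) -> None:
    xyz = cloud.xyz
    if len(xyz) == 0:
        raise FormatError("refusing to write an empty LAS file")
    offset = xyz.min(axis=0)
    scaled = np.round((xyz - offset) / scale)
    if np.abs(scaled).max() > 2**31 - 1:
        raise FormatError("coordinate range too large for LAS int32 at this scale")
    rec = np.zeros(len(xyz), dtype=_LAS_POINT_DTYPE)
    rec["X"], rec["Y"], rec["Z"] = scaled[:, 0], scaled[:, 1], scaled[:, 2]
    if cloud.attributes is not None and "classification" in cloud.attributes:
        rec["classification"] = (
            cloud.attributes["classification"].to_numpy().astype(np.uint8)
        )
    lo, hi = xyz.min(axis=0), xyz.max(axis=0)
    header = struct.pack(
        _LAS_HEADER_FMT,
        b"LASF", 0, 0, b"\0" * 16, 1, 2,
        b"canopyflux".ljust(32, b"\0"), b"canopyflux".ljust(32, b"\0"),
        1, 2020, _LAS_HEADER_SIZE, _LAS_HEADER_SIZE, 0,
        0, _LAS_POINT_DTYPE.itemsize, len(xyz), len(xyz), 0, 0, 0, 0,
        scale, scale, scale, offset[0], offset[1], offset[2],
        hi[0], lo[0], hi[1], lo[1], hi[2], lo[2],
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(rec.tobytes())


def _read_las(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        head = fh.read(_LAS_HEADER_SIZE)
        if len(head) < _LAS_HEADER_SIZE or head[:4] != b"LASF":
            raise FormatError(f"{path}: not a LAS file")
        fields = struct.unpack(_LAS_HEADER_FMT, head)
        point_format, rec_len, n_points = fields[13], fields[14], fields[15]
        data_offset = fields[11]
        sx, sy, sz, ox, oy, oz = fields[21:27]
        if point_format != 0 or rec_len != _LAS_POINT_DTYPE.itemsize:
            raise FormatError(
                f"{path}: unsupported LAS point format {point_format} "
                f"(record length {rec_len}); only format 0 is supported"
            )
        fh.seek(data_offset)
        raw = fh.read(rec_len * n_points)
    rec = np.frombuffer(raw, dtype=_LAS_POINT_DTYPE, count=n_points)
    xyz = np.column_stack([
        rec["X"] * sx + ox, rec["Y"] * sy + oy, rec["Z"] * sz + oz,
    ])
    attrs = pd.DataFrame({"classification": rec["classification"].astype(int)})
    return PointCloud(xyz, attrs)


def read_point_cloud(path: str | Path, format: str | None = None) -> PointCloud:
    """Read a point cloud from LAS 1.2 or delimited XYZ text.

    ``format`` is ``"las"`` or ``"xyz"``; when omitted it is inferred from
    the file extension. Point order is preserved; extra numeric columns in
    XYZ files are attached as an attribute table.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format is None:
        format = "las" if path.suffix.lower() in (".las",) else "xyz"
    if format == "las":
        return _read_las(path)
    if format == "xyz":
        return _read_xyz_text(path)
    raise FormatError(f"unknown point-cloud format {format!r}")


def write_point_cloud(cloud: PointCloud, path: str | Path,
                      format: str | None = None) -> None:
    """Write a point cloud as LAS 1.2 (mm precision) or XYZ text."""
    path = Path(path)
    if format is None:
        format = "las" if path.suffix.lower() == ".las" else "xyz"
    if format == "las":
        _write_las(cloud, path)
    elif format == "xyz":
        cols = [pd.DataFrame(cloud.xyz, columns=["x", "y", "z"])]
        if cloud.attributes is not None:
            cols.append(cloud.attributes.reset_index(drop=True))
        pd.concat(cols, axis=1).to_csv(path, sep=" ", index=False,
                                       float_format="%.6f")
    else:
        raise FormatError(f"unknown point-cloud format {format!r}")


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

@dataclass
class Band:
    """One single-band raster: data grid plus a north-up affine transform.

    ``data`` is float64 with NaN marking nodata. The transform is the
    GeoTIFF convention: ``origin`` is the outer corner of the top-left
    pixel, ``dx > 0`` eastward, ``dy > 0`` is the pixel height southward.
    """

    data: np.ndarray
    x_origin: float
    y_origin: float
    dx: float
    dy: float
    crs: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise FormatError("band data must be 2-D")
        if self.dx <= 0 or self.dy <= 0:
            raise FormatError("pixel sizes must be positive")
        _check_planar_crs(self.crs)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of x (per column) and y (per row) pixel centres."""
        nrow, ncol = self.data.shape
        xs = self.x_origin + (np.arange(ncol) + 0.5) * self.dx
        ys = self.y_origin - (np.arange(nrow) + 0.5) * self.dy
        return xs, ys

    def nearest_index(self, x: np.ndarray, y: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the pixel whose centre is horizontally nearest.

        Ties (points equidistant from two centres) resolve to the lower
        (row, col) index.
        """
        u = (np.asarray(x) - self.x_origin) / self.dx - 0.5
        v = (self.y_origin - np.asarray(y)) / self.dy - 0.5
        col = np.ceil(u - 0.5).astype(int)
        row = np.ceil(v - 0.5).astype(int)
        return row, col

    def bounds(self) -> tuple[float, float, float, float]:
        nrow, ncol = self.data.shape
        return (self.x_origin, self.y_origin - nrow * self.dy,
                self.x_origin + ncol * self.dx, self.y_origin)


@dataclass
class RasterStack:
    """Co-registered single-band rasters keyed by band name.

    Reflectance bands (R, G, B, N) are dimensionless in [0, 1]; the
    radiometric temperature band ``Tr`` is in degrees Celsius. Bands may
    differ in resolution (thermal is typically coarser) but share one CRS.
    """

    bands: dict[str, Band] = field(default_factory=dict)

    def __getitem__(self, name: str) -> Band:
        return self.bands[name]

    def __contains__(self, name: str) -> bool:
        return name in self.bands

    @property
    def crs(self) -> str | None:
        for b in self.bands.values():
            return b.crs
        return None

    def validate(self) -> None:
        crs_set = {b.crs for b in self.bands.values()}
        if len(crs_set) > 1:
            raise FormatError(f"bands disagree on CRS: {sorted(map(str, crs_set))}")
        for name in REFLECTANCE_BANDS:
            if name in self.bands:
                d = self.bands[name].data
                bad = int(np.sum((d < 0) | (d > 1)))
                if bad:
                    raise FormatError(
                        f"band {name}: {bad} pixel(s) outside the reflectance "
                        f"range [0, 1]"
                    )


_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def write_band_geotiff(band: Band, path: str | Path,
                       nodata: float = -9999.0) -> None:
    """Write one band as a GeoTIFF with pixel-scale and tiepoint tags."""
    import tifffile

    data = band.data.copy()
    data[~np.isfinite(data)] = nodata
    desc = json.dumps({"crs": band.crs})
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (band.dx, band.dy, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, band.x_origin, band.y_origin, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(path, data.astype(np.float32), description=desc,
                     extratags=extratags)


def read_band_geotiff(path: str | Path) -> Band:
    """Read a single-band GeoTIFF written by :func:`write_band_geotiff`
    (or any GeoTIFF carrying ModelPixelScale + ModelTiepoint tags)."""
    import tifffile

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(np.float64)
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise FormatError(f"{path}: missing GeoTIFF georeferencing tags")
        sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
        tie = tags[_TAG_MODEL_TIEPOINT].value
        x0 = tie[3] - tie[0] * sx
        y0 = tie[4] + tie[1] * sy
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        crs = None
        if 270 in tags:
            try:
                crs = json.loads(tags[270].value).get("crs")
            except (json.JSONDecodeError, AttributeError):
                crs = None
    if nodata is not None:
        data[data == nodata] = np.nan
    return Band(data, x0, y0, float(sx), float(sy), crs)


def read_raster_stack(paths_by_band: Mapping[str, str | Path]) -> RasterStack:
    """Load one GeoTIFF per band into a validated :class:`RasterStack`.

    Nodata is mapped to NaN; reflectance bands must land in [0, 1]; all
    bands must agree on the CRS. Per-band transforms are retained, so the
    thermal band may be coarser than the optical bands.
    """
    stack = RasterStack({name: read_band_geotiff(p)
                         for name, p in paths_by_band.items()})
    stack.validate()
    return stack


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------

@dataclass
class GridSpec:
    """Axis-aligned square analysis grid with half-open cells.

    Cell ids are row-major from the lower-left corner: id = row * nx + col
    with row 0 at the bottom. Each cell is the half-open box
    [x0, x1) x [y0, y1), so every point belongs to exactly one cell.
    """

    x_min: float
    y_min: float
    cell_size: float
    nx: int
    ny: int
    crs: str | None = None

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise FormatError("cell size must be positive")
        if self.nx <= 0 or self.ny <= 0:
            raise FormatError("grid must have at least one cell")
        _check_planar_crs(self.crs)

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def cell_area(self) -> float:
        return self.cell_size ** 2

    def cell_bounds(self, cell_id: int) -> tuple[float, float, float, float]:
        row, col = divmod(cell_id, self.nx)
        x0 = self.x_min + col * self.cell_size
        y0 = self.y_min + row * self.cell_size
        return x0, y0, x0 + self.cell_size, y0 + self.cell_size

    def cell_polygon(self, cell_id: int) -> Polygon:
        return box(*self.cell_bounds(cell_id))

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Cell id per point; -1 for points outside the grid."""
        col = np.floor((np.asarray(x) - self.x_min) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y) - self.y_min) / self.cell_size).astype(int)
        ids = row * self.nx + col
        outside = (col < 0) | (col >= self.nx) | (row < 0) | (row >= self.ny)
        ids[outside] = -1
        return ids


def make_grid(bounds: Sequence[float], cell_size: float,
              crs: str | None = None) -> GridSpec:
    """Tile ``bounds = (x_min, y_min, x_max, y_max)`` with square cells.

    The tiling starts at the lower-left corner and uses enough cells to
    cover the bounds (ceil division), so the last row/column may extend
    past the data.
    """
    x_min, y_min, x_max, y_max = bounds
    if cell_size <= 0:
        raise FormatError("cell size must be positive")
    if x_max <= x_min or y_max <= y_min:
        raise FormatError("bounds must have positive width and height")
    nx = math.ceil((x_max - x_min) / cell_size - 1e-12)
    ny = math.ceil((y_max - y_min) / cell_size - 1e-12)
    return GridSpec(x_min, y_min, cell_size, nx, ny, crs)


def write_grid_geojson(grid: GridSpec, path: str | Path) -> None:
    features = []
    for cid in range(grid.n_cells):
        features.append({
            "type": "Feature",
            "id": cid,
            "properties": {"cell_id": cid},
            "geometry": mapping(grid.cell_polygon(cid)),
        })
    doc = {
        "type": "FeatureCollection",
        "features": features,
        "properties": {
            "x_min": grid.x_min, "y_min": grid.y_min,
            "cell_size": grid.cell_size, "nx": grid.nx, "ny": grid.ny,
            "crs": grid.crs,
        },
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def read_grid_geojson(path: str | Path) -> GridSpec:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    props = doc.get("properties", {})
    if {"x_min", "y_min", "cell_size", "nx", "ny"} <= props.keys():
        return GridSpec(props["x_min"], props["y_min"], props["cell_size"],
                        props["nx"], props["ny"], props.get("crs"))
    # Fall back to reconstructing the lattice from the cell polygons.
    polys = [shape(f["geometry"]) for f in doc["features"]]
    if not polys:
        raise FormatError(f"{path}: empty grid")
    xs = sorted({p.bounds[0] for p in polys})
    ys = sorted({p.bounds[1] for p in polys})
    cell = polys[0].bounds[2] - polys[0].bounds[0]
    return GridSpec(xs[0], ys[0], cell, len(xs), len(ys))


# ---------------------------------------------------------------------------
# per-cell summary CSV
# ---------------------------------------------------------------------------

def write_cell_csv(summaries: pd.DataFrame | Iterable[dict],
                   path: str | Path) -> None:
    """Write per-cell summaries in the fixed public column order.

    Missing metrics are written as empty fields; the ``flags`` column is a
    semicolon-separated list of condition flags (empty when clean).
    """
    df = summaries if isinstance(summaries, pd.DataFrame) \
        else pd.DataFrame(list(summaries))
    out = pd.DataFrame({c: df[c] if c in df.columns else np.nan
                        for c in CELL_CSV_COLUMNS})
    out["flags"] = out["flags"].fillna("")
    out.to_csv(path, index=False, float_format="%.8g")


def read_cell_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=True)
    missing = [c for c in CELL_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df["flags"] = df["flags"].fillna("")
    return df
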