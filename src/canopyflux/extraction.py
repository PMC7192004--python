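"""Per-cell spectral attribution, ground normalisation and TIN structure.

The extraction walks a square analysis grid over a photogrammetric point
cloud. In every cell it

1. attributes each point with the horizontally nearest pixel value of
   each co-registered raster band (R, G, B, NIR, thermal);
2. establishes a ground reference — mode I takes the minimum elevation
   of the spectrally classified ground points in the cell, mode II takes
   the elevation of the nearest LiDAR-like ground point per point — and
   converts elevations to heights above ground;
3. classifies points into ground / cover crop / vine using an NDVI
   threshold and a 0.5 m relative-height threshold;
4. triangulates each vegetation class in the horizontal plane (Delaunay)
   and integrates the resulting piecewise-linear surface for volume, 3-D
   surface area and nadir-projected area;
5. summarises spectral means and structural metrics per class, plus the
   soil/canopy component temperatures from the NDVI-Tr scatter.

Mode I assumes the ground inside one cell is level (its reference is a
single minimum); mode II follows terrain and is slope-robust.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError, cKDTree

from .io_formats import (CELL_CSV_COLUMNS, GridSpec, PointCloud, RasterStack)
from .temperature import retrieve_cell_temperatures, select_thresholds

__all__ = [
    "ExtractionConfig",
    "TinMetrics",
    "ndvi",
    "attribute_point_spectra",
    "assign_ground_reference",
    "classify_points",
    "tin_metrics",
    "summarize_cell",
    "run_extraction",
]

GROUND, COVER_CROP, VINE = "ground", "cover_crop", "vine"


@dataclass
class ExtractionConfig:
    """Tunable thresholds of the extraction.

    ndvi_threshold : points at or below it are ground (default 0.6).
    vine_height_threshold : m; vegetation at or above it is vine canopy,
        below it cover crop (default 0.5, inclusive on the vine side).
    mode : "I" (spectral ground, per-cell minimum) or "II" (per-point
        nearest LiDAR ground elevation).
    min_points : minimum class size for a trustworthy TIN; smaller
        classes yield zero metrics and an ``insufficient_points`` flag.
    max_tin_edge : m or None; when set, triangles with any horizontal
        edge longer than this are dropped before integration (mitigates
        convex-hull bridging over gaps).
    row_spacing : m; vine row spacing used to derive the canopy width
        w_c = row_spacing * f_c.
    search_radius_pixels : how far (in pixels of each band) to look for a
        valid pixel when the nearest one is nodata.
    """

    ndvi_threshold: float = 0.6
    vine_height_threshold: float = 0.5
    mode: str = "I"
    min_points: int = 10
    max_tin_edge: float | None = None
    row_spacing: float = 3.35
    search_radius_pixels: int = 3
    threshold_method: str = "percentile"
    fixed_thresholds: tuple[float, float] | None = None
    #: mode II ground attribution: "nearest" assigns the z of the
    #: horizontally nearest ground point; "tin" interpolates the ground
    #: surface linearly (exact on planar terrain, avoids the sawtooth
    #: the nearest rule imprints on sloped ground)
    ground_interp: str = "nearest"

    def __post_init__(self) -> None:
        if self.mode not in ("I", "II"):
            raise ValueError(f"mode must be 'I' or 'II', got {self.mode!r}")
        if self.ground_interp not in ("nearest", "tin"):
            raise ValueError("ground_interp must be 'nearest' or 'tin'")
        if not np.isfinite(self.ndvi_threshold):
            raise ValueError("ndvi_threshold must be finite")


def ndvi(nir, red):
    """Normalized difference vegetation index (NIR - R) / (NIR + R).

    Reflectances must be non-negative; a zero denominator yields NaN.
    """
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    if np.any(nir[np.isfinite(nir)] < 0) or np.any(red[np.isfinite(red)] < 0):
        raise ValueError("reflectance must be non-negative")
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (nir - red) / denom, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def attribute_point_spectra(points: PointCloud, rasters: RasterStack,
                            search_radius_pixels: int = 3) -> pd.DataFrame:
    """Per-point band values from the horizontally nearest valid pixel.

    Bands may differ in resolution; each is sampled independently. A point
    whose nearest pixel is nodata is resolved to the nearest valid pixel
    within ``search_radius_pixels``; failing that the value stays NaN and
    the point is flagged (column ``no_pixel``), never dropped.
    """
    if points.crs is not None and rasters.crs is not None \
            and points.crs != rasters.crs:
        raise ValueError(f"CRS mismatch: points {points.crs!r} "
                         f"vs rasters {rasters.crs!r}")
    out = pd.DataFrame(index=range(len(points)))
    no_pixel = np.zeros(len(points), dtype=bool)
    for name, band in rasters.bands.items():
        if band.data.size == 0:
            raise ValueError(f"band {name} is empty")
        nrow, ncol = band.shape
        row, col = band.nearest_index(points.x, points.y)
        row_c = np.clip(row, 0, nrow - 1)
        col_c = np.clip(col, 0, ncol - 1)
        vals = band.data[row_c, col_c]
        # off-raster points are only accepted within the search radius
        off = (np.abs(row - row_c) > search_radius_pixels) | \
              (np.abs(col - col_c) > search_radius_pixels)
        vals = np.where(off, np.nan, vals)
        missing = np.flatnonzero(~np.isfinite(vals) & ~off)
        for i in missing:
            vals[i] = _nearest_valid(band, row_c[i], col_c[i],
                                     search_radius_pixels)
        no_pixel |= ~np.isfinite(vals)
        out[name] = vals
    out["no_pixel"] = no_pixel
    return out


def _nearest_valid(band, row: int, col: int, radius: int) -> float:
    """Nearest finite pixel within a (2r+1)^2 window, centre distance
    metric, ties to the lower (row, col)."""
    nrow, ncol = band.shape
    best, best_d = np.nan, np.inf
    for r in range(max(0, row - radius), min(nrow, row + radius + 1)):
        for c in range(max(0, col - radius), min(ncol, col + radius + 1)):
            v = band.data[r, c]
            if np.isfinite(v):
                d = (r - row) ** 2 + (c - col) ** 2
                if d < best_d:
                    best, best_d = v, d
    return best


def assign_ground_reference(cell: pd.DataFrame, mode: str,
                            ground_tree: cKDTree | None = None,
                            ground_z: np.ndarray | None = None,
                            ndvi_threshold: float = 0.6,
                            ground_lookup=None,
                            ) -> tuple[pd.DataFrame, list[str]]:
    """Attach ``ground_z`` and ``rel_height`` columns to a cell's points.

    Mode I: ground class = NDVI <= threshold; the cell-wide reference is
    the minimum z of those points (fallback: minimum z of all points,
    flagged). Mode II: per point, the z of the horizontally nearest
    LiDAR-like ground point. Relative heights more than 1 cm below zero
    are flagged; all negatives are floored at 0.
    """
    if len(cell) == 0:
        raise ValueError("empty cell")
    flags: list[str] = []
    cell = cell.copy()
    if mode == "I":
        nd = cell["NDVI"].to_numpy() if "NDVI" in cell else \
            np.full(len(cell), np.nan)
        ground_mask = np.isfinite(nd) & (nd <= ndvi_threshold)
        if ground_mask.any():
            ref = float(cell.loc[ground_mask, "z"].min())
        else:
            ref = float(cell["z"].min())
            flags.append("no_ground_class")
        cell["ground_z"] = ref
    elif mode == "II":
        if ground_lookup is not None:
            cell["ground_z"] = ground_lookup(cell[["x", "y"]].to_numpy())
        elif ground_tree is not None and ground_z is not None:
            _, idx = ground_tree.query(cell[["x", "y"]].to_numpy())
            cell["ground_z"] = ground_z[idx]
        else:
            raise ValueError("mode II requires ground points")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rel = cell["z"].to_numpy() - cell["ground_z"].to_numpy()
    if np.any(rel < -0.01):
        flags.append("negative_rel_height")
    cell["rel_height"] = np.maximum(rel, 0.0)
    return cell, flags


def classify_points(cell: pd.DataFrame, config: ExtractionConfig
                    ) -> pd.DataFrame:
    """Label points ground / cover_crop / vine.

    NDVI at or below the threshold is ground; vegetation splits at the
    relative-height threshold, inclusive on the vine side. Points without
    spectra (NaN NDVI) fall through to the structural rule — with no
    index to call them soil, height decides.
    """
    cell = cell.copy()
    nd = cell["NDVI"].to_numpy() if "NDVI" in cell else \
        np.full(len(cell), np.nan)
    rel = cell["rel_height"].to_numpy()
    label = np.where(rel >= config.vine_height_threshold, VINE, COVER_CROP)
    label = np.where(np.isfinite(nd) & (nd <= config.ndvi_threshold),
                     GROUND, label)
    cell["class"] = label
    return cell


@dataclass
class TinMetrics:
    volume: float
    surface_area: float
    projected_area: float
    flags: list[str]


def tin_metrics(xy: np.ndarray, rel_heights: np.ndarray,
                max_tin_edge: float | None = None,
                min_points: int = 3) -> TinMetrics:
    """Volume, 3-D surface area and projected area of a class TIN.

    The points are Delaunay-triangulated on (x, y) with the relative
    height as elevation. Per triangle: the planimetric area contributes
    to the projected area; planimetric area times the mean of the three
    vertex heights contributes to the volume (exact for the
    piecewise-linear surface); the 3-D triangle area contributes to the
    surface area. Duplicate (x, y) positions collapse to the highest
    point (flagged); fewer than ``min_points`` points, or a degenerate
    (collinear) configuration, yields zero metrics and a flag.
    """
    xy = np.asarray(xy, dtype=float)
    h = np.asarray(rel_heights, dtype=float)
    flags: list[str] = []

    if len(xy) > 1:
        # collapse duplicate plan positions, keeping the highest return
        order = np.lexsort((h, xy[:, 1], xy[:, 0]))
        xs, hs = xy[order], h[order]
        same = np.all(xs[1:] == xs[:-1], axis=1)
        if same.any():
            keep = np.append(~same, True)  # last of each run has max h
            xy, h = xs[keep], hs[keep]
            flags.append("duplicate_xy")

    if len(xy) < max(3, min_points):
        flags.append("insufficient_points")
        return TinMetrics(0.0, 0.0, 0.0, flags)
    try:
        tri = Delaunay(xy)
    except QhullError:
        flags.append("degenerate_geometry")
        return TinMetrics(0.0, 0.0, 0.0, flags)

    simp = tri.simplices
    p = xy[simp]                      # (m, 3, 2)
    hz = h[simp]                      # (m, 3)
    if max_tin_edge is not None:
        e = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 1],
                      p[:, 0] - p[:, 2]])
        longest = np.sqrt((e ** 2).sum(-1)).max(axis=0)
        keep = longest <= max_tin_edge
        simp, p, hz = simp[keep], p[keep], hz[keep]
    v1 = p[:, 1] - p[:, 0]
    v2 = p[:, 2] - p[:, 0]
    area2d = 0.5 * np.abs(v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])
    volume = float(np.sum(area2d * hz.mean(axis=1)))
    w1 = np.column_stack([v1, hz[:, 1] - hz[:, 0]])
    w2 = np.column_stack([v2, hz[:, 2] - hz[:, 0]])
    cross = np.cross(w1, w2)
    area3d = 0.5 * np.sqrt((cross ** 2).sum(axis=1))
    return TinMetrics(volume, float(area3d.sum()), float(area2d.sum()), flags)


def summarize_cell(cell: pd.DataFrame, config: ExtractionConfig,
                   cell_area: float, cell_id: int = 0,
                   x_min: float = np.nan, y_min: float = np.nan,
                   extra_flags: list[str] | None = None) -> dict:
    """Collapse one cell's classified points into the summary record.

    Vegetation (subscript v) metrics use all non-ground points; vine
    (subscript vc) metrics use the vine class only. f_c is the vine
    projected area over the cell area; w_c = row_spacing * f_c.
    """
    flags = list(extra_flags or [])
    rec: dict = {c: np.nan for c in CELL_CSV_COLUMNS}
    rec.update(id=cell_id, x_min=x_min, y_min=y_min)

    def _mean(df: pd.DataFrame, col: str) -> float:
        if col not in df or len(df) == 0:
            return np.nan
        v = df[col].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        return float(v.mean()) if v.size else np.nan

    rec["n_all"] = len(cell)
    for col in ("R", "G", "B", "N", "NDVI", "Tr"):
        rec[col] = _mean(cell, col)

    veg = cell[cell["class"] != GROUND]
    vine = cell[cell["class"] == VINE]
    rec["n_veg"], rec["n_vine"] = len(veg), len(vine)
    for sub, df in (("v", veg), ("vc", vine)):
        rec[f"N_{sub}"] = _mean(df, "N")
        rec[f"NDVI_{sub}"] = _mean(df, "NDVI")
        rec[f"Tr_{sub}"] = _mean(df, "Tr")
        rec[f"h_{sub}"] = _mean(df, "rel_height") if len(df) else 0.0
        m = tin_metrics(df[["x", "y"]].to_numpy(),
                        df["rel_height"].to_numpy(),
                        max_tin_edge=config.max_tin_edge,
                        min_points=config.min_points)
        rec[f"Volume_{sub}"] = m.volume
        rec[f"SArea_{sub}"] = m.surface_area
        rec[f"Area_{sub}"] = m.projected_area
        flags.extend(f"{f}_{sub}" for f in m.flags)

    rec["f_c"] = rec["Area_vc"] / cell_area
    rec["w_c"] = config.row_spacing * rec["f_c"]
    rec["flags"] = ";".join(dict.fromkeys(flags))
    return rec


def _empty_cell_record(cell_id: int, x_min: float, y_min: float) -> dict:
    rec: dict = {c: np.nan for c in CELL_CSV_COLUMNS}
    rec.update(id=cell_id, x_min=x_min, y_min=y_min,
               n_all=0, n_veg=0, n_vine=0,
               h_v=0.0, h_vc=0.0, f_c=0.0, w_c=0.0)
    for sub in ("v", "vc"):
        for m in ("Volume", "SArea", "Area"):
            rec[f"{m}_{sub}"] = 0.0
    rec["flags"] = "empty_cell"
    return rec


def run_extraction(point_cloud: PointCloud, rasters: RasterStack | None,
                   grid: GridSpec, config: ExtractionConfig | None = None,
                   ground: PointCloud | None = None) -> pd.DataFrame:
    """Run the full per-cell pipeline over the grid.

    Returns one row per grid cell in id order (cells without points are
    emitted with an ``empty_cell`` flag, preserving the grid shape).
    When rasters with NIR/R and thermal bands are present, per-cell soil
    and canopy temperatures are retrieved as a by-product.
    """
    config = config or ExtractionConfig()
    if config.mode == "II" and (ground is None or len(ground) == 0):
        raise ValueError("mode II requires a non-empty ground point cloud")
    for other, what in ((rasters.crs if rasters else None, "rasters"),
                        (grid.crs, "grid"),
                        (ground.crs if ground else None, "ground points")):
        if point_cloud.crs is not None and other is not None \
                and point_cloud.crs != other:
            raise ValueError(f"CRS mismatch between point cloud and {what}")

    pts = pd.DataFrame(point_cloud.xyz, columns=["x", "y", "z"])
    if rasters is not None and rasters.bands:
        spectra = attribute_point_spectra(point_cloud, rasters,
                                          config.search_radius_pixels)
        pts = pd.concat([pts, spectra], axis=1)
        if "N" in pts and "R" in pts:
            pts["NDVI"] = ndvi(pts["N"].to_numpy(), pts["R"].to_numpy())

    ground_lookup = None
    if ground is not None and len(ground):
        ground_lookup = _make_ground_lookup(ground, config.ground_interp)

    thermal = None
    if rasters is not None and "Tr" in rasters and "N" in rasters \
            and "R" in rasters:
        thermal = _thermal_pixel_table(rasters)
        ndvi_s, ndvi_c = select_thresholds(
            thermal["NDVI"].to_numpy(), method=config.threshold_method,
            fixed=config.fixed_thresholds)

    cell_ids = grid.cell_index(pts["x"].to_numpy(), pts["y"].to_numpy())
    records = []
    for cid in range(grid.n_cells):
        x0, y0, x1, y1 = grid.cell_bounds(cid)
        in_cell = pts[cell_ids == cid]
        if len(in_cell) == 0:
            rec = _empty_cell_record(cid, x0, y0)
        else:
            cell, gflags = assign_ground_reference(
                in_cell, config.mode, ndvi_threshold=config.ndvi_threshold,
                ground_lookup=ground_lookup)
            cell = classify_points(cell, config)
            rec = summarize_cell(cell, config, grid.cell_area, cid, x0, y0,
                                 extra_flags=gflags)
        if thermal is not None:
            sel = thermal[(thermal["x"] >= x0) & (thermal["x"] < x1)
                          & (thermal["y"] >= y0) & (thermal["y"] < y1)]
            ct = retrieve_cell_temperatures(sel["NDVI"].to_numpy(),
                                            sel["Tr"].to_numpy(),
                                            ndvi_s, ndvi_c)
            rec["Ts"], rec["Tc"] = ct.Ts, ct.Tc
            if ct.flags:
                joined = ";".join(filter(None, [rec.get("flags", ""),
                                                *ct.flags]))
                rec["flags"] = joined
        records.append(rec)
    return pd.DataFrame.from_records(records, columns=CELL_CSV_COLUMNS)


def _make_ground_lookup(ground: PointCloud, interp: str):
    """Callable (n,2) xy -> ground z from the LiDAR-like ground cloud."""
    tree = cKDTree(ground.xyz[:, :2])
    gz = ground.xyz[:, 2]

    def nearest(xy: np.ndarray) -> np.ndarray:
        _, idx = tree.query(xy)
        return gz[idx]

    if interp == "nearest":
        return nearest

    from scipy.interpolate import LinearNDInterpolator

    lin = LinearNDInterpolator(ground.xyz[:, :2], gz)

    def tin_interp(xy: np.ndarray) -> np.ndarray:
        z = lin(xy)
        hole = ~np.isfinite(z)
        if hole.any():                 # outside the ground hull
            z[hole] = nearest(xy[hole])
        return z

    return tin_interp


def _thermal_pixel_table(rasters: RasterStack) -> pd.DataFrame:
    """NDVI averaged onto the thermal grid, one row per valid Tr pixel.

    The thermal band is the coarsest, so NDVI is aggregated (mean of the
    optical pixels whose centres fall inside each thermal pixel) rather
    than the thermal data being sharpened.
    """
    from scipy.stats import binned_statistic_2d

    tr = rasters["Tr"]
    nb, rb = rasters["N"], rasters["R"]
    nd = ndvi(nb.data, np.asarray(rb.data, dtype=float)) \
        if nb.shape == rb.shape else None
    if nd is None:
        raise ValueError("N and R bands must share one grid to compute NDVI")
    oxs, oys = nb.pixel_centers()
    ox, oy = np.meshgrid(oxs, oys)
    valid = np.isfinite(nd)
    nrow, ncol = tr.shape
    x_edges = tr.x_origin + np.arange(ncol + 1) * tr.dx
    y_edges = tr.y_origin - np.arange(nrow + 1)[::-1] * tr.dy
    stat, _, _, _ = binned_statistic_2d(
        ox[valid].ravel(), oy[valid].ravel(), nd[valid].ravel(),
        statistic="mean", bins=[x_edges, y_edges])
    ndvi_tr = stat.T[::-1]            # back to row 0 = top
    txs, tys = tr.pixel_centers()
    tx, ty = np.meshgrid(txs, tys)
    ok = np.isfinite(tr.data) & np.isfinite(ndvi_tr)
    return pd.DataFrame({"x": tx[ok], "y": ty[ok],
                         "NDVI": ndvi_tr[ok], "Tr": tr.data[ok]})
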