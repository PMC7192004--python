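"""Parametric vineyard scenes with analytic per-cell truth.

The generator emulates the kind of data a photogrammetric survey of a
trellised vineyard produces: a point cloud sampling the *upper* canopy
envelope (cameras cannot see beneath the canopy), co-registered optical
reflectance and radiometric temperature rasters, and a LiDAR-like ground
point set on the true terrain.

Geometry: vine rows run along x at a fixed spacing, each a box-section
canopy strip (flat top at ``vine_height`` above local ground). A grass
cover-crop band of configurable width occupies the middle of each
inter-row; the rest of the inter-row is bare soil. Optional gaps knock
out vine units (missing plants) and are floored with grass. The terrain
is a plane with configurable slope along x.

Every scene ships with closed-form per-cell truth for the box geometry,
so the downstream TIN extraction can be checked cell by cell. Point
sampling combines a jittered grid with explicit break-line points along
canopy edges and analysis-grid transects; without break lines the convex
hull of a finite sample systematically under-covers the footprint by the
mean point spacing — a tessellation artifact that would mask real
algorithm errors in the recovery comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.ops import unary_union

from .io_formats import Band, GridSpec, PointCloud, RasterStack, make_grid

__all__ = [
    "SceneConfig",
    "Scene",
    "generate_scene",
    "analytic_cell_truth",
    "generate_forcing",
    "generate_lai_observations",
]

SOIL, GRASS, CANOPY = 0, 1, 2
_VINE_UNIT = 1.5          # m along-row length of one vine (plant spacing)
_EDGE_EPS = 1e-3          # m offset of the second break-line transect


@dataclass
class SceneConfig:
    """Parametric description of a synthetic vineyard scene.

    Defaults describe the emulated acquisition: 3.35 m row spacing,
    2.2 m vines over a 0.7 m open trunk zone, a short (0.15 m) inter-row
    cover crop, ~100 points/m2, and a hot-soil / cool-canopy thermal
    contrast around midday.
    """

    width: float = 36.0               # scene extent along x, m
    height: float = 36.0              # scene extent along y, m
    origin: tuple[float, float] = (0.0, 0.0)
    row_spacing: float = 3.35         # m between vine rows
    vine_height: float = 2.2          # canopy top above local ground, m
    canopy_base: float = 0.7          # open space below the crown, m
    canopy_width: float = 1.0         # strip width, m
    cover_height: float = 0.15        # cover-crop height, m (< 0.5)
    cover_fraction: float = 0.4       # fraction of inter-row under grass
    gap_fraction: float = 0.0         # fraction of vine units missing
    point_density: float = 100.0      # photogrammetric points / m2
    ground_point_density: float = 6.0  # LiDAR-like ground returns / m2
    terrain_slope: float = 0.0        # dz/dx
    base_elevation: float = 10.0      # m
    optical_resolution: float = 0.10  # m / pixel (R, G, B, N)
    thermal_resolution: float = 0.60  # m / pixel (Tr)
    veg_reflectance: dict = field(default_factory=lambda: {
        "R": 0.05, "G": 0.08, "B": 0.04, "N": 0.50})
    soil_reflectance: dict = field(default_factory=lambda: {
        "R": 0.20, "G": 0.18, "B": 0.15, "N": 0.25})
    reflectance_noise_sd: float = 0.01
    ts_mean: float = 45.0             # soil temperature, deg C
    tc_mean: float = 30.0             # canopy temperature, deg C
    temperature_noise_sd: float = 0.3  # deg C, thermal pixel noise
    canopy_z_noise_sd: float = 0.02   # m, photogrammetric height noise
    ground_z_noise_sd: float = 0.005  # m
    seed: int = 0
    crs: str = "EPSG:32610"

    def __post_init__(self) -> None:
        if not (0 < self.cover_height < 0.5):
            raise ValueError("cover_height must be in (0, 0.5) m")
        if self.vine_height <= 0.5:
            raise ValueError("vine_height must exceed the 0.5 m class split")
        if self.point_density <= 0 or self.ground_point_density <= 0:
            raise ValueError("point densities must be positive")
        if self.ts_mean < self.tc_mean:
            raise ValueError("soil must not be cooler than canopy (Ts >= Tc)")
        if not (0 <= self.cover_fraction <= 1):
            raise ValueError("cover_fraction must lie in [0, 1]")
        if self.canopy_width >= self.row_spacing:
            raise ValueError("canopy must be narrower than the row spacing")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        x0, y0 = self.origin
        return (x0, y0, x0 + self.width, y0 + self.height)

    @property
    def n_rows(self) -> int:
        return int(self.height // self.row_spacing)


class _Geometry:
    """Deterministic surface layout shared by points, rasters and truth."""

    def __init__(self, config: SceneConfig, rng: np.random.Generator):
        self.cfg = config
        s, w = config.row_spacing, config.canopy_width
        self.strip_lo = s / 2 - w / 2    # within-row offset of strip edges
        self.strip_hi = s / 2 + w / 2
        self.grass_half = config.cover_fraction * (s - w) / 2
        n_units = int(np.ceil(config.width / _VINE_UNIT))
        self.gaps = rng.random((config.n_rows, n_units)) < config.gap_fraction

    def ground_z(self, x, y):
        x0 = self.cfg.origin[0]
        return self.cfg.base_elevation + self.cfg.terrain_slope * \
            (np.asarray(x, float) - x0)

    def surface_class(self, x, y, canopy_dilate: float = 0.0):
        """SOIL / GRASS / CANOPY per (x, y), vectorised.

        ``canopy_dilate`` widens the canopy strips (m per side) when
        classifying raster pixels: a mixed pixel on a canopy edge is
        dominated by the bright canopy signal, so pixels whose centres
        fall within half a pixel of the strip read as vegetation.
        """
        cfg = self.cfg
        x0, y0 = cfg.origin
        xr = np.asarray(x, float) - x0
        yr = np.asarray(y, float) - y0
        k = np.floor(yr / cfg.row_spacing).astype(int)
        y_in = yr - k * cfg.row_spacing
        in_row = (k >= 0) & (k < cfg.n_rows)
        in_strip = in_row & (y_in >= self.strip_lo - canopy_dilate) \
            & (y_in < self.strip_hi + canopy_dilate)
        u = np.clip(np.floor(xr / _VINE_UNIT).astype(int),
                    0, self.gaps.shape[1] - 1)
        gap = self.gaps[np.clip(k, 0, max(cfg.n_rows - 1, 0)), u] & in_strip
        canopy = in_strip & ~gap
        near_band = np.minimum(y_in, cfg.row_spacing - y_in) < self.grass_half
        grass = (~in_strip & near_band) | gap
        return np.where(canopy, CANOPY, np.where(grass, GRASS, SOIL))

    def canopy_segments(self):
        """Rectangles (a, b, lo, hi) of contiguous canopy, scene coords."""
        cfg = self.cfg
        x0, y0 = cfg.origin
        segs = []
        n_units = self.gaps.shape[1]
        for k in range(cfg.n_rows):
            lo = y0 + k * cfg.row_spacing + self.strip_lo
            hi = y0 + k * cfg.row_spacing + self.strip_hi
            j = 0
            while j < n_units:
                if self.gaps[k, j]:
                    j += 1
                    continue
                j0 = j
                while j < n_units and not self.gaps[k, j]:
                    j += 1
                a = x0 + j0 * _VINE_UNIT
                b = x0 + min(j * _VINE_UNIT, cfg.width)
                if b > a:
                    segs.append((a, b, lo, hi))
        return segs

    def grass_polygons(self):
        cfg = self.cfg
        x0, y0 = cfg.origin
        polys = []
        g = self.grass_half
        if g > 0:
            # bands centred on the inter-row midline (y_in = 0 mod spacing)
            for k in range(cfg.n_rows + 1):
                yc = y0 + k * cfg.row_spacing
                polys.append(box(x0, max(y0, yc - g),
                                 x0 + cfg.width,
                                 min(y0 + cfg.height, yc + g)))
        n_units = self.gaps.shape[1]
        for k in range(cfg.n_rows):
            lo = y0 + k * cfg.row_spacing + self.strip_lo
            hi = y0 + k * cfg.row_spacing + self.strip_hi
            for j in range(n_units):
                if self.gaps[k, j]:
                    a = x0 + j * _VINE_UNIT
                    b = x0 + min((j + 1) * _VINE_UNIT, cfg.width)
                    if b > a:
                        polys.append(box(a, lo, b, hi))
        return [p for p in polys if p.area > 0]


@dataclass
class Scene:
    """A generated scene bundle."""

    cloud: PointCloud
    rasters: RasterStack
    ground: PointCloud
    truth: pd.DataFrame
    grid: GridSpec
    config: SceneConfig


def _sample_segment(seg, h, grid_xs, grid_ys, rng):
    """Points covering one canopy rectangle: jittered interior grid,
    perimeter break lines, and paired transects at grid-line crossings."""
    a, b, lo, hi = seg
    pts = []

    def line_x(y, x_from, x_to):
        xs = np.arange(x_from, x_to, h)
        xs = np.append(xs, x_to)
        pts.append(np.column_stack([xs, np.full_like(xs, y)]))

    def line_y(x, y_from, y_to):
        ys = np.arange(y_from, y_to, h)
        ys = np.append(ys, y_to)
        pts.append(np.column_stack([np.full_like(ys, x), ys]))

    # interior jittered grid anchored at the global origin
    xs = np.arange(np.ceil((a + h / 2) / h) * h, b, h)
    ys = np.arange(np.ceil((lo + h / 2) / h) * h, hi, h)
    if xs.size and ys.size:
        gx, gy = np.meshgrid(xs, ys)
        jit = rng.uniform(-0.3 * h, 0.3 * h, size=(gx.size, 2))
        inner = np.column_stack([gx.ravel(), gy.ravel()]) + jit
        inner[:, 0] = np.clip(inner[:, 0], a, b)
        inner[:, 1] = np.clip(inner[:, 1], lo, hi)
        pts.append(inner)
    # perimeter
    line_x(lo, a, b)
    line_x(hi, a, b)
    line_y(a, lo, hi)
    line_y(b, lo, hi)
    # analysis-grid transects, one point row each side of the cell border
    for gx_ in grid_xs[(grid_xs > a) & (grid_xs < b)]:
        line_y(gx_, lo, hi)
        line_y(gx_ - _EDGE_EPS, lo, hi)
    for gy_ in grid_ys[(grid_ys > lo) & (grid_ys < hi)]:
        line_x(gy_, a, b)
        line_x(gy_ - _EDGE_EPS, a, b)
    return np.vstack(pts)


def _make_band(cfg, geom, rng, res, kind):
    x0, y0, x1, y1 = cfg.bounds
    ncol = int(round(cfg.width / res))
    nrow = int(round(cfg.height / res))
    xs = x0 + (np.arange(ncol) + 0.5) * res
    ys = y1 - (np.arange(nrow) + 0.5) * res
    gx, gy = np.meshgrid(xs, ys)
    if kind == "Tr":
        # sub-pixel veg fraction -> linear Ts/Tc mixture; subsample at the
        # optical pixel centres so Tr and aggregated NDVI see the same
        # cover fraction
        sub = max(1, int(round(res / cfg.optical_resolution)))
        off = (np.arange(sub) + 0.5) / sub * res - res / 2
        dil = cfg.optical_resolution / 2
        frac = np.zeros_like(gx)
        for ox in off:
            for oy in off:
                frac += geom.surface_class(gx + ox, gy + oy, dil) != SOIL
        frac /= sub * sub
        data = frac * cfg.tc_mean + (1 - frac) * cfg.ts_mean
        data = data + rng.normal(0, cfg.temperature_noise_sd, data.shape)
    else:
        cls = geom.surface_class(gx, gy, res / 2)
        veg = cls != SOIL
        data = np.where(veg, cfg.veg_reflectance[kind],
                        cfg.soil_reflectance[kind])
        data = data + rng.normal(0, cfg.reflectance_noise_sd, data.shape)
        data = np.clip(data, 0.0, 1.0)
    return Band(data, x0, y1, res, res, crs=cfg.crs)


def generate_scene(config: SceneConfig | None = None,
                   grid: GridSpec | None = None) -> Scene:
    """Build the full scene bundle: points, rasters, ground, truth.

    The scene is a pure function of (config, grid): identical inputs give
    bitwise-identical outputs. The photogrammetric cloud samples the
    canopy top envelope, the grass tops and the visible soil; the
    LiDAR-like ground cloud samples the true terrain everywhere.
    """
    cfg = config or SceneConfig()
    if grid is None:
        grid = make_grid(cfg.bounds, 3.6, crs=cfg.crs)
    if grid.crs is not None and grid.crs != cfg.crs:
        raise ValueError(f"grid CRS {grid.crs!r} != scene CRS {cfg.crs!r}")
    rng = np.random.default_rng(cfg.seed)
    geom = _Geometry(cfg, rng)
    h = 1.0 / np.sqrt(cfg.point_density)
    grid_xs = grid.x_min + np.arange(1, grid.nx) * grid.cell_size
    grid_ys = grid.y_min + np.arange(1, grid.ny) * grid.cell_size

    # canopy points on the top envelope
    segs = geom.canopy_segments()
    canopy_xy = (np.vstack([_sample_segment(s, h, grid_xs, grid_ys, rng)
                            for s in segs])
                 if segs else np.empty((0, 2)))
    canopy_z = geom.ground_z(canopy_xy[:, 0], canopy_xy[:, 1]) \
        + cfg.vine_height \
        + rng.normal(0, cfg.canopy_z_noise_sd, len(canopy_xy))

    # inter-row points (grass tops and bare soil), uniform at density
    x0, y0, x1, y1 = cfg.bounds
    area = cfg.width * cfg.height
    n_open = rng.poisson(cfg.point_density * area)
    open_xy = np.column_stack([rng.uniform(x0, x1, n_open),
                               rng.uniform(y0, y1, n_open)])
    cls = geom.surface_class(open_xy[:, 0], open_xy[:, 1])
    open_xy = open_xy[cls != CANOPY]
    cls = cls[cls != CANOPY]
    open_z = geom.ground_z(open_xy[:, 0], open_xy[:, 1]) \
        + np.where(cls == GRASS, cfg.cover_height, 0.0) \
        + rng.normal(0, cfg.ground_z_noise_sd, len(open_xy))

    xyz = np.vstack([np.column_stack([canopy_xy, canopy_z]),
                     np.column_stack([open_xy, open_z])])
    cloud = PointCloud(xyz, crs=cfg.crs)

    n_ground = rng.poisson(cfg.ground_point_density * area)
    gxy = np.column_stack([rng.uniform(x0, x1, n_ground),
                           rng.uniform(y0, y1, n_ground)])
    gz = geom.ground_z(gxy[:, 0], gxy[:, 1])
    ground = PointCloud(np.column_stack([gxy, gz]), crs=cfg.crs)

    rasters = RasterStack({
        "R": _make_band(cfg, geom, rng, cfg.optical_resolution, "R"),
        "G": _make_band(cfg, geom, rng, cfg.optical_resolution, "G"),
        "B": _make_band(cfg, geom, rng, cfg.optical_resolution, "B"),
        "N": _make_band(cfg, geom, rng, cfg.optical_resolution, "N"),
        "Tr": _make_band(cfg, geom, rng, cfg.thermal_resolution, "Tr"),
    })

    truth = analytic_cell_truth(cfg, grid, geom)
    return Scene(cloud, rasters, ground, truth, grid, cfg)


def analytic_cell_truth(config: SceneConfig, grid: GridSpec,
                        _geom: _Geometry | None = None) -> pd.DataFrame:
    """Closed-form per-cell truth for the box-canopy geometry.

    Vine metrics are exact: footprint area from rectangle intersections,
    flat top so SArea_vc = Area_vc, Volume_vc = Area_vc * vine_height,
    h_vc = vine_height (heights are relative to local ground, so the
    truth is slope-invariant). Vegetation metrics are first-order: flat
    tops summed by class, ignoring the thin transition wedges a TIN
    builds between classes.
    """
    geom = _geom
    if geom is None:
        geom = _Geometry(config, np.random.default_rng(config.seed))
    canopy = unary_union([box(a, lo, b, hi)
                          for a, b, lo, hi in geom.canopy_segments()])
    grass = unary_union(geom.grass_polygons())
    grass = grass.difference(canopy)
    rows = []
    for cid in range(grid.n_cells):
        cell = grid.cell_polygon(cid)
        a_c = canopy.intersection(cell).area
        a_g = grass.intersection(cell).area
        a_v = a_c + a_g
        vol_c = a_c * config.vine_height
        vol_v = vol_c + a_g * config.cover_height
        rows.append({
            "id": cid,
            "Area_vc": a_c, "SArea_vc": a_c, "Volume_vc": vol_c,
            "h_vc": config.vine_height if a_c > 0 else 0.0,
            "Area_v": a_v, "SArea_v": a_v, "Volume_v": vol_v,
            "h_v": ((vol_c / config.vine_height * config.vine_height
                     + a_g * config.cover_height) / a_v
                    if a_v > 0 else 0.0),
            "f_c": a_c / grid.cell_area,
            "Ts": config.ts_mean, "Tc": config.tc_mean,
        })
    df = pd.DataFrame(rows)
    # h_v: area-weighted mean of class top heights
    with np.errstate(invalid="ignore"):
        df["h_v"] = np.where(
            df["Area_v"] > 0,
            (df["Area_vc"] * config.vine_height
             + (df["Area_v"] - df["Area_vc"]) * config.cover_height)
            / df["Area_v"], 0.0)
    return df


def generate_forcing(n_hours: int = 24, seed: int = 0) -> pd.DataFrame:
    """Hourly meteorological forcing with a plausible clear-sky diurnal
    cycle: Ta (deg C), u (m/s, floored at 0.5), S (W/m2), ea (kPa),
    p (kPa), plus the measurement heights."""
    if n_hours < 1:
        raise ValueError("need at least one hour")
    rng = np.random.default_rng(seed)
    hour = np.arange(n_hours) % 24
    ta = 22.0 + 9.0 * np.sin(np.pi * (hour - 7) / 14) \
        + rng.normal(0, 0.5, n_hours)
    ta = np.clip(ta, -10.0, 45.0)
    s = 950.0 * np.clip(np.sin(np.pi * (hour - 6) / 12), 0, None) ** 1.2 \
        * (1 + rng.normal(0, 0.02, n_hours))
    s = np.clip(s, 0.0, None)
    u = np.clip(2.0 + 1.0 * np.sin(np.pi * (hour - 10) / 14)
                + rng.normal(0, 0.4, n_hours), 0.5, None)
    ea = np.clip(1.4 + rng.normal(0, 0.1, n_hours), 0.4, 3.5)
    return pd.DataFrame({"hour": hour, "Ta": ta, "u": u, "S": s,
                         "ea": ea, "p": np.full(n_hours, 101.3),
                         "z_u": 5.0, "z_T": 5.0})


def generate_lai_observations(inputs: pd.DataFrame,
                              coefficients: dict[str, float],
                              noise_sd: float = 0.0,
                              seed: int = 0,
                              intercept: float = 0.0) -> pd.DataFrame:
    """Synthetic LAI observations from a linear model on input columns.

    LAI = intercept + sum(coef * column) + N(0, noise_sd). Negative
    simulated values are kept but flagged in the ``negative`` column.
    The truth coefficients are stored in ``DataFrame.attrs``.
    """
    rng = np.random.default_rng(seed)
    lai = np.full(len(inputs), float(intercept))
    for name, coef in coefficients.items():
        lai = lai + coef * inputs[name].to_numpy(dtype=float)
    if noise_sd > 0:
        lai = lai + rng.normal(0, noise_sd, len(inputs))
    out = inputs.copy()
    out["LAI"] = lai
    out["negative"] = lai < 0
    out.attrs["true_coefficients"] = dict(coefficients)
    out.attrs["true_intercept"] = float(intercept)
    return out


def scene_variant(config: SceneConfig, **changes) -> SceneConfig:
    """Convenience: a copy of ``config`` with fields replaced."""
    return replace(config, **changes)
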