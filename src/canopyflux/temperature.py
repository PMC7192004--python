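"""Contextual soil/canopy temperature retrieval from the NDVI-Tr scatter.

Within each grid cell the radiometric temperature of a mixed pixel is,
to first order, a linear mixture of the soil temperature Ts (at the bare
soil NDVI) and the canopy temperature Tc (at the full-canopy NDVI). A
straight line is fitted by least squares to the per-cell (NDVI, Tr) pixel
pairs at the thermal-band resolution and evaluated at the two NDVI
endpoints; the lower of the two temperatures is the canopy, the higher
the soil.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ComponentTemperatures",
    "fit_ndvi_tr_line",
    "select_thresholds",
    "partition_temperatures",
    "retrieve_cell_temperatures",
]


@dataclass
class ComponentTemperatures:
    """Soil and canopy temperatures retrieved for one grid cell.

    Temperatures are in degrees Celsius. ``slope``/``intercept`` describe
    the fitted Tr = intercept + slope * NDVI line; ``flags`` collects
    quality conditions (``degenerate``, ``positive_slope``, ...).
    """

    Ts: float
    Tc: float
    slope: float
    intercept: float
    ndvi_soil: float
    ndvi_canopy: float
    n_pixels: int
    flags: list[str] = field(default_factory=list)


def fit_ndvi_tr_line(ndvi: np.ndarray, tr: np.ndarray
                     ) -> tuple[float, float, list[str]]:
    """Ordinary least squares line Tr = intercept + slope * NDVI.

    Returns ``(slope, intercept, flags)``. Fewer than 3 valid pairs or
    zero NDVI variance yields a degenerate fit: slope 0, intercept equal
    to the mean Tr, flag ``degenerate``.
    """
    ndvi = np.asarray(ndvi, dtype=float)
    tr = np.asarray(tr, dtype=float)
    ok = np.isfinite(ndvi) & np.isfinite(tr)
    ndvi, tr = ndvi[ok], tr[ok]
    if len(ndvi) < 3 or np.ptp(ndvi) == 0:
        mean = float(np.mean(tr)) if len(tr) else np.nan
        return 0.0, mean, ["degenerate"]
    res = stats.linregress(ndvi, tr)
    return float(res.slope), float(res.intercept), []


def select_thresholds(scene_ndvi: np.ndarray, method: str = "percentile",
                      fixed: tuple[float, float] | None = None,
                      percentiles: tuple[float, float] = (5.0, 95.0),
                      ) -> tuple[float, float]:
    """Scene-wide pure-soil and pure-canopy NDVI endpoints.

    ``method="fixed"`` returns user-supplied values; ``"percentile"``
    takes low/high percentiles (default p5/p95) of the scene NDVI
    histogram as the histogram-analysis realisation.
    """
    if method == "fixed":
        if fixed is None:
            raise ValueError("fixed thresholds requested but none supplied")
        lo, hi = fixed
    elif method == "percentile":
        vals = np.asarray(scene_ndvi, dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError("no valid NDVI values to build a histogram from")
        lo, hi = np.percentile(vals, percentiles)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    if lo >= hi:
        raise ValueError(f"NDVI_s ({lo}) must be below NDVI_c ({hi})")
    return float(lo), float(hi)


def partition_temperatures(slope: float, intercept: float,
                           ndvi_soil: float, ndvi_canopy: float,
                           n_pixels: int = 0,
                           flags: list[str] | None = None,
                           ) -> ComponentTemperatures:
    """Evaluate the fitted line at the NDVI endpoints and split Ts/Tc.

    The lower temperature is assigned to the canopy and the higher to the
    soil; a physically unexpected positive slope (canopy warmer than
    soil) is flagged rather than rejected.
    """
    flags = list(flags or [])
    t_soil_end = intercept + slope * ndvi_soil
    t_canopy_end = intercept + slope * ndvi_canopy
    tc = min(t_soil_end, t_canopy_end)
    ts = max(t_soil_end, t_canopy_end)
    if slope > 0:
        flags.append("positive_slope")
    return ComponentTemperatures(Ts=float(ts), Tc=float(tc),
                                 slope=slope, intercept=intercept,
                                 ndvi_soil=ndvi_soil, ndvi_canopy=ndvi_canopy,
                                 n_pixels=n_pixels, flags=flags)


def retrieve_cell_temperatures(ndvi: np.ndarray, tr: np.ndarray,
                               ndvi_soil: float, ndvi_canopy: float,
                               ) -> ComponentTemperatures:
    """Full per-cell retrieval: fit the line, evaluate the endpoints."""
    slope, intercept, flags = fit_ndvi_tr_line(ndvi, tr)
    n = int(np.sum(np.isfinite(np.asarray(ndvi, float))
                   & np.isfinite(np.asarray(tr, float))))
    return partition_temperatures(slope, intercept, ndvi_soil, ndvi_canopy,
                                  n_pixels=n, flags=flags)
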