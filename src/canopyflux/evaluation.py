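"""Eddy-covariance closure forcing and model evaluation statistics.

Eddy-covariance towers typically under-measure the turbulent fluxes, so
H + LE falls short of the available energy Rn - G. Closure is forced by
distributing the residual over H and LE in proportion to their Bowen
ratio, which preserves H/LE while making H_BR + LE_BR = Rn - G exact.

Model skill is summarised by R2, MAE, RMSE and the relative RMSE
(RRMSE = 100 RMSE / mean(measured)), with the conventional rating scale
excellent (< 10%), good (10-20%), fair (20-30%), poor (> 30%); boundary
values go to the better category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["bowen_closure", "close_tower_records", "fit_metrics",
           "EvalStats", "rate_rrmse"]


def bowen_closure(Rn: float, G: float, H: float, LE: float
                  ) -> tuple[float, float]:
    """Bowen-ratio closure of one hourly record.

    H_BR = H/(H+LE) (Rn - G - H - LE) + H and analogously for LE.
    Raises when H + LE = 0 (the Bowen ratio is undefined); callers
    batching records should flag and skip such hours.
    """
    total = H + LE
    if total == 0:
        raise ValueError("H + LE = 0: Bowen ratio undefined, closure skipped")
    residual = Rn - G - H - LE
    h_br = H / total * residual + H
    le_br = LE / total * residual + LE
    return h_br, le_br


def close_tower_records(records: pd.DataFrame) -> pd.DataFrame:
    """Apply Bowen-ratio closure row-wise to a tower flux table.

    Expects columns Rn, G, H, LE; appends H_BR, LE_BR and a ``flags``
    column (``closure_skipped`` where H + LE = 0).
    """
    out = records.copy()
    h_br = np.full(len(out), np.nan)
    le_br = np.full(len(out), np.nan)
    flags = [""] * len(out)
    for i, row in enumerate(records.itertuples(index=False)):
        try:
            h_br[i], le_br[i] = bowen_closure(row.Rn, row.G, row.H, row.LE)
        except ValueError:
            flags[i] = "closure_skipped"
    out["H_BR"], out["LE_BR"], out["flags"] = h_br, le_br, flags
    return out


@dataclass
class EvalStats:
    """Agreement statistics between measured and estimated series."""

    n: int
    r_squared: float
    mae: float
    rmse: float
    rrmse: float        # percent
    rating: str


def rate_rrmse(rrmse_percent: float) -> str:
    """Rating category for a relative RMSE in percent."""
    if rrmse_percent <= 10.0:
        return "excellent"
    if rrmse_percent <= 20.0:
        return "good"
    if rrmse_percent <= 30.0:
        return "fair"
    return "poor"


def fit_metrics(measured, estimated) -> EvalStats:
    """R2, MAE, RMSE, RRMSE and rating for paired series.

    R2 = 1 - SS_res/SS_tot can go negative and is reported raw; it is
    NaN when the measured series has zero variance. RRMSE needs a
    nonzero measured mean.
    """
    m = np.asarray(measured, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if m.shape != e.shape:
        raise ValueError("measured and estimated must have equal length")
    if m.size < 2:
        raise ValueError("need at least two observations")
    resid = m - e
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    mae = float(np.mean(np.abs(resid)))
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    mbar = float(m.mean())
    if mbar == 0:
        raise ValueError("measured mean is zero; RRMSE undefined")
    rrmse = 100.0 * rmse / mbar
    return EvalStats(n=m.size, r_squared=r2, mae=mae, rmse=rmse,
                     rrmse=rrmse, rating=rate_rrmse(rrmse))
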