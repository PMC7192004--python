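"""Leaf-area-index models on normalized per-cell canopy metrics.

Three published regression-form models map per-cell spectral means and
grid-area-normalized structural metrics to LAI:

* model 1 — spectral only (NIR means, NDVI, radiometric temperature);
* model 2 — structural only (projected areas, volume);
* model 3 — spectral + structural.

Model 1 has an unambiguous printed form. The printed forms of models 2
and 3 are typographically ambiguous (fraction and exponent placement),
so they are held here as *configurable expressions*: the defaults below
are one documented reading, and callers can substitute another without
touching code. Tr enters in degrees Celsius; structural volumes are in
m3/m2 (i.e. metres) and areas in m2/m2 after normalization.

An ordinary-least-squares refit utility supports recovery testing of
linear models on the same inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LaiModelSpec",
    "DEFAULT_MODELS",
    "normalize_inputs",
    "evaluate_model",
    "lai_model1",
    "lai_model2",
    "lai_model3",
    "refit_linear",
]

STRUCTURAL_FIELDS = ("Volume_v", "SArea_v", "Area_v",
                     "Volume_vc", "SArea_vc", "Area_vc")
SPECTRAL_FIELDS = ("N", "NDVI", "Tr", "N_v", "N_vc")


@dataclass
class LaiModelSpec:
    """One LAI model: an expression over named inputs.

    The expression is evaluated with numpy semantics; the allowed names
    are the spectral and normalized structural fields plus ``exp``,
    ``power`` and ``where``. ``clamp_nonnegative`` floors predictions at
    zero (off by default: the printed forms can go negative and are
    reported raw).
    """

    model_id: int
    expression: str
    clamp_nonnegative: bool = False
    description: str = ""


DEFAULT_MODELS: dict[int, LaiModelSpec] = {
    1: LaiModelSpec(
        1,
        "5.85 + 17.37*N*N_v + 0.85*NDVI*Tr - 0.52*Tr"
        " - 8.51*N_vc**2 - 14.96*NDVI**2",
        description="spectral-only"),
    2: LaiModelSpec(
        2,
        "0.47 + 2.39*Area_vc"
        " - 2.29*Area_vc*Area_v**0.41*43.07**(-Volume_v)",
        description="structural-only (default reading)"),
    3: LaiModelSpec(
        3,
        "2.69*N*Volume_vc + 0.11*Tr*Area_v - 0.67*Area_v/N_vc"
        " - 0.38*1.54**Tr*N**2*NDVI**2/(6.92*N_vc**4*Volume_vc)",
        description="spectral-structural (default reading)"),
}


def normalize_inputs(cells: pd.DataFrame | dict, cell_area: float
                     ) -> pd.DataFrame:
    """Divide structural metrics by the grid-cell area; pass spectra through.

    Volumes become m3/m2 (metres), areas dimensionless fractions, which
    removes the grid-size dependence of the structural predictors.
    """
    if cell_area <= 0:
        raise ValueError("cell area must be positive")
    df = pd.DataFrame([cells]) if isinstance(cells, dict) else cells.copy()
    out = df.copy()
    for col in STRUCTURAL_FIELDS:
        if col in out:
            out[col] = out[col] / cell_area
    return out


_SAFE_NAMES = {"exp": np.exp, "log": np.log, "sqrt": np.sqrt,
               "power": np.power, "where": np.where, "abs": np.abs}


def evaluate_model(spec: LaiModelSpec, inputs: pd.DataFrame | dict
                   ) -> np.ndarray:
    """Evaluate an LAI model expression on normalized inputs.

    Division by zero and fractional powers of negative bases produce NaN
    (a missing marker), never an exception. Scalars in, scalar out.
    """
    scalar = isinstance(inputs, dict)
    df = pd.DataFrame([inputs]) if scalar else inputs
    ns = dict(_SAFE_NAMES)
    needed = _expression_names(spec.expression)
    missing = [n for n in needed if n not in df.columns]
    if missing:
        raise KeyError(f"model {spec.model_id} needs missing input(s) "
                       f"{missing}")
    for col in needed:
        ns[col] = df[col].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        val = eval(spec.expression, {"__builtins__": {}}, ns)  # noqa: S307
    val = np.asarray(val, dtype=float)
    val = np.where(np.isinf(val), np.nan, val)
    if spec.clamp_nonnegative:
        val = np.where(np.isfinite(val), np.maximum(val, 0.0), val)
    if scalar or val.ndim == 0:
        return float(np.ravel(val)[0])
    return val


def _expression_names(expr: str) -> list[str]:
    import ast
    tree = ast.parse(expr, mode="eval")
    return sorted({n.id for n in ast.walk(tree) if isinstance(n, ast.Name)
                   and n.id not in _SAFE_NAMES})


def lai_model1(inputs, clamp_nonnegative: bool = False):
    """Spectral-only LAI model."""
    spec = DEFAULT_MODELS[1]
    if clamp_nonnegative:
        spec = LaiModelSpec(1, spec.expression, True, spec.description)
    return evaluate_model(spec, inputs)


def lai_model2(inputs, clamp_nonnegative: bool = False):
    """Structural-only LAI model (default expression reading)."""
    spec = DEFAULT_MODELS[2]
    if clamp_nonnegative:
        spec = LaiModelSpec(2, spec.expression, True, spec.description)
    return evaluate_model(spec, inputs)


def lai_model3(inputs, clamp_nonnegative: bool = False):
    """Spectral-structural LAI model (default expression reading).

    Cells with zero vine NIR mean or zero vine volume yield NaN (the
    rational terms are undefined there)."""
    spec = DEFAULT_MODELS[3]
    if clamp_nonnegative:
        spec = LaiModelSpec(3, spec.expression, True, spec.description)
    return evaluate_model(spec, inputs)


@dataclass
class LinearFit:
    """Result of an ordinary-least-squares refit."""

    terms: list[str]
    coefficients: np.ndarray       # intercept first
    std_errors: np.ndarray
    r_squared: float
    rmse: float
    n: int
    model: object = field(repr=False, default=None)


def refit_linear(inputs: pd.DataFrame, lai: np.ndarray,
                 terms: list[str] | None = None) -> LinearFit:
    """OLS fit LAI ~ 1 + selected input columns.

    Raises on rank deficiency, naming the collinear term(s) so the
    caller can drop them.
    """
    import statsmodels.api as sm

    terms = list(terms if terms is not None else inputs.columns)
    y = np.asarray(lai, dtype=float)
    if len(y) < len(terms) + 2:  # intercept + at least 1 residual df
        raise ValueError(f"need at least {len(terms) + 2} observations "
                         f"for {len(terms)} terms plus intercept")
    X = inputs[terms].to_numpy(dtype=float)
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError(
            "design matrix is rank deficient; collinear term(s): "
            f"{_collinear_terms(Xc, terms)}")
    res = sm.OLS(y, Xc).fit()
    resid = y - res.fittedvalues
    return LinearFit(terms=terms,
                     coefficients=np.asarray(res.params),
                     std_errors=np.asarray(res.bse),
                     r_squared=float(res.rsquared),
                     rmse=float(np.sqrt(np.mean(resid ** 2))),
                     n=len(y), model=res)


def _collinear_terms(Xc: np.ndarray, terms: list[str]) -> list[str]:
    bad = []
    rank = np.linalg.matrix_rank(Xc[:, :1])
    for j in range(1, Xc.shape[1]):
        new_rank = np.linalg.matrix_rank(Xc[:, :j + 1])
        if new_rank == rank:
            bad.append(terms[j - 1])
        rank = new_rank
    return bad or ["<unidentified>"]


def append_lai_columns(cells: pd.DataFrame, cell_area: float,
                       models: dict[int, LaiModelSpec] | None = None
                       ) -> pd.DataFrame:
    """Evaluate all three models per cell, appending LAI_m1..LAI_m3."""
    models = models or DEFAULT_MODELS
    norm = normalize_inputs(cells, cell_area)
    out = cells.copy()
    for mid, spec in models.items():
        out[f"LAI_m{mid}"] = evaluate_model(spec, norm)
    return out
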