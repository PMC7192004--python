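"""Two-source energy balance with known component temperatures (TSEB-2T).

Given separately retrieved soil and canopy temperatures, the model
partitions net radiation between canopy and soil, takes soil heat flux
as a fixed fraction of soil net radiation, solves the series-resistance
network for the sensible heat of each source with Monin-Obukhov
stability iteration, and closes each component balance by computing
latent heat as the residual:

    LE_s = Rn_s - G - H_s        LE_c = Rn_c - H_c

Longwave partitioning uses exponential extinction with coefficient k_L
and clumping factor Omega; shortwave partitioning uses a beam-extinction
canopy transmittance with a spherical leaf-angle distribution. The
resistance network is the series form: air at T_AC in the canopy air
space exchanges with the atmosphere through R_a, with the leaves through
the bulk boundary-layer resistance R_x = (C/LAI) sqrt(l_w/U), and with
the soil surface through R_s = 1/(a + b u_s). Supporting formulations
(Businger-Dyer stability functions, Goudriaan in-canopy wind
attenuation, Brutsaert clear-sky emissivity) are the standard choices of
the TSEB lineage. Temperatures cross the API in degrees Celsius and are
converted to kelvin only inside the radiation and stability physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STEFAN_BOLTZMANN",
    "RadiationConfig",
    "ResistanceConfig",
    "MeteoForcing",
    "FluxState",
    "longwave_sources",
    "partition_longwave",
    "solar_transmittance",
    "net_radiation",
    "soil_heat_flux",
    "canopy_boundary_resistance",
    "aero_resistances",
    "solve_fluxes",
]

STEFAN_BOLTZMANN = 5.670374419e-8   # W m-2 K-4
VON_KARMAN = 0.41
GRAVITY = 9.81                      # m s-2
R_DRY = 287.04                      # J kg-1 K-1
_L_NEUTRAL = 1.0e6                  # m; |L| at/above this is neutral
_ZETA_MIN, _ZETA_MAX = -5.0, 0.45   # stability-parameter clamps


@dataclass
class RadiationConfig:
    """Radiative properties of the two sources.

    k_L : longwave extinction coefficient (default 0.95).
    omega : vegetation clumping factor (1.0 = random canopy).
    eps_c, eps_s : canopy and soil emissivities.
    alpha_c, alpha_s : canopy and soil shortwave albedos.
    """

    k_L: float = 0.95
    omega: float = 1.0
    eps_c: float = 0.98
    eps_s: float = 0.95
    alpha_c: float = 0.20
    alpha_s: float = 0.15

    def __post_init__(self) -> None:
        for name in ("eps_c", "eps_s", "alpha_c", "alpha_s"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not 0 < self.omega <= 1.2:
            raise ValueError("omega must be in (0, 1.2]")


@dataclass
class ResistanceConfig:
    """Resistance-network parameters.

    C : leaf boundary-layer coefficient, s^1/2 m-1 (default 90).
    leaf_width : average leaf width, m.
    rs_a, rs_b : soil-surface resistance R_s = 1/(rs_a + rs_b * u_s).
    c_G : soil heat flux fraction of Rn_s.
    """

    C: float = 90.0
    leaf_width: float = 0.1
    rs_a: float = 0.004
    rs_b: float = 0.012
    c_G: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.c_G <= 1:
            raise ValueError("c_G must be in [0, 1]")


@dataclass
class MeteoForcing:
    """One hour of meteorological forcing.

    Ta in deg C, u in m/s (> 0), S incoming shortwave in W/m2, ea vapor
    pressure in kPa, p air pressure in kPa; z_u and z_T are the wind and
    temperature measurement heights in m.
    """

    Ta: float
    u: float
    S: float
    ea: float = 1.4
    p: float = 101.3
    z_u: float = 5.0
    z_T: float = 5.0

    def __post_init__(self) -> None:
        if self.u <= 0:
            raise ValueError("wind speed must be positive")
        if self.S < 0:
            raise ValueError("solar radiation must be non-negative")


@dataclass
class FluxState:
    """Converged per-cell energy balance."""

    Rn: float
    Rn_c: float
    Rn_s: float
    G: float
    H: float
    H_c: float
    H_s: float
    LE: float
    LE_c: float
    LE_s: float
    T_AC: float          # canopy air-space temperature, deg C
    L_MO: float          # Monin-Obukhov length, m
    u_star: float
    R_a: float
    R_x: float
    R_s: float
    iterations: int
    converged: bool
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# radiation
# ---------------------------------------------------------------------------

def _to_kelvin(t_c: float) -> float:
    if t_c < -100.0:
        raise ValueError(f"nonphysical temperature {t_c} degC")
    return t_c + 273.15


def clear_sky_emissivity(ea_kpa: float, ta_c: float) -> float:
    """Brutsaert clear-sky atmospheric emissivity from vapor pressure
    (kPa) and air temperature (deg C)."""
    return 1.24 * ((ea_kpa * 10.0) / _to_kelvin(ta_c)) ** (1.0 / 7.0)


def longwave_sources(Ts: float, Tc: float, Ta: float, ea: float,
                     config: RadiationConfig | None = None,
                     ) -> tuple[float, float, float]:
    """Longwave emission of soil, canopy and sky, W/m2 (inputs deg C)."""
    cfg = config or RadiationConfig()
    L_s = cfg.eps_s * STEFAN_BOLTZMANN * _to_kelvin(Ts) ** 4
    L_c = cfg.eps_c * STEFAN_BOLTZMANN * _to_kelvin(Tc) ** 4
    eps_a = clear_sky_emissivity(ea, Ta)
    L_sky = eps_a * STEFAN_BOLTZMANN * _to_kelvin(Ta) ** 4
    return L_s, L_c, L_sky


def partition_longwave(lai: float, config: RadiationConfig,
                       L_sky: float, L_s: float, L_c: float,
                       ) -> tuple[float, float]:
    """Net longwave of canopy and soil by exponential extinction.

    Ln_c = (1 - e)(L_sky + L_s - 2 L_c) and
    Ln_s = e * L_sky + (1 - e) L_c - L_s with e = exp(-k_L Omega LAI).
    At LAI = 0 the canopy nets nothing and the soil sees the sky; as
    LAI grows the soil sees only canopy.
    """
    if lai < 0:
        raise ValueError("LAI must be non-negative")
    e = math.exp(-config.k_L * config.omega * lai)
    ln_c = (1.0 - e) * (L_sky + L_s - 2.0 * L_c)
    ln_s = e * L_sky + (1.0 - e) * L_c - L_s
    return ln_c, ln_s


def beam_extinction(zenith_deg: float, x: float = 1.0) -> float:
    """Ellipsoidal-distribution beam extinction coefficient; x = 1 is
    the spherical leaf-angle distribution (K ~ 0.5 at nadir sun)."""
    if zenith_deg >= 90.0:
        raise ValueError("solar zenith must be below 90 degrees")
    t = math.tan(math.radians(zenith_deg))
    return math.sqrt(x * x + t * t) / (x + 1.774 * (x + 1.182) ** -0.733)


def solar_transmittance(lai: float, omega: float = 1.0,
                        solar_zenith: float = 30.0) -> float:
    """Canopy transmittance to direct beam, tau = exp(-K_be Omega LAI)."""
    if lai < 0:
        raise ValueError("LAI must be non-negative")
    k = beam_extinction(solar_zenith)
    return math.exp(-k * omega * lai)


def net_radiation(Ln_c: float, Ln_s: float, tau_s: float, S: float,
                  config: RadiationConfig | None = None,
                  ) -> tuple[float, float, float]:
    """Component and total net radiation.

    Rn_c = Ln_c + (1 - tau_s)(1 - alpha_c) S and
    Rn_s = Ln_s + tau_s (1 - alpha_s) S; Rn is their sum.
    """
    cfg = config or RadiationConfig()
    if S < 0:
        raise ValueError("S must be non-negative")
    rn_c = Ln_c + (1.0 - tau_s) * (1.0 - cfg.alpha_c) * S
    rn_s = Ln_s + tau_s * (1.0 - cfg.alpha_s) * S
    return rn_c, rn_s, rn_c + rn_s


def soil_heat_flux(Rn_s: float, c_G: float = 0.3) -> float:
    """G as a fixed fraction of soil net radiation (sign passed through)."""
    if not 0 <= c_G <= 1:
        raise ValueError("c_G must be in [0, 1]")
    return c_G * Rn_s


# ---------------------------------------------------------------------------
# turbulence
# ---------------------------------------------------------------------------

def air_properties(ta_c: float, ea_kpa: float, p_kpa: float
                   ) -> tuple[float, float]:
    """Moist air density (kg/m3) and specific heat (J/kg/K)."""
    t_k = _to_kelvin(ta_c)
    t_v = t_k / (1.0 - 0.378 * ea_kpa / p_kpa)
    rho = (p_kpa * 1000.0) / (R_DRY * t_v)
    q = 0.622 * ea_kpa / (p_kpa - 0.378 * ea_kpa)
    cp = 1004.67 * (1.0 + 0.84 * q)
    return rho, cp


def _psi_m(zeta: float) -> float:
    zeta = min(max(zeta, _ZETA_MIN), _ZETA_MAX)
    if zeta >= 0:
        return -5.0 * zeta
    x = (1.0 - 16.0 * zeta) ** 0.25
    return (2.0 * math.log((1.0 + x) / 2.0)
            + math.log((1.0 + x * x) / 2.0)
            - 2.0 * math.atan(x) + math.pi / 2.0)


def _psi_h(zeta: float) -> float:
    zeta = min(max(zeta, _ZETA_MIN), _ZETA_MAX)
    if zeta >= 0:
        return -5.0 * zeta
    x = (1.0 - 16.0 * zeta) ** 0.25
    return 2.0 * math.log((1.0 + x * x) / 2.0)


def canopy_boundary_resistance(lai: float, leaf_width: float,
                               u_d0z0m: float, C: float = 90.0) -> float:
    """Bulk leaf boundary-layer resistance R_x = (C/LAI) sqrt(l_w/U).

    LAI = 0 decouples the canopy: infinite resistance.
    """
    if lai <= 0:
        return math.inf
    if u_d0z0m <= 0:
        raise ValueError("wind speed at d0+z0M must be positive")
    return (C / lai) * math.sqrt(leaf_width / u_d0z0m)


def aero_resistances(forcing: MeteoForcing, h_c: float, L_MO: float,
                     lai: float, config: ResistanceConfig | None = None,
                     ) -> tuple[float, float, float, float]:
    """Friction velocity, aerodynamic and soil resistances, and the wind
    speed at the heat-exchange height d0 + z0M.

    Log profile with Businger-Dyer stability corrections above the
    canopy (d0 = 0.65 h_c, z0M = 0.125 h_c), Goudriaan exponential
    attenuation within it, and R_s = 1/(a + b u_s) with u_s the wind
    speed just above the soil surface.
    """
    cfg = config or ResistanceConfig()
    if forcing.z_u <= h_c:
        raise ValueError("measurement height must exceed canopy height")
    d0 = 0.65 * h_c
    z0m = 0.125 * h_c
    k = VON_KARMAN
    inv_l = 0.0 if not math.isfinite(L_MO) or L_MO == 0 else 1.0 / L_MO
    zeta_u = (forcing.z_u - d0) * inv_l
    zeta_t = (forcing.z_T - d0) * inv_l
    zeta_0 = z0m * inv_l
    denom = math.log((forcing.z_u - d0) / z0m) - _psi_m(zeta_u) \
        + _psi_m(zeta_0)
    denom = max(denom, 0.1)  # guard against free-convection blowup
    u_star = max(k * forcing.u / denom, 0.01)
    r_a = (math.log((forcing.z_T - d0) / z0m) - _psi_h(zeta_t)
           + _psi_h(zeta_0)) / (k * u_star)
    r_a = max(r_a, 1.0)

    u_c = (u_star / k) * math.log((h_c - d0) / z0m)
    u_c = max(u_c, 0.01)
    # Goudriaan in-canopy attenuation
    a = 0.28 * max(lai, 0.01) ** (2.0 / 3.0) * h_c ** (1.0 / 3.0) \
        * cfg.leaf_width ** (-1.0 / 3.0)
    u_d0z0m = max(u_c * math.exp(-a * (1.0 - (d0 + z0m) / h_c)), 0.01)
    u_s = max(u_c * math.exp(-a * (1.0 - 0.05 / h_c)), 0.01)
    r_s = 1.0 / (cfg.rs_a + cfg.rs_b * u_s)
    return u_star, r_a, r_s, u_d0z0m


def _series_network(Ts: float, Tc: float, Ta: float,
                    r_a: float, r_x: float, r_s: float, rho_cp: float,
                    ) -> tuple[float, float, float]:
    """In-canopy air temperature and component sensible heat fluxes for
    fixed resistances (the inner step of the stability iteration)."""
    g_a, g_s = 1.0 / r_a, 1.0 / r_s
    g_x = 0.0 if math.isinf(r_x) else 1.0 / r_x
    t_ac = (Ta * g_a + Tc * g_x + Ts * g_s) / (g_a + g_x + g_s)
    h_c = rho_cp * (Tc - t_ac) * g_x
    h_s = rho_cp * (Ts - t_ac) * g_s
    return t_ac, h_c, h_s


def solve_fluxes(Ts: float, Tc: float, lai: float, h_c: float,
                 f_c: float, forcing: MeteoForcing,
                 radiation: RadiationConfig | None = None,
                 resistance: ResistanceConfig | None = None,
                 solar_zenith: float = 30.0,
                 max_iterations: int = 100,
                 tol: float = 1e-5,
                 clamp_le_s: bool = False) -> FluxState:
    """Full per-cell TSEB-2T solution.

    Radiation is partitioned once from (Ts, Tc, LAI); the sensible-heat
    network is then iterated with the Monin-Obukhov length updated from
    the total H until successive lengths differ by less than ``tol``
    (or the iteration cap is hit, which sets ``converged=False``).
    Latent heat closes each component balance as a residual; with
    ``clamp_le_s`` the soil latent heat is floored at zero (daytime
    condensation suppressed) and H_s recomputed as the residual, flagged.
    """
    rad = radiation or RadiationConfig()
    res = resistance or ResistanceConfig()
    flags: list[str] = []

    L_s, L_c, L_sky = longwave_sources(Ts, Tc, forcing.Ta, forcing.ea, rad)
    ln_c, ln_s = partition_longwave(lai, rad, L_sky, L_s, L_c)
    tau = solar_transmittance(lai, rad.omega, solar_zenith)
    rn_c, rn_s, rn = net_radiation(ln_c, ln_s, tau, forcing.S, rad)
    g = soil_heat_flux(rn_s, res.c_G)

    rho, cp = air_properties(forcing.Ta, forcing.ea, forcing.p)
    rho_cp = rho * cp
    t_v = _to_kelvin(forcing.Ta) / (1.0 - 0.378 * forcing.ea / forcing.p)

    l_mo = _L_NEUTRAL
    t_ac = h_c_flux = h_s_flux = 0.0
    u_star = r_a = r_x = r_s = math.nan
    converged = False
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        u_star, r_a, r_s, u_d0z0m = aero_resistances(
            forcing, h_c, l_mo, lai, res)
        r_x = canopy_boundary_resistance(lai, res.leaf_width, u_d0z0m,
                                         res.C)
        if r_a <= 0 or r_s <= 0 or r_x <= 0:
            raise RuntimeError(
                f"nonpositive resistance (R_a={r_a}, R_x={r_x}, R_s={r_s})")
        t_ac, h_c_flux, h_s_flux = _series_network(
            Ts, Tc, forcing.Ta, r_a, r_x, r_s, rho_cp)
        h_total = h_c_flux + h_s_flux
        if abs(h_total) < 1e-9:
            l_new = _L_NEUTRAL
        else:
            l_new = -rho_cp * u_star ** 3 * t_v / \
                (VON_KARMAN * GRAVITY * h_total)
            if abs(l_new) >= _L_NEUTRAL:
                l_new = _L_NEUTRAL
        if abs(l_new - l_mo) < tol:
            l_mo = l_new
            converged = True
            break
        l_mo = l_new
    if not converged:
        flags.append("unconverged")

    h_total = h_c_flux + h_s_flux
    le_s = rn_s - g - h_s_flux
    le_c = rn_c - h_c_flux
    if clamp_le_s and le_s < 0:
        le_s = 0.0
        h_s_flux = rn_s - g
        h_total = h_c_flux + h_s_flux
        flags.append("le_s_clamped")
    return FluxState(Rn=rn, Rn_c=rn_c, Rn_s=rn_s, G=g,
                     H=h_total, H_c=h_c_flux, H_s=h_s_flux,
                     LE=le_s + le_c, LE_c=le_c, LE_s=le_s,
                     T_AC=t_ac, L_MO=l_mo, u_star=u_star,
                     R_a=r_a, R_x=r_x, R_s=r_s,
                     iterations=iterations, converged=converged,
                     flags=flags)
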