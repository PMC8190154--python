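"""PT-JPL latent-heat model: constraints, partitioning, flux components.

The model reduces Priestley–Taylor potential evaporation with five
multiplicative biophysical constraints and splits the result into soil,
canopy and interception latent-heat fluxes:

    LE_total = LE_s + LE_c + LE_i

with

    PT   = alpha * delta / (delta + gamma)
    LE_c = (1 - f_wet) * f_g * f_T * f_M * PT * Rn_c
    LE_s = (f_wet + f_SM * (1 - f_wet)) * PT * max(Rn_s - G, 0)
    LE_i = f_wet * PT * Rn_c

All functions are vectorized: scalars, 1-D series and 2-D grids
broadcast freely.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from fieldet.forcing_io import NDVIStack, daytime_mask

__all__ = [
    "PTJPLParams",
    "Constraints",
    "FluxComponents",
    "met_derivatives",
    "vegetation_indices",
    "constraints",
    "estimate_topt",
    "radiation_partition",
    "soil_heat_flux",
    "solar_seconds",
    "compute_fluxes",
    "run_scene",
]


@dataclass(frozen=True)
class PTJPLParams:
    """Model constants. Defaults follow the canonical published forms.

    ``topt`` (°C) is normally estimated from the season's forcing via
    :func:`estimate_topt`; the default is only a fallback.
    """

    alpha: float = 1.26           # Priestley–Taylor coefficient
    beta: float = 1.0             # soil-moisture sensitivity scale, kPa
    gamma: float = 0.066          # psychrometric constant, kPa/°C
    k_rn: float = 0.6             # net-radiation extinction coefficient
    k_par: float = 0.5            # PAR extinction coefficient
    savi_slope: float = 0.45      # NDVI -> SAVI
    savi_offset: float = 0.132
    fapar_slope: float = 1.3632   # SAVI -> fAPAR
    fapar_offset: float = -0.048
    fipar_slope: float = 1.0      # NDVI -> fIPAR
    fipar_offset: float = -0.05
    topt: float = 25.0            # optimum growth temperature, °C
    lambda_v: float = 2.26e6      # latent heat of vaporization, J/kg
    g_amplitude: float = 0.31     # soil-heat-flux cosine amplitude (fraction)
    g_period: float = 74000.0     # soil-heat-flux cosine period, s
    g_shift: float = 10800.0      # soil-heat-flux phase shift, s

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "k_rn", "k_par", "lambda_v"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def with_topt(self, topt: float) -> "PTJPLParams":
        if topt <= 0:
            raise ValueError("topt must be > 0 °C")
        return replace(self, topt=float(topt))


@dataclass
class Constraints:
    """The five PT-JPL reduction factors, each clipped to [0, 1]."""

    f_g: np.ndarray
    f_wet: np.ndarray
    f_t: np.ndarray
    f_m: np.ndarray
    f_sm: np.ndarray


@dataclass
class FluxComponents:
    """Soil/canopy/interception latent heat fluxes and diagnostics (W/m²)."""

    le_s: np.ndarray
    le_c: np.ndarray
    le_i: np.ndarray
    le_total: np.ndarray
    rn_s: np.ndarray
    rn_c: np.ndarray
    g: np.ndarray


def met_derivatives(ta, rh) -> dict[str, np.ndarray]:
    """Psychrometric derivatives from air temperature and humidity.

    Magnus/FAO-56 forms: e_sat = 0.6108·exp(17.27·Ta/(Ta+237.3)) kPa,
    delta = 4098·e_sat/(Ta+237.3)² kPa/°C.
    """
    ta = np.asarray(ta, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if np.any((ta <= -40) | (ta >= 60)):
        raise ValueError("air temperature outside (-40, 60) °C")
    e_sat = 0.6108 * np.exp(17.27 * ta / (ta + 237.3))
    e_a = rh * e_sat
    vpd = e_sat - e_a
    delta = 4098.0 * e_sat / (ta + 237.3) ** 2
    return {"e_sat": e_sat, "e_a": e_a, "vpd": vpd, "delta": delta}


def vegetation_indices(ndvi, params: PTJPLParams = PTJPLParams()) -> dict[str, np.ndarray]:
    """NDVI-derived canopy descriptors: SAVI, fAPAR, fIPAR, f_c, LAI.

    LAI inverts Beer–Lambert through the PAR extinction coefficient, with
    canopy cover capped at 0.98 to keep the logarithm finite.
    """
    ndvi = np.asarray(ndvi, dtype=float)
    savi = params.savi_slope * ndvi + params.savi_offset
    f_apar = np.clip(params.fapar_slope * savi + params.fapar_offset, 0.0, 1.0)
    f_ipar = np.clip(params.fipar_slope * ndvi + params.fipar_offset, 0.0, 1.0)
    f_c = f_ipar
    lai = -np.log(1.0 - np.minimum(f_c, 0.98)) / params.k_par
    return {"savi": savi, "f_apar": f_apar, "f_ipar": f_ipar, "f_c": f_c, "lai": lai}


def constraints(
    met_derivs: Mapping[str, np.ndarray],
    veg: Mapping[str, np.ndarray],
    params: PTJPLParams,
    f_apar_max,
    ta=None,
    rh=None,
) -> Constraints:
    """Evaluate the five biophysical constraints.

    f_wet = RH⁴; f_g = fAPAR/fIPAR (0 where fIPAR = 0);
    f_T = exp(−((Ta − Topt)/Topt)²); f_M = fAPAR/fAPAR_max;
    f_SM = RH^(VPD/beta), forced to 1 when VPD ≤ 0.

    ``ta``/``rh`` must be supplied (they are not part of the derivative
    dict); everything broadcasts.
    """
    if ta is None or rh is None:
        raise ValueError("constraints() needs ta and rh alongside met_derivs")
    if params.topt <= 0:
        raise ValueError("topt must be > 0 °C")
    ta = np.asarray(ta, dtype=float)
    rh = np.asarray(rh, dtype=float)
    vpd = np.asarray(met_derivs["vpd"], dtype=float)
    f_apar = np.asarray(veg["f_apar"], dtype=float)
    f_ipar = np.asarray(veg["f_ipar"], dtype=float)
    f_apar_max = np.asarray(f_apar_max, dtype=float)
    if np.any(f_apar_max <= 0):
        raise ValueError("f_apar_max must be > 0")

    f_wet = np.clip(rh, 0.0, 1.0) ** 4
    with np.errstate(divide="ignore", invalid="ignore"):
        f_g = np.where(f_ipar > 0, f_apar / np.where(f_ipar > 0, f_ipar, 1.0), 0.0)
    f_g = np.clip(f_g, 0.0, 1.0)
    f_t = np.exp(-(((ta - params.topt) / params.topt) ** 2))
    f_m = np.clip(f_apar / f_apar_max, 0.0, 1.0)
    with np.errstate(invalid="ignore"):
        f_sm = np.where(vpd > 0, np.clip(rh, 0.0, 1.0) ** (np.maximum(vpd, 0.0) / params.beta), 1.0)
    f_sm = np.clip(f_sm, 0.0, 1.0)
    return Constraints(f_g=f_g, f_wet=f_wet, f_t=f_t, f_m=f_m, f_sm=f_sm)


def estimate_topt(
    met: pd.DataFrame,
    ndvi_at_site: pd.Series,
    params: PTJPLParams = PTJPLParams(),
    fallback: float = 25.0,
) -> float:
    """Optimum growth temperature: Ta of the daytime hour maximizing
    fAPAR·Rn·Ta/VPD over the season.

    ``ndvi_at_site`` is indexed by date; each hour uses its date's NDVI.
    Falls back to 25 °C when no daytime hour has positive VPD.
    """
    if len(met) == 0:
        raise ValueError("empty record set")
    day = daytime_mask(met)
    md = met_derivatives(met["Ta"].to_numpy(), met["RH"].to_numpy())
    ndvi = ndvi_at_site.reindex(pd.Index([t.date() for t in met.index])).to_numpy()
    f_apar = vegetation_indices(ndvi, params)["f_apar"]
    vpd = md["vpd"]
    valid = day.to_numpy() & (vpd > 0) & np.isfinite(f_apar)
    if not valid.any():
        return float(fallback)
    score = np.where(valid, f_apar * met["Rn"].to_numpy() * met["Ta"].to_numpy() / np.where(vpd > 0, vpd, np.inf), -np.inf)
    topt = float(met["Ta"].to_numpy()[int(np.argmax(score))])
    return topt if topt > 0 else float(fallback)


def radiation_partition(rn, lai, params: PTJPLParams = PTJPLParams()) -> dict[str, np.ndarray]:
    """Beer–Lambert split of net radiation into soil and canopy parts."""
    rn = np.asarray(rn, dtype=float)
    lai = np.asarray(lai, dtype=float)
    rn_s = rn * np.exp(-params.k_rn * lai)
    return {"rn_s": rn_s, "rn_c": rn - rn_s}


def soil_heat_flux(rn_s, t_solar, params: PTJPLParams = PTJPLParams()) -> np.ndarray:
    """Diurnal soil heat flux from soil net radiation.

    G = A·cos(2π·(t_solar + shift)/B)·Rn_s with ``t_solar`` in seconds
    relative to local solar noon; floored at 0 where Rn_s > 0 so the soil
    never gains more heat than its available radiation at night-edge
    hours.  Spatial variation enters through per-pixel Rn_s.
    """
    rn_s = np.asarray(rn_s, dtype=float)
    t_solar = np.asarray(t_solar, dtype=float)
    g = params.g_amplitude * np.cos(
        2.0 * np.pi * (t_solar + params.g_shift) / params.g_period
    ) * rn_s
    return np.where(rn_s > 0, np.maximum(g, 0.0), 0.0)


def solar_seconds(
    timestamps: pd.DatetimeIndex,
    longitude: float,
    timezone: float,
    midpoint: bool = True,
) -> np.ndarray:
    """Seconds relative to local solar noon for each record.

    Solar time = clock time + 4 min per degree east of the standard
    meridian (15°·timezone); the equation of time is ignored (≤ ~15 min).
    With ``midpoint`` the half-open hourly record [t, t+1h) is evaluated
    at t + 30 min.
    """
    hours = timestamps.hour.to_numpy() + timestamps.minute.to_numpy() / 60.0
    if midpoint:
        hours = hours + 0.5
    solar_hour = hours + (longitude - 15.0 * timezone) / 15.0
    return np.asarray((solar_hour - 12.0) * 3600.0)


def compute_fluxes(
    met_derivs: Mapping[str, np.ndarray],
    cons: Constraints,
    rn_c,
    rn_s,
    g,
    params: PTJPLParams = PTJPLParams(),
) -> FluxComponents:
    """Combine constraints, partitioned radiation and G into flux components.

    All components are floored at 0 (daytime condensation excluded) and
    the total is their exact sum.
    """
    delta = np.asarray(met_derivs["delta"], dtype=float)
    rn_c = np.asarray(rn_c, dtype=float)
    rn_s = np.asarray(rn_s, dtype=float)
    g = np.asarray(g, dtype=float)
    pt = params.alpha * delta / (delta + params.gamma)

    le_c = np.maximum((1.0 - cons.f_wet) * cons.f_g * cons.f_t * cons.f_m * pt * rn_c, 0.0)
    le_s = np.maximum((cons.f_wet + cons.f_sm * (1.0 - cons.f_wet)) * pt * np.maximum(rn_s - g, 0.0), 0.0)
    le_i = np.maximum(cons.f_wet * pt * rn_c, 0.0)
    return FluxComponents(
        le_s=le_s, le_c=le_c, le_i=le_i, le_total=le_s + le_c + le_i,
        rn_s=rn_s, rn_c=rn_c, g=g,
    )


def run_scene(
    stack: NDVIStack,
    date: dt.date,
    met_day: pd.DataFrame,
    params: PTJPLParams,
    f_apar_max_grid: np.ndarray,
    longitude: float,
    timezone: float,
) -> tuple[pd.DatetimeIndex, FluxComponents]:
    """Per-pixel fluxes for every daytime hour of one date.

    The single daily NDVI grid is reused for all hours (NDVI assumed
    constant through the day); meteorology is spatially uniform.  Output
    arrays have shape ``(n_daytime_hours, rows, cols)``.
    """
    ndvi = stack.grid_for(date)
    day = daytime_mask(met_day)
    met_day = met_day[day]
    if len(met_day) == 0:
        raise ValueError(f"no daytime hours for {date}")

    veg = vegetation_indices(ndvi, params)
    ta = met_day["Ta"].to_numpy()[:, None, None]
    rh = met_day["RH"].to_numpy()[:, None, None]
    rn = met_day["Rn"].to_numpy()[:, None, None]
    md = met_derivatives(ta, rh)
    cons = constraints(md, veg, params, f_apar_max_grid, ta=ta, rh=rh)
    part = radiation_partition(rn, veg["lai"], params)
    t_solar = solar_seconds(met_day.index, longitude, timezone)[:, None, None]
    g = soil_heat_flux(part["rn_s"], t_solar, params)
    fluxes = compute_fluxes(md, cons, part["rn_c"], part["rn_s"], g, params)
    return met_day.index, fluxes


def f_apar_max_from_stack(stack: NDVIStack, params: PTJPLParams = PTJPLParams()) -> np.ndarray:
    """Per-pixel seasonal maximum fAPAR over the NDVI stack."""
    ndvi_max = stack.grids.max(axis=0)
    f_apar = vegetation_indices(ndvi_max, params)["f_apar"]
    # guard against never-vegetated pixels: f_M denominator must be > 0
    return np.maximum(f_apar, 1e-6)
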