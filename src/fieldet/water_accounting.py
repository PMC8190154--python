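"""Depth conversion, daily/zonal aggregation, smoothing, cumulative accounting.

Fluxes (W/m²) convert to water depths through the latent heat of
vaporization; depths aggregate to mm/day over daytime hours (nighttime
contributes zero), then to field scale via pixel-center zonal statistics.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.signal import savgol_filter

from fieldet.forcing_io import FieldBoundary, GeoTransform

__all__ = [
    "ZonalStats",
    "flux_to_depth",
    "depth_to_flux",
    "aggregate_daily",
    "zonal_pixel_mask",
    "zonal_mean",
    "smooth_series",
    "cumulative_compare",
    "cumulative_e_map",
    "underperformance_mask",
]

SECONDS_PER_HOUR = 3600.0
DEFAULT_BIN_WIDTH = 0.05  # mm/day


@dataclass
class ZonalStats:
    mean: float
    std: float
    n_pixels: int
    histogram: tuple[np.ndarray, np.ndarray]  # (counts, bin_edges)


def flux_to_depth(le, lambda_v: float = 2.26e6):
    """Latent heat flux (W/m²) to evaporation depth rate (mm/h).

    E(mm/h) = LE(W/m²) · 3600 / λ, with λ in J/kg.
    """
    if lambda_v <= 0:
        raise ValueError("lambda_v must be > 0")
    return np.asarray(le, dtype=float) * SECONDS_PER_HOUR / lambda_v


def depth_to_flux(e_mm_h, lambda_v: float = 2.26e6):
    """Inverse of :func:`flux_to_depth`."""
    if lambda_v <= 0:
        raise ValueError("lambda_v must be > 0")
    return np.asarray(e_mm_h, dtype=float) * lambda_v / SECONDS_PER_HOUR


def aggregate_daily(hourly_mm: pd.Series, day_mask: pd.Series) -> pd.Series:
    """Sum hourly depths (mm/h) to mm/day over daytime hours.

    Nighttime contributes 0; dates with no daytime hour come out NaN.
    """
    day_mask = day_mask.reindex(hourly_mm.index, fill_value=False)
    contrib = hourly_mm.where(day_mask, 0.0)
    dates = pd.Index([t.date() for t in hourly_mm.index], name="date")
    daily = contrib.groupby(dates).sum(min_count=1)
    has_day = day_mask.groupby(dates).any()
    return daily.where(has_day)


def zonal_pixel_mask(
    shape: tuple[int, int], transform: GeoTransform, boundary: FieldBoundary
) -> np.ndarray:
    """Pixels whose centers fall inside the boundary polygon."""
    x, y = transform.pixel_centers(shape)
    return shapely.contains_xy(boundary.polygon, x, y)


def zonal_mean(
    raster: np.ndarray,
    transform: GeoTransform,
    boundary: FieldBoundary,
    bin_width: float = DEFAULT_BIN_WIDTH,
    bin_edges: np.ndarray | None = None,
) -> ZonalStats:
    """Zonal statistics over pixels with centers inside the polygon."""
    raster = np.asarray(raster, dtype=float)
    inside = zonal_pixel_mask(raster.shape, transform, boundary)
    values = raster[inside]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no pixel centers inside the boundary")
    if bin_edges is None:
        lo = np.floor(values.min() / bin_width) * bin_width
        hi = np.ceil(values.max() / bin_width) * bin_width
        n = max(int(round((hi - lo) / bin_width)), 1)
        bin_edges = lo + bin_width * np.arange(n + 1)
    counts, edges = np.histogram(values, bins=bin_edges)
    return ZonalStats(
        mean=float(values.mean()),
        std=float(values.std()),
        n_pixels=int(values.size),
        histogram=(counts, edges),
    )


def smooth_series(values, window: int = 15, polyorder: int = 3) -> np.ndarray:
    """Savitzky–Golay least-squares smoothing.

    Edges are handled by fitting the polynomial on the truncated window
    (scipy's ``mode='interp'``); a polynomial of degree ≤ polyorder is
    therefore reproduced exactly.
    """
    values = np.asarray(values, dtype=float)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    if values.size < window:
        raise ValueError(f"series length {values.size} shorter than window {window}")
    return savgol_filter(values, window_length=window, polyorder=polyorder, mode="interp")


def cumulative_compare(
    daily: pd.DataFrame,
    season: tuple[dt.date, dt.date],
    include_irrigation: bool = False,
) -> pd.DataFrame:
    """Running totals of E and precipitation over the growing season.

    ``daily`` is indexed by date with columns ``E_mm`` and ``precip_mm``
    (optionally ``irrigation_mm``, added to the water supply when
    ``include_irrigation``).  Rows are restricted to [sowing, harvest].
    """
    sowing, harvest = season
    sel = daily.loc[(daily.index >= sowing) & (daily.index <= harvest)].copy()
    supply = sel["precip_mm"].fillna(0.0)
    if include_irrigation and "irrigation_mm" in sel:
        supply = supply + sel["irrigation_mm"].fillna(0.0)
    return pd.DataFrame(
        {
            "cum_E": sel["E_mm"].fillna(0.0).cumsum(),
            "cum_P": supply.cumsum(),
        },
        index=sel.index,
    )


def cumulative_e_map(
    daily_rasters: np.ndarray,
    dates: Sequence[dt.date],
    season: tuple[dt.date, dt.date] | None = None,
) -> np.ndarray:
    """Per-pixel seasonal total of daily E rasters (mm)."""
    daily_rasters = np.asarray(daily_rasters, dtype=float)
    if daily_rasters.ndim != 3 or daily_rasters.shape[0] != len(dates):
        raise ValueError("daily_rasters must be (n_dates, rows, cols) aligned with dates")
    if season is None:
        keep = np.ones(len(dates), dtype=bool)
    else:
        sowing, harvest = season
        keep = np.array([sowing <= d <= harvest for d in dates])
    return np.nansum(daily_rasters[keep], axis=0)


def underperformance_mask(
    cumulative: np.ndarray,
    transform: GeoTransform,
    boundary: FieldBoundary,
    k: float = 1.5,
) -> np.ndarray:
    """Flag in-field pixels more than ``k`` zonal standard deviations
    below the zonal mean of the cumulative E raster."""
    stats = zonal_mean(cumulative, transform, boundary)
    inside = zonal_pixel_mask(np.asarray(cumulative).shape, transform, boundary)
    if stats.std == 0:
        return np.zeros_like(inside)
    return inside & (np.asarray(cumulative, dtype=float) < stats.mean - k * stats.std)
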