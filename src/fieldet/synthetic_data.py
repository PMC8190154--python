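"""Seeded generators for NDVI scenes, meteorology and tower flux records.

The generators share one :class:`SyntheticConfig` and a single integer
seed.  Independent substreams (``default_rng([seed, k])``) are used for
each stochastic component — patches (k=0), clouds (k=1), rain (k=2),
flux noise (k=3), gap insertion (k=4) — so the draw order of one
component never perturbs another.

Tower truth is produced by the same :mod:`fieldet.ptjpl_core`
operations the pipeline uses, which makes the energy-closure residual
correction exact on noise-free synthetic records: the sensible heat flux
is constructed so that ``Rn − G − H`` equals the true latent heat flux.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box

from fieldet import ptjpl_core
from fieldet.forcing_io import FieldBoundary, GeoTransform, NDVIStack, daytime_mask
from fieldet.ptjpl_core import PTJPLParams

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "gen_ndvi_stack",
    "gen_patch_mask",
    "gen_met_series",
    "gen_tower_record",
    "gen_boundary",
    "insert_gaps",
    "double_logistic",
    "ndvi_series_at",
    "tower_pixel",
    "daylight_window",
]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic field scene and tower."""

    grid_shape: tuple[int, int] = (64, 64)
    pixel_size: float = 3.0
    season_start: dt.date = dt.date(2019, 4, 1)
    season_end: dt.date = dt.date(2019, 11, 15)
    sowing_doy: int = 109
    harvest_doy: int = 311

    # phenology
    ndvi_base: float = 0.15
    ndvi_peak: float = 0.85
    green_up_rate: float = 0.12     # 1/day
    senescence_rate: float = 0.10   # 1/day
    green_up_lag: int = 25          # days after sowing to green-up inflection
    senescence_lead: int = 20       # days before harvest to senescence inflection

    # heterogeneity
    n_patches: int = 3
    patch_amplitude_drop: float = 0.3
    patch_size: tuple[int, int] = (6, 14)   # side length range, pixels

    # meteorology
    rn_max: float = 600.0           # clear-sky peak net radiation, W/m²
    sunrise_hour: float = 6.0
    sunset_hour: float = 18.0
    ta_mean: float = 12.0
    ta_amp_seasonal: float = 12.0
    ta_amp_diurnal: float = 6.0
    rh_mean: float = 0.65
    rh_amp: float = 0.25
    cloud_prob: float = 0.25
    cloud_attenuation: float = 0.5
    rain_prob: float = 0.25         # probability of a rain event per day
    rain_mean_mm: float = 6.0       # mean event depth (exponential)

    # tower
    closure_gap_fraction: float = 0.15
    noise_sd: float = 0.0           # W/m² on measured LE
    longitude: float = -96.4766
    timezone: float = -6.0

    irrigation_events: tuple[tuple[dt.date, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.ndvi_base < self.ndvi_peak <= 1):
            raise ConfigurationError("require 0 <= ndvi_base < ndvi_peak <= 1")
        if not self.sowing_doy < self.harvest_doy:
            raise ConfigurationError("sowing_doy must precede harvest_doy")
        if not 0 <= self.closure_gap_fraction <= 0.5:
            raise ConfigurationError("closure_gap_fraction must be in [0, 0.5]")
        if self.season_start > self.season_end:
            raise ConfigurationError("season_start must not follow season_end")
        if self.n_patches > 0 and min(self.grid_shape) < self.patch_size[1]:
            raise ConfigurationError(
                f"grid {self.grid_shape} too small to place {self.n_patches} "
                f"patch(es) of size up to {self.patch_size[1]}"
            )

    @property
    def dates(self) -> list[dt.date]:
        n = (self.season_end - self.season_start).days + 1
        return [self.season_start + dt.timedelta(days=i) for i in range(n)]

    @property
    def transform(self) -> GeoTransform:
        return GeoTransform(
            x_origin=0.0,
            y_origin=self.grid_shape[0] * self.pixel_size,
            pixel_size=self.pixel_size,
        )


@dataclass
class SyntheticTruth:
    """Reference values behind a generated tower record."""

    le_true: pd.Series           # W/m², the model truth at the tower pixel
    g: pd.Series                 # W/m²
    h: pd.Series                 # W/m², constructed so Rn - G - H = le_true
    closure_gap: pd.Series       # W/m² removed from measured LE
    topt: float
    f_apar_max: float
    ndvi_at_tower: pd.Series     # indexed by date


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def tower_pixel(config: SyntheticConfig) -> tuple[int, int]:
    """Row/column of the tower pixel (grid center)."""
    return config.grid_shape[0] // 2, config.grid_shape[1] // 2


def daylight_window(config: SyntheticConfig) -> tuple[float, float]:
    """Local hours [sunrise, sunset) during which generated Rn > 0."""
    return config.sunrise_hour, config.sunset_hour


def double_logistic(
    doy,
    base: float,
    peak: float,
    green_up_rate: float,
    senescence_rate: float,
    d_up: float,
    d_down: float,
):
    """Seasonal NDVI curve: rising and falling logistic terms.

    NDVI(d) = base + (peak − base)·[1/(1+exp(−g·(d−d_up)))
                                   − 1/(1+exp(−s·(d−d_down)))],
    clipped to [0, 1].
    """
    d = np.asarray(doy, dtype=float)
    up = 1.0 / (1.0 + np.exp(-green_up_rate * (d - d_up)))
    down = 1.0 / (1.0 + np.exp(-senescence_rate * (d - d_down)))
    return np.clip(base + (peak - base) * (up - down), 0.0, 1.0)


def gen_patch_mask(config: SyntheticConfig) -> np.ndarray:
    """Boolean mask of the heterogeneity patches (rectangles).

    Deterministic in the seed; regenerating the mask never consumes draws
    from any other component's stream.
    """
    rows, cols = config.grid_shape
    mask = np.zeros((rows, cols), dtype=bool)
    if config.n_patches == 0:
        return mask
    rng = _rng(config, 0)
    lo, hi = config.patch_size
    for _ in range(config.n_patches):
        h = int(rng.integers(lo, hi + 1))
        w = int(rng.integers(lo, hi + 1))
        r0 = int(rng.integers(0, rows - h + 1))
        c0 = int(rng.integers(0, cols - w + 1))
        mask[r0 : r0 + h, c0 : c0 + w] = True
    return mask


def gen_ndvi_stack(config: SyntheticConfig) -> NDVIStack:
    """Daily NDVI rasters following the double-logistic phenology.

    The peak NDVI is reduced by ``patch_amplitude_drop`` (as a fraction
    of the seasonal amplitude) inside heterogeneity patches.
    """
    dates = config.dates
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)
    d_up = config.sowing_doy + config.green_up_lag
    d_down = config.harvest_doy - config.senescence_lead

    patch = gen_patch_mask(config)
    peak = np.where(
        patch,
        config.ndvi_base + (1.0 - config.patch_amplitude_drop) * (config.ndvi_peak - config.ndvi_base),
        config.ndvi_peak,
    )
    grids = double_logistic(
        doy[:, None, None],
        config.ndvi_base,
        1.0,  # placeholder; amplitude applied below per pixel
        config.green_up_rate,
        config.senescence_rate,
        d_up,
        d_down,
    )
    # rebuild with per-pixel peak: curve shape times per-pixel amplitude
    shape = (grids - config.ndvi_base) / (1.0 - config.ndvi_base)
    grids = np.clip(config.ndvi_base + shape * (peak[None] - config.ndvi_base), 0.0, 1.0)
    return NDVIStack(dates=list(dates), grids=grids.astype(np.float32), transform=config.transform)


def gen_boundary(config: SyntheticConfig, site_id: str = "synthetic") -> FieldBoundary:
    """Rectangular field boundary inset one pixel from the grid edge."""
    t = config.transform
    rows, cols = config.grid_shape
    pad = t.pixel_size
    poly = box(pad, pad, cols * t.pixel_size - pad, rows * t.pixel_size - pad)
    return FieldBoundary(polygon=poly, site_id=site_id)


def gen_met_series(config: SyntheticConfig) -> pd.DataFrame:
    """Hourly meteorology over the season.

    Rn is a clipped half-sine over the daylight window scaled by a daily
    cloud factor; Ta a diurnal sinusoid on a seasonal baseline; RH in
    anti-phase with Ta; rain events are daily Bernoulli draws with
    exponential depths.  Records are evaluated at the hour midpoint
    (half-open [t, t+1h) convention).
    """
    dates = config.dates
    n_days = len(dates)
    index = pd.date_range(
        dt.datetime.combine(config.season_start, dt.time(0)),
        periods=n_days * 24,
        freq="h",
        name="timestamp",
    )
    h = index.hour.to_numpy() + 0.5
    doy = np.repeat([d.timetuple().tm_yday for d in dates], 24).astype(float)

    cloud_rng = _rng(config, 1)
    cloudy = cloud_rng.random(n_days) < config.cloud_prob
    factor = np.where(cloudy, 1.0 - config.cloud_attenuation, 1.0)
    factor_h = np.repeat(factor, 24)

    day_len = config.sunset_hour - config.sunrise_hour
    rn = config.rn_max * np.sin(np.pi * (h - config.sunrise_hour) / day_len)
    rn = np.maximum(rn, 0.0) * factor_h
    rn[(h < config.sunrise_hour) | (h > config.sunset_hour)] = 0.0

    ta_base = config.ta_mean + config.ta_amp_seasonal * np.sin(2 * np.pi * (doy - 130.0) / 365.0)
    ta = ta_base + config.ta_amp_diurnal * np.cos(2 * np.pi * (h - 15.0) / 24.0)
    rh = np.clip(config.rh_mean - config.rh_amp * np.cos(2 * np.pi * (h - 15.0) / 24.0), 0.05, 1.0)

    rain_rng = _rng(config, 2)
    rains = rain_rng.random(n_days) < config.rain_prob
    depths = rain_rng.exponential(config.rain_mean_mm, n_days) * rains
    p = np.zeros(n_days * 24)
    p[4::24] = depths  # events booked in the 04:00 hour

    df = pd.DataFrame(
        {"Ta": ta, "RH": rh, "Rn": rn, "G": 0.0, "H": 0.0, "LE": np.nan, "P": p},
        index=index,
    )
    df.attrs["timezone"] = config.timezone
    return df


def ndvi_series_at(stack: NDVIStack, row: int, col: int) -> pd.Series:
    """NDVI trajectory of one pixel, indexed by date."""
    return pd.Series(stack.grids[:, row, col].astype(float), index=pd.Index(stack.dates))


def gen_tower_record(
    config: SyntheticConfig,
    ndvi_at_tower: pd.Series,
    met: pd.DataFrame,
    params: PTJPLParams = PTJPLParams(),
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Tower flux record with an imposed closure gap and noise.

    True LE is computed by the PT-JPL operations at the tower pixel; the
    measured LE is ``true_LE·(1 − closure_gap_fraction) + N(0, noise_sd)``
    while H is set so that ``Rn − G − H = true_LE`` exactly — the full
    gap sits in LE, matching the residual correction's assumption that H
    is measured correctly.
    """
    record_dates = pd.Index([t.date() for t in met.index])
    if not set(record_dates).issubset(set(ndvi_at_tower.index)):
        raise ValueError("NDVI series does not cover the met period")

    f_apar_max = float(
        ptjpl_core.vegetation_indices(float(ndvi_at_tower.max()), params)["f_apar"]
    )
    f_apar_max = max(f_apar_max, 1e-6)
    topt = ptjpl_core.estimate_topt(met, ndvi_at_tower, params)
    params = params.with_topt(topt)

    ta = met["Ta"].to_numpy()
    rh = met["RH"].to_numpy()
    rn = met["Rn"].to_numpy()
    ndvi = ndvi_at_tower.reindex(record_dates).to_numpy()

    md = ptjpl_core.met_derivatives(ta, rh)
    veg = ptjpl_core.vegetation_indices(ndvi, params)
    cons = ptjpl_core.constraints(md, veg, params, f_apar_max, ta=ta, rh=rh)
    part = ptjpl_core.radiation_partition(rn, veg["lai"], params)
    t_solar = ptjpl_core.solar_seconds(met.index, config.longitude, config.timezone)
    g = ptjpl_core.soil_heat_flux(part["rn_s"], t_solar, params)
    fluxes = ptjpl_core.compute_fluxes(md, cons, part["rn_c"], part["rn_s"], g, params)

    le_true = fluxes.le_total
    h_flux = rn - g - le_true
    # round-trip through the closure identity so Rn - G - H recovers the
    # stored truth bit-exactly (differs from the raw model value by <=1 ulp)
    le_true = rn - g - h_flux
    noise_rng = _rng(config, 3)
    noise = noise_rng.normal(0.0, config.noise_sd, len(met)) if config.noise_sd > 0 else 0.0
    le_meas = le_true * (1.0 - config.closure_gap_fraction) + noise

    out = met.copy()
    out.attrs = dict(met.attrs)
    out["G"] = g
    out["H"] = h_flux
    out["LE"] = le_meas

    truth = SyntheticTruth(
        le_true=pd.Series(le_true, index=met.index, name="LE_true"),
        g=pd.Series(g, index=met.index, name="G"),
        h=pd.Series(h_flux, index=met.index, name="H"),
        closure_gap=pd.Series(le_true * config.closure_gap_fraction, index=met.index, name="gap"),
        topt=topt,
        f_apar_max=f_apar_max,
        ndvi_at_tower=ndvi_at_tower,
    )
    return out, truth


def insert_gaps(
    records: pd.DataFrame,
    gap_fraction: float,
    neg_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Knock out / negate a fraction of daytime LE records.

    ``round(fraction · n_daytime)`` records are affected for each action;
    gap and negation positions are disjoint and reproducible under the
    seed.  Returns the modified copy and the counts applied.
    """
    if not (0 <= gap_fraction < 0.5 and 0 <= neg_fraction < 0.5):
        raise ValueError("fractions must be in [0, 0.5)")
    day_idx = np.flatnonzero(daytime_mask(records).to_numpy())
    n_day = len(day_idx)
    n_gap = int(round(gap_fraction * n_day))
    n_neg = int(round(neg_fraction * n_day))
    if n_gap + n_neg > n_day:
        raise ValueError("requested fractions exceed the available daytime records")

    rng = np.random.default_rng([seed, 4])
    perm = rng.permutation(day_idx)
    gap_pos = perm[:n_gap]
    neg_pos = perm[n_gap : n_gap + n_neg]

    out = records.copy()
    out.attrs = dict(records.attrs)
    le = out["LE"].to_numpy(dtype=float, copy=True)
    le[gap_pos] = np.nan
    le[neg_pos] = -np.abs(le[neg_pos])
    out["LE"] = le
    return out, {"n_gapped": n_gap, "n_negated": n_neg, "n_daytime": n_day}
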