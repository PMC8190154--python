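"""End-to-end orchestration: QC'd forcing + NDVI stack -> E products + stats."""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fieldet import evaluation, ptjpl_core, water_accounting
from fieldet.evaluation import EvalStats
from fieldet.forcing_io import (
    FieldBoundary,
    NDVIStack,
    QCReport,
    closure_correct,
    daytime_mask,
    prepare_met,
)
from fieldet.ptjpl_core import PTJPLParams

__all__ = ["PipelineResult", "run_season", "evaluate_against_tower"]


@dataclass
class PipelineResult:
    """Everything a season run produces."""

    dates: list[dt.date]
    daily_rasters: np.ndarray            # (n_dates, rows, cols), mm/day
    hourly_field_mean: pd.Series         # mm/h, daytime hours only
    hourly_tower_pixel: pd.Series        # mm/h, daytime hours only
    field_series: pd.DataFrame           # per-day field stats
    cumulative: pd.DataFrame             # cum_E / cum_P over the season
    cumulative_map: np.ndarray           # mm
    underperformance: np.ndarray         # bool raster
    met: pd.DataFrame                    # QC'd forcing
    qc: QCReport
    params: PTJPLParams
    topt: float
    stats: EvalStats | None = None
    pairs: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def run_season(
    stack: NDVIStack,
    met_raw: pd.DataFrame,
    boundary: FieldBoundary,
    longitude: float,
    timezone: float,
    season: tuple[dt.date, dt.date] | None = None,
    params: PTJPLParams = PTJPLParams(),
    tower_rc: tuple[int, int] | None = None,
    irrigation_events: list[tuple[dt.date, float]] | None = None,
    include_irrigation: bool = False,
    smooth_window: int = 15,
    smooth_polyorder: int = 3,
    underperformance_k: float = 1.5,
    evaluate: bool = True,
    eval_mode: str = "field_mean",
) -> PipelineResult:
    """Run the full analysis for one site/season.

    Quality-controls the tower record, estimates the optimum growth
    temperature, forces the flux model hourly against the daily NDVI
    grids, converts to water depths and aggregates daily/zonal series,
    cumulative totals and the underperformance map, and (optionally)
    evaluates field-mean E against the closure-corrected tower E.
    """
    met, qc = prepare_met(met_raw)
    met_dates = pd.unique(pd.Index([t.date() for t in met.index]))
    dates = [d for d in stack.dates if d in set(met_dates)]
    if not dates:
        raise ValueError("NDVI stack and meteorology share no dates")
    if season is None:
        season = (dates[0], dates[-1])

    rows, cols = stack.shape
    if tower_rc is None:
        tower_rc = (rows // 2, cols // 2)

    f_apar_max = ptjpl_core.f_apar_max_from_stack(stack, params)
    ndvi_tower = pd.Series(
        stack.grids[:, tower_rc[0], tower_rc[1]].astype(float), index=pd.Index(stack.dates)
    )
    topt = ptjpl_core.estimate_topt(met, ndvi_tower, params)
    params = params.with_topt(topt)

    inside = water_accounting.zonal_pixel_mask(stack.shape, stack.transform, boundary)
    if not inside.any():
        raise ValueError("boundary contains no pixel centers")

    by_date = {d: g for d, g in met.groupby(met.index.date)}
    daily_rasters = np.zeros((len(dates), rows, cols))
    mean_index, mean_values = [], []
    tower_values = []
    for i, date in enumerate(dates):
        met_day = by_date[date]
        if not daytime_mask(met_day).any():
            daily_rasters[i] = np.nan
            continue
        hours, fluxes = ptjpl_core.run_scene(
            stack, date, met_day, params, f_apar_max, longitude, timezone
        )
        e_mm_h = water_accounting.flux_to_depth(fluxes.le_total, params.lambda_v)
        daily_rasters[i] = e_mm_h.sum(axis=0)
        mean_index.extend(hours)
        mean_values.append(e_mm_h[:, inside].mean(axis=1))
        tower_values.append(e_mm_h[:, tower_rc[0], tower_rc[1]])

    hourly_field_mean = pd.Series(
        np.concatenate(mean_values), index=pd.DatetimeIndex(mean_index), name="E_model"
    )
    hourly_tower_pixel = pd.Series(
        np.concatenate(tower_values), index=pd.DatetimeIndex(mean_index), name="E_model_tower_px"
    )

    # per-day field statistics
    e_mm = np.array([r[inside].mean() for r in daily_rasters])
    pixel_std = np.array([r[inside].std() for r in daily_rasters])
    precip = met["P"].groupby(met.index.date).sum()
    irrigation = pd.Series(0.0, index=pd.Index(dates))
    for d, depth in irrigation_events or []:
        if d in irrigation.index:
            irrigation.loc[d] += depth

    field_series = pd.DataFrame(
        {
            "E_mm": e_mm,
            "pixel_std": pixel_std,
            "precip_mm": precip.reindex(dates).fillna(0.0).to_numpy(),
            "irrigation_mm": irrigation.to_numpy(),
        },
        index=pd.Index(dates, name="date"),
    )
    window = min(smooth_window, len(field_series) - (len(field_series) + 1) % 2)
    if window > smooth_polyorder:
        field_series["E_smooth"] = water_accounting.smooth_series(
            field_series["E_mm"].to_numpy(), window=window, polyorder=smooth_polyorder
        )
    else:
        field_series["E_smooth"] = field_series["E_mm"]

    cumulative = water_accounting.cumulative_compare(
        field_series, season, include_irrigation=include_irrigation
    )
    cumulative_map = water_accounting.cumulative_e_map(daily_rasters, dates, season)
    underperf = water_accounting.underperformance_mask(
        cumulative_map, stack.transform, boundary, k=underperformance_k
    )

    result = PipelineResult(
        dates=dates,
        daily_rasters=daily_rasters,
        hourly_field_mean=hourly_field_mean,
        hourly_tower_pixel=hourly_tower_pixel,
        field_series=field_series,
        cumulative=cumulative,
        cumulative_map=cumulative_map,
        underperformance=underperf,
        met=met,
        qc=qc,
        params=params,
        topt=topt,
    )
    if evaluate:
        evaluate_against_tower(result, season, eval_mode=eval_mode)
    return result


def evaluate_against_tower(
    result: PipelineResult,
    season: tuple[dt.date, dt.date],
    eval_mode: str = "field_mean",
) -> EvalStats:
    """Pair model E with residual-corrected tower E and compute statistics.

    ``eval_mode`` selects the model series: the field-mean ('field_mean',
    default) or the single tower pixel ('tower_pixel').
    """
    if eval_mode == "field_mean":
        model = result.hourly_field_mean
    elif eval_mode == "tower_pixel":
        model = result.hourly_tower_pixel
    else:
        raise ValueError(f"unknown eval_mode {eval_mode!r}")
    le_corr = closure_correct(result.met)
    measured = pd.Series(
        water_accounting.flux_to_depth(le_corr.to_numpy(), result.params.lambda_v),
        index=result.met.index,
        name="E_measured",
    )
    pairs = evaluation.pair_series(
        model, measured, season=season, day_mask=daytime_mask(result.met)
    )
    stats = evaluation.compute_stats(pairs)
    result.stats = stats
    result.pairs = pairs
    return stats
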