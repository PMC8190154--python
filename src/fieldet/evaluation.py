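"""Model-vs-tower pairing and performance statistics (r², bias, MAE).

Conventions: x is the measured (closure-corrected) series, y the model.
Moments use the population (1/n) normalization throughout — the squared
correlation is invariant to that choice.  The normalized bias is
expressed as a percentage of the measured range.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EvalStats", "pair_series", "compute_stats"]


@dataclass
class EvalStats:
    r2: float | None
    bias: float
    bias_norm: float | None  # % of measured range
    mae: float
    n: int
    r2_undefined_reason: str | None = None


def pair_series(
    model: pd.Series,
    measured: pd.Series,
    season: tuple[dt.date, dt.date] | None = None,
    day_mask: pd.Series | None = None,
) -> pd.DataFrame:
    """Align model and measured hourly series into evaluation pairs.

    Only timestamps present in both series, inside the season and (when a
    mask is given) flagged daytime, with both values present, survive.
    Returns a frame with columns ``x`` (measured) and ``y`` (model).
    """
    df = pd.concat({"y": model, "x": measured}, axis=1, join="inner")
    if day_mask is not None:
        df = df[day_mask.reindex(df.index, fill_value=False)]
    if season is not None:
        sowing, harvest = season
        dates = pd.Index([t.date() for t in df.index])
        df = df[(dates >= sowing) & (dates <= harvest)]
    df = df.dropna()
    if len(df) == 0:
        raise ValueError("no overlapping valid samples to pair")
    return df[["x", "y"]]


def compute_stats(pairs: pd.DataFrame) -> EvalStats:
    """r², mean bias and MAE of modeled (y) against measured (x) samples.

    r² is the squared ratio of covariance to the product of standard
    deviations; bias is mean(y − x); MAE is mean|y − x|.  With zero
    variance in either series r² is undefined and reported as None with a
    reason.
    """
    x = pairs["x"].to_numpy(dtype=float)
    y = pairs["y"].to_numpy(dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")

    bias = float(np.mean(y - x))
    mae = float(np.mean(np.abs(y - x)))

    x_range = float(x.max() - x.min())
    bias_norm = 100.0 * abs(bias) / x_range if x_range > 0 else None

    sx = float(x.std())
    sy = float(y.std())
    if sx == 0 or sy == 0:
        return EvalStats(
            r2=None, bias=bias, bias_norm=bias_norm, mae=mae, n=n,
            r2_undefined_reason="zero variance in at least one series",
        )
    cov = float(np.mean((x - x.mean()) * (y - y.mean())))
    r2 = (cov / (sy * sx)) ** 2
    return EvalStats(r2=float(min(r2, 1.0)), bias=bias, bias_norm=bias_norm, mae=mae, n=n)
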