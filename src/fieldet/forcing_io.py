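"""Tower forcing/evaluation I/O, quality control and closure correction.

Hourly tower records are held in a :class:`pandas.DataFrame` indexed by
naive local-standard-time timestamps (half-open convention: a record
stamped ``t`` covers ``[t, t + 1h)``) with the columns

    ``Ta`` (°C), ``RH`` (fraction), ``Rn`` (W/m²), ``G`` (W/m²),
    ``H`` (W/m²), ``LE`` (W/m²), ``P`` (mm per hour).

CSV ingestion follows the AmeriFlux convention (``TIMESTAMP_START``
``YYYYMMDDHHMM``; ``-9999`` missing sentinel; ``RH`` in percent).
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "MetRecord",
    "MET_COLUMNS",
    "GeoTransform",
    "NDVIStack",
    "FieldBoundary",
    "SiteManagement",
    "QCReport",
    "read_met_csv",
    "write_met_csv",
    "daytime_mask",
    "gap_fill_linear",
    "screen_negative_daytime_le",
    "closure_correct",
    "prepare_met",
    "read_ndvi_stack",
    "write_ndvi_stack",
    "read_boundary",
    "write_boundary",
    "read_management_log",
]

MET_COLUMNS = ["Ta", "RH", "Rn", "G", "H", "LE", "P"]

#: AmeriFlux-style CSV column names mapped to internal names.
_CSV_COLUMNS = {
    "TA": "Ta",
    "RH": "RH",
    "NETRAD": "Rn",
    "G": "G",
    "H": "H",
    "LE": "LE",
    "P": "P",
}

MISSING_SENTINEL = -9999.0


class MetRecord(NamedTuple):
    """One hour of tower forcing/evaluation data."""

    timestamp: dt.datetime
    Ta: float
    RH: float
    Rn: float
    G: float
    H: float
    LE: float
    P: float


class SchemaError(ValueError):
    """A required input column is absent."""


class AlignmentError(ValueError):
    """Rasters in a stack disagree in shape or georeferencing."""


@dataclass(frozen=True)
class GeoTransform:
    """North-up affine georeferencing: origin is the top-left corner."""

    x_origin: float
    y_origin: float
    pixel_size: float

    def pixel_centers(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) coordinate arrays of the pixel centers."""
        rows, cols = shape
        x = self.x_origin + (np.arange(cols) + 0.5) * self.pixel_size
        y = self.y_origin - (np.arange(rows) + 0.5) * self.pixel_size
        return np.meshgrid(x, y)


@dataclass
class NDVIStack:
    """Dated sequence of co-registered NDVI grids.

    ``grids`` has shape ``(n_dates, rows, cols)`` and is kept sorted by
    ``dates``.  Values are fractions in [-1, 1].
    """

    dates: list[dt.date]
    grids: np.ndarray
    transform: GeoTransform

    def __post_init__(self) -> None:
        self.grids = np.asarray(self.grids, dtype=np.float32)
        if self.grids.ndim != 3 or len(self.dates) != self.grids.shape[0]:
            raise ValueError("grids must be (n_dates, rows, cols) matching dates")
        order = np.argsort(np.asarray(self.dates, dtype="datetime64[D]"))
        if not np.array_equal(order, np.arange(len(self.dates))):
            self.dates = [self.dates[i] for i in order]
            self.grids = self.grids[order]

    @property
    def shape(self) -> tuple[int, int]:
        return self.grids.shape[1:]

    def grid_for(self, date: dt.date) -> np.ndarray:
        try:
            i = self.dates.index(date)
        except ValueError:
            raise KeyError(f"date {date} not present in NDVI stack") from None
        return self.grids[i]


@dataclass
class FieldBoundary:
    """Field polygon in the raster coordinate system."""

    polygon: BaseGeometry
    site_id: str = "field"

    def __post_init__(self) -> None:
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise ValueError("boundary must be a valid polygon with nonzero area")


@dataclass
class SiteManagement:
    """Management-log entry for one study site."""

    site_id: str
    latitude: float
    longitude: float
    crop: str
    sowing_date: dt.date
    harvest_date: dt.date
    irrigation_events: list[tuple[dt.date, float]] = field(default_factory=list)
    total_rainfall_mm: float | None = None
    rainfall_growing_season_mm: float | None = None

    @property
    def sowing_doy(self) -> int:
        return self.sowing_date.timetuple().tm_yday

    @property
    def harvest_doy(self) -> int:
        return self.harvest_date.timetuple().tm_yday

    def total_irrigation_mm(self) -> float:
        return float(sum(depth for _, depth in self.irrigation_events))


@dataclass
class QCReport:
    """Bookkeeping of quality-control actions on a tower record."""

    n_records: int = 0
    n_gap_filled: dict[str, int] = field(default_factory=dict)
    n_negative_daytime_le: int = 0


# ---------------------------------------------------------------------------
# Tower CSV
# ---------------------------------------------------------------------------

def read_met_csv(
    path: str | Path,
    timezone: float,
    rh_unit: str = "percent",
) -> pd.DataFrame:
    """Read an AmeriFlux-style hourly CSV into the internal met frame.

    Parameters
    ----------
    path
        CSV with columns ``TIMESTAMP_START, TA, RH, NETRAD, G, H, LE, P``.
    timezone
        UTC offset (hours) of the local standard time of the timestamps;
        stored in ``df.attrs['timezone']`` for solar-time computations.
    rh_unit
        ``'percent'`` (divided by 100), ``'fraction'`` (taken as-is) or
        ``'auto'`` (percent assumed when any value exceeds 1.5).
    """
    raw = pd.read_csv(path, dtype={"TIMESTAMP_START": str})
    missing = [c for c in ("TIMESTAMP_START", *_CSV_COLUMNS) if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    index = pd.to_datetime(raw["TIMESTAMP_START"], format="%Y%m%d%H%M")
    if not index.is_monotonic_increasing or index.duplicated().any():
        raise ValueError("timestamps must be strictly increasing")

    df = raw[list(_CSV_COLUMNS)].rename(columns=_CSV_COLUMNS).astype(float)
    df.index = pd.DatetimeIndex(index, name="timestamp")
    df = df.replace(MISSING_SENTINEL, np.nan)

    rh = df["RH"]
    if rh_unit == "auto":
        rh_unit = "percent" if np.nanmax(rh.to_numpy()) > 1.5 else "fraction"
    if rh_unit == "percent":
        df["RH"] = rh / 100.0
    elif rh_unit != "fraction":
        raise ValueError(f"unknown rh_unit {rh_unit!r}")
    bad_rh = df["RH"].dropna()
    if ((bad_rh < 0) | (bad_rh > 1)).any():
        raise ValueError("RH outside [0, 1] after unit normalization")

    df.attrs["timezone"] = float(timezone)
    return df


def write_met_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write the internal met frame back to AmeriFlux-style CSV."""
    out = pd.DataFrame(
        {
            "TIMESTAMP_START": df.index.strftime("%Y%m%d%H%M"),
            "TA": df["Ta"],
            "RH": df["RH"] * 100.0,
            "NETRAD": df["Rn"],
            "G": df["G"],
            "H": df["H"],
            "LE": df["LE"],
            "P": df["P"],
        }
    )
    out = out.fillna(MISSING_SENTINEL)
    out.to_csv(path, index=False)


def iter_records(df: pd.DataFrame) -> Iterable[MetRecord]:
    """Yield rows as :class:`MetRecord` tuples."""
    for ts, row in df.iterrows():
        yield MetRecord(ts.to_pydatetime(), *(row[c] for c in MET_COLUMNS))


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def daytime_mask(df: pd.DataFrame) -> pd.Series:
    """True where net radiation is positive (the daytime rule)."""
    return df["Rn"] > 0


def gap_fill_linear(df: pd.DataFrame, fields: str | Sequence[str]) -> pd.DataFrame:
    """Fill missing values by time-linear interpolation.

    Interior gaps are interpolated linearly in time between the nearest
    valid neighbours; leading/trailing gaps are extended from the nearest
    valid value (no extrapolation).
    """
    if isinstance(fields, str):
        fields = [fields]
    out = df.copy()
    out.attrs = dict(df.attrs)
    for f in fields:
        s = out[f]
        if s.isna().all():
            raise ValueError(f"cannot gap-fill {f!r}: all values missing")
        out[f] = s.interpolate(method="time").ffill().bfill()
    return out


def screen_negative_daytime_le(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Replace negative daytime LE by interpolated values.

    Daytime condensation is treated as implausible: negative daytime LE is
    set missing and re-filled with :func:`gap_fill_linear`.  Nighttime
    values are untouched.  Returns the screened frame and the count of
    replaced records.
    """
    day = daytime_mask(df)
    bad = day & (df["LE"] < 0)
    n_bad = int(bad.sum())
    if n_bad == 0:
        return df.copy(), 0
    out = df.copy()
    out.attrs = dict(df.attrs)
    out.loc[bad, "LE"] = np.nan
    out = gap_fill_linear(out, "LE")
    night = ~day
    out.loc[night, "LE"] = df.loc[night, "LE"]
    return out, n_bad


def closure_correct(df: pd.DataFrame) -> pd.Series:
    """Residual energy-balance closure: LE = Rn − G − H.

    Assumes the sensible heat flux is measured correctly and attributes
    the whole closure gap to LE.  Missing inputs propagate to NaN; the
    measured LE column is left untouched for diagnostics.
    """
    return (df["Rn"] - df["G"] - df["H"]).rename("LE_corrected")


def prepare_met(
    df: pd.DataFrame,
    gap_fill_fields: Sequence[str] = ("Ta", "RH", "Rn", "G", "H", "LE"),
) -> tuple[pd.DataFrame, QCReport]:
    """Run the standard QC chain: gap-fill, then screen negative daytime LE."""
    report = QCReport(n_records=len(df))
    for f in gap_fill_fields:
        report.n_gap_filled[f] = int(df[f].isna().sum())
    out = gap_fill_linear(df, gap_fill_fields)
    out, n_neg = screen_negative_daytime_le(out)
    report.n_negative_daytime_le = n_neg
    return out, report


# ---------------------------------------------------------------------------
# Rasters (GeoTIFF via tifffile: ModelPixelScale/ModelTiepoint tags)
# ---------------------------------------------------------------------------

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922


def write_ndvi_stack(stack: NDVIStack, directory: str | Path, prefix: str = "NDVI") -> list[Path]:
    """Write one single-band GeoTIFF per date, dated filenames."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    t = stack.transform
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (t.pixel_size, t.pixel_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.x_origin, t.y_origin, 0.0)),
    ]
    paths = []
    for date, grid in zip(stack.dates, stack.grids):
        p = directory / f"{prefix}_{date.isoformat()}.tif"
        tifffile.imwrite(p, grid.astype(np.float32), extratags=extratags)
        paths.append(p)
    return paths


def _read_geotiff(path: Path) -> tuple[np.ndarray, GeoTransform]:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        grid = page.asarray()
        tags = page.tags
        try:
            scale = tags[_TAG_PIXEL_SCALE].value
            tie = tags[_TAG_TIEPOINT].value
        except KeyError:
            raise AlignmentError(f"{path} lacks georeferencing tags") from None
    transform = GeoTransform(x_origin=tie[3], y_origin=tie[4], pixel_size=scale[0])
    return np.asarray(grid, dtype=np.float32), transform


def read_ndvi_stack(paths: Sequence[str | Path] | str | Path) -> NDVIStack:
    """Read dated single-band GeoTIFFs into a stack.

    ``paths`` may be a directory (all ``*.tif`` inside are taken) or an
    explicit sequence.  Dates are parsed from the trailing ``YYYY-MM-DD``
    of each filename stem; files are returned date-sorted regardless of
    input order.
    """
    if isinstance(paths, (str, Path)) and Path(paths).is_dir():
        paths = sorted(Path(paths).glob("*.tif"))
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no raster files to read")

    dates, grids = [], []
    transform = None
    for p in paths:
        date = dt.date.fromisoformat(p.stem[-10:])
        grid, t = _read_geotiff(p)
        if transform is None:
            transform, shape0 = t, grid.shape
        elif t != transform or grid.shape != shape0:
            raise AlignmentError(
                f"{p} disagrees with the stack (shape {grid.shape} vs {shape0}, "
                f"transform {t} vs {transform})"
            )
        dates.append(date)
        grids.append(grid)
    return NDVIStack(dates=dates, grids=np.stack(grids), transform=transform)


# ---------------------------------------------------------------------------
# Boundaries (GeoJSON)
# ---------------------------------------------------------------------------

def read_boundary(path: str | Path) -> FieldBoundary:
    """Read the first polygon feature of a GeoJSON file."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        features = gj["features"]
        if not features:
            raise ValueError(f"{path}: empty FeatureCollection")
        feature = features[0]
    elif gj.get("type") == "Feature":
        feature = gj
    else:
        feature = {"type": "Feature", "geometry": gj, "properties": {}}
    polygon = shape(feature["geometry"])
    site_id = (feature.get("properties") or {}).get("site_id", "field")
    return FieldBoundary(polygon=polygon, site_id=site_id)


def write_boundary(boundary: FieldBoundary, path: str | Path) -> None:
    gj = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(boundary.polygon),
                "properties": {"site_id": boundary.site_id},
            }
        ],
    }
    with open(path, "w") as fh:
        json.dump(gj, fh, indent=1)


# ---------------------------------------------------------------------------
# Management logs
# ---------------------------------------------------------------------------

def read_management_log(path: str | Path | None = None) -> dict[str, SiteManagement]:
    """Read a management log (sowing/harvest, irrigation events, rainfall).

    With no ``path``, the packaged log for the three Nebraska AmeriFlux
    maize sites (US-Ne1/2/3, 2019 season) is loaded.
    """
    if path is None:
        path = Path(__file__).parent / "data" / "enrec_sites.json"
    with open(path) as fh:
        raw = json.load(fh)
    sites = {}
    for site_id, s in raw["sites"].items():
        sites[site_id] = SiteManagement(
            site_id=site_id,
            latitude=s["latitude"],
            longitude=s["longitude"],
            crop=s.get("crop", ""),
            sowing_date=dt.date.fromisoformat(s["sowing_date"]),
            harvest_date=dt.date.fromisoformat(s["harvest_date"]),
            irrigation_events=[
                (dt.date.fromisoformat(d), float(depth))
                for d, depth in s.get("irrigation_events", [])
            ],
            total_rainfall_mm=s.get("total_rainfall_mm"),
            rainfall_growing_season_mm=s.get("rainfall_growing_season_mm"),
        )
    return sites
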