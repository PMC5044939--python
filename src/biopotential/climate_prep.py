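"""Daily-to-monthly climate aggregation and climate-region assignment.

The crop engine consumes one record per station, year and month: mean air
temperature and monthly precipitation.  Daily station records are aggregated
here; precipitation is carried both as the monthly total (what a water balance
needs) and as the mean daily rate, so either reading of "monthly mean values"
is recoverable downstream.  Long-term monthly normals and relative rainfall
surpluses support anomaly diagnostics, and soil units are attached to discrete
climate regions (explicit id, polygon containment, or nearest station).
"""

from __future__ import annotations

import calendar
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ClimateRegion",
    "aggregate_daily_to_monthly",
    "long_term_monthly_mean",
    "relative_surplus",
    "assign_climate_region",
    "DEFAULT_NORMAL_PERIOD",
    "MISSING_DAY_TOLERANCE",
]

#: Default averaging window for long-term monthly normals.
DEFAULT_NORMAL_PERIOD = (1981, 2010)

#: Months missing more than this many days are flagged (not dropped).
MISSING_DAY_TOLERANCE = 5


@dataclass(frozen=True)
class ClimateRegion:
    """A discrete climate region represented by exactly one station."""

    region_id: str
    station_id: str
    polygon: Optional[object] = None  # shapely geometry
    centroid: Optional[tuple] = None  # (x, y) fallback for nearest-station


def aggregate_daily_to_monthly(daily: pd.DataFrame) -> pd.DataFrame:
    """Aggregate daily station records to per-month values.

    Parameters
    ----------
    daily
        Columns ``station_id, date, t_mean, precip`` (optionally ``t_min``,
        ``t_max``).  ``date`` anything ``pd.to_datetime`` accepts.

    Returns
    -------
    DataFrame with one row per (station_id, year, month): temperature columns
    averaged, ``precip_sum`` (mm/month), ``precip_mean`` (mm/day), ``n_days``,
    and a boolean ``incomplete`` flag for months missing more than
    :data:`MISSING_DAY_TOLERANCE` calendar days.
    """
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"])
    if df.duplicated(subset=["station_id", "date"]).any():
        dups = df[df.duplicated(subset=["station_id", "date"], keep=False)]
        raise ValueError(
            f"duplicate (station, date) records, e.g. {dups.iloc[0].station_id} "
            f"{dups.iloc[0].date.date()}"
        )
    if (df["precip"] < 0).any():
        raise ValueError("negative precipitation in daily records")
    df["year"] = df["date"].dt.year
    df["month"] = df["date"].dt.month
    agg = {"t_mean": "mean", "precip": ["sum", "mean", "size"]}
    for c in ("t_min", "t_max"):
        if c in df.columns:
            agg[c] = "mean"
    g = df.groupby(["station_id", "year", "month"], sort=True).agg(agg)
    out = pd.DataFrame(
        {
            "t_mean": g[("t_mean", "mean")],
            "precip_sum": g[("precip", "sum")],
            "precip_mean": g[("precip", "mean")],
            "n_days": g[("precip", "size")].astype(int),
        }
    )
    for c in ("t_min", "t_max"):
        if (c, "mean") in g.columns:
            out[c] = g[(c, "mean")]
    out = out.reset_index()
    out["incomplete"] = [
        n < calendar.monthrange(y, m)[1] - MISSING_DAY_TOLERANCE
        for y, m, n in zip(out["year"], out["month"], out["n_days"])
    ]
    n_inc = int(out["incomplete"].sum())
    if n_inc:
        logger.warning("%d station-months missing more than %d days", n_inc, MISSING_DAY_TOLERANCE)
    return out


def long_term_monthly_mean(
    monthly: pd.DataFrame,
    month: int,
    period: tuple = DEFAULT_NORMAL_PERIOD,
    column: str = "precip_sum",
) -> float:
    """Arithmetic mean of one month's values over a year range (inclusive)."""
    if not 1 <= int(month) <= 12:
        raise ValueError(f"month {month!r} outside 1..12")
    lo, hi = period
    sel = monthly[(monthly["month"] == int(month)) & monthly["year"].between(lo, hi)]
    if sel.empty:
        raise ValueError(f"no records for month {month} in {lo}-{hi}")
    return float(sel[column].mean())


def relative_surplus(value: float, reference: float) -> float:
    """Percent departure of ``value`` from a long-term ``reference`` (> 0)."""
    if reference <= 0:
        raise ValueError(f"reference must be positive, got {reference!r}")
    return 100.0 * (value - reference) / reference


def assign_climate_region(unit, regions: Sequence[ClimateRegion]) -> str:
    """Attach a soil unit to a climate region.

    Resolution order: an explicit ``climate_region`` on the unit wins; else
    polygon containment of the unit's geometry; else the region of the nearest
    station centroid.
    """
    if not regions:
        raise ValueError("no climate regions supplied")
    region_ids = {r.region_id for r in regions}
    explicit = getattr(unit, "climate_region", None)
    if explicit:
        if explicit not in region_ids:
            raise ValueError(f"unit carries unknown climate region {explicit!r}")
        return explicit
    geom = getattr(unit, "geometry_ref", None)
    if geom is None:
        raise ValueError(f"unit {getattr(unit, 'unit_id', unit)!r} has neither region id nor geometry")
    from shapely.geometry import shape

    if isinstance(geom, dict):  # GeoJSON geometry mapping
        geom = shape(geom)
    for r in regions:
        if r.polygon is not None and r.polygon.contains(geom.representative_point()):
            return r.region_id
    # fall back to nearest station centroid
    p = geom.representative_point()
    best, best_d = None, np.inf
    for r in regions:
        c = r.centroid if r.centroid is not None else (
            (r.polygon.centroid.x, r.polygon.centroid.y) if r.polygon is not None else None
        )
        if c is None:
            continue
        d = float(np.hypot(p.x - c[0], p.y - c[1]))
        if d < best_d:
            best, best_d = r.region_id, d
    if best is None:
        raise ValueError("no region has a polygon or centroid to match against")
    return best


def monthly_series_for_season(
    monthly: pd.DataFrame,
    station_id: str,
    harvest_year: int,
    season_months: Iterable[int],
) -> pd.DataFrame:
    """Rows of ``monthly`` covering one growth season, in season order.

    Season months are calendar months; a month larger than the harvest month
    that precedes January in the sequence belongs to the previous calendar
    year (winter crops sown in autumn of ``harvest_year - 1``).
    """
    months = list(season_months)
    # months listed after a descending step (e.g. 10,11,12,1..7) wrap years
    years = []
    wrapped = False
    for i, m in enumerate(months):
        if i and m < months[i - 1]:
            wrapped = True
        years.append(harvest_year if (wrapped or not _season_wraps(months)) else harvest_year - 1)
    rows = []
    sel = monthly[monthly["station_id"] == station_id]
    for y, m in zip(years, months):
        r = sel[(sel["year"] == y) & (sel["month"] == m)]
        if r.empty:
            raise ValueError(f"missing climate for station {station_id}, {y}-{m:02d}")
        rows.append(r.iloc[0])
    return pd.DataFrame(rows).reset_index(drop=True)


def _season_wraps(months: Sequence[int]) -> bool:
    return any(b < a for a, b in zip(months, months[1:]))
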