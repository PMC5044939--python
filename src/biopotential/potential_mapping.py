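"""From simulated data-unit yields to per-parcel biomass-potential surfaces.

The crop engine produces yields for a few dozen (soil type, nFK class,
climate region) data units; the soil map holds on the order of 10^5 parcels
with arbitrary soil numbers.  The bridge is a set of per-(crop, soil type,
region) polynomial *interpolation curves* fitted to the (nFK class, mean
yield) points of the simulated units, averaged over a climate period.  Each
parcel's continuous nFK estimate is pushed through the matching curve
(clamped to the fitted nFK domain, floored at zero), optionally scaled by the
crop's adjustment factor, and classified into yield bands for mapping.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "YieldCurve",
    "DEFAULT_BAND_EDGES",
    "DEFAULT_PERIOD",
    "average_over_period",
    "fit_yield_curve",
    "fit_curves_by_group",
    "interpolate_yield",
    "classify_band",
    "join_potentials",
    "read_soil_map_geojson",
    "write_soil_map_geojson",
]

#: Yield-band edges (t DM/ha) used for map classification.
DEFAULT_BAND_EDGES = (12.0, 14.0, 16.0, 17.0, 19.0)

#: Default climate period for potential averaging (inclusive).
DEFAULT_PERIOD = (1991, 2007)


@dataclass(frozen=True)
class YieldCurve:
    """Polynomial nFK (mm) -> mean yield (t DM/ha) interpolation curve."""

    crop: str
    soil_type: str
    climate_region: str
    coefficients: tuple  # numpy polyval order
    domain: tuple  # (lo, hi) nFK mm of the fitted points

    def __call__(self, nfk) -> float:
        lo, hi = self.domain
        x = float(np.clip(nfk, lo, hi))
        y = float(np.polyval(self.coefficients, x))
        if y < 0:
            logger.warning(
                "%s/%s/%s: negative interpolated yield %.2f floored to 0",
                self.crop, self.soil_type, self.climate_region, y,
            )
            y = 0.0
        return y


def average_over_period(simulated: pd.DataFrame, period: tuple = DEFAULT_PERIOD) -> pd.DataFrame:
    """Mean dry-matter yield per (soil_type, nfk_class, climate_region, crop).

    Rows outside the (inclusive) year range are ignored; groups with no rows
    in the period are simply absent from the output.
    """
    lo, hi = period
    sel = simulated[simulated["year"].between(lo, hi)]
    if sel.empty:
        raise ValueError(f"no simulated rows in period {lo}-{hi}")
    dropped = (
        simulated.groupby(["soil_type", "nfk_class", "climate_region", "crop"]).size().shape[0]
        - sel.groupby(["soil_type", "nfk_class", "climate_region", "crop"]).size().shape[0]
    )
    if dropped:
        logger.warning("%d data-unit groups have no rows in %d-%d", dropped, lo, hi)
    return (
        sel.groupby(["soil_type", "nfk_class", "climate_region", "crop"], as_index=False)[
            "dm_yield"
        ]
        .mean()
        .rename(columns={"dm_yield": "mean_yield"})
    )


def fit_yield_curve(
    points: Sequence[tuple], crop: str = "", soil_type: str = "", climate_region: str = ""
) -> YieldCurve:
    """Least-squares polynomial of degree min(2, n-1) through (nFK, yield) points."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError(f"need >= 3 points to fit a yield curve, got {len(pts)}")
    x, y = pts[:, 0], pts[:, 1]
    if len(np.unique(x)) != len(x):
        raise ValueError("duplicate nFK values among fit points")
    deg = min(2, len(x) - 1)
    coef = np.polyfit(x, y, deg)
    return YieldCurve(
        crop=crop,
        soil_type=soil_type,
        climate_region=climate_region,
        coefficients=tuple(float(c) for c in coef),
        domain=(float(x.min()), float(x.max())),
    )


def fit_curves_by_group(mean_yields: pd.DataFrame) -> dict:
    """One :class:`YieldCurve` per (crop, soil_type, climate_region)."""
    curves = {}
    for (crop, st, region), grp in mean_yields.groupby(["crop", "soil_type", "climate_region"]):
        pts = list(zip(grp["nfk_class"], grp["mean_yield"]))
        curves[(crop, st, region)] = fit_yield_curve(pts, crop, st, region)
    return curves


def interpolate_yield(curve: YieldCurve, nfk: float) -> float:
    """Evaluate a fitted curve (clamped to its domain, floored at zero)."""
    return curve(nfk)


def classify_band(value: float, edges: Sequence[float] = DEFAULT_BAND_EDGES) -> str:
    """Half-open, lower-inclusive yield band label for one value.

    With the default edges the labels are ``"<12"``, ``"12-14"``, ...,
    ``">=19"`` (t DM/ha).
    """
    edges = list(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("band edges must be strictly increasing")
    fmt = lambda e: f"{e:g}"
    if value < edges[0]:
        return f"<{fmt(edges[0])}"
    for lo, hi in zip(edges, edges[1:]):
        if lo <= value < hi:
            return f"{fmt(lo)}-{fmt(hi)}"
    return f">={fmt(edges[-1])}"


def join_potentials(
    soil_map: pd.DataFrame,
    curves: Mapping[tuple, YieldCurve],
    nfk_estimates: np.ndarray,
    crops: Sequence[str],
    adjustment_factors: Optional[Mapping[str, float]] = None,
    band_edges: Sequence[float] = DEFAULT_BAND_EDGES,
    strict: bool = False,
    max_unresolved_fraction: float = 0.10,
) -> pd.DataFrame:
    """Attach per-crop potentials and band labels to every soil-map record.

    Parameters
    ----------
    soil_map
        One row per parcel with ``unit_id``, ``soil_type``, ``climate_region``.
    nfk_estimates
        Continuous nFK (mm) per row of ``soil_map`` (same order).
    adjustment_factors
        Optional per-crop multiplicative calibration factors applied to the
        interpolated (trial-level) yields.
    strict
        If true, fail when more than ``max_unresolved_fraction`` of records
        cannot be matched to a fitted curve.

    Returns
    -------
    DataFrame with one row per input record (cardinality preserved) carrying
    ``potential_<crop>`` (t DM/ha, NaN if unresolved), ``band_<crop>`` and a
    ``reason`` column for unresolved records.
    """
    adjustment_factors = adjustment_factors or {}
    n = len(soil_map)
    nfk_estimates = np.asarray(nfk_estimates, dtype=float)
    if nfk_estimates.shape[0] != n:
        raise ValueError("nfk_estimates must align with soil_map rows")
    out = soil_map[["unit_id", "soil_type", "climate_region"]].copy()
    out["nfk_est_mm"] = nfk_estimates
    reason = np.array([""] * n, dtype=object)
    for crop in crops:
        fac = float(adjustment_factors.get(crop, 1.0))
        vals = np.full(n, np.nan)
        # group rows by (soil_type, region) so each curve is evaluated once,
        # vectorised over the group's nFK values
        for (st, region), idx in out.groupby(["soil_type", "climate_region"]).groups.items():
            curve = curves.get((crop, st, region))
            pos = out.index.get_indexer(idx)
            if curve is None:
                reason[pos] = f"no curve for ({st}, {region})"
                continue
            lo, hi = curve.domain
            x = np.clip(nfk_estimates[pos], lo, hi)
            y = np.polyval(curve.coefficients, x)
            vals[pos] = np.maximum(y, 0.0) * fac
        out[f"potential_{crop}"] = vals
        out[f"band_{crop}"] = [
            classify_band(v, band_edges) if np.isfinite(v) else "" for v in vals
        ]
    out["reason"] = reason
    unresolved = (reason != "").mean() if n else 0.0
    if strict and unresolved > max_unresolved_fraction:
        raise RuntimeError(
            f"{unresolved:.1%} of soil-map records unresolved "
            f"(limit {max_unresolved_fraction:.0%})"
        )
    return out


# ---------------------------------------------------------------------------
# GeoJSON I/O (attribute-focused; geometries are passed through untouched)

def read_soil_map_geojson(path) -> pd.DataFrame:
    """Read a soil-map FeatureCollection into a DataFrame.

    Feature properties become columns; the raw GeoJSON geometry mapping is
    kept in a ``geometry`` column (``None`` where absent).
    """
    with open(path) as fh:
        fc = json.load(fh)
    if fc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    rows = []
    for feat in fc.get("features", []):
        row = dict(feat.get("properties") or {})
        row["geometry"] = feat.get("geometry")
        rows.append(row)
    return pd.DataFrame(rows)


def write_soil_map_geojson(df: pd.DataFrame, path, geometry_col: str = "geometry") -> None:
    """Write a DataFrame (with a GeoJSON-mapping geometry column) back out."""
    feats = []
    for _, row in df.iterrows():
        props = {
            k: (None if (np.isscalar(v) and pd.isna(v)) else v)
            for k, v in row.items()
            if k != geometry_col
        }
        feats.append(
            {"type": "Feature", "geometry": row.get(geometry_col), "properties": props}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def render_choropleth(joined: pd.DataFrame, crop: str, path, band_edges=DEFAULT_BAND_EDGES):
    """Render a simple banded potential map to PNG (requires point geometry
    columns ``x``/``y``); intended for synthetic regions and quick looks."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    sc = ax.scatter(
        joined["x"], joined["y"], c=joined[f"potential_{crop}"], s=4, cmap="YlGn"
    )
    fig.colorbar(sc, ax=ax, label=f"{crop} potential (t DM/ha)")
    ax.set_xlabel("x (km)")
    ax.set_ylabel("y (km)")
    ax.set_title(f"Biomass potential - {crop}")
    fig.savefig(path, dpi=120)
    plt.close(fig)
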