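"""Pedotransfer from soil-evaluation records to plant-available field capacity.

German soil-evaluation (Bodenschätzung) records describe a site by its dominant
soil texture class and its quality index, the *Bodenzahl* (soil number,
roughly 1-100).  A reference table maps each (texture class, soil-number
interval) to a plant-available field capacity class (nFK, mm of water in the
rooted zone).  This module exposes both views of that mapping:

* :func:`classify_nfk` -- the discrete class lookup, exactly as tabulated;
* :func:`fit_nfk_curve` / :func:`estimate_nfk` -- smooth low-order polynomial
  curves fitted through the class anchors, so that a continuous nFK value can
  be attached to any soil number.

The continuous curves are fitted through one anchor per class interval (the
interval midpoint; the open-ended top interval is anchored half the preceding
interval's width above its lower bound), using the smallest polynomial degree
(capped at 4) that reproduces every anchor within 5 mm.  Because a raw
polynomial can dip outside its anchor range, evaluation goes through an
isotonic (non-decreasing) repair on the integer soil-number grid and is
clamped into the class-value range of the soil type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SoilType",
    "SoilUnit",
    "NfkReferenceTable",
    "NfkCurve",
    "NFK_CLASS_VALUES",
    "load_reference_table",
    "classify_nfk",
    "anchor_points",
    "fit_nfk_curve",
    "fit_all_curves",
    "estimate_nfk",
    "add_nfk_columns",
]

#: All nFK class values (mm) that occur in the reference table.
NFK_CLASS_VALUES = (50, 90, 140, 200, 250, 270, 300)

#: Soil numbers are a quality index on this closed range.
SOIL_NUMBER_RANGE = (1, 100)

#: Max absolute deviation (mm) allowed between a fitted curve and its anchors.
ANCHOR_TOLERANCE_MM = 5.0


class SoilType(str, Enum):
    """The eight soil texture classes of the evaluation scheme."""

    S = "S"  # sand
    Sl = "Sl"  # slightly loamy sand
    lS = "lS"  # loamy sand
    SL = "SL"  # very loamy sand
    sL = "sL"  # sandy loam
    L = "L"  # loam (includes silts in this scheme)
    LC = "LC"  # heavy loam
    C = "C"  # clay

    @property
    def long_name(self) -> str:
        return _LONG_NAMES[self]


_LONG_NAMES = {
    SoilType.S: "sand",
    SoilType.Sl: "slightly loamy sand",
    SoilType.lS: "loamy sand",
    SoilType.SL: "very loamy sand",
    SoilType.sL: "sandy loam",
    SoilType.L: "loam",
    SoilType.LC: "heavy loam",
    SoilType.C: "clay",
}


def _coerce_soil_type(soil_type) -> SoilType:
    try:
        return SoilType(soil_type)
    except ValueError:
        raise ValueError(
            f"unknown soil type {soil_type!r}; expected one of "
            f"{[t.value for t in SoilType]}"
        ) from None


def _coerce_soil_number(soil_number) -> int:
    n = float(soil_number)
    if not np.isfinite(n):
        raise ValueError(f"soil number must be finite, got {soil_number!r}")
    if n != int(n):
        warnings.warn(
            f"soil number {soil_number!r} is not an integer; flooring to {int(n)}",
            stacklevel=3,
        )
    n = int(n)
    lo, hi = SOIL_NUMBER_RANGE
    if not lo <= n <= hi:
        raise ValueError(f"soil number {soil_number!r} outside [{lo}, {hi}]")
    return n


@dataclass(frozen=True)
class SoilUnit:
    """One soil-evaluation record."""

    unit_id: str
    soil_type: SoilType
    soil_number: int
    climate_region: str
    geometry_ref: Optional[object] = None

    def __post_init__(self):
        object.__setattr__(self, "soil_type", _coerce_soil_type(self.soil_type))
        object.__setattr__(self, "soil_number", _coerce_soil_number(self.soil_number))


@dataclass(frozen=True)
class NfkReferenceTable:
    """Ordered (soil-number interval -> nFK class) mapping per soil type.

    ``intervals[t]`` is a list of ``(lo_exclusive, hi_inclusive, nfk_mm)``
    tuples in increasing order; ``hi_inclusive is None`` marks the open-ended
    top interval.
    """

    intervals: Mapping[SoilType, Sequence[tuple]]

    def __post_init__(self):
        for t, ivs in self.intervals.items():
            prev_hi, prev_v = 0, 0
            for i, (lo, hi, v) in enumerate(ivs):
                if lo != prev_hi:
                    raise ValueError(f"{t}: intervals not contiguous at {lo}")
                if hi is None and i != len(ivs) - 1:
                    raise ValueError(f"{t}: open interval before the last position")
                if v <= prev_v:
                    raise ValueError(f"{t}: class values must strictly increase")
                prev_hi, prev_v = hi, v
            if prev_hi is not None:
                raise ValueError(f"{t}: last interval must be open-ended")

    def classes_for(self, soil_type) -> list:
        """nFK class values (mm) available for one soil type, ascending."""
        return [v for (_, _, v) in self.intervals[_coerce_soil_type(soil_type)]]

    @property
    def n_classes(self) -> int:
        return sum(len(v) for v in self.intervals.values())


def load_reference_table() -> NfkReferenceTable:
    """Load the packaged nFK reference table."""
    with resources.files("biopotential.data").joinpath("nfk_reference.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    out: dict = {}
    for t, grp in df.groupby("soil_type", sort=False):
        ivs = []
        for _, row in grp.iterrows():
            hi = None if pd.isna(row.hi_inclusive) else int(row.hi_inclusive)
            ivs.append((int(row.lo_exclusive), hi, int(row.nfk_mm)))
        out[SoilType(t)] = tuple(ivs)
    return NfkReferenceTable(out)


_DEFAULT_TABLE: Optional[NfkReferenceTable] = None


def default_reference_table() -> NfkReferenceTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_reference_table()
    return _DEFAULT_TABLE


def classify_nfk(soil_type, soil_number, table: Optional[NfkReferenceTable] = None) -> int:
    """Discrete nFK class (mm) for a soil type and soil number.

    Interval membership follows the tabulated predicates: a soil number equal
    to an upper bound belongs to that interval (``lo < n <= hi``).
    """
    table = table or default_reference_table()
    t = _coerce_soil_type(soil_type)
    n = _coerce_soil_number(soil_number)
    for lo, hi, v in table.intervals[t]:
        if n > lo and (hi is None or n <= hi):
            return v
    raise AssertionError("reference intervals do not cover the soil-number range")


def anchor_points(soil_type, table: Optional[NfkReferenceTable] = None) -> np.ndarray:
    """(soil number, nFK) anchors used for curve fitting, one per interval.

    Closed intervals are anchored at their midpoint; the open-ended top
    interval at its lower bound plus half the preceding interval's width.
    """
    table = table or default_reference_table()
    ivs = table.intervals[_coerce_soil_type(soil_type)]
    pts = []
    for i, (lo, hi, v) in enumerate(ivs):
        if hi is not None:
            x = (lo + hi) / 2.0
        else:
            plo, phi, _ = ivs[i - 1]
            x = lo + (phi - plo) / 2.0
        pts.append((x, float(v)))
    return np.asarray(pts)


@dataclass(frozen=True)
class NfkCurve:
    """Fitted continuous soil-number -> nFK (mm) curve for one soil type.

    Evaluation is tabulated on the integer soil-number grid, repaired to be
    non-decreasing, and clamped into ``[nfk_min, nfk_max]``.
    """

    soil_type: SoilType
    coefficients: tuple  # numpy polyval order (highest degree first)
    domain: tuple  # (lo, hi) soil numbers
    nfk_min: float
    nfk_max: float
    _grid_values: np.ndarray = field(repr=False, default=None)

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, soil_number) -> float:
        n = _coerce_soil_number(soil_number)
        lo, _ = SOIL_NUMBER_RANGE
        return float(self._grid_values[n - lo])


def fit_nfk_curve(soil_type, table: Optional[NfkReferenceTable] = None) -> NfkCurve:
    """Fit the continuous nFK curve for one soil type.

    The degree is the smallest (<= min(n_anchors - 1, 4)) whose least-squares
    fit reproduces every anchor within :data:`ANCHOR_TOLERANCE_MM`; the raw
    polynomial is then projected onto non-decreasing values over the integer
    grid and clamped into the type's class-value range.
    """
    table = table or default_reference_table()
    t = _coerce_soil_type(soil_type)
    pts = anchor_points(t, table)
    if len(pts) < 2:
        raise ValueError(f"{t}: need at least 2 anchors to fit a curve")
    xs, ys = pts[:, 0], pts[:, 1]
    best = None
    for deg in range(1, min(len(xs) - 1, 4) + 1):
        coef = np.polyfit(xs, ys, deg)
        resid = float(np.abs(np.polyval(coef, xs) - ys).max())
        if best is None or resid < best[1]:
            best = (coef, resid)
        if resid <= ANCHOR_TOLERANCE_MM:
            break
    coef, _ = best
    lo, hi = SOIL_NUMBER_RANGE
    grid = np.polyval(coef, np.arange(lo, hi + 1, dtype=float))
    grid = np.maximum.accumulate(grid)  # isotonic repair of local dips
    nfk_min, nfk_max = float(ys.min()), float(ys.max())
    grid = np.clip(grid, nfk_min, nfk_max)
    return NfkCurve(
        soil_type=t,
        coefficients=tuple(float(c) for c in coef),
        domain=(float(xs.min()), float(xs.max())),
        nfk_min=nfk_min,
        nfk_max=nfk_max,
        _grid_values=grid,
    )


def fit_all_curves(table: Optional[NfkReferenceTable] = None) -> dict:
    """Fitted curves for every soil type, keyed by :class:`SoilType`."""
    table = table or default_reference_table()
    return {t: fit_nfk_curve(t, table) for t in table.intervals}


def estimate_nfk(soil_type, soil_number, curves: Mapping[SoilType, NfkCurve]) -> float:
    """Continuous nFK estimate (mm), clamped into the type's class range."""
    t = _coerce_soil_type(soil_type)
    try:
        curve = curves[t]
    except KeyError:
        raise KeyError(f"no fitted nFK curve for soil type {t.value!r}") from None
    return curve(soil_number)


def add_nfk_columns(
    units: pd.DataFrame,
    table: Optional[NfkReferenceTable] = None,
    curves: Optional[Mapping[SoilType, NfkCurve]] = None,
) -> pd.DataFrame:
    """Vectorised convenience: append nfk_class_mm / nfk_est_mm to a unit table.

    ``units`` needs columns ``soil_type`` and ``soil_number``.
    """
    table = table or default_reference_table()
    if curves is None:
        curves = fit_all_curves(table)
    out = units.copy()
    cls = np.empty(len(out), dtype=int)
    est = np.empty(len(out), dtype=float)
    # per-type lookup tables over the integer grid keep this O(grid) per type
    lo, hi = SOIL_NUMBER_RANGE
    grid = np.arange(lo, hi + 1)
    for t, idx in out.groupby("soil_type").groups.items():
        st = _coerce_soil_type(t)
        cls_lut = np.array([classify_nfk(st, int(n), table) for n in grid])
        est_lut = curves[st]._grid_values
        nums = out.loc[idx, "soil_number"].to_numpy().astype(int)
        if (nums < lo).any() or (nums > hi).any():
            raise ValueError(f"soil numbers outside [{lo}, {hi}] for type {t}")
        cls[out.index.get_indexer(idx)] = cls_lut[nums - lo]
        est[out.index.get_indexer(idx)] = est_lut[nums - lo]
    out["nfk_class_mm"] = cls
    out["nfk_est_mm"] = est
    return out
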