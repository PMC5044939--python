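"""Calibration against regional harvest statistics and validation statistics.

Model predictions calibrated on field trials systematically exceed the yields
of practical agriculture (regional statistics can run up to ~30% lower than
trial results).  The calibration step therefore derives a multiplicative
*adjustment factor* -- mean observed over mean predicted -- and applies it to
the predictions.  Model performance is then summarised per year (percent
errors of the raw and adjusted predictions) and overall (RMSE, the percent
error derived from the RMSE, Pearson correlation, and the Willmott index of
agreement), in the shape of a per-year comparison table with a summary footer.

The Willmott index of agreement is the 1981 form

    d = 1 - sum (P_i - O_i)^2 / sum (|P_i - Obar| + |O_i - Obar|)^2

bounded on [0, 1] with 1 for perfect agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "percent_error",
    "adjustment_factor",
    "apply_adjustment",
    "rmse",
    "overall_percent_error",
    "willmott_index",
    "pearson_r",
    "filter_units_by_nfk",
    "ValidationReport",
    "build_report",
]


def _pair(observed, compared, min_len=1):
    o = np.asarray(observed, dtype=float)
    p = np.asarray(compared, dtype=float)
    if o.shape != p.shape:
        raise ValueError(f"series lengths differ: {o.shape} vs {p.shape}")
    if o.size < min_len:
        raise ValueError(f"need at least {min_len} pairs, got {o.size}")
    return o, p


def percent_error(observed, predicted) -> float:
    """Percent error of a prediction, ``100 (pred - obs) / obs``."""
    if np.any(np.asarray(observed, dtype=float) <= 0):
        raise ValueError("observed yield must be positive")
    out = 100.0 * (np.asarray(predicted, float) - np.asarray(observed, float)) / np.asarray(
        observed, float
    )
    return float(out) if out.ndim == 0 else out


def adjustment_factor(observed, predicted) -> float:
    """Mean observed divided by mean predicted (full precision)."""
    o, p = _pair(observed, predicted, min_len=2)
    mp = p.mean()
    if mp <= 0:
        raise ValueError("mean predicted yield must be positive")
    return float(o.mean() / mp)


def apply_adjustment(predicted, factor: float):
    """Scale predictions by a (positive) adjustment factor."""
    if factor <= 0:
        raise ValueError(f"adjustment factor must be positive, got {factor!r}")
    out = np.asarray(predicted, dtype=float) * factor
    return float(out) if out.ndim == 0 else out


def rmse(observed, compared) -> float:
    """Root-mean-square error between two equal-length series."""
    o, p = _pair(observed, compared, min_len=1)
    return float(np.sqrt(np.mean((p - o) ** 2)))


def overall_percent_error(rmse_value: float, mean_observed: float) -> float:
    """RMSE expressed as a percentage of the observed mean."""
    if mean_observed <= 0:
        raise ValueError("mean observed must be positive")
    return 100.0 * rmse_value / mean_observed


def willmott_index(observed, compared) -> float:
    """Willmott's index of agreement d in [0, 1] (1 = perfect agreement)."""
    o, p = _pair(observed, compared, min_len=2)
    obar = o.mean()
    denom = np.sum((np.abs(p - obar) + np.abs(o - obar)) ** 2)
    if denom == 0:
        return 1.0  # both series constant and equal: perfect, degenerate
    return float(1.0 - np.sum((p - o) ** 2) / denom)


def pearson_r(observed, compared):
    """Product-moment correlation and two-sided p-value."""
    o, p = _pair(observed, compared, min_len=3)
    if o.std() == 0 or p.std() == 0:
        raise ValueError("correlation undefined for a zero-variance series")
    r = stats.pearsonr(o, p)
    return float(r.statistic), float(r.pvalue)


def filter_units_by_nfk(units: pd.DataFrame, min_nfk_exclusive: Optional[float]) -> pd.DataFrame:
    """Drop soil/data units at or below an nFK threshold (mm).

    Regional yield statistics only cover soils a crop is actually grown on:
    winter cereals are compared on units with nFK > 90 mm; for maize only the
    very poorest soils (field capacity < 40 mm) are omitted.  ``units`` must
    carry an ``nfk_class_mm`` (or ``nfk_mm``) column.
    """
    if min_nfk_exclusive is None:
        return units
    col = "nfk_class_mm" if "nfk_class_mm" in units.columns else "nfk_mm"
    return units[units[col] > min_nfk_exclusive]


#: Conventional nFK pre-filters (mm, exclusive lower bound) per crop.
DEFAULT_NFK_FILTERS = {"winter_wheat": 90.0, "triticale": 90.0, "maize": 39.0, "cup_plant": None}


@dataclass
class ValidationReport:
    """Per-year comparison rows plus the summary statistics footer."""

    crop: str
    rows: pd.DataFrame  # year, observed, predicted, e_pct, adjusted, ae_pct
    factor_full: float
    factor: float  # as applied (possibly externally fixed / rounded)
    factor_mode: str
    mean_observed: float
    mean_predicted: float
    mean_adjusted: float
    rmse: float
    overall_error_pct: float
    pearson_r: float
    p_value: float
    willmott_d: float
    basis: str = "adjusted"

    def to_frame(self) -> pd.DataFrame:
        """Rows rounded to the report's print precision (one decimal)."""
        out = self.rows.copy()
        for c in ("observed", "predicted", "adjusted"):
            out[c] = out[c].round(1)
        for c in ("e_pct", "ae_pct"):
            out[c] = out[c].round(1)
        return out

    def footer(self) -> dict:
        return {
            "mean_observed": round(self.mean_observed, 1),
            "mean_predicted": round(self.mean_predicted, 1),
            "mean_adjusted": round(self.mean_adjusted, 1),
            "factor": round(self.factor, 2),
            "rmse": round(self.rmse, 1),
            "overall_error_pct": round(self.overall_error_pct, 1),
            "pearson_r": round(self.pearson_r, 2),
            "p_value": self.p_value,
            "willmott_d": round(self.willmott_d, 2),
        }

    def __str__(self) -> str:
        lines = [f"Yield validation report - {self.crop}", self.to_frame().to_string(index=False)]
        f = self.footer()
        lines.append(
            f"factor={f['factor']} ({self.factor_mode}; full precision {self.factor_full:.4f})  "
            f"RMSE={f['rmse']}  %error={f['overall_error_pct']}  "
            f"r={f['pearson_r']} (p={f['p_value']:.2g})  d={f['willmott_d']}"
        )
        return "\n".join(lines)


def build_report(
    observed: pd.Series,
    predicted: pd.Series,
    crop: str = "crop",
    factor_mode: str = "computed",
    fixed_factor: Optional[float] = None,
    basis: str = "adjusted",
) -> ValidationReport:
    """Assemble the full calibration/validation report.

    Parameters
    ----------
    observed, predicted
        Year-indexed series in statistics units (dt/ha), aligned on years.
    factor_mode
        ``"computed"`` uses the full-precision mean ratio; ``"fixed"`` applies
        ``fixed_factor`` as printed/rounded reports would.
    basis
        Series the RMSE/Willmott/overall-error block compares against the
        observations: ``"adjusted"`` (default) or ``"predicted"``.
    """
    observed = pd.Series(observed).astype(float).sort_index()
    predicted = pd.Series(predicted).astype(float).sort_index()
    if not observed.index.equals(predicted.index):
        raise ValueError("observed and predicted series must share the same years")
    factor_full = adjustment_factor(observed, predicted)
    if factor_mode == "computed":
        factor = factor_full
    elif factor_mode == "fixed":
        if fixed_factor is None:
            raise ValueError("factor_mode='fixed' needs fixed_factor")
        factor = float(fixed_factor)
    else:
        raise ValueError(f"unknown factor_mode {factor_mode!r}")
    adjusted = apply_adjustment(predicted.to_numpy(), factor)
    rows = pd.DataFrame(
        {
            "year": observed.index.to_numpy(),
            "observed": observed.to_numpy(),
            "predicted": predicted.to_numpy(),
            "e_pct": percent_error(observed.to_numpy(), predicted.to_numpy()),
            "adjusted": adjusted,
            "ae_pct": percent_error(observed.to_numpy(), adjusted),
        }
    )
    if basis == "adjusted":
        cmp_series = adjusted
    elif basis == "predicted":
        cmp_series = predicted.to_numpy()
    else:
        raise ValueError(f"unknown basis {basis!r}")
    rm = rmse(observed.to_numpy(), cmp_series)
    try:
        r, p = pearson_r(observed.to_numpy(), predicted.to_numpy())
    except ValueError:  # constant series: correlation undefined
        r, p = float("nan"), float("nan")
    return ValidationReport(
        crop=crop,
        rows=rows,
        factor_full=factor_full,
        factor=factor,
        factor_mode=factor_mode,
        mean_observed=float(observed.mean()),
        mean_predicted=float(predicted.mean()),
        mean_adjusted=float(np.mean(adjusted)),
        rmse=rm,
        overall_error_pct=overall_percent_error(rm, float(observed.mean())),
        pearson_r=r,
        p_value=p,
        willmott_d=willmott_index(observed.to_numpy(), cmp_series),
        basis=basis,
    )
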