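"""Unit conversions between model output and harvest statistics.

Crop-model output is dry matter (t DM/ha).  German harvest statistics report
silage maize as deci-tons fresh mass per hectare and cereals as deci-tons
grain per hectare.  Two conversions bridge the gap:

* fresh mass: ``dt fresh/ha = t DM/ha x 10 / dm_fraction`` with a conventional
  35% dry-matter content for maize harvested as silage;
* grain: an empirical linear regression between whole-plant dry matter and
  grain yield in winter cereals,
  ``grain [dt/ha] = (DM [t/ha] x 10 + 51.377) / 2.5188``.

Additionally, :func:`breeding_trend_deduct` removes the breeding-progress
component from model predictions: a model calibrated on recent cultivars
over-predicts the yields achievable in earlier decades, so predictions before
a pivot year are reduced along the regression line of the observed yields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConversionConfig",
    "dm_to_fresh",
    "dm_to_grain",
    "breeding_trend_deduct",
]

#: Validity window (t DM/ha) for the whole-plant -> grain regression; the
#: positive intercept makes extrapolation to very small biomass meaningless.
GRAIN_DM_WINDOW = (4.0, 30.0)


@dataclass(frozen=True)
class ConversionConfig:
    """Constants of the statistics-unit conversions."""

    maize_dm_fraction: float = 0.35
    grain_intercept: float = 51.377
    grain_slope_divisor: float = 2.5188
    trend_pivot_year: int = 2000

    def __post_init__(self):
        if not 0 < self.maize_dm_fraction < 1:
            raise ValueError("dm_fraction must lie in (0, 1)")
        if self.grain_slope_divisor <= 0:
            raise ValueError("grain_slope_divisor must be positive")


def dm_to_fresh(dm, dm_fraction: float = 0.35):
    """Dry matter (t/ha) to fresh mass (dt/ha) at a given dry-matter fraction."""
    if not 0 < dm_fraction < 1:
        raise ValueError(f"dm_fraction must lie in (0, 1), got {dm_fraction!r}")
    dm = np.asarray(dm, dtype=float)
    if (dm < 0).any():
        raise ValueError("dry matter must be non-negative")
    out = dm * 10.0 / dm_fraction
    return float(out) if out.ndim == 0 else out


def dm_to_grain(dm, config: ConversionConfig = ConversionConfig()):
    """Whole-plant dry matter (t/ha) to cereal grain yield (dt/ha).

    Raises
    ------
    ValueError
        If ``dm`` falls below the regression's validity window
        (:data:`GRAIN_DM_WINDOW`).
    """
    dm = np.asarray(dm, dtype=float)
    lo, hi = GRAIN_DM_WINDOW
    if (dm < lo).any():
        raise ValueError(
            f"dry matter below {lo} t/ha is outside the grain regression's validity window"
        )
    out = (dm * 10.0 + config.grain_intercept) / config.grain_slope_divisor
    return float(out) if out.ndim == 0 else out


def breeding_trend_deduct(
    predicted: pd.Series,
    observed: pd.Series,
    pivot: int = 2000,
    fit_window: str = "pre_pivot",
):
    """Remove the breeding trend from a year-indexed prediction series.

    An OLS regression of the observed yields on year estimates the annual
    breeding gain; predictions for years before ``pivot`` are reduced by
    ``slope x (pivot - year)``, later years are left unchanged.  The slope is
    fitted on the pre-pivot observed years by default (``fit_window =
    "pre_pivot"``), where breeding progress is assumed to act; ``"all"`` fits
    on the full series.

    Returns
    -------
    (adjusted, fit)
        The adjusted prediction series and the scipy ``LinregressResult``.
    """
    predicted = pd.Series(predicted).astype(float)
    observed = pd.Series(observed).astype(float)
    years = observed.index.to_numpy(dtype=float)
    py = predicted.index.to_numpy(dtype=float)
    if not (py < pivot).any():
        # pivot precedes (or equals) every year: nothing to deduct
        return predicted.copy(), None
    if fit_window == "pre_pivot":
        mask = years < pivot
    elif fit_window == "all":
        mask = np.ones_like(years, dtype=bool)
    else:
        raise ValueError(f"unknown fit_window {fit_window!r}")
    if mask.sum() < 2 or len(np.unique(years[mask])) < 2:
        raise ValueError("breeding-trend regression needs >= 2 distinct years")
    if len(observed) < 5 or not (years < pivot).any():
        raise ValueError("observed series must span >= 5 years including pre-pivot years")
    fit = stats.linregress(years[mask], observed.to_numpy()[mask])
    deduction = np.where(py < pivot, fit.slope * (pivot - py), 0.0)
    return predicted - deduction, fit
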