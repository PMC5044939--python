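"""Data-unit aggregation and a transparent surrogate crop-growth engine.

Rather than simulating every soil polygon of a region, the pipeline collapses
the soil map into *data units* -- unique (soil type, nFK class, climate
region) combinations -- and runs the crop engine once per data unit and year.
With the default class selection (35 soil-type x nFK-class combinations) and
five climate regions this yields 175 data units.

The engine itself is a deliberately simple, fully documented water- and
temperature-limited monthly model; it is a stand-in with a stable interface,
not a reimplementation of any particular process model.  Per season month:

* the soil water bucket (capacity = nFK, full at season start) is topped up
  by the month's precipitation and capped at capacity;
* atmospheric demand is ``crop_coefficient x EVAP_COEFF_MM_PER_DEGC x
  max(t_mean, 0)`` mm/month, supply is what the bucket can deliver;
* the growth increment is ``max_monthly_growth`` scaled by a piecewise-linear
  temperature response (0 at/below ``temp_base``, 1 at/above ``temp_optimum``)
  and by the water-stress ratio ``min(1, supply/demand)``.

Season totals times the harvest index give yield in t DM/ha.  The model is
deterministic, monotone in available soil water, and saturates once the
bucket never limits supply.  Crop parameter files were calibrated once so
that adjusted regional mean yields fall in realistic bands for the region
(maize 12-19, triticale 14-17, cup plant 12-19 t DM/ha).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .soil_capacity import NfkReferenceTable, SoilType, default_reference_table

__all__ = [
    "CropParameters",
    "DataUnit",
    "load_crop_parameters",
    "default_class_selection",
    "build_data_units",
    "simulate_yield",
    "run_units",
    "EVAP_COEFF_MM_PER_DEGC",
    "YIELD_CEILING_T_HA",
]

#: Evaporative-demand proxy: mm of water demanded per month and degree C of
#: monthly mean temperature (above 0 degrees C), before the crop coefficient.
EVAP_COEFF_MM_PER_DEGC = 5.0

#: Hard cap on simulated dry-matter yield (t DM/ha).
YIELD_CEILING_T_HA = 30.0


@dataclass(frozen=True)
class CropParameters:
    """Parameters of the surrogate engine for one crop."""

    name: str
    pathway: str  # "C3" | "C4"
    season: tuple  # calendar months of active growth, in season order
    max_monthly_growth: float  # t DM/ha per month at optimum
    temp_optimum: float  # degrees C
    temp_base: float  # degrees C
    crop_coefficient: float  # demand multiplier, dimensionless
    harvest_index: float = 1.0  # fraction of biomass harvested

    def __post_init__(self):
        if self.pathway not in ("C3", "C4"):
            raise ValueError(f"pathway must be C3 or C4, got {self.pathway!r}")
        if not 0 < self.harvest_index <= 1:
            raise ValueError("harvest_index must lie in (0, 1]")
        if self.temp_base >= self.temp_optimum:
            raise ValueError("temp_base must be below temp_optimum")
        if not self.season:
            raise ValueError("season must be non-empty")
        months = list(self.season)
        if any(m < 1 or m > 12 for m in months):
            raise ValueError("season months must lie in 1..12")
        if any((b - a) % 12 != 1 for a, b in zip(months, months[1:])):
            raise ValueError("season months must be contiguous calendar months")

    @property
    def is_winter_crop(self) -> bool:
        months = list(self.season)
        return any(b < a for a, b in zip(months, months[1:]))


def load_crop_parameters(name_or_path) -> CropParameters:
    """Load crop parameters from a packaged crop name or a YAML path."""
    text = None
    p = str(name_or_path)
    if p.endswith((".yaml", ".yml")):
        with open(p) as fh:
            text = fh.read()
    else:
        res = resources.files("biopotential.data.crops").joinpath(f"{p}.yaml")
        try:
            text = res.read_text()
        except FileNotFoundError:
            raise KeyError(f"no packaged crop parameter file {p!r}") from None
    d = yaml.safe_load(text)
    d["season"] = tuple(int(m) for m in d["season"])
    return CropParameters(**d)


DEFAULT_CROPS = ("maize", "winter_wheat", "triticale", "cup_plant")


@dataclass(frozen=True)
class DataUnit:
    """One (soil type, nFK class, climate region) simulation cell."""

    soil_type: SoilType
    nfk_class: int  # mm
    climate_region: str

    def __post_init__(self):
        object.__setattr__(self, "soil_type", SoilType(self.soil_type))


def default_class_selection(table: Optional[NfkReferenceTable] = None) -> dict:
    """Default 35-combination selection of nFK classes per soil type.

    Broad-span types would contribute up to seven classes each; to keep three
    to five classes per type the lowest classes of the broad types are
    dropped (the poorest soils are excluded from regional yield comparisons
    anyway): SL, sL and LC drop the 50 mm class, L drops 50 and 90 mm.
    """
    table = table or default_reference_table()
    drop = {
        SoilType.SL: {50},
        SoilType.sL: {50},
        SoilType.L: {50, 90},
        SoilType.LC: {50},
    }
    return {
        t: [c for c in table.classes_for(t) if c not in drop.get(t, ())]
        for t in table.intervals
    }


def build_data_units(
    class_selection: Mapping, regions: Sequence[str], table: Optional[NfkReferenceTable] = None
) -> list:
    """Cross the per-type class selection with the climate regions."""
    table = table or default_reference_table()
    units = []
    for t, classes in class_selection.items():
        st = SoilType(t)
        if not 3 <= len(classes) <= 5:
            raise ValueError(f"{st.value}: expected 3-5 selected classes, got {len(classes)}")
        available = set(table.classes_for(st))
        for c in classes:
            if c not in available:
                raise ValueError(f"{st.value}: nFK class {c} mm not in the reference table")
        units.extend(DataUnit(st, int(c), str(r)) for c in classes for r in regions)
    return units


def _temperature_response(t_mean, base: float, optimum: float):
    return np.clip((np.asarray(t_mean, float) - base) / (optimum - base), 0.0, 1.0)


def simulate_yield(crop: CropParameters, climate: pd.DataFrame, nfk: float) -> float:
    """Yield (t DM/ha) for one season of monthly climate and one nFK value.

    ``climate`` must hold one row per season month, in season order, with
    columns ``month``, ``t_mean`` and ``precip_sum``.
    """
    if nfk <= 0:
        raise ValueError(f"nfk must be positive, got {nfk!r}")
    months = list(climate["month"].astype(int))
    if months != list(crop.season):
        raise ValueError(
            f"climate months {months} do not match the {crop.name} season {list(crop.season)}"
        )
    water = float(nfk)  # bucket full at season start (winter refill)
    biomass = 0.0
    for t, rain in zip(climate["t_mean"].to_numpy(float), climate["precip_sum"].to_numpy(float)):
        water = min(nfk, water + rain)
        demand = crop.crop_coefficient * EVAP_COEFF_MM_PER_DEGC * max(t, 0.0)
        supply = min(water, demand)
        stress = supply / demand if demand > 0 else 1.0
        water -= supply
        biomass += crop.max_monthly_growth * float(
            _temperature_response(t, crop.temp_base, crop.temp_optimum)
        ) * stress
    return min(crop.harvest_index * biomass, YIELD_CEILING_T_HA)


def run_units(
    units: Sequence[DataUnit],
    monthly_climate: pd.DataFrame,
    crops: Iterable[CropParameters],
    years: Sequence[int],
    region_stations: Mapping[str, str],
    strict: bool = True,
) -> pd.DataFrame:
    """Simulate every data unit x crop x year.

    ``monthly_climate`` is the station-level table from
    :func:`biopotential.climate_prep.aggregate_daily_to_monthly`;
    ``region_stations`` maps region ids to their representative station.
    Returns one row per (unit, crop, year) with the dry-matter yield.

    The inner loop is vectorised over data units: all units sharing a region
    see the same monthly weather, so the bucket update runs once per crop,
    year and season month on an array of units.
    """
    units = list(units)
    years = list(years)
    idx = monthly_climate.set_index(["station_id", "year", "month"])
    t_mean = idx["t_mean"]
    precip = idx["precip_sum"]

    regions = sorted({u.climate_region for u in units})
    missing = [r for r in regions if r not in region_stations]
    if missing:
        raise ValueError(f"no station for region(s) {missing}")
    region_of = np.array([regions.index(u.climate_region) for u in units])
    nfk = np.array([float(u.nfk_class) for u in units])

    frames = []
    skipped = []
    for crop in crops:
        season = list(crop.season)
        wraps = crop.is_winter_crop
        for year in years:
            try:
                tm = np.empty((len(season), len(regions)))
                pr = np.empty_like(tm)
                for j, r in enumerate(regions):
                    st = region_stations[r]
                    wrapped = False
                    for i, m in enumerate(season):
                        if i and m < season[i - 1]:
                            wrapped = True
                        y = year if (wrapped or not wraps) else year - 1
                        tm[i, j] = t_mean.loc[(st, y, m)]
                        pr[i, j] = precip.loc[(st, y, m)]
            except KeyError as err:
                skipped.append((crop.name, year, str(err)))
                continue
            water = nfk.copy()
            biomass = np.zeros(len(units))
            for i in range(len(season)):
                t = tm[i, region_of]
                rain = pr[i, region_of]
                water = np.minimum(nfk, water + rain)
                demand = crop.crop_coefficient * EVAP_COEFF_MM_PER_DEGC * np.maximum(t, 0.0)
                supply = np.minimum(water, demand)
                stress = np.where(demand > 0, supply / np.where(demand > 0, demand, 1.0), 1.0)
                water = water - supply
                biomass += crop.max_monthly_growth * _temperature_response(
                    t, crop.temp_base, crop.temp_optimum
                ) * stress
            dm = np.minimum(crop.harvest_index * biomass, YIELD_CEILING_T_HA)
            frames.append(
                pd.DataFrame(
                    {
                        "soil_type": [u.soil_type.value for u in units],
                        "nfk_class": [u.nfk_class for u in units],
                        "climate_region": [u.climate_region for u in units],
                        "crop": crop.name,
                        "year": year,
                        "dm_yield": dm,
                    }
                )
            )
    if skipped:
        msg = f"missing climate for {len(skipped)} crop-years, e.g. {skipped[0]}"
        if strict:
            raise ValueError(msg)
        import logging

        logging.getLogger(__name__).warning(msg)
    if not frames:
        return pd.DataFrame(
            columns=["soil_type", "nfk_class", "climate_region", "crop", "year", "dm_yield"]
        )
    return pd.concat(frames, ignore_index=True)
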