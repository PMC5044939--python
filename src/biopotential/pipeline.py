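"""End-to-end orchestration: soil map -> data units -> engine -> calibration
-> validation -> potential surfaces.

The stages mirror how a regional biomass-potential study is actually run:

1. attach discrete nFK classes and continuous nFK estimates to the soil map;
2. collapse the map into (soil type, nFK class, climate region) data units
   and simulate each unit for every year with the crop engine;
3. aggregate the simulated yields to regional statistics units (weighting
   data units by the number of parcels they represent), calibrate against
   observed harvest statistics (adjustment factor, breeding-trend deduction
   for winter cereals) and emit validation reports;
4. average over the mapping climate period, fit per-(crop, soil type,
   region) interpolation curves and join adjusted potentials back onto every
   parcel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import climate_prep, crop_engine, potential_mapping, soil_capacity, validation
from .synthetic_data import SyntheticConfig, gen_daily_climate, gen_observed_yields, gen_soil_map, region_stations
from .validation import DEFAULT_NFK_FILTERS
from .yield_units import ConversionConfig, breeding_trend_deduct, dm_to_fresh, dm_to_grain

__all__ = [
    "PipelineResult",
    "attach_nfk",
    "assign_data_unit_classes",
    "regional_statistics_series",
    "run_synthetic_pipeline",
]

#: Crops mapped onto potential surfaces, and the calibration factor each uses
#: (winter-cereal factor reused for the crops without their own statistics).
MAPPED_CROPS = ("maize", "triticale", "cup_plant")


def attach_nfk(soil_map: pd.DataFrame) -> pd.DataFrame:
    """Add nfk_class_mm and nfk_est_mm columns to a parcel table."""
    return soil_capacity.add_nfk_columns(soil_map)


def assign_data_unit_classes(
    soil_map: pd.DataFrame, class_selection: Mapping
) -> pd.DataFrame:
    """Snap each parcel's nFK class to the nearest simulated class of its type.

    Parcels whose tabulated class is not in the simulated selection (the
    dropped poorest classes of broad-span types) are represented by the
    nearest selected class.
    """
    out = soil_map.copy()
    snapped = np.empty(len(out), dtype=int)
    for t, idx in out.groupby("soil_type").groups.items():
        classes = np.asarray(sorted(class_selection[soil_capacity.SoilType(t)]))
        vals = out.loc[idx, "nfk_class_mm"].to_numpy()
        pos = out.index.get_indexer(idx)
        snapped[pos] = classes[np.abs(classes[None, :] - vals[:, None]).argmin(axis=1)]
    out["du_nfk_class"] = snapped
    return out


def regional_statistics_series(
    simulated: pd.DataFrame,
    soil_map: pd.DataFrame,
    crop: str,
    conversion: ConversionConfig = ConversionConfig(),
    nfk_filter: Optional[float] = None,
) -> pd.Series:
    """Per-year regional prediction in statistics units for one crop.

    Data-unit yields are weighted by the number of parcels each unit
    represents (after the crop's nFK pre-filter) and converted: maize dry
    matter to dt fresh mass/ha, winter cereals to dt grain/ha; other crops
    stay in t DM/ha.
    """
    if nfk_filter is None:
        nfk_filter = DEFAULT_NFK_FILTERS.get(crop)
    parcels = validation.filter_units_by_nfk(soil_map, nfk_filter)
    weights = (
        parcels.groupby(["soil_type", "du_nfk_class", "climate_region"])
        .size()
        .rename("weight")
        .reset_index()
    )
    sim = simulated[simulated["crop"] == crop].merge(
        weights,
        left_on=["soil_type", "nfk_class", "climate_region"],
        right_on=["soil_type", "du_nfk_class", "climate_region"],
    )
    if sim.empty:
        raise ValueError(f"no simulated units left for {crop} after the nFK filter")
    by_year = sim.groupby("year").apply(
        lambda g: np.average(g["dm_yield"], weights=g["weight"]), include_groups=False
    )
    if crop == "maize":
        series = pd.Series(dm_to_fresh(by_year.to_numpy(), conversion.maize_dm_fraction), index=by_year.index)
    elif crop in ("winter_wheat", "triticale"):
        series = pd.Series(dm_to_grain(by_year.to_numpy(), conversion), index=by_year.index)
    else:
        series = by_year
    series.index.name = "year"
    return series.rename(crop)


@dataclass
class PipelineResult:
    """Everything the synthetic end-to-end run produces."""

    config: SyntheticConfig
    soil_map: pd.DataFrame
    monthly_climate: pd.DataFrame
    simulated: pd.DataFrame
    predicted_statistics: pd.DataFrame
    observed: pd.DataFrame
    reports: dict = field(default_factory=dict)
    factors: dict = field(default_factory=dict)
    trend_fit: Optional[object] = None
    potentials: Optional[pd.DataFrame] = None
    curves: dict = field(default_factory=dict)


def run_synthetic_pipeline(
    config: SyntheticConfig,
    crops: Sequence[str] = ("maize", "winter_wheat", "triticale", "cup_plant"),
    mapping_period: tuple = potential_mapping.DEFAULT_PERIOD,
    observed: Optional[pd.DataFrame] = None,
) -> PipelineResult:
    """Generate a synthetic region and push it through every stage.

    If ``observed`` is None, observed statistics are generated from the
    engine's own regional predictions (known gap factor and breeding trend),
    which makes the calibration a parameter-recovery exercise.
    """
    y0, y1 = config.years
    years = list(range(y0, y1 + 1))
    soil_map = attach_nfk(gen_soil_map(config))
    selection = crop_engine.default_class_selection()
    soil_map = assign_data_unit_classes(soil_map, selection)
    # one lead year so winter crops harvested in the first year have their
    # autumn sowing months
    daily = gen_daily_climate(config, lead_years=1)
    monthly = climate_prep.aggregate_daily_to_monthly(daily)
    units = crop_engine.build_data_units(selection, list(region_stations()))
    crop_params = [crop_engine.load_crop_parameters(c) for c in crops]
    simulated = crop_engine.run_units(
        units, monthly, crop_params, years, region_stations()
    )
    conversion = ConversionConfig(trend_pivot_year=config.trend_pivot)
    pred_rows = []
    for crop in crops:
        if crop not in ("maize", "winter_wheat"):
            continue
        series = regional_statistics_series(simulated, soil_map, crop, conversion)
        pred_rows.append(
            pd.DataFrame({"crop": crop, "year": series.index, "value": series.to_numpy()})
        )
    predicted_statistics = pd.concat(pred_rows, ignore_index=True)
    if observed is None:
        observed = gen_observed_yields(config, predicted_statistics)

    reports, factors = {}, {}
    trend_fit = None
    for crop in predicted_statistics["crop"].unique():
        pred = predicted_statistics[predicted_statistics["crop"] == crop].set_index("year")["value"]
        obs = observed[observed["crop"] == crop].set_index("year")["value"]
        common = pred.index.intersection(obs.index)
        pred, obs = pred.loc[common], obs.loc[common]
        if crop == "winter_wheat":
            pred, trend_fit = breeding_trend_deduct(pred, obs, pivot=config.trend_pivot)
        reports[crop] = validation.build_report(obs, pred, crop=crop)
        factors[crop] = reports[crop].factor_full

    means = potential_mapping.average_over_period(simulated, mapping_period)
    curves = potential_mapping.fit_curves_by_group(means)
    adj = {
        "maize": factors.get("maize", 1.0),
        "triticale": factors.get("winter_wheat", 1.0),
        "cup_plant": factors.get("winter_wheat", 1.0),
    }
    mapped = [c for c in MAPPED_CROPS if c in set(crops)]
    potentials = potential_mapping.join_potentials(
        soil_map,
        curves,
        soil_map["nfk_est_mm"].to_numpy(),
        mapped,
        adjustment_factors={c: adj[c] for c in mapped},
    )
    potentials = potentials.join(soil_map[["x", "y"]])
    return PipelineResult(
        config=config,
        soil_map=soil_map,
        monthly_climate=monthly,
        simulated=simulated,
        predicted_statistics=predicted_statistics,
        observed=observed,
        reports=reports,
        factors=factors,
        trend_fit=trend_fit,
        potentials=potentials,
        curves=curves,
    )
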