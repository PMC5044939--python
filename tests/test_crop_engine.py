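"""Data-unit construction and the surrogate growth engine's contract."""

import pandas as pd
import pytest

from biopotential.crop_engine import (
    EVAP_COEFF_MM_PER_DEGC,
    CropParameters,
    DataUnit,
    build_data_units,
    default_class_selection,
    load_crop_parameters,
    run_units,
    simulate_yield,
)
from conftest import season_climate

REGIONS5 = ["R1", "R2", "R3", "R4", "R5"]


def summer_crop(**kw):
    d = dict(
        name="test",
        pathway="C4",
        season=(5, 6, 7, 8, 9),
        max_monthly_growth=2.0,
        temp_optimum=18.0,
        temp_base=8.0,
        crop_coefficient=1.0,
        harvest_index=1.0,
    )
    d.update(kw)
    return CropParameters(**d)


def climate_frame(season, t_mean, precip):
    return pd.DataFrame({"month": list(season), "t_mean": t_mean, "precip_sum": precip})


class TestDataUnits:
    def test_default_selection_yields_175_units(self):
        sel = default_class_selection()
        assert sum(len(v) for v in sel.values()) == 35
        assert all(3 <= len(v) <= 5 for v in sel.values())
        assert len(build_data_units(sel, REGIONS5)) == 175

    def test_small_cross_products(self):
        sel = {"S": [50, 90, 140]}
        assert len(build_data_units(sel, ["R1"])) == 3
        sel2 = {"S": [50, 90, 140], "Sl": [50, 90, 140, 200]}
        assert len(build_data_units(sel2, ["R1", "R2"])) == 14

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="not in the reference table"):
            build_data_units({"S": [50, 90, 250]}, ["R1"])


class TestSimulateYield:
    def test_zero_yield_below_base_temperature(self):
        crop = summer_crop()
        clim = climate_frame(crop.season, [5.0] * 5, [100.0] * 5)
        assert simulate_yield(crop, clim, nfk=200) == 0.0

    def test_closed_form_in_unlimited_water_optimum_temperature(self):
        crop = summer_crop(max_monthly_growth=2.0, harvest_index=0.9)
        clim = climate_frame(crop.season, [18.0] * 5, [1000.0] * 5)
        assert simulate_yield(crop, clim, nfk=300) == pytest.approx(0.9 * 2.0 * 5)

    def test_season_mismatch_rejected(self):
        crop = summer_crop()
        clim = climate_frame([5, 6, 7], [15] * 3, [50] * 3)
        with pytest.raises(ValueError, match="season"):
            simulate_yield(crop, clim, nfk=200)

    def test_monotone_and_saturating_in_nfk(self, monthly_climate):
        crop = load_crop_parameters("maize")
        clim = season_climate(monthly_climate, "ST1", 1991, crop.season)
        ys = [simulate_yield(crop, clim, nfk) for nfk in range(50, 301, 10)]
        assert all(b >= a - 1e-12 for a, b in zip(ys, ys[1:]))
        assert ys[-1] == pytest.approx(ys[-2])  # saturated at high nFK

    def test_oracle_equivalence_against_straight_line_reimplementation(
        self, monthly_climate
    ):
        """The vectorised engine equals a plain-Python bucket model."""
        crop = load_crop_parameters("maize")
        clim = season_climate(monthly_climate, "ST1", 1991, crop.season)
        for nfk in (50, 140, 200, 300):
            water, biomass = float(nfk), 0.0
            for _, row in clim.iterrows():
                water = min(nfk, water + row.precip_sum)
                demand = crop.crop_coefficient * EVAP_COEFF_MM_PER_DEGC * max(row.t_mean, 0.0)
                supply = min(water, demand)
                water -= supply
                f_t = min(max((row.t_mean - crop.temp_base) / (crop.temp_optimum - crop.temp_base), 0.0), 1.0)
                biomass += crop.max_monthly_growth * f_t * (supply / demand if demand > 0 else 1.0)
            expected = crop.harvest_index * biomass
            assert simulate_yield(crop, clim, nfk) == pytest.approx(expected, abs=1e-12)

    def test_determinism(self, monthly_climate):
        crop = load_crop_parameters("triticale")
        clim = season_climate(monthly_climate, "ST1", 1991, crop.season)
        assert simulate_yield(crop, clim, 140) == simulate_yield(crop, clim, 140)


class TestQualitativeOrdering:
    def test_maize_outyields_c3_crops_when_warm_and_watered(self):
        crops = {c: load_crop_parameters(c) for c in ("maize", "triticale", "cup_plant")}
        normals_t = (0.9, 1.4, 4.5, 8.4, 13.0, 15.9, 17.5, 17.2, 13.8, 9.6, 4.9, 2.1)
        yields = {}
        for name, crop in crops.items():
            t = [normals_t[m - 1] + 1.5 for m in crop.season]  # warm year
            clim = climate_frame(crop.season, t, [150.0] * len(crop.season))
            yields[name] = simulate_yield(crop, clim, nfk=300)
        assert yields["maize"] > yields["triticale"]
        assert yields["maize"] > yields["cup_plant"]

    def test_triticale_nfk_spread_smaller_than_maize_on_sand(self, pipeline_result):
        sim = pipeline_result.simulated
        sandy = sim[sim.soil_type == "S"]
        spreads = {}
        for crop in ("maize", "triticale"):
            m = sandy[sandy.crop == crop].groupby("nfk_class").dm_yield.mean()
            spreads[crop] = m.max() - m.min()
        assert spreads["triticale"] < spreads["maize"]


class TestRunUnits:
    def test_cardinality_175_units_27_years(self, pipeline_result):
        sim = pipeline_result.simulated
        maize = sim[sim.crop == "maize"]
        assert len(maize) == 175 * 27

    def test_small_cardinalities(self, monthly_climate):
        units = [DataUnit("S", 90, "R1")]
        crops = [summer_crop(), summer_crop(name="test2")]
        out = run_units(units, monthly_climate, crops, [1991, 1992], {"R1": "ST1"})
        assert len(out) == 4
        empty = run_units(units, monthly_climate, crops, [], {"R1": "ST1"})
        assert len(empty) == 0

    def test_missing_climate_strict_raises(self, monthly_climate):
        units = [DataUnit("S", 90, "R1")]
        with pytest.raises(ValueError, match="missing climate"):
            run_units(units, monthly_climate, [summer_crop()], [2050], {"R1": "ST1"})
        out = run_units(
            units, monthly_climate, [summer_crop()], [1991, 2050], {"R1": "ST1"}, strict=False
        )
        assert set(out.year) == {1991}

    def test_run_units_matches_scalar_engine(self, monthly_climate):
        crop = load_crop_parameters("winter_wheat")
        units = [DataUnit("L", 200, "R1")]
        out = run_units(units, monthly_climate, [crop], [1991], {"R1": "ST1"})
        clim = season_climate(monthly_climate, "ST1", 1991, crop.season)
        assert out.dm_yield.iloc[0] == pytest.approx(simulate_yield(crop, clim, 200), abs=1e-10)


def test_crop_parameter_validation():
    with pytest.raises(ValueError, match="pathway"):
        summer_crop(pathway="CAM")
    with pytest.raises(ValueError, match="harvest_index"):
        summer_crop(harvest_index=1.2)
    with pytest.raises(ValueError, match="temp_base"):
        summer_crop(temp_base=20.0)
    with pytest.raises(ValueError, match="contiguous"):
        summer_crop(season=(10, 1, 12))
    assert load_crop_parameters("winter_wheat").is_winter_crop
    assert not load_crop_parameters("maize").is_winter_crop
    with pytest.raises(KeyError):
        load_crop_parameters("rye")
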