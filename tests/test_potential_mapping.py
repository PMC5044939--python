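"""Period averaging, yield interpolation curves, map join and banding."""

import json

import numpy as np
import pandas as pd
import pytest

from biopotential.potential_mapping import (
    YieldCurve,
    average_over_period,
    classify_band,
    fit_yield_curve,
    interpolate_yield,
    join_potentials,
    read_soil_map_geojson,
    write_soil_map_geojson,
)


def sim_frame(rows):
    return pd.DataFrame(
        rows, columns=["soil_type", "nfk_class", "climate_region", "crop", "year", "dm_yield"]
    )


class TestAverageOverPeriod:
    def test_trivial_means(self):
        sim = sim_frame(
            [("S", 90, "R1", "maize", y, v) for y, v in [(1991, 12.0), (1992, 18.0)]]
        )
        out = average_over_period(sim, (1991, 2007))
        assert out.mean_yield.iloc[0] == pytest.approx(15.0)

    def test_period_filter_and_golden_groupby(self, pipeline_result):
        sim = pipeline_result.simulated
        out = average_over_period(sim, (1991, 2007))
        # independent re-mean for one group
        g = sim[
            (sim.soil_type == "L")
            & (sim.nfk_class == 200)
            & (sim.climate_region == "R1")
            & (sim.crop == "maize")
            & sim.year.between(1991, 2007)
        ]
        got = out[
            (out.soil_type == "L")
            & (out.nfk_class == 200)
            & (out.climate_region == "R1")
            & (out.crop == "maize")
        ].mean_yield.iloc[0]
        assert got == pytest.approx(g.dm_yield.mean())

    def test_empty_period_rejected(self):
        sim = sim_frame([("S", 90, "R1", "maize", 1985, 10.0)])
        with pytest.raises(ValueError, match="no simulated rows"):
            average_over_period(sim, (1991, 2007))


class TestFitYieldCurve:
    def test_collinear_points_fit_exact_line(self):
        pts = [(50, 10.0), (100, 15.0), (150, 20.0)]
        c = fit_yield_curve(pts)
        assert c.coefficients[0] == pytest.approx(0.0, abs=1e-9)  # quadratic term
        for x, y in pts:
            assert interpolate_yield(c, x) == pytest.approx(y)

    def test_quadratic_recovered_exactly_through_three_points(self):
        f = lambda x: -0.0004 * x**2 + 0.2 * x - 2
        pts = [(x, f(x)) for x in (60, 120, 220)]
        c = fit_yield_curve(pts)
        assert np.allclose(c.coefficients, [-0.0004, 0.2, -2], atol=1e-9)

    def test_loam_like_fixture_is_concave(self):
        # strong gains 100 -> 150 mm, then gains decline
        pts = [(100, 12.0), (150, 16.5), (200, 18.5), (250, 19.0)]
        c = fit_yield_curve(pts)
        assert c.coefficients[0] < 0  # negative curvature on the domain

    def test_input_validation(self):
        with pytest.raises(ValueError, match=">= 3 points"):
            fit_yield_curve([(50, 1.0), (90, 2.0)])
        with pytest.raises(ValueError, match="duplicate"):
            fit_yield_curve([(50, 1.0), (50, 2.0), (90, 3.0)])


class TestInterpolation:
    def curve(self):
        return fit_yield_curve([(100, 12.0), (150, 16.5), (200, 18.5)])

    def test_clamped_outside_domain(self):
        c = self.curve()
        assert interpolate_yield(c, 50) == pytest.approx(interpolate_yield(c, 100))
        assert interpolate_yield(c, 300) == pytest.approx(interpolate_yield(c, 200))

    def test_continuous_at_domain_edges(self):
        c = self.curve()
        assert interpolate_yield(c, 99.999) == pytest.approx(interpolate_yield(c, 100.001), abs=1e-3)

    def test_mid_domain_golden_value(self):
        c = self.curve()
        assert interpolate_yield(c, 150) == pytest.approx(16.5, abs=1e-9)
        # direct polynomial arithmetic at 125 mm
        a, b, d = c.coefficients
        assert interpolate_yield(c, 125) == pytest.approx(a * 125**2 + b * 125 + d)

    def test_negative_interpolation_floored(self):
        c = YieldCurve("x", "S", "R1", coefficients=(0.0, 0.1, -50.0), domain=(50, 300))
        assert interpolate_yield(c, 60) == 0.0


class TestClassifyBand:
    @pytest.mark.parametrize(
        "value,expected",
        [(11.9, "<12"), (16.5, "16-17"), (12.0, "12-14"), (19.0, ">=19"), (14.0, "14-16")],
    )
    def test_band_labels(self, value, expected):
        assert classify_band(value) == expected

    def test_edges_must_increase(self):
        with pytest.raises(ValueError):
            classify_band(10.0, edges=[12, 12, 16])


class TestJoin:
    def test_cardinality_conserved_and_reasons(self, pipeline_result):
        res = pipeline_result
        assert len(res.potentials) == len(res.soil_map)
        assert (res.potentials.reason == "").all()

    def test_unknown_soil_type_gets_reason_code(self, pipeline_result):
        res = pipeline_result
        soil = res.soil_map.head(4).copy()
        soil.loc[soil.index[0], "soil_type"] = "Sx"
        out = join_potentials(
            soil, res.curves, soil.nfk_est_mm.to_numpy(), ["maize"]
        )
        assert len(out) == 4
        assert out.reason.iloc[0].startswith("no curve")
        assert np.isnan(out.potential_maize.iloc[0])
        with pytest.raises(RuntimeError, match="unresolved"):
            join_potentials(
                soil, res.curves, soil.nfk_est_mm.to_numpy(), ["maize"], strict=True,
                max_unresolved_fraction=0.1,
            )

    def test_empty_map(self, pipeline_result):
        soil = pipeline_result.soil_map.iloc[:0]
        out = join_potentials(soil, pipeline_result.curves, np.array([]), ["maize"])
        assert len(out) == 0


def test_north_south_potential_ordering_for_all_crops(pipeline_result):
    pot = pipeline_result.potentials
    north = pot[pot.y > 50]
    south = pot[pot.y <= 50]
    for crop in ("maize", "triticale", "cup_plant"):
        assert south[f"potential_{crop}"].mean() >= north[f"potential_{crop}"].mean(), crop


def test_geojson_roundtrip(tmp_path):
    df = pd.DataFrame(
        {
            "unit_id": ["a", "b"],
            "soil_type": ["S", "L"],
            "geometry": [
                {"type": "Point", "coordinates": [1.0, 2.0]},
                None,
            ],
        }
    )
    path = tmp_path / "map.geojson"
    write_soil_map_geojson(df, path)
    back = read_soil_map_geojson(path)
    assert list(back.unit_id) == ["a", "b"]
    assert back.geometry.iloc[0]["coordinates"] == [1.0, 2.0]
    with pytest.raises(ValueError, match="FeatureCollection"):
        (tmp_path / "bad.json").write_text(json.dumps({"type": "Feature"}))
        read_soil_map_geojson(tmp_path / "bad.json")
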