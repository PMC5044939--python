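"""Seeded synthetic inputs with the structure the pipeline assumes.

Three generators emulate a temperate lowland region with a pronounced
soil-quality gradient (sandy soils dominating the north, loams and silts the
south), so that every pipeline stage can be exercised end to end without any
external data:

* :func:`gen_soil_map` -- parcel records (soil type, soil number, climate
  region, point/rectangle geometry) on a 100 x 100 km region;
* :func:`gen_daily_climate` -- daily temperature (seasonal sine + AR(1)
  anomalies) and precipitation (per-month wet-day occurrence with gamma
  amounts whose monthly normals follow the regional climatology, e.g. May
  ~56 mm, June ~65 mm, July ~67 mm) for five stations over 1981-2007;
* :func:`gen_observed_yields` -- regional harvest statistics derived from
  the engine's own regional means, embedding a known multiplicative
  field-vs-trial gap, a pre-pivot linear breeding trend for the winter-cereal
  analogue, and multiplicative lognormal noise.

Everything is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
import numpy as np
import pandas as pd

from .soil_capacity import SoilType

__all__ = [
    "SyntheticConfig",
    "REGION_IDS",
    "gen_soil_map",
    "gen_daily_climate",
    "gen_observed_yields",
]

#: Climate regions (west-east bands) and their representative stations.
REGION_IDS = ("R1", "R2", "R3", "R4", "R5")
STATION_IDS = ("ST1", "ST2", "ST3", "ST4", "ST5")

#: Monthly temperature normals (degrees C) of the emulated region.
MONTHLY_T_NORMALS = (0.9, 1.4, 4.5, 8.4, 13.0, 15.9, 17.5, 17.2, 13.8, 9.6, 4.9, 2.1)

#: Monthly precipitation normals (mm).
MONTHLY_P_NORMALS = (49.0, 37.0, 45.0, 42.0, 56.0, 65.0, 67.0, 62.0, 49.0, 43.0, 46.0, 52.0)

#: North/south soil-type mixtures (order follows SoilType declaration).
_TYPES = tuple(SoilType)
_P_NORTH = np.array([0.35, 0.25, 0.20, 0.08, 0.05, 0.03, 0.02, 0.02])
_P_SOUTH = np.array([0.04, 0.06, 0.10, 0.15, 0.25, 0.25, 0.10, 0.05])

#: Plausible soil-number spans per type (Bodenzahl increases with quality).
_NUMBER_SPAN = {
    SoilType.S: (7, 45),
    SoilType.Sl: (10, 55),
    SoilType.lS: (12, 70),
    SoilType.SL: (18, 85),
    SoilType.sL: (20, 95),
    SoilType.L: (25, 100),
    SoilType.LC: (20, 90),
    SoilType.C: (15, 80),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic region; defaults are the study conditions."""

    seed: int = 0
    n_units: int = 5_000  # soil-map parcels (full-scale preset: 114_357)
    n_stations: int = 5
    years: tuple = (1981, 2007)  # inclusive
    gap_factor: float = 0.75  # field yields as a fraction of trial yields
    trend_slope: float = 0.9  # dt/ha/yr breeding gain, winter-cereal analogue
    trend_pivot: int = 2000
    noise_cv: float = 0.07  # lognormal CV of the observed statistics

    def __post_init__(self):
        if not 0 < self.gap_factor <= 1:
            raise ValueError("gap_factor must lie in (0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


FULL_SCALE_N_UNITS = 114_357


def _rng(config: SyntheticConfig, stream: str) -> np.random.Generator:
    # str.hash is salted per process; crc32 keeps the substreams reproducible
    tag = zlib.crc32(stream.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) % (2**31), tag]))


def gen_soil_map(config: SyntheticConfig, with_geometry: bool = False) -> pd.DataFrame:
    """Parcel table with a sandy-north / loamy-south gradient.

    Coordinates live on a 100 x 100 km square, y increasing northward.  The
    soil-type mixture blends from the southern (loam-rich) to the northern
    (sand-rich) composition with a logistic ramp in y; soil numbers are drawn
    uniformly within each type's plausible span.  Climate regions are five
    west-east bands in x.
    """
    rng = _rng(config, "soil_map")
    n = config.n_units
    x = rng.uniform(0, 100, n)
    y = rng.uniform(0, 100, n)
    w_north = 1.0 / (1.0 + np.exp(-(y - 50.0) / 10.0))
    probs = w_north[:, None] * _P_NORTH[None, :] + (1 - w_north)[:, None] * _P_SOUTH[None, :]
    u = rng.random(n)
    type_idx = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    types = [_TYPES[i] for i in type_idx]
    numbers = np.empty(n, dtype=int)
    for i, t in enumerate(types):
        lo, hi = _NUMBER_SPAN[t]
        numbers[i] = rng.integers(lo, hi + 1)
    region = np.clip((x / 100.0 * len(REGION_IDS)).astype(int), 0, len(REGION_IDS) - 1)
    df = pd.DataFrame(
        {
            "unit_id": [f"U{i:06d}" for i in range(n)],
            "soil_type": [t.value for t in types],
            "soil_number": numbers,
            "climate_region": [REGION_IDS[r] for r in region],
            "x": x,
            "y": y,
        }
    )
    if with_geometry:
        # small square parcels around each point, as GeoJSON mappings
        h = 0.2
        df["geometry"] = [
            {
                "type": "Polygon",
                "coordinates": [
                    [
                        [xi - h, yi - h],
                        [xi + h, yi - h],
                        [xi + h, yi + h],
                        [xi - h, yi + h],
                        [xi - h, yi - h],
                    ]
                ],
            }
            for xi, yi in zip(x, y)
        ]
    return df


def region_stations() -> dict:
    """Region id -> representative station id."""
    return dict(zip(REGION_IDS, STATION_IDS))


def gen_daily_climate(config: SyntheticConfig, lead_years: int = 0) -> pd.DataFrame:
    """Daily weather for every station and day of the configured years.

    Temperature is a seasonal sine through the monthly normals plus a small
    west-east station gradient and AR(1) daily anomalies; precipitation is a
    per-month Bernoulli wet-day process with gamma-distributed wet-day
    amounts whose expectation reproduces the monthly normals.  ``lead_years``
    prepends extra years so winter crops harvested in the first configured
    year have their autumn sowing months available.
    """
    y0, y1 = config.years
    y0 -= int(lead_years)
    dates = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy()
    month = dates.month.to_numpy()
    t_seasonal = 9.2 - 8.6 * np.cos(2 * np.pi * (doy - 15) / 365.25)
    p_normal = np.asarray(MONTHLY_P_NORMALS)[month - 1]
    days_in_month = dates.days_in_month.to_numpy()
    frames = []
    wet_prob = 0.5
    for s_i in range(config.n_stations):
        rng = _rng(config, f"climate/{s_i}")
        station_offset = (s_i - (config.n_stations - 1) / 2) * 0.3  # degrees C
        eps = rng.normal(0, 1.6, len(dates))
        anom = np.empty(len(dates))
        a = 0.0
        for i in range(len(dates)):  # AR(1), phi = 0.8
            a = 0.8 * a + eps[i]
            anom[i] = a
        t_mean = t_seasonal + station_offset + anom
        wet = rng.random(len(dates)) < wet_prob
        mean_wet_amount = p_normal / (days_in_month * wet_prob)
        shape = 0.8
        amounts = rng.gamma(shape, mean_wet_amount / shape)
        precip = np.where(wet, amounts, 0.0)
        diurnal = 4.0 + 2.0 * np.sin(2 * np.pi * (doy - 105) / 365.25)
        frames.append(
            pd.DataFrame(
                {
                    "station_id": STATION_IDS[s_i],
                    "date": dates,
                    "t_mean": t_mean,
                    "t_min": t_mean - diurnal,
                    "t_max": t_mean + diurnal,
                    "precip": precip,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def gen_observed_yields(
    config: SyntheticConfig,
    predicted_statistics: pd.DataFrame,
) -> pd.DataFrame:
    """Observed regional yield statistics derived from model predictions.

    ``predicted_statistics`` holds per-crop, per-year regional predictions in
    statistics units (columns ``crop, year, value``).  The observed analogue
    is ``gap_factor x prediction``, minus a pre-pivot breeding-trend deficit
    ``trend_slope x (pivot - year)`` for winter cereals (older cultivars
    yielded less), times multiplicative lognormal noise with CV ``noise_cv``.
    """
    rng = _rng(config, "observed")
    out = predicted_statistics.copy().sort_values(["crop", "year"], ignore_index=True)
    sigma = float(np.sqrt(np.log(1.0 + config.noise_cv**2)))
    values = []
    for _, row in out.iterrows():
        v = config.gap_factor * float(row.value)
        if row.crop in ("winter_wheat", "triticale") and row.year < config.trend_pivot:
            v -= config.trend_slope * (config.trend_pivot - row.year)
        if sigma > 0:
            v *= float(rng.lognormal(-(sigma**2) / 2.0, sigma))
        values.append(v)
    out["value"] = values
    out["unit"] = np.where(out["crop"] == "maize", "dt_fresh/ha", "dt_grain/ha")
    return out
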