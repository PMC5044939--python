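import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")

from biopotential.pipeline import run_synthetic_pipeline
from biopotential.synthetic_data import SyntheticConfig, gen_daily_climate
from biopotential import aggregate_daily_to_monthly


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(seed=7, n_units=2000)


@pytest.fixture(scope="session")
def pipeline_result(small_config):
    """One full synthetic end-to-end run shared across tests."""
    return run_synthetic_pipeline(small_config)


@pytest.fixture(scope="session")
def monthly_climate():
    """Monthly climate for a 3-year single-region synthetic fixture."""
    cfg = SyntheticConfig(seed=3, years=(1990, 1992), n_stations=1)
    return aggregate_daily_to_monthly(gen_daily_climate(cfg, lead_years=1))


def season_climate(monthly, station, harvest_year, season):
    """Season-ordered monthly rows for one station/harvest year."""
    rows = []
    wrapped, prev = False, None
    for m in season:
        if prev is not None and m < prev:
            wrapped = True
        wraps = any(b < a for a, b in zip(season, season[1:]))
        y = harvest_year if (wrapped or not wraps) else harvest_year - 1
        sel = monthly[
            (monthly.station_id == station) & (monthly.year == y) & (monthly.month == m)
        ]
        rows.append(sel.iloc[0])
        prev = m
    return pd.DataFrame(rows).reset_index(drop=True)
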