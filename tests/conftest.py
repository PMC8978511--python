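import datetime as dt

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mobiflux as mf

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


D0 = dt.date(2020, 3, 5)


@pytest.fixture(scope="session")
def tiny_locations() -> mf.LocationTable:
    """Hub plus three counterparts with easy geometry."""
    return mf.LocationTable(
        [
            mf.Location("UK", "United Kingdom", 51.5, -0.1, 67_000_000),
            mf.Location("FR", "France", 48.9, 2.3, 67_500_000),
            mf.Location("IT", "Italy", 41.9, 12.5, 59_000_000),
            mf.Location("DE", "Germany", 52.5, 13.4, 83_000_000),
        ],
        hub_id="UK",
    )


@pytest.fixture(scope="session")
def tiny_flows(tiny_locations) -> mf.FlowPanel:
    rows = []
    for k, date in enumerate([D0, D0 + dt.timedelta(days=1)]):
        for i, c in enumerate(["FR", "IT", "DE"]):
            rows.append({"date": date, "origin": c, "destination": "UK", "flow": 100 * (i + 1) + k})
            rows.append({"date": date, "origin": "UK", "destination": c, "flow": 90 * (i + 1) + k})
    return mf.FlowPanel(pd.DataFrame(rows), star_hub="UK")


@pytest.fixture(scope="session")
def tiny_stringency(tiny_locations, tiny_flows) -> mf.StringencyPanel:
    rows = [
        {"date": d, "location": loc, "si": 10.0 * i + 5.0 * (d - D0).days}
        for d in tiny_flows.dates
        for i, loc in enumerate(tiny_locations.ids)
    ]
    return mf.StringencyPanel(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_world() -> mf.World:
    """A 12-country, 20-day world reused by slower integration tests."""
    cfg = mf.SynthConfig(n_countries=12, n_days=20, seed=42)
    return mf.generate_world(cfg, seed=42)
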