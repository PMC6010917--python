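import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from grazetrack.ingest import Pasture
from grazetrack.synthetic_herd import HerdSimConfig, simulate_herd
from grazetrack.workflows import scheme_daily_table, simulate_deployment


@pytest.fixture(scope="session")
def default_config() -> HerdSimConfig:
    """The default study deployment: 3 animals, 7 days, 20-s cadence."""
    return HerdSimConfig(seed=1)


@pytest.fixture(scope="session")
def default_sim(default_config):
    """Daytime-filtered analysis fixes per animal for the default
    deployment (shared across the heavier tests)."""
    return simulate_deployment(default_config, daytime=True)


@pytest.fixture(scope="session")
def default_daily(default_sim):
    """Per-day distance table for every scheme, per animal."""
    frames = [scheme_daily_table(fixes, animal_id=aid)
              for aid, fixes in default_sim.items()]
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def square_pastures(default_config):
    """Two adjacent 800 x 800 m pastures sharing a fence (UTM metres)."""
    e0, n0 = default_config.origin_utm()
    side = default_config.pasture_side_m
    return {
        "P1": Pasture("P1", "sheep", box(e0, n0, e0 + side, n0 + side)),
        "P2": Pasture("P2", "cattle",
                      box(e0 + side, n0, e0 + 2 * side, n0 + side)),
    }


def constant_cadence_fixes(start="2017-07-07 08:00:00", n=180, step_s=20,
                           easting0=0.0, northing0=0.0, deast=0.0,
                           dnorth=0.0):
    """Deterministic fix frame at a constant cadence walking a straight
    line in UTM metres (lat/lon columns left as placeholders)."""
    t = pd.date_range(start, periods=n, freq=f"{step_s}s")
    return pd.DataFrame({
        "time_utc": t + pd.Timedelta(hours=6),
        "time_local": t,
        "lat_dd": 46.0,
        "lon_dd": -102.65,
        "easting_m": easting0 + deast * np.arange(n),
        "northing_m": northing0 + dnorth * np.arange(n),
        "fix_quality": 1,
        "satellites": 8,
    })
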