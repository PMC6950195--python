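import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from stwreg import PanelDataset, Location, SimConfig, simulate

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def tiny_panel() -> PanelDataset:
    """Hand-built 2-location × 5-week panel with exact decimal values."""
    locations = [Location(0, "alpha", 0.25, 0.75), Location(1, "beta", 0.5, 0.125)]
    rows = []
    for lid in (0, 1):
        for t in (1, 2, 3, 4, 5):
            rows.append(
                {
                    "location_id": lid,
                    "t": t,
                    "SO2": 10.0 + lid + 0.5 * t,
                    "NO2": 20.0 + 2 * lid + t,
                    "PM10": 50.0 + 5 * lid + 2 * t,
                    "CO": 0.5 + 0.1 * lid + 0.05 * t,
                    "O3": 70.0 - 3 * lid - t,
                    "PM25": 30.0 + 4 * lid + 1.5 * t,
                }
            )
    return PanelDataset(locations=locations, records=pd.DataFrame(rows))


@pytest.fixture(scope="session")
def default_panel():
    """One default-configuration draw (13 × 210, mixed mode)."""
    return simulate(SimConfig(seed=7))


@pytest.fixture(scope="session")
def small_varying_panel():
    """Varying-coefficient draw at a desk scale usable by local models."""
    return simulate(SimConfig(n_locations=5, n_times=30, seed=11, mode="varying"))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
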