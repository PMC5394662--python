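import numpy as np
import pandas as pd
import pytest

from psforage.simulate import SimConfig, simulate_population


def make_records(rows):
    """Build a sorted single-device visit table from (bird, arrive, depart,
    opened) tuples."""
    df = pd.DataFrame(rows, columns=["bird_id", "arrive_s", "depart_s", "opened"])
    df["device_id"] = "PB0"
    df["device_type"] = "puzzlebox"
    df["subpop"] = "S0"
    df["replicate"] = "S0_Y1"
    return df.sort_values("arrive_s", kind="stable").reset_index(drop=True)


@pytest.fixture(scope="session")
def small_sim():
    """One 70-bird subpopulation at full daily visit rate, 20 puzzle days,
    a reduced feeder schedule. Shared read-only across tests."""
    cfg = SimConfig(
        n_subpops=1,
        subpop_sizes=(70,),
        n_days_puzzle=20,
        n_days_feeder=2,
        n_feeders_per_subpop=2,
        visit_rate=170,
        seed=3,
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def small_events(small_sim):
    from psforage.events import classify_all

    events, chains = classify_all(small_sim.visits)
    return events, chains


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
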