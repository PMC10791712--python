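import datetime as dt

import pandas as pd
import pytest

import emwater as ew


@pytest.fixture(scope="session")
def sim_config():
    return ew.default_config()


@pytest.fixture(scope="session")
def sim_dataset(sim_config):
    """One study-design synthetic dataset, shared across tests."""
    return ew.generate(sim_config, seed=11)


@pytest.fixture
def tiny_frame():
    """A small, valid long-format frame (one date, one site)."""
    rows = []
    for rep in (1, 2, 3):
        rows.append(("2019-07-02", 1, 30, rep, "PH", 7.0 + 0.1 * rep))
        rows.append(("2019-07-02", 1, 30, rep, "TP", 0.10 * rep))
    return pd.DataFrame(
        rows,
        columns=["date", "site", "depth_cm", "replicate", "parameter",
                 "value"],
    )


def make_dataset(records, application_date=dt.date(2021, 8, 9),
                 schedule=None):
    """Build a MonitoringDataset from (date, site, depth, rep, param, value)
    tuples."""
    frame = pd.DataFrame(
        records,
        columns=["date", "site", "depth_cm", "replicate", "parameter",
                 "value"],
    )
    if schedule is None:
        schedule = sorted({dt.date.fromisoformat(str(r[0])) for r in records})
    return ew.MonitoringDataset(
        frame, application_date=application_date, schedule=tuple(schedule)
    )
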