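import datetime as dt

import pandas as pd
import pytest

from kitepeck import build_dataset, make_scenario, generate_dataset
from kitepeck.simulate import default_weight_table


def _t(s: str) -> dt.time:
    return dt.time.fromisoformat(s)


@pytest.fixture
def tiny_tables():
    """One brood of three, ten pecks, a few bouts and deliveries."""
    broods = pd.DataFrame(
        {
            "brood_id": ["B1"] * 3,
            "nestling_id": ["B1_S", "B1_M", "B1_J"],
            "hatch_date": ["2020-05-01", "2020-05-02", "2020-05-05"],
            "hatch_rank": ["S", "M", "J"],
        }
    )
    peck_rows = [
        ("B1", "2020-05-08", "09:00:00", "B1_S", "B1_M"),
        ("B1", "2020-05-08", "09:00:05", "B1_S", "B1_M"),
        ("B1", "2020-05-08", "09:10:00", "B1_S", "B1_J"),
        ("B1", "2020-05-08", "10:00:00", "B1_M", "B1_J"),
        ("B1", "2020-05-09", "08:30:00", "B1_S", "B1_M"),
        ("B1", "2020-05-09", "08:31:00", "B1_M", "B1_S"),
        ("B1", "2020-05-09", "11:00:00", "B1_S", "B1_J"),
        ("B1", "2020-05-09", "11:30:00", "B1_J", "B1_S"),
        ("B1", "2020-05-10", "12:00:00", "B1_S", "B1_M"),
        ("B1", "2020-05-10", "13:59:59", "B1_M", "B1_J"),
    ]
    pecks = pd.DataFrame(
        peck_rows,
        columns=["brood_id", "date", "time", "attacker_id", "recipient_id"],
    )
    bouts = pd.DataFrame(
        {
            "brood_id": ["B1"] * 4,
            "date": ["2020-05-08", "2020-05-08", "2020-05-09", "2020-05-10"],
            "time": ["09:30:00", "09:31:00", "10:00:00", "09:00:00"],
            "recipient_id": ["B1_S", "B1_M", "B1_J", "B1_S"],
        }
    )
    deliveries = pd.DataFrame(
        {
            "brood_id": ["B1"] * 3,
            "date": ["2020-05-08", "2020-05-09", "2020-05-10"],
            "category": ["mammal", "bird", "invertebrate"],
            "fraction": ["1", "0.5", "1"],
            "observer_mass_g": ["", "55", ""],
        }
    )
    return {"pecks": pecks, "bouts": bouts, "deliveries": deliveries,
            "broods": broods}


@pytest.fixture
def tiny_csv_dir(tmp_path, tiny_tables):
    for name, df in tiny_tables.items():
        df.to_csv(tmp_path / f"{name}.csv", index=False)
    return tmp_path


@pytest.fixture
def tiny_dataset(tiny_tables):
    return build_dataset(**tiny_tables)


@pytest.fixture(scope="session")
def weights():
    return default_weight_table()


@pytest.fixture(scope="session")
def small_sim_dataset():
    """Six simulated broods under the baseline scenario (seeded)."""
    return generate_dataset(make_scenario("baseline", n_broods=6), seed=42)
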