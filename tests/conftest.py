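import numpy as np
import pandas as pd
import pytest

from beepartite import SimConfig, make_visit_log, plant_modular_log, simulate_colony

FLOWERS = [f"F{i}" for i in range(1, 11)]


@pytest.fixture
def tiny_log_df():
    """Three valid visits by two bees on one day."""
    return pd.DataFrame(
        {
            "day": [1, 1, 1],
            "bee_id": ["b1", "b1", "b2"],
            "flower_id": ["F1", "F2", "F1"],
            "t_arrival_s": [10.0, 40.0, 25.0],
            "t_departure_s": [15.0, 48.0, 30.0],
        }
    )


@pytest.fixture
def tiny_log_csv(tmp_path, tiny_log_df):
    path = tmp_path / "visits.csv"
    tiny_log_df.to_csv(path, index=False)
    return path


@pytest.fixture(scope="session")
def planted():
    """A planted-module visit log with its ground truth (two modules,
    fidelity 0.95)."""
    return plant_modular_log(fidelity=0.95, seed=101)


@pytest.fixture(scope="session")
def sim():
    """One-day flight-cage simulation output (log, events, truth)."""
    return simulate_colony(SimConfig(seed=42, n_days=1))


def bout_df(bee, day, start, n_visits, spacing=20.0, flower="F1"):
    """A compact bout: n visits by one bee starting at `start`."""
    rows = []
    t = start
    for _ in range(n_visits):
        rows.append(
            {
                "day": day,
                "bee_id": bee,
                "flower_id": flower,
                "t_arrival_s": t,
                "t_departure_s": t + 5.0,
            }
        )
        t += spacing
    return pd.DataFrame(rows)


@pytest.fixture
def make_log():
    def _make(df, flowers=None):
        return make_visit_log(df, flowers)

    return _make
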