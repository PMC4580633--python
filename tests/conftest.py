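import numpy as np
import pandas as pd
import pytest

from killcluster import SimConfig, simulate_dataset
from killcluster.schedule import FixSchedule


@pytest.fixture
def schedule() -> FixSchedule:
    return FixSchedule()


@pytest.fixture
def make_fixes():
    """Factory building a fixes frame from (time, x, y) triples."""

    def _make(rows, animal_id="A01", downloaded=None, schedule=FixSchedule()):
        times = pd.to_datetime([r[0] for r in rows])
        df = pd.DataFrame(
            {
                "animal_id": animal_id,
                "time": times,
                "x": [float(r[1]) for r in rows],
                "y": [float(r[2]) for r in rows],
                "downloaded": downloaded if downloaded is not None else True,
            }
        )
        slots, slot_dt, night = [], [], []
        for ts in df["time"]:
            hit = schedule.assign_slot(ts.to_pydatetime())
            if hit is None:
                slots.append("")
                slot_dt.append(pd.NaT)
                night.append(False)
            else:
                st, sd = hit
                slots.append(FixSchedule.label(st))
                slot_dt.append(pd.Timestamp.combine(pd.Timestamp(sd), st))
                night.append(schedule.is_night(st))
        df["slot"] = slots
        df["slot_dt"] = pd.to_datetime(slot_dt)
        df["night"] = night
        return df.sort_values(["animal_id", "time"]).reset_index(drop=True)

    return _make


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated dataset shared across tests (12 animals, 90 d)."""
    cfg = SimConfig(n_animals=12, duration_days=90.0, seed=42)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_sim_covariates(small_sim):
    from killcluster import build_covariate_table

    cfg = small_sim.truth.config
    return build_covariate_table(
        small_sim.clusters, small_sim.fixes, small_sim.activity,
        small_sim.visits, cfg.schedule,
    )
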