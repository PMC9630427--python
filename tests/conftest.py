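import datetime as dt

import numpy as np
import pandas as pd
import pytest

from pasight.io import SightingTable

START = dt.date(2010, 1, 1)


def make_table(rows, study_days=6 * 365, study_start=START):
    """Build a SightingTable from compact tuples.

    Each row is (day_offset, individual_id, sex, age_class, state[, group_id]);
    group_id defaults to one group per (day, tuple index) so individuals sighted
    with an explicit shared group_id co-occur.
    """
    recs = []
    for k, row in enumerate(rows):
        day, ind, sex, age, state = row[:5]
        gid = row[5] if len(row) > 5 else f"auto{k}"
        stage = "peak" if state == "musth" else "none"
        if len(row) > 6:
            stage = row[6]
        recs.append(
            {
                "date": pd.Timestamp(study_start) + pd.Timedelta(days=int(day)),
                "x": float(k),
                "y": float(k) * 2,
                "group_id": gid,
                "individual_id": ind,
                "sex": sex,
                "age_class": age,
                "state": state,
                "musth_stage": stage,
            }
        )
    from pasight.io import COLUMNS

    df = pd.DataFrame(recs, columns=COLUMNS if not recs else None)
    end = study_start + dt.timedelta(days=study_days - 1)
    return SightingTable(df, study_start, end)


@pytest.fixture
def tiny_table():
    """Three females in two group sightings plus a male seen foraging and in musth."""
    return make_table(
        [
            (0, "A", "F", "21-30", "foraging", "g1"),
            (0, "B", "F", "21-30", "foraging", "g1"),
            (5, "A", "F", "21-30", "foraging", "g2"),
            (3, "M1", "M", "31-40", "foraging", "g3"),
            (400, "M1", "M", "31-40", "musth", "g4"),
        ]
    )


@pytest.fixture(scope="session")
def small_sim():
    """One small deterministic simulation shared across tests."""
    from pasight.simulate import SimConfig, simulate

    cfg = SimConfig(
        study_days=3 * 365,
        n_communities=3,
        community_sizes=[8, 6, 5],
        n_males=20,
        detection_prob=0.5,
        residency_mixing_rho=0.9,
        seed=11,
    )
    roster, truth, table = simulate(cfg)
    return cfg, roster, truth, table
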