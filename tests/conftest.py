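import numpy as np
import pandas as pd
import pytest

from cesdr_mobile import CohortConfig
from cesdr_mobile.simulate import simulate_cohort


def diary_frame(rows, pid="P0001"):
    """Build a session-record frame from (day, item, response, rt_ms) tuples."""
    if not rows:
        return pd.DataFrame(
            {
                "participant_id": pd.Series([], dtype=str),
                "day_index": pd.Series([], dtype=int),
                "timestamp": pd.Series([], dtype=float),
                "item_id": pd.Series([], dtype=int),
                "response": pd.Series([], dtype=int),
                "rt_ms": pd.Series([], dtype=float),
            }
        )
    days, items, resp, rts = zip(*rows)
    return pd.DataFrame(
        {
            "participant_id": pid,
            "day_index": list(days),
            "timestamp": [d * 86_400.0 for d in days],
            "item_id": list(items),
            "response": list(resp),
            "rt_ms": list(rts),
        }
    )


def full_diary(n_items, n_days, yes_counts, pid="P0001", rt=1000.0):
    """Complete diary where item i is answered Yes on its first yes_counts[i] days."""
    rows = []
    for day in range(1, n_days + 1):
        for item in range(1, n_items + 1):
            rows.append((day, item, int(day <= yes_counts[item - 1]), rt))
    return diary_frame(rows, pid=pid)


def fit_cohort(records, alpha=0.05):
    """Score -> latency-profile -> schema-model fit for an in-memory cohort."""
    from cesdr_mobile import LatencySchemaModel
    from cesdr_mobile.rt import rt_profiles
    from cesdr_mobile.scoring import score_cohort

    cohort = score_cohort(records)
    elig = cohort.summary.loc[cohort.summary["eligible"], ["participant_id", "total"]]
    profiles = rt_profiles(records[records["participant_id"].isin(elig["participant_id"])])
    merged = profiles.merge(elig, on="participant_id")
    model = LatencySchemaModel(merged["total"].astype(int), merged["mean_centered_rt"])
    return model.fit(alpha=alpha)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared by read-only tests."""
    config = CohortConfig(seed=20_240_101)
    records, truth = simulate_cohort(config)
    return config, records, truth
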