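"""Item-mean-centered response latencies: the implicit self-schema measure.

Only the item effect (item length, vocabulary level) is removed from raw
latencies, by subtracting each item's pooled mean. Person effects (reading
and motor speed) are deliberately retained — double standardization, which
also removes them, induces artefactual negative correlations between items
and discards severity-related slowing that is part of the signal. Each
eligible participant is then summarised by the mean of their centered
latencies across all items and sessions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import MissingItemError


@dataclass(frozen=True)
class RTProfile:
    participant_id: str
    mean_centered_rt: float
    n_responses: int


def item_mean_rt(
    records: pd.DataFrame, expected_items: Optional[Sequence[int]] = None
) -> pd.Series:
    """Pooled arithmetic mean latency per item over all supplied records.

    ``expected_items`` lets callers insist on full item coverage; any
    expected item with zero responses raises :class:`MissingItemError`.
    """
    if len(records) == 0:
        raise ValueError("no records supplied")
    means = records.groupby("item_id")["rt_ms"].mean()
    if expected_items is not None:
        missing = sorted(int(i) for i in set(expected_items) - set(means.index))
        if missing:
            raise MissingItemError(f"no responses for item(s) {missing}")
    return means


def center_rt(records: pd.DataFrame, item_means: pd.Series) -> pd.DataFrame:
    """Return a copy of the records with rt_ms replaced by rt_ms - mu_item."""
    unknown = sorted(int(i) for i in set(records["item_id"].unique()) - set(item_means.index))
    if unknown:
        raise MissingItemError(f"no centering mean for item(s) {unknown}")
    out = records.copy()
    out["rt_ms"] = out["rt_ms"].to_numpy() - item_means.reindex(out["item_id"]).to_numpy()
    return out


def person_mean_rt(centered: pd.DataFrame) -> RTProfile:
    """Mean centered latency across one participant's items and sessions."""
    if len(centered) == 0:
        raise ValueError("no centered records supplied")
    if centered["participant_id"].nunique() > 1:
        raise ValueError("records must belong to a single participant")
    return RTProfile(
        participant_id=centered["participant_id"].iloc[0],
        mean_centered_rt=float(centered["rt_ms"].mean()),
        n_responses=int(len(centered)),
    )


def rt_profiles(
    records: pd.DataFrame,
    winsorize_ms: Optional[float] = None,
    expected_items: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Item-center the supplied records and aggregate to one value per participant.

    Parameters
    ----------
    records : DataFrame
        Session records of the participants entering the analysis (i.e.
        already filtered to eligible participants, so the pooled item means
        match the analysis sample).
    winsorize_ms : float, optional
        If given, raw latencies are capped at this value before centering.
        Off by default: outliers are surfaced by residual diagnostics instead.

    Returns
    -------
    DataFrame with columns participant_id, mean_centered_rt, n_responses.
    """
    if len(records) == 0:
        raise ValueError("no records supplied")
    work = records
    if winsorize_ms is not None:
        work = records.copy()
        work["rt_ms"] = work["rt_ms"].clip(upper=winsorize_ms)
    means = item_mean_rt(work, expected_items=expected_items)
    centered = center_rt(work, means)
    grouped = centered.groupby("participant_id")["rt_ms"]
    out = pd.DataFrame(
        {
            "participant_id": grouped.mean().index,
            "mean_centered_rt": grouped.mean().to_numpy(),
            "n_responses": grouped.size().to_numpy(),
        }
    )
    return out
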