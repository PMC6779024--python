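"""Binary-to-ordinal conversion scoring for daily mobile depression diaries.

A participant answers each of 20 symptom items Yes/No once per day for two
weeks. For each item the fraction of Yes days, Y = Q / P (Q = Yes count,
P = completed-day count), is mapped onto the familiar 0-4 ordinal scale of
the retrospective instrument through fixed cutoffs expressed in fourteenths:

    0 : 0     <= Y < 2/14
    1 : 2/14  <= Y < 5/14
    2 : 5/14  <= Y < 9/14
    3 : 9/14  <= Y < 13/14
    4 : 13/14 <= Y <= 1

Totals range 0-80; participants with fewer than 7 completed days receive no
total, and a total of 13 or more flags elevated depression risk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Union

import numpy as np
import pandas as pd

from .errors import DataIntegrityError

#: Left-closed bin edges of the conversion algorithm, in units of 1/14.
BIN_EDGES = np.array([2 / 14, 5 / 14, 9 / 14, 13 / 14])

#: Adherence rule: a total is computed only with at least this many completed days.
MIN_COMPLETED_DAYS = 7

#: At-risk threshold on the 0-80 total.
RISK_CUTOFF = 13


@dataclass(frozen=True)
class ItemRatio:
    """Yes-fraction bookkeeping for one item of one participant."""

    item_id: int
    q: int
    p: int

    @property
    def y(self) -> float:
        return self.q / self.p

    def __post_init__(self) -> None:
        if not (0 <= self.q <= self.p):
            raise DataIntegrityError(
                f"item {self.item_id}: need 0 <= Q <= P, got Q={self.q}, P={self.p}"
            )


@dataclass
class ParticipantScore:
    """Conversion output for one participant.

    ``item_ratios``, ``item_scores``, ``total`` and ``at_risk`` are ``None``
    when the participant is ineligible (fewer completed days than the
    adherence rule requires).
    """

    participant_id: str
    completed_days: int
    eligible: bool
    item_ratios: Optional[List[ItemRatio]] = None
    item_scores: Optional[np.ndarray] = None
    total: Optional[int] = None
    at_risk: Optional[bool] = None


def bin_item_score(y: float) -> int:
    """Map a Yes-fraction Y in [0, 1] onto the 0-4 ordinal scale.

    Intervals are left-closed/right-open; the top bin is closed at 1 so
    fractions above 13/14 arising from P < 14 remain scorable.
    """
    if not (0.0 <= y <= 1.0) or not np.isfinite(y):
        raise ValueError(f"Y must lie in [0, 1], got {y!r}")
    return int(np.searchsorted(BIN_EDGES, y, side="right"))


def bin_item_scores(y: np.ndarray) -> np.ndarray:
    """Vectorised :func:`bin_item_score`."""
    y = np.asarray(y, dtype=float)
    if np.any(~np.isfinite(y)) or np.any((y < 0) | (y > 1)):
        raise ValueError("all Y values must lie in [0, 1]")
    return np.searchsorted(BIN_EDGES, y, side="right")


def adherence_filter(completed_days: int, min_days: int = MIN_COMPLETED_DAYS) -> bool:
    """True iff the participant completed enough daily sessions for a total."""
    return completed_days >= min_days


def risk_flag(
    total_mobile: Optional[int], total_standard: Optional[int] = None, cutoff: int = RISK_CUTOFF
) -> bool:
    """Either-scale risk rule: flag if any supplied total reaches the cutoff."""
    totals = [t for t in (total_mobile, total_standard) if t is not None]
    for t in totals:
        if not (0 <= t <= 80):
            raise ValueError(f"total must lie in 0..80, got {t!r}")
    return any(t >= cutoff for t in totals)


def _check_duplicates(records: pd.DataFrame, keys: list) -> None:
    dup = records.duplicated(keys)
    if dup.any():
        first = records.loc[dup, keys].iloc[0].tolist()
        raise DataIntegrityError(f"duplicate {tuple(keys)} record: {first}")


def count_completed_days(records: pd.DataFrame, n_items: int = 20) -> int:
    """Number of days on which the participant answered every item.

    A day with partial responses does not count: the app only uploads a
    session after the final save, so incomplete days indicate corrupted
    exports and are excluded from the denominator P.
    """
    if len(records) == 0:
        return 0
    if records["participant_id"].nunique() > 1:
        raise ValueError("records must belong to a single participant")
    _check_duplicates(records, ["day_index", "item_id"])
    per_day = records.groupby("day_index")["item_id"].nunique()
    return int((per_day == n_items).sum())


def score_participant(
    records: pd.DataFrame,
    n_items: int = 20,
    min_days: int = MIN_COMPLETED_DAYS,
    cutoff: int = RISK_CUTOFF,
) -> ParticipantScore:
    """Run the full conversion algorithm for one participant's records."""
    if len(records) == 0:
        raise ValueError("no records supplied")
    pid = records["participant_id"].iloc[0]
    if records["participant_id"].nunique() > 1:
        raise ValueError("records must belong to a single participant")
    _check_duplicates(records, ["day_index", "item_id"])

    per_day = records.groupby("day_index")["item_id"].nunique()
    complete_days = per_day.index[per_day == n_items]
    p = len(complete_days)
    eligible = adherence_filter(p, min_days)
    if not eligible:
        return ParticipantScore(participant_id=pid, completed_days=p, eligible=False)

    on_complete = records[records["day_index"].isin(complete_days)]
    q = (
        on_complete.groupby("item_id")["response"]
        .sum()
        .reindex(range(1, n_items + 1), fill_value=0)
        .astype(int)
    )
    ratios = [ItemRatio(item_id=int(i), q=int(qi), p=p) for i, qi in q.items()]
    scores = bin_item_scores(q.to_numpy() / p)
    total = int(scores.sum())
    return ParticipantScore(
        participant_id=pid,
        completed_days=p,
        eligible=True,
        item_ratios=ratios,
        item_scores=scores,
        total=total,
        at_risk=risk_flag(total, cutoff=cutoff),
    )


@dataclass
class CohortScores:
    """Cohort-level conversion output.

    Attributes
    ----------
    summary : DataFrame
        One row per participant: participant_id, completed_days, eligible,
        total (nullable), at_risk (nullable).
    item_scores : DataFrame
        Eligible participants x items matrix of converted 0-4 scores.
    item_ratios : DataFrame
        Eligible participants x items matrix of Yes-fractions Y.
    """

    summary: pd.DataFrame
    item_scores: pd.DataFrame
    item_ratios: pd.DataFrame

    @property
    def n_excluded(self) -> int:
        return int((~self.summary["eligible"]).sum())


def score_cohort(
    records: pd.DataFrame,
    n_items: int = 20,
    min_days: int = MIN_COMPLETED_DAYS,
    cutoff: int = RISK_CUTOFF,
) -> CohortScores:
    """Vectorised conversion scoring of a whole cohort's session records."""
    if len(records) == 0:
        raise ValueError("no records supplied")
    _check_duplicates(records, ["participant_id", "day_index", "item_id"])

    per_day = records.groupby(["participant_id", "day_index"])["item_id"].nunique()
    complete = per_day[per_day == n_items]
    p = complete.groupby(level="participant_id").size()
    all_pids = records["participant_id"].unique()
    p = p.reindex(all_pids, fill_value=0).sort_index()

    keyed = records.set_index(["participant_id", "day_index"])
    on_complete = keyed.loc[keyed.index.isin(complete.index)].reset_index()

    q = (
        on_complete.pivot_table(
            index="participant_id", columns="item_id", values="response", aggfunc="sum"
        )
        .reindex(columns=range(1, n_items + 1), fill_value=0)
        .fillna(0)
        .astype(int)
    )

    eligible = p >= min_days
    elig_ids = p.index[eligible]
    q_elig = q.reindex(elig_ids).fillna(0).astype(int)
    y = q_elig.div(p.loc[elig_ids], axis=0)
    scores = pd.DataFrame(
        bin_item_scores(y.to_numpy()), index=y.index, columns=y.columns, dtype=int
    )
    totals = scores.sum(axis=1)

    summary = pd.DataFrame(
        {
            "participant_id": p.index,
            "completed_days": p.to_numpy(),
            "eligible": eligible.to_numpy(),
        }
    )
    summary["total"] = summary["participant_id"].map(totals).astype("Int64")
    summary["at_risk"] = pd.array(
        [None if pd.isna(t) else bool(t >= cutoff) for t in summary["total"]],
        dtype="boolean",
    )
    return CohortScores(summary=summary, item_scores=scores, item_ratios=y)
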