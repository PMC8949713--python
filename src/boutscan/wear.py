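"""Wear-time validation: valid days and the per-protocol analysis set.

A calendar day is *valid* when the device was worn for at least
``min_wear_minutes_per_day`` minutes (default 480, i.e. 8 hours); a
participant-timepoint enters the analysis set when it has at least
``min_valid_days`` valid days (default 4).  Validity is assessed per
timepoint, so a participant can qualify at baseline and fail at discharge;
paired analyses downstream require both.

Days are midnight-to-midnight calendar days, not rolling 24-hour windows.
Non-worn epochs contribute to no metric: their MET and step values are
ignored entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .bouts import CLASSES, IntensityThresholds, classify_epochs
from .errors import InputError


@dataclass(frozen=True)
class ValidityCriteria:
    """Wear-time inclusion rule: >=8 h of worn data per day on >=4 days."""

    min_wear_minutes_per_day: int = 480
    min_valid_days: int = 4

    def __post_init__(self):
        if self.min_wear_minutes_per_day <= 0 or self.min_valid_days <= 0:
            raise InputError("validity criteria must be strictly positive")


@dataclass
class DaySummary:
    """Per-day wear accounting for one participant-day.

    ``met_sum`` is the sum of MET values over worn epochs; it is carried so
    that wear-weighted MET means can be pooled across days without
    revisiting the epochs.
    """

    participant_id: str
    timepoint: str
    date: object
    wear_minutes: int
    valid: bool
    steps: int
    minutes_by_class: dict[str, int]
    met_sum: float


def summarize_day(day: pd.DataFrame,
                  thresholds: IntensityThresholds | None = None,
                  criteria: ValidityCriteria | None = None) -> DaySummary:
    """Summarise one participant-day: wear minutes, steps, class minutes.

    Only worn epochs count; ``wear_minutes`` equals the sum of the
    per-class minutes by construction.  An empty day yields a zero summary
    marked invalid.
    """
    criteria = criteria or ValidityCriteria()
    if day.empty:
        return empty_day_summary("", "", None)
    pids = day["participant_id"].unique()
    tps = day["timepoint"].unique()
    dates = pd.to_datetime(day["timestamp"]).dt.date.unique()
    if len(pids) != 1 or len(tps) != 1 or len(dates) != 1:
        raise InputError("summarize_day expects epochs from a single "
                         "participant-day")
    worn = day["worn"].to_numpy(bool)
    mets = day["mets"].to_numpy(float)
    steps = day["steps"].to_numpy()
    cls = classify_epochs(mets[worn], thresholds)
    by_class = {c: int((cls == c).sum()) for c in CLASSES}
    wear_minutes = int(worn.sum())
    return DaySummary(
        participant_id=str(pids[0]),
        timepoint=str(tps[0]),
        date=dates[0],
        wear_minutes=wear_minutes,
        valid=wear_minutes >= criteria.min_wear_minutes_per_day,
        steps=int(steps[worn].sum()),
        minutes_by_class=by_class,
        met_sum=float(mets[worn].sum()),
    )


def empty_day_summary(participant_id: str, timepoint: str, date) -> DaySummary:
    return DaySummary(participant_id, timepoint, date, 0, False, 0,
                      {c: 0 for c in CLASSES}, 0.0)


def summarize_days(epochs: pd.DataFrame,
                   thresholds: IntensityThresholds | None = None,
                   criteria: ValidityCriteria | None = None) -> list[DaySummary]:
    """Summarise every participant-day in an epoch frame."""
    from .io_epochs import iter_participant_days

    return [summarize_day(day, thresholds, criteria)
            for _, day in iter_participant_days(epochs)]


def day_summary_frame(summaries: Iterable[DaySummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "participant_id": s.participant_id,
            "timepoint": s.timepoint,
            "date": s.date,
            "wear_minutes": s.wear_minutes,
            "valid": s.valid,
            "steps": s.steps,
            "met_sum": s.met_sum,
        }
        row.update({f"min_{c}": s.minutes_by_class[c] for c in CLASSES})
        rows.append(row)
    return pd.DataFrame(rows)


def select_valid_participants(
    summaries: Sequence[DaySummary],
    criteria: ValidityCriteria | None = None,
) -> tuple[set[tuple[str, str]], dict[tuple[str, str], str]]:
    """Split participant-timepoints into included and excluded sets.

    A participant-timepoint is included iff its count of valid days (wear
    minutes >= the daily minimum, recomputed against `criteria`) reaches
    ``min_valid_days``.  Exclusions carry a human-readable reason.  The
    decision is monotone: relaxing either criterion never shrinks the
    included set.
    """
    criteria = criteria or ValidityCriteria()
    counts: dict[tuple[str, str], int] = {}
    for s in summaries:
        key = (s.participant_id, s.timepoint)
        ok = s.wear_minutes >= criteria.min_wear_minutes_per_day
        counts[key] = counts.get(key, 0) + int(ok)
    included = {k for k, n in counts.items() if n >= criteria.min_valid_days}
    excluded = {k: f"too few valid days: {n}"
                for k, n in counts.items() if n < criteria.min_valid_days}
    return included, excluded
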