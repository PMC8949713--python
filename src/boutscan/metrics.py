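"""Per-participant physical-activity summaries at one timepoint.

For every participant-timepoint that passes wear validity this module
produces the standard summary row: steps per day, the wear-weighted daily
MET mean, percent of wear time spent in the moderate class, the mean MVPA
bout length, mean bouts per day at each duration floor, and total MVPA
minutes per day.

Conventions:

* ``daily_mets`` is the mean MET over worn epochs pooled across valid days
  (wear-weighted), so non-wear time cannot dilute it.
* ``pct_time_moderate`` uses the moderate class only, not MVPA, matching
  the separate "percentage of moderate activity" summary measure.
* All per-day quantities average over valid days only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .bouts import (DEFAULT_DURATION_THRESHOLDS, BoutSpectrum,
                    IntensityThresholds, bout_spectrum, detect_bouts)
from .errors import InputError
from .wear import DaySummary, ValidityCriteria, summarize_day

#: columns of a participant summary that are group-comparable metrics
METRIC_COLUMNS = ("steps_per_day", "daily_mets", "pct_time_moderate",
                  "mean_bout_length_min", "bouts_2", "bouts_5", "bouts_10",
                  "bouts_20", "total_mvpa_min")


@dataclass
class ParticipantSummary:
    participant_id: str
    timepoint: str
    n_valid_days: int
    steps_per_day: float
    daily_mets: float
    pct_time_moderate: float
    mean_bout_length_min: float
    bouts_by_threshold: dict[int, float]
    total_mvpa_min: float


def percent_change(baseline: float, discharge: float) -> float:
    """100 * (discharge - baseline) / baseline; undefined for baseline <= 0."""
    if baseline <= 0:
        raise InputError(f"percent change undefined for baseline {baseline}")
    return 100.0 * (discharge - baseline) / baseline


def format_percent_change(value: float, decimals: int = 0) -> str:
    """Render a percent change the way a results table prints it ("12%")."""
    if decimals <= 0:
        return f"{round(value):.0f}%"
    return f"{value:.{decimals}f}%"


def summarize_participant(valid_days: Sequence[DaySummary],
                          spectrum: BoutSpectrum) -> ParticipantSummary:
    """Fold a participant-timepoint's valid days and spectrum into one row."""
    days = [d for d in valid_days]
    if not days:
        raise InputError("participant failed wear validity: no valid days")
    if any(not d.valid for d in days):
        raise InputError("summarize_participant accepts valid days only")
    pid = days[0].participant_id
    tp = days[0].timepoint
    wear_total = sum(d.wear_minutes for d in days)
    moderate_total = sum(d.minutes_by_class["moderate"] for d in days)
    return ParticipantSummary(
        participant_id=pid,
        timepoint=tp,
        n_valid_days=len(days),
        steps_per_day=float(np.mean([d.steps for d in days])),
        daily_mets=sum(d.met_sum for d in days) / wear_total,
        pct_time_moderate=100.0 * moderate_total / wear_total,
        mean_bout_length_min=spectrum.mean_bout_length_min,
        bouts_by_threshold=dict(spectrum.counts_per_day),
        total_mvpa_min=spectrum.total_mvpa_min,
    )


def participant_summary_frame(summaries: Sequence[ParticipantSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "participant_id": s.participant_id,
            "timepoint": s.timepoint,
            "n_valid_days": s.n_valid_days,
            "steps_per_day": s.steps_per_day,
            "daily_mets": s.daily_mets,
            "pct_time_moderate": s.pct_time_moderate,
            "mean_bout_length_min": s.mean_bout_length_min,
        }
        row.update({f"bouts_{d}": v for d, v in sorted(s.bouts_by_threshold.items())})
        row["total_mvpa_min"] = s.total_mvpa_min
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_cohort(
    epochs: pd.DataFrame,
    thresholds: IntensityThresholds | None = None,
    criteria: ValidityCriteria | None = None,
    duration_thresholds: Sequence[int] = DEFAULT_DURATION_THRESHOLDS,
    max_break_min: int = 0,
) -> tuple[pd.DataFrame, dict[tuple[str, str], str]]:
    """Run wear validation, bout detection and summarisation over a cohort.

    Returns ``(summary_frame, exclusions)`` where the frame holds one row
    per included participant-timepoint and ``exclusions`` maps excluded
    (participant_id, timepoint) pairs to their reason.
    """
    from .io_epochs import iter_participant_days

    thresholds = thresholds or IntensityThresholds()
    criteria = criteria or ValidityCriteria()

    day_records: dict[tuple[str, str], list[tuple[DaySummary, pd.DataFrame]]] = {}
    for (pid, tp, _date), day in iter_participant_days(epochs):
        summary = summarize_day(day, thresholds, criteria)
        day_records.setdefault((str(pid), str(tp)), []).append((summary, day))

    summaries: list[ParticipantSummary] = []
    exclusions: dict[tuple[str, str], str] = {}
    for key in sorted(day_records):
        records = day_records[key]
        valid = [(s, d) for s, d in records if s.valid]
        if len(valid) < criteria.min_valid_days:
            exclusions[key] = f"too few valid days: {len(valid)}"
            continue
        bouts = []
        for _s, day in valid:
            bouts.extend(detect_bouts(day, thresholds, max_break_min))
        spectrum = bout_spectrum(bouts, len(valid), duration_thresholds)
        summaries.append(summarize_participant([s for s, _ in valid], spectrum))

    frame = participant_summary_frame(summaries)
    if frame.empty:
        cols = (["participant_id", "timepoint", "n_valid_days", "steps_per_day",
                 "daily_mets", "pct_time_moderate", "mean_bout_length_min"]
                + [f"bouts_{d}" for d in duration_thresholds]
                + ["total_mvpa_min"])
        frame = pd.DataFrame(columns=cols)
    return frame, exclusions


def build_cohort_table(summary_frame: pd.DataFrame,
                       manifest: pd.DataFrame) -> pd.DataFrame:
    """Join participant summaries with arm and clinical covariates."""
    if summary_frame.empty:
        return summary_frame.copy()
    merged = summary_frame.merge(manifest, on="participant_id", how="left",
                                 validate="many_to_one")
    return merged
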