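"""MET intensity classification and MVPA bout detection.

An epoch is classified from its MET value: vigorous strictly above the
vigorous cut-point, moderate on the closed band [moderate_min, moderate_max]
(6.0 METs is moderate, not vigorous), light on the open band between the
light and moderate cut-points, and sedentary-or-below otherwise.

A *bout* is a maximal run of consecutive worn epochs at moderate or vigorous
intensity (MVPA): vigorous minutes never interrupt a bout.  A recording gap
or a non-worn epoch always ends a run.  By default a single worn sub-moderate
minute also ends the run (``max_break_min=0``); a positive tolerance allows
runs separated by at most that many consecutive worn sub-moderate minutes to
merge, with the bout duration still counting MVPA minutes only.

The bout-accumulation spectrum summarises bouts over a participant's valid
days: mean bouts per day at each duration floor (default >=2, >=5, >=10 and
>=20 minutes), the pooled mean bout length, and total MVPA minutes per day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, UndefinedSpectrumError

CLASSES = ("sedentary_or_below", "light", "moderate", "vigorous")
DEFAULT_DURATION_THRESHOLDS = (2, 5, 10, 20)


@dataclass(frozen=True)
class IntensityThresholds:
    """MET cut-points for the four-level intensity classification.

    light_min is an exclusive lower bound for light; the moderate band is
    the closed interval [moderate_min, moderate_max]; vigorous_min is an
    exclusive lower bound for vigorous.
    """

    light_min: float = 1.5
    moderate_min: float = 3.0
    moderate_max: float = 6.0
    vigorous_min: float = 6.0

    def __post_init__(self):
        if not (self.light_min < self.moderate_min <= self.moderate_max
                <= self.vigorous_min):
            raise InputError(
                "intensity cut-points must satisfy "
                "light_min < moderate_min <= moderate_max <= vigorous_min")


@dataclass(frozen=True)
class Bout:
    """One maximal MVPA run within a participant-day."""

    participant_id: str
    timepoint: str
    start: pd.Timestamp
    duration_min: int
    mean_mets: float


@dataclass
class BoutSpectrum:
    """Bout accumulation over a set of valid days (per-day means)."""

    counts_per_day: dict[int, float]
    mean_bout_length_min: float
    total_mvpa_min: float
    n_valid_days: int
    no_bouts: bool = field(default=False)


def classify_epoch(mets: float, thresholds: IntensityThresholds | None = None) -> str:
    """Classify a single MET value into an intensity class."""
    if mets < 0:
        raise InputError(f"METs must be non-negative, got {mets}")
    thr = thresholds or IntensityThresholds()
    if mets > thr.vigorous_min:
        return "vigorous"
    if thr.moderate_min <= mets <= thr.moderate_max:
        return "moderate"
    if thr.light_min < mets < thr.moderate_min:
        return "light"
    return "sedentary_or_below"


def classify_epochs(mets: np.ndarray,
                    thresholds: IntensityThresholds | None = None) -> np.ndarray:
    """Vectorised classification; returns an array of class-name strings."""
    thr = thresholds or IntensityThresholds()
    m = np.asarray(mets, dtype=float)
    if (m < 0).any():
        raise InputError("METs must be non-negative")
    out = np.full(m.shape, "sedentary_or_below", dtype=object)
    out[(thr.light_min < m) & (m < thr.moderate_min)] = "light"
    out[(thr.moderate_min <= m) & (m <= thr.moderate_max)] = "moderate"
    out[m > thr.vigorous_min] = "vigorous"
    return out


def mvpa_mask(mets: np.ndarray, worn: np.ndarray,
              thresholds: IntensityThresholds | None = None) -> np.ndarray:
    """Boolean mask of worn epochs classified moderate or vigorous."""
    thr = thresholds or IntensityThresholds()
    m = np.asarray(mets, dtype=float)
    moderate = (thr.moderate_min <= m) & (m <= thr.moderate_max)
    vigorous = m > thr.vigorous_min
    return np.asarray(worn, bool) & (moderate | vigorous)


def _minute_index(timestamps: pd.Series) -> np.ndarray:
    ts = pd.to_datetime(timestamps).to_numpy()
    if len(ts) > 1 and not (np.diff(ts) > np.timedelta64(0, "s")).all():
        raise InputError("epochs within a day must be strictly time-ordered")
    if len(ts) == 0:
        return np.empty(0, dtype=np.int64)
    return ((ts - ts[0]) / np.timedelta64(60, "s")).astype(np.int64)


def detect_bouts(day: pd.DataFrame,
                 thresholds: IntensityThresholds | None = None,
                 max_break_min: int = 0) -> list[Bout]:
    """Find all maximal MVPA runs within one participant-day.

    `day` holds one participant-day of epochs (columns ``participant_id,
    timepoint, timestamp, mets, worn``), strictly time-ordered.  Runs of
    length 1 are retained as 1-minute bouts: they contribute to the mean
    bout length and to total MVPA minutes but meet no >=2-minute floor.
    """
    if day.empty:
        return []
    minutes = _minute_index(day["timestamp"])
    mets = day["mets"].to_numpy(float)
    worn = day["worn"].to_numpy(bool)
    active = mvpa_mask(mets, worn, thresholds)

    idx = np.flatnonzero(active)
    if idx.size == 0:
        return []
    # split at positional breaks or timestamp gaps (>1 min between epochs)
    contiguous = (np.diff(idx) == 1) & (np.diff(minutes[idx]) == 1)
    runs: list[np.ndarray] = np.split(idx, np.flatnonzero(~contiguous) + 1)

    if max_break_min > 0:
        runs = _merge_runs(runs, minutes, worn, max_break_min)

    pid = str(day["participant_id"].iloc[0])
    tp = str(day["timepoint"].iloc[0])
    ts = pd.to_datetime(day["timestamp"]).reset_index(drop=True)
    bouts = []
    for run in runs:
        bouts.append(Bout(
            participant_id=pid,
            timepoint=tp,
            start=ts.iloc[int(run[0])],
            duration_min=int(run.size),
            mean_mets=float(mets[run].mean()),
        ))
    return bouts


def _merge_runs(runs: list[np.ndarray], minutes: np.ndarray,
                worn: np.ndarray, max_break_min: int) -> list[np.ndarray]:
    """Merge runs separated by <= max_break_min worn, gap-free minutes."""
    merged = [runs[0]]
    for run in runs[1:]:
        prev = merged[-1]
        lo, hi = int(prev[-1]), int(run[0])
        between = np.arange(lo + 1, hi)
        gap_minutes = minutes[hi] - minutes[lo] - 1
        recording_gap = gap_minutes != between.size  # missing epochs in between
        if (not recording_gap and gap_minutes <= max_break_min
                and worn[between].all()):
            merged[-1] = np.concatenate([prev, run])
        else:
            merged.append(run)
    return merged


def bout_spectrum(bouts: Iterable[Bout], n_valid_days: int,
                  duration_thresholds: Sequence[int] = DEFAULT_DURATION_THRESHOLDS,
                  ) -> BoutSpectrum:
    """Aggregate bouts from a participant's valid days into a spectrum.

    counts_per_day[d] is the number of bouts of duration >= d across all
    valid days, divided by the number of valid days.  The spectrum is
    necessarily non-increasing in d, and the sum of bout durations equals
    total MVPA minutes.
    """
    if n_valid_days <= 0:
        raise UndefinedSpectrumError(
            "bout spectrum is undefined over zero valid days")
    durations = np.array([b.duration_min for b in bouts], dtype=float)
    counts = {int(d): float((durations >= d).sum()) / n_valid_days
              for d in duration_thresholds}
    if durations.size:
        return BoutSpectrum(counts, float(durations.mean()),
                            float(durations.sum()) / n_valid_days,
                            n_valid_days)
    return BoutSpectrum(counts, 0.0, 0.0, n_valid_days, no_bouts=True)
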