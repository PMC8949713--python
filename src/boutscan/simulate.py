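"""Synthetic two-arm, two-timepoint minute-epoch cohorts with planted truth.

The generator emulates the kind of minute-level armband export a pulmonary
rehabilitation trial collects: each participant-day is 1440 one-minute
epochs with a daily wear window, a sedentary MET baseline, scattered light
activity, and MVPA bouts whose count is Poisson and whose lengths are
geometric (memoryless and analytically tractable: a bout of mean length
1/p has P(length >= d) = (1-p)^(d-1), so the expected bout-accumulation
spectrum is available in closed form for oracle tests).  Steps accumulate
per intensity class at fixed Poisson rates.

Bouts are placed uniformly at random inside the wear window, separated
from each other and from the window edges by at least one non-MVPA minute,
so that each planted bout is recoverable as exactly one maximal run.  A
day sampled "invalid" gets a truncated wear window below the 480-minute
validity floor.

Every planted quantity (bout starts and lengths, per-class minutes, steps)
is recorded in a truth ledger so downstream modules can be tested against
generator bookkeeping rather than against themselves.

Intervention effects act on the profile: an additive change to the bout
rate, a multiplicative change to the geometric parameter p (smaller p =
longer bouts), and a multiplicative step-rate change.  The two default
arm effects encode the two response phenotypes of interest: the web arm
adds short bouts (bout rate up, lengths unchanged) and the conventional
arm lengthens bouts at a matched >=2-minute bout count (p down, rate down).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, SimulationError
from .io_epochs import write_epoch_csv

#: per-arm covariate distributions (mean, sd) emulating a two-arm COPD
#: rehabilitation cohort at baseline; sex is P(male).
ARM_COVARIATES = {
    "web": {"age": (68.3, 6.5), "bmi": (27.2, 5.5),
            "fev1_pct_pred": (54.2, 26.9), "iswt_m": (338.5, 185.7),
            "eswt_s": (263.9, 250.1), "p_male": 18 / 20},
    "conventional": {"age": (67.4, 8.6), "bmi": (29.8, 6.6),
                     "fev1_pct_pred": (55.8, 19.4), "iswt_m": (286.8, 159.4),
                     "eswt_s": (256.2, 157.1), "p_male": 19 / 34},
}

_COVARIATE_BOUNDS = {"age": (40, 95), "bmi": (15, 55),
                     "fev1_pct_pred": (15, 100), "iswt_m": (10, 1200),
                     "eswt_s": (30, 1800)}


@dataclass(frozen=True)
class ActivityProfile:
    """Generative parameters for one participant-condition.

    Defaults emulate a sedentary COPD cohort: ~28 MVPA bouts/day of
    geometric mean length ~2.8 min (so ~18 bouts reach 2 minutes), ~2 h of
    light activity inside a 15-hour wear window, and step rates that put
    the expected total near 5,300 steps/day with a wear-weighted daily MET
    mean near 1.5.
    """

    basal_met_mean: float = 1.1
    basal_met_sd: float = 0.15
    light_rate: float = 120.0          # expected light minutes/day
    light_met_mean: float = 2.2
    light_met_sd: float = 0.3
    mvpa_bout_rate: float = 28.0       # expected bouts/day (Poisson)
    bout_length_p: float = 0.36        # geometric parameter; mean length 1/p
    bout_met_mean: float = 4.0
    bout_met_sd: float = 0.5
    steps_per_mvpa_min: float = 50.0
    steps_per_light_min: float = 12.0
    wear_start_min: int = 420          # 07:00
    wear_end_min: int = 1320           # 22:00
    p_invalid_day: float = 0.15

    def __post_init__(self):
        if not (0.0 < self.bout_length_p <= 1.0):
            raise InputError("bout_length_p must lie in (0, 1]")
        if not (3.0 <= self.bout_met_mean <= 6.0):
            raise InputError("bout_met_mean must lie in the moderate band [3, 6]")
        for name in ("light_rate", "mvpa_bout_rate", "steps_per_mvpa_min",
                     "steps_per_light_min"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")
        if not (0 <= self.wear_start_min < self.wear_end_min <= 1440):
            raise InputError("wear window must satisfy 0 <= start < end <= 1440")
        if not (0.0 <= self.p_invalid_day <= 1.0):
            raise InputError("p_invalid_day must be a probability")

    @property
    def mean_bout_length(self) -> float:
        return 1.0 / self.bout_length_p

    def expected_spectrum_count(self, d: int) -> float:
        """Expected bouts/day of duration >= d under the planted model."""
        return self.mvpa_bout_rate * (1.0 - self.bout_length_p) ** (d - 1)

    @property
    def expected_mvpa_min_per_day(self) -> float:
        return self.mvpa_bout_rate / self.bout_length_p

    @property
    def expected_steps_per_day(self) -> float:
        return (self.steps_per_mvpa_min * self.expected_mvpa_min_per_day
                + self.steps_per_light_min * self.light_rate)


@dataclass(frozen=True)
class InterventionEffect:
    """How discharge generation differs from baseline for one arm."""

    delta_bout_rate: float = 0.0        # additive bouts/day
    bout_length_p_scale: float = 1.0    # multiplicative on p; <1 lengthens
    steps_scale: float = 1.0            # multiplicative on both step rates

    def apply(self, profile: ActivityProfile) -> ActivityProfile:
        return dataclasses.replace(
            profile,
            mvpa_bout_rate=profile.mvpa_bout_rate + self.delta_bout_rate,
            bout_length_p=min(1.0, profile.bout_length_p * self.bout_length_p_scale),
            steps_per_mvpa_min=profile.steps_per_mvpa_min * self.steps_scale,
            steps_per_light_min=profile.steps_per_light_min * self.steps_scale,
        )


#: default arm effects: short-bout shift (web) vs long-bout shift
#: (conventional).  The web arm simply gains bouts, so its step increase
#: accrues through the added short bouts; the conventional rate drop keeps
#: its expected >=2-minute bout count matched to baseline while the
#: length distribution's tail thickens (p 0.36 -> 0.22).
DEFAULT_WEB_EFFECT = InterventionEffect(delta_bout_rate=5.0)
DEFAULT_CONVENTIONAL_EFFECT = InterventionEffect(
    delta_bout_rate=-5.0, bout_length_p_scale=0.61)


def _place_bouts(lengths: np.ndarray, window: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Place bouts in [0, window) with >=1 non-MVPA minute between bouts
    and at each edge; returns start offsets.  Drops the longest bouts (and
    warns via the caller's ledger) only through SimulationError if even a
    single bout cannot fit."""
    k = lengths.size
    if k == 0:
        return np.empty(0, dtype=np.int64)
    slack = window - int(lengths.sum()) - (k - 1) - 2
    if slack < 0:
        raise SimulationError("bouts do not fit in the wear window")
    # compose slack into k+1 random non-negative gaps
    if slack == 0:
        gaps = np.zeros(k + 1, dtype=np.int64)
    else:
        gaps = rng.multinomial(slack, np.full(k + 1, 1.0 / (k + 1)))
    starts = np.empty(k, dtype=np.int64)
    pos = 1 + gaps[0]
    for i in range(k):
        starts[i] = pos
        pos += int(lengths[i]) + 1 + int(gaps[i + 1])
    return starts


def simulate_participant_day(profile: ActivityProfile,
                             rng: np.random.Generator,
                             participant_id: str = "P000",
                             timepoint: str = "baseline",
                             date: str = "2014-01-06",
                             ) -> tuple[pd.DataFrame, dict]:
    """Generate 1440 one-minute epochs for one day plus its truth ledger."""
    day_start = pd.Timestamp(date)
    timestamps = day_start + pd.to_timedelta(np.arange(1440), unit="m")

    invalid = rng.random() < profile.p_invalid_day
    if invalid:
        wear_len = int(rng.integers(60, 480))
        w0 = profile.wear_start_min
        w1 = min(w0 + wear_len, 1440)
    else:
        w0, w1 = profile.wear_start_min, profile.wear_end_min
    window = w1 - w0

    worn = np.zeros(1440, dtype=bool)
    worn[w0:w1] = True

    # sedentary baseline METs for worn minutes, clipped below the light band
    mets = np.zeros(1440, dtype=float)
    basal = rng.normal(profile.basal_met_mean, profile.basal_met_sd, window)
    mets[w0:w1] = np.clip(basal, 0.0, 1.5)

    # draw and place MVPA bouts; shed the longest bouts if the window is
    # too tight (truncated invalid-day windows), recording what was planted
    n_bouts = int(rng.poisson(profile.mvpa_bout_rate))
    lengths = rng.geometric(profile.bout_length_p, n_bouts).astype(np.int64)
    order = rng.permutation(n_bouts)
    lengths = lengths[order]
    shed = 0
    while lengths.size and lengths.sum() + (lengths.size - 1) + 2 > window:
        lengths = np.delete(lengths, int(np.argmax(lengths)))
        shed += 1
    starts_rel = _place_bouts(lengths, window, rng)
    starts = starts_rel + w0

    mvpa_planted = np.zeros(1440, dtype=bool)
    for s, length in zip(starts, lengths):
        seg = slice(int(s), int(s + length))
        mvpa_planted[seg] = True
        mets[seg] = np.clip(
            rng.normal(profile.bout_met_mean, profile.bout_met_sd, int(length)),
            3.0, 6.0)

    # light activity on a random subset of the remaining worn minutes
    free = np.flatnonzero(worn & ~mvpa_planted)
    n_light = min(int(rng.poisson(profile.light_rate)), free.size)
    light_idx = rng.choice(free, size=n_light, replace=False) if n_light else \
        np.empty(0, dtype=np.int64)
    light_planted = np.zeros(1440, dtype=bool)
    light_planted[light_idx] = True
    mets[light_idx] = np.clip(
        rng.normal(profile.light_met_mean, profile.light_met_sd, n_light),
        1.51, 2.99)

    steps = np.zeros(1440, dtype=np.int64)
    if profile.steps_per_mvpa_min > 0:
        steps[mvpa_planted] = rng.poisson(profile.steps_per_mvpa_min,
                                          int(mvpa_planted.sum()))
    if profile.steps_per_light_min > 0:
        steps[light_planted] = rng.poisson(profile.steps_per_light_min, n_light)

    df = pd.DataFrame({
        "participant_id": participant_id,
        "timepoint": timepoint,
        "timestamp": timestamps,
        "mets": mets,
        "steps": steps,
        "worn": worn,
    })
    df["date"] = df["timestamp"].dt.date

    ledger = {
        "participant_id": participant_id,
        "timepoint": timepoint,
        "date": str(day_start.date()),
        "worn_minutes": int(window),
        "valid": bool(window >= 480),
        "n_bouts": int(lengths.size),
        "bouts_shed": int(shed),
        "bout_starts": [int(s) for s in starts],
        "bout_lengths": [int(x) for x in lengths],
        "mvpa_minutes": int(lengths.sum()),
        "light_minutes": int(n_light),
        "sedentary_minutes": int(window - lengths.sum() - n_light),
        "steps": int(steps.sum()),
    }
    return df, ledger


@dataclass
class SimulatedCohort:
    """A generated cohort: epochs, manifest, and the planted-truth ledger."""

    epochs: pd.DataFrame
    manifest: pd.DataFrame
    truth: pd.DataFrame
    seed: int

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "epochs": out / "epochs.csv",
            "manifest": out / "manifest.csv",
            "truth": out / "truth.csv",
        }
        write_epoch_csv(self.epochs, paths["epochs"])
        self.manifest.to_csv(paths["manifest"], index=False)
        truth = self.truth.copy()
        for col in ("bout_starts", "bout_lengths"):
            truth[col] = truth[col].map(lambda v: " ".join(map(str, v)))
        truth.to_csv(paths["truth"], index=False)
        return paths


def _draw_covariates(arm: str, rng: np.random.Generator) -> dict:
    params = ARM_COVARIATES[arm]
    row = {}
    for name, (mean, sd) in ((k, v) for k, v in params.items() if k != "p_male"):
        lo, hi = _COVARIATE_BOUNDS[name]
        row[name] = float(np.clip(rng.normal(mean, sd), lo, hi).round(1))
    row["sex"] = "m" if rng.random() < params["p_male"] else "f"
    return row


def simulate_cohort(n_web: int = 20, n_conventional: int = 34,
                    base_profile: ActivityProfile | None = None,
                    web_effect: InterventionEffect | None = None,
                    conventional_effect: InterventionEffect | None = None,
                    n_days: int = 7, seed: int = 0,
                    start_date: str = "2014-01-06") -> SimulatedCohort:
    """Generate a complete two-arm, two-timepoint cohort.

    Each participant contributes `n_days` consecutive days at baseline and
    again at discharge (dated 10 weeks later); discharge days are drawn
    from the arm's effect-modified profile.  One master seed fans out to
    per-participant streams, so regenerating any participant alone
    reproduces their data.
    """
    if n_web < 1 or n_conventional < 1:
        raise InputError("arm sizes must be at least 1")
    base_profile = base_profile or ActivityProfile()
    effects = {
        "web": web_effect or DEFAULT_WEB_EFFECT,
        "conventional": conventional_effect or DEFAULT_CONVENTIONAL_EFFECT,
    }
    arms = ["web"] * n_web + ["conventional"] * n_conventional
    master = np.random.SeedSequence(seed)
    streams = master.spawn(len(arms))

    epoch_frames, manifest_rows, ledgers = [], [], []
    t0 = pd.Timestamp(start_date)
    for i, (arm, stream) in enumerate(zip(arms, streams)):
        pid = f"{arm[0].upper()}{i + 1:03d}"
        rng = np.random.default_rng(stream)
        manifest_rows.append({"participant_id": pid, "arm": arm,
                              **_draw_covariates(arm, rng)})
        for timepoint, profile, offset in (
                ("baseline", base_profile, 0),
                ("discharge", effects[arm].apply(base_profile), 70)):
            for d in range(n_days):
                date = (t0 + pd.Timedelta(days=offset + d)).strftime("%Y-%m-%d")
                df, ledger = simulate_participant_day(
                    profile, rng, pid, timepoint, date)
                epoch_frames.append(df)
                ledgers.append(ledger)

    epochs = pd.concat(epoch_frames, ignore_index=True)
    epochs = epochs.sort_values(["participant_id", "timepoint", "timestamp"],
                                kind="mergesort").reset_index(drop=True)
    manifest = pd.DataFrame(manifest_rows)[
        ["participant_id", "arm", "age", "bmi", "fev1_pct_pred", "sex",
         "iswt_m", "eswt_s"]]
    truth = pd.DataFrame(ledgers)
    return SimulatedCohort(epochs, manifest, truth, seed)
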