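import numpy as np
import pandas as pd
import pytest

from boutscan.bouts import IntensityThresholds
from boutscan.simulate import ActivityProfile, simulate_cohort
from boutscan.wear import ValidityCriteria


def make_day(mets, worn=None, steps=None, pid="P001", timepoint="baseline",
             date="2014-01-06", start_minute=480):
    """Build a participant-day frame from a MET sequence (1-min epochs)."""
    mets = np.asarray(mets, dtype=float)
    n = mets.size
    worn = np.ones(n, bool) if worn is None else np.asarray(worn, bool)
    steps = np.zeros(n, int) if steps is None else np.asarray(steps, int)
    ts = pd.Timestamp(date) + pd.to_timedelta(start_minute + np.arange(n),
                                              unit="m")
    df = pd.DataFrame({"participant_id": pid, "timepoint": timepoint,
                       "timestamp": ts, "mets": mets, "steps": steps,
                       "worn": worn})
    df["date"] = df["timestamp"].dt.date
    return df


@pytest.fixture
def thresholds():
    return IntensityThresholds()


@pytest.fixture
def criteria():
    return ValidityCriteria()


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete simulated cohort reused across tests."""
    return simulate_cohort(n_web=5, n_conventional=7, n_days=5, seed=42)


@pytest.fixture(scope="session")
def quiet_profile():
    """A profile with no invalid days, for exact-recovery tests."""
    return ActivityProfile(p_invalid_day=0.0)
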