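"""Reading and writing minute-epoch accelerometer CSVs and the participant manifest.

The canonical epoch schema is one row per participant per minute::

    participant_id,timepoint,timestamp,mets,steps[,worn]

with ISO-8601 timestamps at minute resolution, ``timepoint`` in
{baseline, discharge}, ``mets`` a non-negative float (multiples of resting
oxygen consumption), ``steps`` a non-negative integer, and ``worn`` an
optional 0/1 on-body flag.  When ``worn`` is absent an epoch is treated as
non-worn iff its ``mets`` cell is blank: the device only produces a MET
estimate while it is on the body, so a missing value is the only defensible
proxy for off-body time.

The manifest schema is one row per participant::

    participant_id,arm,age,bmi,fev1_pct_pred,sex[,iswt_m,eswt_s]

with ``arm`` in {web, conventional}; the walking-test columns (incremental
and endurance shuttle walk) are optional covariates.
"""

from __future__ import annotations

import warnings
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError

TIMEPOINTS = ("baseline", "discharge")
ARMS = ("web", "conventional")

EPOCH_REQUIRED = ("participant_id", "timepoint", "timestamp", "mets", "steps")
EPOCH_COLUMNS = EPOCH_REQUIRED + ("worn",)

MANIFEST_REQUIRED = ("participant_id", "arm", "age", "bmi", "fev1_pct_pred", "sex")
MANIFEST_COLUMNS = MANIFEST_REQUIRED + ("iswt_m", "eswt_s")


def _apply_schema(df: pd.DataFrame, schema: Mapping[str, str] | None) -> pd.DataFrame:
    """Rename file columns to canonical names via a canonical->actual map."""
    if schema:
        rename = {actual: canonical for canonical, actual in schema.items()}
        df = df.rename(columns=rename)
    return df


def read_epoch_csv(path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a minute-epoch CSV into a validated, day-sorted DataFrame.

    Parameters
    ----------
    path
        CSV file following the canonical epoch schema (or mapped onto it
        via `schema`, a ``{canonical_name: actual_name}`` dict).

    Returns
    -------
    DataFrame with columns ``participant_id, timepoint, timestamp, mets,
    steps, worn, date``, sorted by (participant_id, timepoint, timestamp).
    Rows whose timestamp or numeric fields cannot be parsed, or whose
    values are negative, are dropped; their count is reported in
    ``df.attrs["n_malformed"]``.

    Raises
    ------
    SchemaError
        If a required column is absent.
    DataError
        If a participant-day contains duplicate timestamps.
    """
    raw = pd.read_csv(path, dtype={"participant_id": str},
                      float_precision="round_trip")
    raw = _apply_schema(raw, schema)

    missing = [c for c in EPOCH_REQUIRED if c not in raw.columns]
    if missing:
        raise SchemaError(f"epoch file {path} is missing required column(s): "
                          f"{', '.join(missing)}")

    has_worn = "worn" in raw.columns
    df = raw.loc[:, [c for c in EPOCH_COLUMNS if c in raw.columns]].copy()

    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce",
                                     format="ISO8601")
    df["mets"] = pd.to_numeric(df["mets"], errors="coerce")
    df["steps"] = pd.to_numeric(df["steps"], errors="coerce")

    if has_worn:
        worn = df["worn"].astype(float).fillna(0.0) != 0
    else:
        # no on-body flag: absence of a MET estimate marks off-body time
        worn = df["mets"].notna()
    df["worn"] = worn.to_numpy(bool)
    df["mets"] = df["mets"].fillna(0.0)

    bad_tp = ~df["timepoint"].isin(TIMEPOINTS)
    malformed = (df["timestamp"].isna() | df["steps"].isna()
                 | (df["mets"] < 0) | (df["steps"] < 0) | bad_tp)
    n_malformed = int(malformed.sum())
    if n_malformed:
        warnings.warn(f"dropping {n_malformed} malformed epoch row(s) from {path}")
        df = df.loc[~malformed]

    df["steps"] = df["steps"].astype(np.int64)
    df = df.sort_values(["participant_id", "timepoint", "timestamp"],
                        kind="mergesort").reset_index(drop=True)
    df["date"] = df["timestamp"].dt.date

    dup = df.duplicated(["participant_id", "timepoint", "timestamp"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise DataError(
            "duplicate timestamp for participant "
            f"{row['participant_id']} ({row['timepoint']}) on {row['date']}")

    df.attrs["n_malformed"] = n_malformed
    return df


def write_epoch_csv(df: pd.DataFrame, path) -> None:
    """Write epochs in the canonical schema (fixed column order, worn as 0/1)."""
    out = df.loc[:, list(EPOCH_REQUIRED)].copy()
    out["worn"] = df["worn"].astype(int)
    out["timestamp"] = pd.to_datetime(df["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    """Read the participant manifest (one row per participant)."""
    df = pd.read_csv(path, dtype={"participant_id": str},
                     float_precision="round_trip")
    if df.empty:
        warnings.warn(f"manifest {path} is empty")
        for c in MANIFEST_COLUMNS:
            if c not in df.columns:
                df[c] = pd.Series(dtype=float)
        return df.loc[:, list(MANIFEST_COLUMNS)]
    missing = [c for c in MANIFEST_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"manifest {path} is missing required column(s): "
                          f"{', '.join(missing)}")
    dup = df["participant_id"].duplicated()
    if dup.any():
        raise DataError("duplicated participant_id in manifest: "
                        f"{df.loc[dup.idxmax(), 'participant_id']}")
    bad_arm = ~df["arm"].isin(ARMS)
    if bad_arm.any():
        raise DataError(f"unknown arm value(s): {sorted(df.loc[bad_arm, 'arm'].unique())}")
    for c in ("iswt_m", "eswt_s"):
        if c not in df.columns:
            df[c] = np.nan
    return df.reset_index(drop=True)


def reconcile(epochs: pd.DataFrame, manifest: pd.DataFrame) -> dict:
    """Cross-check participant ids between epoch data and the manifest.

    Returns a report dict with ids present in the epoch data but absent
    from the manifest and vice versa; an empty report means full agreement.
    """
    epoch_ids = set(epochs["participant_id"].unique())
    manifest_ids = set(manifest["participant_id"].unique())
    return {
        "missing_in_manifest": sorted(epoch_ids - manifest_ids),
        "missing_in_epochs": sorted(manifest_ids - epoch_ids),
    }


def iter_participant_days(
    epochs: pd.DataFrame,
) -> Iterator[tuple[tuple[str, str, object], pd.DataFrame]]:
    """Yield ((participant_id, timepoint, date), day_frame) partitions.

    Every accepted epoch row appears in exactly one yielded group; groups
    are ordered by participant, timepoint, then calendar date.
    """
    for key, day in epochs.groupby(["participant_id", "timepoint", "date"],
                                   sort=True):
        yield key, day
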