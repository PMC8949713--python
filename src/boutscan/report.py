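"""Group summary tables, percent-change profiles, and the end-to-end run.

``build_group_summary`` produces the arm x timepoint mean (SD) table for
every participant-level activity metric together with each arm's percent
change.  Percent change is computed on the cell means (the change of the
group mean), matching how trial tables usually print it; the mean of
individual percent changes is available via ``change_on='participants'``.

``run_pipeline`` wires the whole package together: read epochs and
manifest, apply wear validity, detect bouts, summarise participants, build
group and statistics tables, and write everything with a run log that
records criteria, exclusions and the number of tests performed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import metrics as metrics_mod
from . import stats as stats_mod
from .bouts import DEFAULT_DURATION_THRESHOLDS, IntensityThresholds
from .errors import InputError
from .io_epochs import ARMS, TIMEPOINTS, read_epoch_csv, read_manifest, reconcile
from .metrics import METRIC_COLUMNS, build_cohort_table, summarize_cohort
from .wear import ValidityCriteria

CLINICAL_FIELDS = ("age", "bmi", "fev1_pct_pred")

#: display rounding per metric family (underlying CSVs keep full precision)
_DISPLAY_DECIMALS = {"steps_per_day": 0, "daily_mets": 2, "pct_time_moderate": 2,
                     "mean_bout_length_min": 1, "total_mvpa_min": 1}


@dataclass
class PipelineConfig:
    """Everything configurable about an end-to-end run."""

    min_wear_hours: float = 8.0
    min_valid_days: int = 4
    met_light: float = 1.5
    met_moderate: float = 3.0
    met_vigorous: float = 6.0
    bout_thresholds: tuple[int, ...] = DEFAULT_DURATION_THRESHOLDS
    max_break_min: int = 0
    alpha: float = 0.05
    change_on: str = "group_means"
    correlation_pa_field: str = "bouts_10"

    @property
    def criteria(self) -> ValidityCriteria:
        return ValidityCriteria(int(round(self.min_wear_hours * 60)),
                                self.min_valid_days)

    @property
    def thresholds(self) -> IntensityThresholds:
        return IntensityThresholds(self.met_light, self.met_moderate,
                                   self.met_vigorous, self.met_vigorous)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise InputError(f"unknown config key(s): {sorted(unknown)}")
        if "bout_thresholds" in raw:
            raw["bout_thresholds"] = tuple(int(x) for x in raw["bout_thresholds"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["bout_thresholds"] = list(self.bout_thresholds)
        return d


def build_group_summary(cohort: pd.DataFrame,
                        metric_columns: Sequence[str] | None = None,
                        change_on: str = "group_means") -> pd.DataFrame:
    """Arm x timepoint mean/SD for each metric, with per-arm percent change.

    One row per (metric, arm).  SD is NaN (flagged in the ``note`` column)
    when a cell has fewer than two participants; an absent cell leaves its
    columns NaN and the run continues.
    """
    if cohort.empty:
        raise InputError("cohort table is empty")
    if change_on not in ("group_means", "participants"):
        raise InputError("change_on must be 'group_means' or 'participants'")
    if metric_columns is None:
        metric_columns = [c for c in METRIC_COLUMNS if c in cohort.columns] + \
            [c for c in cohort.columns
             if c.startswith("bouts_") and c not in METRIC_COLUMNS]
        metric_columns = list(dict.fromkeys(
            c for c in cohort.columns if c in metric_columns))
    rows = []
    for metric in metric_columns:
        for arm in ARMS:
            sub = cohort.loc[cohort["arm"] == arm]
            if sub.empty:
                continue
            row: dict = {"metric": metric, "arm": arm}
            note = []
            for tp in TIMEPOINTS:
                vals = sub.loc[sub["timepoint"] == tp, metric].dropna()
                row[f"{tp}_n"] = int(vals.size)
                row[f"{tp}_mean"] = float(vals.mean()) if vals.size else np.nan
                if vals.size >= 2:
                    row[f"{tp}_sd"] = float(vals.std(ddof=1))
                else:
                    row[f"{tp}_sd"] = np.nan
                    note.append(f"SD undefined at {tp} (n={vals.size})")
            row["abs_change"] = row["discharge_mean"] - row["baseline_mean"]
            row["pct_change"] = _percent_change_cell(sub, metric, change_on, note)
            row["note"] = "; ".join(note)
            rows.append(row)
    return pd.DataFrame(rows)


def _percent_change_cell(sub: pd.DataFrame, metric: str, change_on: str,
                         note: list) -> float:
    try:
        if change_on == "group_means":
            base = sub.loc[sub["timepoint"] == "baseline", metric].dropna()
            disc = sub.loc[sub["timepoint"] == "discharge", metric].dropna()
            if base.empty or disc.empty:
                raise InputError("missing cell")
            return metrics_mod.percent_change(float(base.mean()),
                                              float(disc.mean()))
        wide = sub.pivot_table(index="participant_id", columns="timepoint",
                               values=metric).dropna()
        changes = [metrics_mod.percent_change(b, d)
                   for b, d in zip(wide["baseline"], wide["discharge"])
                   if b > 0]
        if not changes:
            raise InputError("no usable pairs")
        return float(np.mean(changes))
    except InputError as exc:
        note.append(f"percent change undefined: {exc}")
        return np.nan


def render_group_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Display-rounded copy of a group summary (steps to integers, METs and
    bout metrics to 1-2 decimals, percent change to whole percent)."""
    out = table.copy()

    def _round_row(r):
        dec = _DISPLAY_DECIMALS.get(r["metric"], 1)
        for col in ("baseline_mean", "baseline_sd", "discharge_mean",
                    "discharge_sd", "abs_change"):
            if pd.notna(r[col]):
                r[col] = round(r[col], dec) if dec else int(round(r[col]))
        if pd.notna(r["pct_change"]):
            r["pct_change"] = int(round(r["pct_change"]))
        return r
    return out.apply(_round_row, axis=1)


def build_stats_table(cohort: pd.DataFrame, config: PipelineConfig,
                      metric_columns: Sequence[str] | None = None) -> pd.DataFrame:
    """All trial tests on a cohort table, one row per test.

    Per metric: within-arm paired t tests, the between-arm baseline
    independent t, and the three mixed-ANOVA effects; plus the Spearman
    screen of clinical covariates against the configured activity metric
    at each timepoint.  No multiplicity adjustment is applied.
    """
    if metric_columns is None:
        metric_columns = [c for c in cohort.columns if c in METRIC_COLUMNS
                          or (c.startswith("bouts_") and
                              cohort[c].dtype.kind in "fi")]
    rows = []

    def add(scope: str, metric: str, res: stats_mod.StatResult):
        df1, df2 = (res.df if isinstance(res.df, tuple) else (res.df, np.nan))
        rows.append({"family": res.test_name, "metric": metric, "scope": scope,
                     "estimate": res.estimate, "statistic": res.statistic,
                     "df1": df1, "df2": df2, "p": res.p_two_sided,
                     "p_display": res.p_display, "note": res.note})

    for metric in metric_columns:
        for arm in ARMS:
            sub = cohort.loc[cohort["arm"] == arm]
            wide = sub.pivot_table(index="participant_id", columns="timepoint",
                                   values=metric).dropna()
            if len(wide) >= 2:
                add(arm, metric, stats_mod.paired_t(
                    wide["baseline"], wide["discharge"], alpha=config.alpha))
        base = cohort.loc[cohort["timepoint"] == "baseline"]
        a = base.loc[base["arm"] == "web", metric].dropna()
        b = base.loc[base["arm"] == "conventional", metric].dropna()
        if len(a) >= 2 and len(b) >= 2:
            add("baseline_between_arms", metric,
                stats_mod.independent_t(a, b, alpha=config.alpha))
        try:
            anova = stats_mod.mixed_anova(cohort, metric, alpha=config.alpha)
            for effect, res in anova.items():
                add(f"anova_{effect}", metric, res)
        except InputError:
            pass

    if config.correlation_pa_field not in cohort.columns:
        return pd.DataFrame(rows)
    for tp in TIMEPOINTS:
        screen = stats_mod.correlation_screen(
            cohort, CLINICAL_FIELDS, config.correlation_pa_field, tp,
            alpha=config.alpha)
        for _, r in screen.iterrows():
            rows.append({"family": "spearman", "metric": r["pa_field"],
                         "scope": f"{tp}:{r['clinical_field']}",
                         "estimate": r["rho"], "statistic": r["statistic"],
                         "df1": r["df"], "df2": np.nan, "p": r["p"],
                         "p_display": r["p_display"], "note": r["note"]})
    return pd.DataFrame(rows)


def run_pipeline(epochs_path, manifest_path, config: PipelineConfig | None = None,
                 out_dir="results") -> dict[str, Path]:
    """End-to-end run: epochs + manifest in, four artefacts out.

    Writes ``participant_summaries.csv`` (per participant-timepoint, joined
    with arm and covariates), ``group_summary.csv``, ``stats.csv`` and
    ``run_log.json``.  Outputs are deterministic for identical inputs and
    configuration.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    epochs = read_epoch_csv(epochs_path)
    manifest = read_manifest(manifest_path)
    recon = reconcile(epochs, manifest)

    summary_frame, exclusions = summarize_cohort(
        epochs, config.thresholds, config.criteria, config.bout_thresholds,
        config.max_break_min)
    cohort = build_cohort_table(summary_frame, manifest)
    if cohort.empty:
        raise InputError("no participant passed wear validity; nothing to report")

    group_summary = build_group_summary(cohort, change_on=config.change_on)
    stats_table = build_stats_table(cohort, config)

    paths = {
        "participant_summaries": out / "participant_summaries.csv",
        "group_summary": out / "group_summary.csv",
        "stats": out / "stats.csv",
        "run_log": out / "run_log.json",
    }
    cohort.to_csv(paths["participant_summaries"], index=False)
    group_summary.to_csv(paths["group_summary"], index=False)
    stats_table.to_csv(paths["stats"], index=False)

    log = {
        "config": config.to_dict(),
        "n_epoch_rows": int(len(epochs)),
        "n_malformed_rows": int(epochs.attrs.get("n_malformed", 0)),
        "reconciliation": recon,
        "included_participant_timepoints": int(len(cohort)),
        "exclusions": {f"{pid}:{tp}": reason
                       for (pid, tp), reason in sorted(exclusions.items())},
        "n_tests_performed": int(len(stats_table)),
        "alpha": config.alpha,
        "multiple_testing_adjustment": "none",
    }
    with open(paths["run_log"], "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return paths
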