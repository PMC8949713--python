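"""Trial statistics: t tests, mixed-design ANOVA, Spearman correlation.

All tests are implemented from their sum-of-squares / closed-form
definitions (only the reference distributions come from scipy):

* ``independent_t`` — classical pooled-variance Student t (a Welch option
  is exposed), two-sided.
* ``paired_t`` — one-sample t on within-participant differences.
* ``mixed_anova`` — two-way mixed design with one between-subjects factor
  (trial arm) and one within-subjects factor (timepoint).  The total sum
  of squares is partitioned into between-subjects {group,
  subjects-within-group} and within-subjects {time, group x time,
  time x subjects-within-group} strata.  With two within levels sphericity
  holds trivially, and the interaction F equals the squared pooled t on
  change scores.
* ``spearman`` — Pearson correlation of mid-ranks (tie-aware), with the
  two-sided p from the t approximation t = rho * sqrt((n-2)/(1-rho^2)).

Zero-variance degenerate inputs yield flagged conventional results
(t = 0, p = 1 for identical groups; p = 0 for a nonzero difference with no
spread) rather than NaNs.  No multiple-testing adjustment is applied; the
reporting layer prints the number of tests performed alongside alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError, UndefinedStatisticError

DEFAULT_ALPHA = 0.05


@dataclass
class StatResult:
    """One hypothesis test: estimate, statistic, df, two-sided p."""

    test_name: str
    estimate: float
    statistic: float
    df: float | tuple[float, float]
    p_two_sided: float
    alpha: float = DEFAULT_ALPHA
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.p_two_sided < self.alpha

    @property
    def p_display(self) -> str:
        return format_p(self.p_two_sided)


def format_p(p: float) -> str:
    """Three-decimal p with the '<.001' convention."""
    if np.isnan(p):
        return "NA"
    if p < 0.001:
        return "<.001"
    return f"{p:.3f}".lstrip("0")


def _check_sample(x, name: str, min_n: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InputError(f"{name} must be one-dimensional")
    arr = arr[~np.isnan(arr)]
    if arr.size < min_n:
        raise InputError(f"{name} needs at least {min_n} observations, "
                         f"got {arr.size}")
    return arr


def independent_t(group_a, group_b, welch: bool = False,
                  alpha: float = DEFAULT_ALPHA) -> StatResult:
    """Two-sided two-sample t test (pooled-variance Student by default)."""
    a = _check_sample(group_a, "group_a", 2)
    b = _check_sample(group_b, "group_b", 2)
    na, nb = a.size, b.size
    diff = a.mean() - b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0:
            return _degenerate_t("independent_t_welch", diff, float(na + nb - 2),
                                 alpha)
        t = diff / np.sqrt(se2)
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        name = "independent_t_welch"
    else:
        df = float(na + nb - 2)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        if sp2 == 0:
            return _degenerate_t("independent_t", diff, df, alpha)
        t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        name = "independent_t"
    p = 2.0 * sps.t.sf(abs(t), df)
    return StatResult(name, float(diff), float(t), float(df), float(p), alpha)


def _degenerate_t(name: str, diff: float, df: float, alpha: float) -> StatResult:
    if diff == 0:
        return StatResult(name, 0.0, 0.0, df, 1.0, alpha,
                          note="zero variance, equal means: p=1 by convention")
    stat = np.inf if diff > 0 else -np.inf
    return StatResult(name, float(diff), float(stat), df, 0.0, alpha,
                      note="zero variance, nonzero difference: p=0 by convention")


def paired_t(before, after, alpha: float = DEFAULT_ALPHA) -> StatResult:
    """Two-sided paired t test: one-sample t on after - before."""
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if a.shape != b.shape:
        raise InputError("paired_t requires equal-length, aligned samples")
    keep = ~(np.isnan(a) | np.isnan(b))
    d = (a - b)[keep]
    if d.size < 2:
        raise InputError("paired_t needs at least 2 complete pairs")
    mean_d = d.mean()
    sd = d.std(ddof=1)
    df = float(d.size - 1)
    if sd == 0:
        return _degenerate_t("paired_t", float(mean_d), df, alpha)
    t = mean_d / (sd / np.sqrt(d.size))
    p = 2.0 * sps.t.sf(abs(t), df)
    return StatResult("paired_t", float(mean_d), float(t), df, float(p), alpha)


# ---------------------------------------------------------------------------
# mixed-design ANOVA


def mixed_anova_arrays(y: np.ndarray, groups: np.ndarray,
                       alpha: float = DEFAULT_ALPHA) -> dict[str, StatResult]:
    """Mixed ANOVA on a complete wide array.

    `y` is an (n_subjects, n_time_levels) matrix of the outcome and
    `groups` labels each subject's between-subjects level.  Returns the
    three named effects {group, time, interaction}.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise InputError("y must be (n_subjects, n_time_levels>=2)")
    if np.isnan(y).any():
        raise InputError("mixed_anova_arrays requires complete data")
    groups = np.asarray(groups)
    labels, g_idx = np.unique(groups, return_inverse=True)
    n_groups = labels.size
    n, k = y.shape
    if n_groups < 2:
        raise InputError("need at least two between-subject groups")
    counts = np.bincount(g_idx)
    if (counts < 2).any():
        raise InputError("each group needs at least two subjects")

    grand = y.mean()
    subj_means = y.mean(axis=1)                       # n
    time_means = y.mean(axis=0)                       # k
    group_means = np.array([subj_means[g_idx == g].mean()
                            for g in range(n_groups)])
    cell_means = np.vstack([y[g_idx == g].mean(axis=0)
                            for g in range(n_groups)])  # G x k

    ss_group = k * float(np.sum(counts * (group_means - grand) ** 2))
    ss_subj = k * float(np.sum((subj_means - group_means[g_idx]) ** 2))
    ss_time = n * float(np.sum((time_means - grand) ** 2))
    inter = cell_means - group_means[:, None] - time_means[None, :] + grand
    ss_inter = float(np.sum(counts[:, None] * inter ** 2))
    resid = y - subj_means[:, None] - cell_means[g_idx] + group_means[g_idx, None]
    ss_err = float(np.sum(resid ** 2))

    df_group, df_subj = n_groups - 1.0, float(n - n_groups)
    df_time = k - 1.0
    df_inter = (n_groups - 1.0) * (k - 1.0)
    df_err = (n - n_groups) * (k - 1.0)

    def effect(name, ss, df_num, ss_denom, df_denom):
        ms_num = ss / df_num
        ms_den = ss_denom / df_denom
        if ms_den == 0:
            f = 0.0 if ms_num == 0 else np.inf
            p = 1.0 if ms_num == 0 else 0.0
            note = "zero error variance: conventional result"
        else:
            f = ms_num / ms_den
            p = float(sps.f.sf(f, df_num, df_denom))
            note = ""
        return StatResult(f"mixed_anova_{name}", float(f), float(f),
                          (df_num, df_denom), float(p), alpha, note)

    return {
        "group": effect("group", ss_group, df_group, ss_subj, df_subj),
        "time": effect("time", ss_time, df_time, ss_err, df_err),
        "interaction": effect("interaction", ss_inter, df_inter, ss_err, df_err),
    }


def mixed_anova(cohort: pd.DataFrame, outcome: str,
                subject: str = "participant_id", group: str = "arm",
                time: str = "timepoint", strict: bool = False,
                alpha: float = DEFAULT_ALPHA) -> dict[str, StatResult]:
    """Two-way mixed ANOVA on a long-format cohort table.

    Participants missing a timepoint (or with a missing outcome value) are
    dropped with a warning under the default complete-case policy, or raise
    under ``strict=True``.
    """
    needed = {subject, group, time, outcome}
    missing = needed - set(cohort.columns)
    if missing:
        raise InputError(f"cohort is missing column(s): {sorted(missing)}")
    wide = cohort.pivot_table(index=subject, columns=time, values=outcome,
                              aggfunc="mean")
    arm_of = cohort.drop_duplicates(subject).set_index(subject)[group]
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        if strict:
            raise InputError(f"{n_dropped} participant(s) lack complete "
                             f"{outcome} data at both timepoints")
        warnings.warn(f"dropping {n_dropped} participant(s) without complete "
                      f"{outcome} data (complete-case analysis)")
    # order time levels canonically if they are the standard pair
    cols = list(complete.columns)
    if set(cols) == {"baseline", "discharge"}:
        complete = complete[["baseline", "discharge"]]
    return mixed_anova_arrays(complete.to_numpy(),
                              arm_of.loc[complete.index].to_numpy(), alpha)


# ---------------------------------------------------------------------------
# rank correlation


def _midranks(x: np.ndarray) -> np.ndarray:
    """Mid-ranks (average rank over ties), 1-based."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(x.size, dtype=float)
    sx = x[order]
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman(x, y, alpha: float = DEFAULT_ALPHA) -> StatResult:
    """Spearman rank correlation with mid-rank tie handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("spearman requires equal-length samples")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise InputError("spearman needs at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError(
            "spearman undefined for a constant sample")
    rx, ry = _midranks(x), _midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    rho = float(np.clip(rho, -1.0, 1.0))
    df = float(n - 2)
    if abs(rho) == 1.0:
        return StatResult("spearman", rho, np.inf if rho > 0 else -np.inf,
                          df, 0.0, alpha, note="perfect monotone association")
    t = rho * np.sqrt(df / (1.0 - rho ** 2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return StatResult("spearman", rho, float(t), df, float(p), alpha)


def correlation_screen(cohort: pd.DataFrame, clinical_fields: Sequence[str],
                       pa_field: str, timepoint: str,
                       alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Spearman screen of clinical covariates against one activity metric.

    Arms are pooled.  A covariate for which the correlation is undefined
    (constant input, too few pairs) yields a row with NaN estimates and an
    explanatory note instead of aborting the screen.
    """
    sub = cohort.loc[cohort["timepoint"] == timepoint]
    rows = []
    for fieldname in clinical_fields:
        row = {"timepoint": timepoint, "clinical_field": fieldname,
               "pa_field": pa_field}
        try:
            if fieldname not in sub.columns:
                raise InputError(f"cohort lacks column {fieldname}")
            res = spearman(sub[fieldname], sub[pa_field], alpha)
            pair_n = int((~(sub[fieldname].isna() | sub[pa_field].isna())).sum())
            row.update(n=pair_n, rho=res.estimate, statistic=res.statistic,
                       df=res.df, p=res.p_two_sided, p_display=res.p_display,
                       note=res.note)
        except (InputError, UndefinedStatisticError) as exc:
            row.update(n=int(len(sub)), rho=np.nan, statistic=np.nan,
                       df=np.nan, p=np.nan, p_display="NA", note=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)


def type_one_error_rates(n_reps: int = 2000, n_a: int = 20, n_b: int = 34,
                         alpha: float = DEFAULT_ALPHA,
                         seed: int = 0) -> dict[str, float]:
    """Empirical rejection rates of the three tests under a two-arm null.

    Each replicate draws a two-arm, two-timepoint cohort with a shared
    subject random effect and no group, time or interaction effect, then
    applies the paired t (arm A, before vs after), the independent t
    (baseline, arm A vs arm B) and the mixed-ANOVA interaction.  Rates
    should sit near alpha for calibrated tests.
    """
    rng = np.random.default_rng(seed)
    groups = np.repeat([0, 1], [n_a, n_b])
    hits = {"paired_t": 0, "independent_t": 0, "anova_interaction": 0}
    for _ in range(n_reps):
        subj = rng.normal(0.0, 1.0, n_a + n_b)
        noise = rng.normal(0.0, 1.0, (n_a + n_b, 2))
        y = subj[:, None] + noise
        hits["paired_t"] += paired_t(y[:n_a, 0], y[:n_a, 1]).significant
        hits["independent_t"] += independent_t(y[:n_a, 0], y[n_a:, 0]).significant
        res = mixed_anova_arrays(y, groups, alpha)
        hits["anova_interaction"] += res["interaction"].significant
    return {k: v / n_reps for k, v in hits.items()}
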