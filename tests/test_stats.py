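import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from boutscan.errors import InputError, UndefinedStatisticError
from boutscan.stats import (correlation_screen, format_p, independent_t,
                            mixed_anova, mixed_anova_arrays, paired_t,
                            spearman)


def _cohort_frame(y, groups, subjects=None):
    n = len(groups)
    subjects = subjects or [f"S{i}" for i in range(n)]
    rows = []
    for i in range(n):
        rows.append({"participant_id": subjects[i], "arm": groups[i],
                     "timepoint": "baseline", "y": y[i][0]})
        rows.append({"participant_id": subjects[i], "arm": groups[i],
                     "timepoint": "discharge", "y": y[i][1]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- t tests


def test_identical_groups_give_t0_p1():
    res = independent_t([1, 2, 3], [1, 2, 3])
    assert res.statistic == 0.0 and res.p_two_sided == 1.0


def test_degenerate_zero_variance_conventions():
    res = independent_t([0, 0, 0, 0], [1, 1, 1, 1])
    assert res.p_two_sided == 0.0 and "zero variance" in res.note
    same = paired_t([3, 3, 3], [3, 3, 3])
    assert same.statistic == 0.0 and same.p_two_sided == 1.0
    shifted = paired_t([1, 2, 3], [2, 3, 4])
    assert shifted.p_two_sided == 0.0 and "zero variance" in shifted.note


@settings(max_examples=100, derandomize=True)
@given(st.integers(0, 10_000))
def test_independent_t_matches_reference(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, rng.integers(2, 30))
    b = rng.normal(0.3, 1.5, rng.integers(2, 30))
    ours = independent_t(a, b)
    ref = sps.ttest_ind(a, b, equal_var=True)
    assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
    assert ours.p_two_sided == pytest.approx(ref.pvalue, abs=1e-10)
    ours_w = independent_t(a, b, welch=True)
    ref_w = sps.ttest_ind(a, b, equal_var=False)
    assert ours_w.statistic == pytest.approx(ref_w.statistic, abs=1e-10)
    assert ours_w.p_two_sided == pytest.approx(ref_w.pvalue, abs=1e-10)


@settings(max_examples=100, derandomize=True)
@given(st.integers(0, 10_000))
def test_paired_t_matches_reference(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 25))
    before = rng.normal(0, 1, n)
    after = before + rng.normal(0.2, 0.7, n)
    ours = paired_t(before, after)
    ref = sps.ttest_rel(after, before)
    assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
    assert ours.p_two_sided == pytest.approx(ref.pvalue, abs=1e-10)


def test_independent_t_power_against_noncentral_closed_form():
    """Planted-shift rejection rate matches noncentral-t power."""
    rng = np.random.default_rng(2024)
    n_a, n_b, delta, reps = 12, 15, 1.0, 2000
    rejections = sum(
        independent_t(rng.normal(0, 1, n_a),
                      rng.normal(delta, 1, n_b)).significant
        for _ in range(reps))
    df = n_a + n_b - 2
    ncp = delta / np.sqrt(1 / n_a + 1 / n_b)
    crit = sps.t.ppf(0.975, df)
    power = sps.nct.sf(crit, df, ncp) + sps.nct.cdf(-crit, df, ncp)
    se = np.sqrt(power * (1 - power) / reps)
    assert rejections / reps == pytest.approx(power, abs=4 * se)


def test_input_validation():
    with pytest.raises(InputError):
        independent_t([1.0], [1, 2, 3])
    with pytest.raises(InputError):
        paired_t([1, 2, 3], [1, 2])


# ---------------------------------------------------------- mixed ANOVA


def test_zero_noise_parallel_arms_have_zero_interaction():
    y = np.array([[0.0, 1.0], [2.0, 3.0], [1.0, 2.0], [4.0, 5.0]])
    res = mixed_anova_arrays(y, ["a", "a", "b", "b"])
    assert res["interaction"].statistic == pytest.approx(0.0, abs=1e-12)
    assert res["time"].p_two_sided < 0.05  # everyone rises by exactly 1


@pytest.mark.parametrize("n_a,n_b,seed", [(8, 8, 0), (6, 11, 1), (20, 34, 2)])
def test_mixed_anova_matches_pingouin(n_a, n_b, seed):
    rng = np.random.default_rng(seed)
    n = n_a + n_b
    y = rng.normal(0, 1, (n, 2)) + rng.normal(0, 1, n)[:, None]
    groups = np.array(["a"] * n_a + ["b"] * n_b)
    cohort = _cohort_frame(y, groups)
    ours = mixed_anova(cohort, "y")
    ref = pg.mixed_anova(cohort, dv="y", within="timepoint",
                         subject="participant_id", between="arm")
    ref = ref.set_index("Source")
    assert ours["group"].statistic == pytest.approx(ref.loc["arm", "F"],
                                                    rel=1e-9)
    assert ours["time"].statistic == pytest.approx(ref.loc["timepoint", "F"],
                                                   rel=1e-9)
    assert ours["interaction"].statistic == pytest.approx(
        ref.loc["Interaction", "F"], rel=1e-9)
    assert ours["interaction"].p_two_sided == pytest.approx(
        ref.loc["Interaction", "p_unc"], rel=1e-9)


@settings(max_examples=100, derandomize=True)
@given(st.integers(0, 10_000))
def test_interaction_equals_change_score_t_squared(seed):
    rng = np.random.default_rng(seed)
    n_a = int(rng.integers(3, 15))
    n_b = int(rng.integers(3, 15))
    y = rng.normal(0, 1, (n_a + n_b, 2))
    groups = np.repeat(["a", "b"], [n_a, n_b])
    res = mixed_anova_arrays(y, groups)
    d = y[:, 1] - y[:, 0]
    t = independent_t(d[:n_a], d[n_a:])
    assert res["interaction"].statistic == pytest.approx(t.statistic ** 2,
                                                         abs=1e-10)
    assert res["interaction"].p_two_sided == pytest.approx(t.p_two_sided,
                                                           abs=1e-10)


def test_mixed_anova_drops_incomplete_participants():
    y = np.random.default_rng(5).normal(0, 1, (8, 2))
    cohort = _cohort_frame(y, ["a"] * 4 + ["b"] * 4)
    cohort = cohort.drop(cohort.index[-1])  # S7 loses discharge
    with pytest.warns(UserWarning, match="complete-case"):
        res = mixed_anova(cohort, "y")
    assert res["group"].df == (1.0, 5.0)  # 7 subjects, 2 groups
    with pytest.raises(InputError):
        mixed_anova(cohort, "y", strict=True)


# -------------------------------------------------------------- spearman


def test_monotone_relationship_is_perfect():
    res = spearman([1, 2, 3, 5], [10, 20, 21, 400])
    assert res.estimate == 1.0 and res.p_two_sided == 0.0


def test_hand_ranked_example():
    res = spearman([1, 2, 3, 4], [2, 1, 4, 3])
    assert res.estimate == pytest.approx(0.6)


def test_constant_input_is_undefined():
    with pytest.raises(UndefinedStatisticError):
        spearman([1, 1, 1, 1], [1, 2, 3, 4])


def brute_force_spearman(x, y):
    def midranks(v):
        v = np.asarray(v, float)
        return np.array([(np.sum(v < vi) + 1 + np.sum(v <= vi)) / 2 for vi in v])
    rx, ry = midranks(x), midranks(y)
    return np.corrcoef(rx, ry)[0, 1]


@settings(max_examples=100, derandomize=True)
@given(st.integers(0, 10_000))
def test_spearman_matches_midrank_brute_force_with_ties(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 30))
    x = rng.integers(0, 5, n).astype(float)   # heavy ties
    y = x + rng.integers(-2, 3, n)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return
    res = spearman(x, y)
    assert res.estimate == pytest.approx(brute_force_spearman(x, y), abs=1e-12)
    ref = sps.spearmanr(x, y)
    assert res.estimate == pytest.approx(ref.statistic, abs=1e-12)


@settings(max_examples=50, derandomize=True)
@given(st.integers(0, 10_000))
def test_spearman_invariant_under_monotone_transforms(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, 20)
    y = rng.normal(0, 1, 20)
    base = spearman(x, y)
    transformed = spearman(np.exp(x), 3 * y - 7)
    assert transformed.estimate == pytest.approx(base.estimate, abs=1e-12)
    assert transformed.p_two_sided == pytest.approx(base.p_two_sided, abs=1e-12)


def test_correlation_screen_flags_planted_signal():
    rng = np.random.default_rng(9)
    n = 60
    age = rng.uniform(55, 80, n)
    bmi = rng.uniform(20, 40, n)
    fev1 = rng.uniform(30, 90, n)
    bouts = -0.35 * age + rng.normal(0, 2.0, n) + 30  # monotone in age only
    cohort = pd.DataFrame({
        "participant_id": [f"P{i}" for i in range(n)],
        "timepoint": "baseline", "arm": "web",
        "age": age, "bmi": bmi, "fev1_pct_pred": fev1, "bouts_10": bouts})
    screen = correlation_screen(cohort, ("age", "bmi", "fev1_pct_pred"),
                                "bouts_10", "baseline")
    by_field = screen.set_index("clinical_field")
    assert by_field.loc["age", "p"] < 0.05 and by_field.loc["age", "rho"] < 0
    assert by_field.loc["bmi", "p"] > 0.05
    assert by_field.loc["fev1_pct_pred", "p"] > 0.05


def test_correlation_screen_survives_constant_field():
    cohort = pd.DataFrame({
        "participant_id": list("abcd"), "timepoint": "baseline",
        "age": [60, 61, 62, 63], "bmi": [25, 25, 25, 25],
        "fev1_pct_pred": [50, 55, 60, 65], "bouts_10": [1, 1, 1, 1]})
    screen = correlation_screen(cohort, ("age", "bmi"), "bouts_10", "baseline")
    assert screen["rho"].isna().all()
    assert (screen["p_display"] == "NA").all()


def test_p_display_conventions():
    assert format_p(0.0004) == "<.001"
    assert format_p(0.049) == ".049"
    assert format_p(0.2) == ".200"
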