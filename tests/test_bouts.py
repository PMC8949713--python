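import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boutscan.bouts import (Bout, IntensityThresholds, bout_spectrum,
                            classify_epoch, classify_epochs, detect_bouts)
from boutscan.errors import (InputError, UndefinedSpectrumError)

from conftest import make_day


def brute_force_bouts(mets, worn, thresholds=None):
    """Quadratic oracle: a bout is any interval that is all-MVPA, all-worn,
    contiguous, and maximal. Returns (start_index, length) pairs."""
    thr = thresholds or IntensityThresholds()

    def is_mvpa(i):
        if not worn[i]:
            return False
        m = mets[i]
        return (thr.moderate_min <= m <= thr.moderate_max) or m > thr.vigorous_min

    n = len(mets)
    out = []
    for i in range(n):
        for j in range(i, n):
            if not all(is_mvpa(k) for k in range(i, j + 1)):
                continue
            left_max = i == 0 or not is_mvpa(i - 1)
            right_max = j == n - 1 or not is_mvpa(j + 1)
            if left_max and right_max:
                out.append((i, j - i + 1))
    return out


@pytest.mark.parametrize("mets,expected", [
    (6.0, "moderate"), (6.01, "vigorous"), (3.0, "moderate"),
    (2.99, "light"), (1.5, "sedentary_or_below"), (1.51, "light"),
    (0.0, "sedentary_or_below"), (10.0, "vigorous"),
])
def test_met_cut_points(mets, expected):
    """Moderate is the closed band [3, 6]; light and vigorous bounds are open."""
    assert classify_epoch(mets) == expected
    assert classify_epochs(np.array([mets]))[0] == expected


def test_negative_mets_rejected():
    with pytest.raises(InputError):
        classify_epoch(-0.1)


def test_invalid_threshold_ordering_rejected():
    with pytest.raises(InputError):
        IntensityThresholds(moderate_min=7.0)


def test_hand_checked_run_scan():
    day = make_day([2, 4, 4, 2, 4, 4, 4, 2])
    bouts = detect_bouts(day)
    assert [b.duration_min for b in bouts] == [2, 3]
    assert bouts[0].mean_mets == 4.0


def test_all_light_day_has_no_bouts():
    day = make_day([2.0] * 30)
    assert detect_bouts(day) == []


def test_single_long_block_counts_at_every_threshold():
    day = make_day([1.0] * 5 + [3.5] * 25 + [1.0] * 5)
    bouts = detect_bouts(day)
    assert len(bouts) == 1 and bouts[0].duration_min == 25
    spec = bout_spectrum(bouts, n_valid_days=1)
    assert spec.counts_per_day == {2: 1.0, 5: 1.0, 10: 1.0, 20: 1.0}


def test_vigorous_epochs_do_not_break_a_bout():
    day = make_day([4.0, 8.0, 4.0])
    bouts = detect_bouts(day)
    assert [b.duration_min for b in bouts] == [3]


def test_timestamp_gap_breaks_a_run():
    day = make_day([4.0] * 6)
    day = day.drop(index=3).reset_index(drop=True)  # missing minute
    bouts = detect_bouts(day)
    assert sorted(b.duration_min for b in bouts) == [2, 3]


def test_unordered_epochs_rejected():
    day = make_day([4.0] * 4).iloc[::-1].reset_index(drop=True)
    with pytest.raises(InputError, match="ordered"):
        detect_bouts(day)


def test_break_tolerance_merges_runs():
    day = make_day([4, 4, 2, 4, 4])
    assert [b.duration_min for b in detect_bouts(day)] == [2, 2]
    merged = detect_bouts(day, max_break_min=1)
    # duration counts MVPA minutes only
    assert [b.duration_min for b in merged] == [4]


def test_break_tolerance_does_not_merge_across_nonwear():
    worn = [True, True, False, True, True]
    day = make_day([4, 4, 2, 4, 4], worn=worn)
    assert [b.duration_min for b in detect_bouts(day, max_break_min=1)] == [2, 2]


def test_spectrum_hand_count():
    bouts = [Bout("P", "baseline", None, d, 4.0) for d in (2, 3, 25)]
    spec = bout_spectrum(bouts, n_valid_days=1)
    assert spec.counts_per_day == {2: 3.0, 5: 1.0, 10: 1.0, 20: 1.0}
    assert spec.mean_bout_length_min == 10.0
    assert spec.total_mvpa_min == 30.0


def test_spectrum_no_bouts_flagged():
    spec = bout_spectrum([], n_valid_days=3)
    assert spec.no_bouts
    assert spec.mean_bout_length_min == 0.0
    assert all(v == 0.0 for v in spec.counts_per_day.values())


def test_spectrum_zero_valid_days_is_an_error():
    with pytest.raises(UndefinedSpectrumError):
        bout_spectrum([], n_valid_days=0)


@settings(max_examples=200, derandomize=True)
@given(st.lists(st.floats(0, 12, allow_nan=False), min_size=0, max_size=60),
       st.data())
def test_detector_matches_quadratic_oracle(mets, data):
    worn = data.draw(st.lists(st.booleans(), min_size=len(mets),
                              max_size=len(mets)))
    day = make_day(mets, worn=worn) if mets else None
    detected = detect_bouts(day) if day is not None else []
    expected = brute_force_bouts(mets, worn)
    assert [(b.duration_min) for b in detected] == [l for _, l in expected]
    # spectrum monotonicity + duration-sum conservation on the same input
    if detected:
        spec = bout_spectrum(detected, n_valid_days=1)
        counts = [spec.counts_per_day[d] for d in (2, 5, 10, 20)]
        assert counts == sorted(counts, reverse=True)
        assert spec.total_mvpa_min == sum(b.duration_min for b in detected)


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.floats(0, 12, allow_nan=False), min_size=5, max_size=40),
       st.data())
def test_nonworn_met_values_are_irrelevant(mets, data):
    worn = data.draw(st.lists(st.booleans(), min_size=len(mets),
                              max_size=len(mets)))
    day = make_day(mets, worn=worn)
    reference = [(b.start, b.duration_min) for b in detect_bouts(day)]
    scrambled = np.asarray(mets, float).copy()
    rng = np.random.default_rng(0)
    idx = np.flatnonzero(~np.asarray(worn))
    scrambled[idx] = rng.uniform(0, 12, idx.size)
    day2 = make_day(scrambled, worn=worn)
    assert [(b.start, b.duration_min) for b in detect_bouts(day2)] == reference
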