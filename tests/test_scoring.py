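"""Sleep/wake scoring, night summaries, and both composite metrics."""

from datetime import datetime

import numpy as np
import pytest

from actisleep import scoring, synth
from actisleep.config import ScoringConfig
from actisleep.types import ActigraphyRecord, NightSummary, ParameterError

START = datetime(2024, 1, 1, 12, 0)


def rec(counts):
    counts = np.asarray(counts, dtype=float)
    return ActigraphyRecord("P", START, counts, np.zeros(counts.size, dtype=np.int8))


def night(duration=420.0, latency=10.0, waso=20.0, onset=23.5, idx=0):
    offset = (onset + (latency + duration + waso) / 60.0) % 24
    tib = latency + duration + waso
    return NightSummary(idx, onset, offset, duration, latency, waso,
                        100.0 * duration / tib, scoring.circular_midpoint(onset, offset))


# ---- epoch scoring ---------------------------------------------------------

def test_zero_counts_score_sleep_and_high_counts_wake():
    assert np.all(scoring.score_sleep_wake(rec(np.zeros(100))) == 1)
    assert np.all(scoring.score_sleep_wake(rec(np.full(100, 500.0))) == 0)


def test_scoring_rejects_gappy_or_short_records():
    with pytest.raises(ParameterError):
        scoring.score_sleep_wake(rec([np.nan] + [0] * 50))
    with pytest.raises(ParameterError):
        scoring.score_sleep_wake(rec([0, 0, 0]))


def test_sleep_onset_recovered_within_ten_minutes():
    rec_, gt = synth.generate_participant(synth.LOW_NOISE_PROFILE, 3, seed=5)
    nights, _ = scoring.summarize_record(rec_)
    by_idx = {n.night_index: n for n in nights}
    for g in gt.nights:
        n = by_idx[g.night_index]
        assert scoring.circular_diff_minutes(n.onset, g.onset) <= 10
        assert scoring.circular_diff_minutes(n.offset, g.offset) <= 10


# ---- night summaries -------------------------------------------------------

def test_all_asleep_interval():
    sw = np.ones(600, dtype=np.int8)
    s = scoring.summarize_night(sw, (60, 540), rec(np.zeros(600)), 0)
    assert (s.duration, s.efficiency, s.latency, s.waso) == (480.0, 100.0, 0.0, 0.0)


def test_fragmented_interval_hand_count():
    # 480-min interval: 20 wake, 300 sleep, 20 wake, 140 sleep
    sw = np.concatenate([np.zeros(20), np.ones(300), np.zeros(20), np.ones(140)]).astype(np.int8)
    s = scoring.summarize_night(sw, (0, 480), rec(np.zeros(480)), 0)
    assert s.latency == 20.0
    assert s.duration == 440.0
    assert s.waso == 20.0
    assert s.efficiency == pytest.approx(100 * 440 / 480, abs=0.01)  # 91.67


def test_interval_with_no_sleep():
    sw = np.zeros(480, dtype=np.int8)
    s = scoring.summarize_night(sw, (0, 480), rec(np.zeros(480)), 0)
    assert s.duration == 0.0 and s.efficiency == 0.0 and s.latency == 480.0


def test_midpoint_across_midnight():
    assert scoring.circular_midpoint(23.0, 7.0) == pytest.approx(3.0)
    assert scoring.circular_midpoint(22.0, 2.0) == pytest.approx(0.0)
    assert scoring.circular_midpoint(1.0, 9.0) == pytest.approx(5.0)


# ---- component subscores ---------------------------------------------------

@pytest.mark.parametrize(
    "component,value,expected",
    [
        ("efficiency", 95.0, 0), ("efficiency", 85.0, 0), ("efficiency", 84.9, 1),
        ("efficiency", 75.0, 1), ("efficiency", 70.0, 2), ("efficiency", 64.9, 3),
        ("latency", 10.0, 0), ("latency", 15.0, 0), ("latency", 16.0, 1),
        ("latency", 30.0, 1), ("latency", 45.0, 2), ("latency", 61.0, 3),
        ("duration", 450.0, 0), ("duration", 420.0, 0), ("duration", 400.0, 1),
        ("duration", 330.0, 2), ("duration", 200.0, 3),
        ("waso", 10.0, 0), ("waso", 30.0, 1), ("waso", 50.0, 2), ("waso", 90.0, 3),
    ],
)
def test_component_subscore_bands(component, value, expected):
    assert scoring.component_subscore(component, value) == expected


def test_component_subscore_rejects_unknown_and_negative():
    with pytest.raises(ParameterError):
        scoring.component_subscore("snoring", 1.0)
    with pytest.raises(ParameterError):
        scoring.component_subscore("latency", -1.0)


def test_subscores_monotone_in_value():
    cfg = ScoringConfig()
    for comp, worse_is_higher in [("latency", True), ("waso", True),
                                  ("efficiency", False), ("duration", False)]:
        values = np.linspace(0, 100 if comp == "efficiency" else 600, 200)
        scores = [scoring.component_subscore(comp, v, cfg) for v in values]
        diffs = np.diff(scores)
        assert np.all(diffs >= 0) if worse_is_higher else np.all(diffs <= 0)


# ---- weekly quality score --------------------------------------------------

def test_sqw_bounds_and_classes():
    good = [night(duration=460, latency=5, waso=5) for _ in range(7)]
    label = scoring.sleep_qual_week(good)
    assert label.score == 0.0 and label.class_id == 0
    bad = [night(duration=200, latency=90, waso=90) for _ in range(7)]
    label = scoring.sleep_qual_week(bad)
    assert label.score == 12.0 and label.class_id == 2


@pytest.mark.parametrize("score,cls", [(0, 0), (4, 0), (4.999, 0), (5, 1), (8, 1), (8.001, 2), (9, 2), (12, 2)])
def test_sqw_class_boundaries(score, cls):
    assert scoring.sqw_class(score) == cls


def test_sqw_requires_nights():
    with pytest.raises(ParameterError):
        scoring.sleep_qual_week([])


def test_sqw_monotone_under_degradation():
    base = [night(duration=400, latency=20, waso=25) for _ in range(7)]
    s0 = scoring.sleep_qual_week(base).score
    worse_latency = [night(duration=400, latency=70, waso=25) for _ in range(7)]
    worse_duration = [night(duration=280, latency=20, waso=25) for _ in range(7)]
    worse_waso = [night(duration=400, latency=20, waso=80) for _ in range(7)]
    for nights in (worse_latency, worse_duration, worse_waso):
        assert scoring.sleep_qual_week(nights).score >= s0


# ---- consistency score -----------------------------------------------------

def test_cons_zero_variance_is_class_zero():
    nights = [night(idx=i) for i in range(7)]
    day_types = ["weekday"] * 5 + ["weekend"] * 2
    label = scoring.sleep_cons(nights, day_types)
    assert label.score == pytest.approx(0.0, abs=1e-9)
    assert label.class_id == 0


@pytest.mark.parametrize("score,cls", [(0, 0), (49.99, 0), (50, 1), (100, 1), (199.99, 1),
                                       (200, 2), (250, 2), (399.99, 2), (400, 3), (450, 3)])
def test_cons_class_boundaries(score, cls):
    assert scoring.cons_class(score) == cls


def test_cons_weights_sum_to_score():
    # components (100, 100, 100) with weights (0.4, 0.3, 0.3) -> 100
    durations = [380, 480, 430, 330, 530, 430, 430]  # SD(ddof=1) about 65.6
    nights = [night(duration=d, idx=i, onset=23.0) for i, d in enumerate(durations)]
    day_types = ["weekday"] * 5 + ["weekend"] * 2
    label = scoring.sleep_cons(nights, day_types)
    sv = np.std(durations, ddof=1)
    mv = scoring.circular_sd_minutes(np.array([n.midpoint for n in nights]))
    wd = scoring.circular_diff_minutes(
        scoring.circular_mean_hours(np.array([n.midpoint for n in nights[:5]])),
        scoring.circular_mean_hours(np.array([n.midpoint for n in nights[5:]])),
    )
    assert label.score == pytest.approx(0.4 * sv + 0.3 * wd + 0.3 * mv)


def test_cons_requires_two_nights_and_warns_without_weekend():
    with pytest.raises(ParameterError):
        scoring.sleep_cons([night()], ["weekday"])
    nights = [night(duration=d, idx=i) for i, d in enumerate([400, 500, 420, 380])]
    label = scoring.sleep_cons(nights, ["weekday"] * 4)  # WeekendDiff -> 0
    sv = np.std([400, 500, 420, 380], ddof=1)
    mv = scoring.circular_sd_minutes(np.array([n.midpoint for n in nights]))
    assert label.score == pytest.approx(0.4 * sv + 0.3 * mv)


def test_cons_reorder_invariance_and_dispersion_scaling():
    rng = np.random.default_rng(1)
    durations = 420 + rng.normal(0, 60, 7)
    nights = [night(duration=d, idx=i) for i, d in enumerate(durations)]
    day_types = ["weekday"] * 5 + ["weekend"] * 2
    s1 = scoring.sleep_cons(nights, day_types).score
    perm = [nights[i] for i in [3, 1, 4, 0, 2, 6, 5]]
    pt = [day_types[i] for i in [3, 1, 4, 0, 2, 6, 5]]
    assert scoring.sleep_cons(perm, pt).score == pytest.approx(s1)
    doubled = [night(duration=420 + 2 * (d - 420), idx=i) for i, d in enumerate(durations)]
    s2 = scoring.sleep_cons(doubled, day_types).score
    # SleepVar doubles exactly; circular terms double to first order
    assert s2 >= 1.8 * s1


def test_circular_stats_basics():
    assert scoring.circular_diff_minutes(23.5, 0.5) == pytest.approx(60.0)
    assert scoring.circular_mean_hours(np.array([23.0, 1.0])) == pytest.approx(0.0, abs=1e-9)
    assert scoring.circular_sd_minutes(np.array([3.0, 3.0, 3.0])) == pytest.approx(0.0, abs=1e-6)
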