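"""Preprocessing stages versus brute-force reference implementations."""

from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actisleep import preprocess as pp
from actisleep.types import ActigraphyRecord, HourlySeries, ParameterError, StateError

START = datetime(2024, 1, 1, 12, 0)


def rec(counts, offwrist=None, start=START):
    counts = np.asarray(counts, dtype=float)
    ow = np.zeros(counts.size, dtype=np.int8) if offwrist is None else np.asarray(offwrist)
    return ActigraphyRecord("P", start, counts, ow)


# ---- trim ------------------------------------------------------------------

def test_trim_removes_edges_keeps_interior():
    counts = np.concatenate([np.full(10, np.nan), np.arange(100.0), np.full(5, np.nan)])
    ow = np.concatenate([np.ones(10), np.zeros(100), np.ones(5)]).astype(np.int8)
    ow[50] = 1
    counts[50] = np.nan
    out = pp.trim_offwrist_edges(rec(counts, ow))
    assert len(out) == 100
    assert np.isnan(out.counts[40])  # interior off-wrist kept as missing
    assert out.start_time == START + timedelta(minutes=10)


def test_trim_identity_without_offwrist():
    r = rec(np.arange(50.0))
    assert pp.trim_offwrist_edges(r) == r


def test_trim_rejects_fully_offwrist():
    r = rec(np.full(20, np.nan), np.ones(20, dtype=np.int8))
    with pytest.raises(pp.EmptyRecordError):
        pp.trim_offwrist_edges(r)


# ---- forward fill ----------------------------------------------------------

def test_forward_fill_example_and_identity():
    out = pp.forward_fill(rec([3, np.nan, np.nan, 7]))
    assert list(out.counts) == [3, 3, 3, 7]
    r = rec([1.0, 2.0, 3.0])
    assert pp.forward_fill(r) == r


def test_forward_fill_requires_valid_first_epoch():
    with pytest.raises(StateError):
        pp.forward_fill(rec([np.nan, 5]))


# ---- hourly downsampling ---------------------------------------------------

def test_hourly_mean_examples():
    assert list(pp.downsample_hourly(rec(np.full(60, 10.0))).values) == [10.0]
    two = np.concatenate([np.zeros(60), np.full(60, 6.0)])
    assert list(pp.downsample_hourly(rec(two)).values) == [0.0, 6.0]
    assert pp.downsample_hourly(rec(np.arange(1.0, 61.0))).values[0] == pytest.approx(30.5)


def test_hourly_drops_trailing_partial_hour():
    out = pp.downsample_hourly(rec(np.arange(130.0)))
    assert len(out) == 2


def test_hourly_rejects_short_record():
    with pytest.raises(pp.TooShortError):
        pp.downsample_hourly(rec(np.arange(59.0)))


def test_hourly_clock_alignment_skips_partial_leading_hour():
    start = datetime(2024, 1, 1, 12, 30)
    r = rec(np.arange(120.0), start=start)
    out = pp.downsample_hourly(r, alignment="clock")
    assert out.start_time == datetime(2024, 1, 1, 13, 0)
    assert len(out) == 1
    assert out.values[0] == pytest.approx(np.mean(np.arange(30.0, 90.0)))


@settings(max_examples=30, deadline=None)
@given(st.integers(min_value=60, max_value=400), st.integers(min_value=0, max_value=10_000))
def test_hourly_matches_naive_loop(n, seed):
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 500, n).astype(float)
    got = pp.downsample_hourly(rec(counts)).values
    expected = [counts[h * 60 : (h + 1) * 60].mean() for h in range(n // 60)]
    assert np.allclose(got, expected)


# ---- windowing -------------------------------------------------------------

def hourly(values):
    return HourlySeries("P", np.asarray(values, dtype=float), START)


@pytest.mark.parametrize("length,expected", [(168, 13), (24, 1), (36, 2), (35, 1)])
def test_window_counts(length, expected):
    ws = pp.make_windows(hourly(np.arange(length)))
    assert len(ws) == expected
    assert np.all(np.diff(ws.window_start_hours) == 12)


def test_window_too_short():
    with pytest.raises(pp.TooShortError):
        pp.make_windows(hourly(np.arange(23)))


def test_windows_cover_every_hour_when_aligned():
    L = 24 + 12 * 5
    ws = pp.make_windows(hourly(np.arange(L)))
    covered = set()
    for s in ws.window_start_hours:
        covered.update(range(s, s + 24))
    assert covered == set(range(L))


# ---- normalization ---------------------------------------------------------

def test_minmax_examples():
    ws = pp.make_windows(hourly(np.tile([0, 5, 10], 8)))
    out = pp.minmax_normalize(ws)
    assert out.windows.min() == 0.0 and out.windows.max() == 1.0
    assert out.windows[0][1] == pytest.approx(0.5)


def test_minmax_constant_maps_to_zero():
    ws = pp.make_windows(hourly(np.full(24, 7.0)))
    for scope in ("per_record", "per_window"):
        assert np.all(pp.minmax_normalize(ws, scope).windows == 0.0)


def test_minmax_per_window_scales_each_row():
    vals = np.concatenate([np.arange(24.0), 10 * np.arange(24.0) + 5])
    ws = pp.make_windows(hourly(vals), window_len=24, step=24)
    out = pp.minmax_normalize(ws, "per_window")
    for row in out.windows:
        assert row.min() == 0.0 and row.max() == 1.0


def test_minmax_idempotent_when_already_unit_range():
    ws = pp.make_windows(hourly(np.linspace(0, 1, 24)))
    out = pp.minmax_normalize(ws)
    assert np.allclose(out.windows, ws.windows)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_minmax_oracle_per_record(seed):
    rng = np.random.default_rng(seed)
    vals = rng.uniform(0, 300, 48)
    ws = pp.make_windows(hourly(vals))
    out = pp.minmax_normalize(ws)
    lo, hi = ws.windows.min(), ws.windows.max()
    assert np.allclose(out.windows, (ws.windows - lo) / (hi - lo))


# ---- composition -----------------------------------------------------------

def test_pipeline_idempotent_from_hourly_stage():
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 300, 1440 * 2).astype(float)
    ws1 = pp.preprocess_record(rec(counts))
    ws2 = pp.minmax_normalize(ws1)  # renormalizing is a no-op
    assert np.allclose(ws1.windows, ws2.windows)
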