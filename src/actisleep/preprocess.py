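"""Epoch-to-window preprocessing.

Fixed stage order: trim off-wrist edges -> forward fill -> hourly
downsampling -> 24-h sliding windows (12-h step) -> min-max normalization
to [0, 1]. Hour bins are aligned to the first retained epoch by default
(clock-aligned binning available), a trailing partial hour is dropped, and
a constant series normalizes to all zeros by convention.
"""

from __future__ import annotations

import numpy as np

from .types import ActigraphyRecord, HourlySeries, ParameterError, StateError, WindowSet


class TooShortError(ParameterError):
    pass


class EmptyRecordError(ParameterError):
    pass


def trim_offwrist_edges(record: ActigraphyRecord) -> ActigraphyRecord:
    """Drop leading/trailing off-wrist runs; interior off-wrist stays missing."""
    ow = record.offwrist
    worn = np.flatnonzero(ow == 0)
    if worn.size == 0:
        raise EmptyRecordError("record is entirely off-wrist")
    s, e = int(worn[0]), int(worn[-1]) + 1
    if s == 0 and e == len(record):
        return record.copy()
    from datetime import timedelta

    return ActigraphyRecord(
        record.participant_id,
        record.start_time + timedelta(minutes=s),
        record.counts[s:e].copy(),
        record.offwrist[s:e].copy(),
    )


def forward_fill(record: ActigraphyRecord) -> ActigraphyRecord:
    """Replace every missing count with the nearest preceding valid count."""
    counts = record.counts
    if np.isnan(counts[0]):
        raise StateError("leading missing count: trim off-wrist edges first")
    if not np.isnan(counts).any():
        return record.copy()
    valid = ~np.isnan(counts)
    idx = np.where(valid, np.arange(counts.size), 0)
    np.maximum.accumulate(idx, out=idx)
    return ActigraphyRecord(
        record.participant_id, record.start_time, counts[idx], record.offwrist.copy()
    )


def downsample_hourly(record: ActigraphyRecord, alignment: str = "record") -> HourlySeries:
    """Mean count per hour; bins align to the record start (or wall clock).

    A trailing partial hour is dropped rather than padded.
    """
    counts = record.counts
    if np.isnan(counts).any():
        raise ParameterError("downsampling requires a gap-free record (forward fill first)")
    start = record.start_time
    offset = 0
    if alignment == "clock" and start.minute != 0:
        offset = 60 - start.minute  # skip to the next full clock hour
    elif alignment not in ("record", "clock"):
        raise ParameterError("alignment must be 'record' or 'clock'")
    usable = counts[offset:]
    n_hours = usable.size // 60
    if n_hours < 1:
        raise TooShortError("record shorter than one full hour")
    values = usable[: n_hours * 60].reshape(n_hours, 60).mean(axis=1)
    from datetime import timedelta

    return HourlySeries(record.participant_id, values, start + timedelta(minutes=offset))


def make_windows(series: HourlySeries, window_len: int = 24, step: int = 12) -> WindowSet:
    """Overlapping sliding windows: floor((L - window_len)/step) + 1 of them."""
    L = len(series)
    if L < window_len:
        raise TooShortError(f"need at least {window_len} hourly values, got {L}")
    starts = np.arange(0, L - window_len + 1, step)
    windows = np.stack([series.values[s : s + window_len] for s in starts])
    return WindowSet(series.participant_id, windows, starts)


def minmax_normalize(windows: WindowSet, scope: str = "per_record") -> WindowSet:
    """Scale to [0, 1]; min -> 0, max -> 1 within the chosen scope.

    ``per_record`` uses one min/max over all of a participant's windows
    (preserving day/night amplitude differences between windows);
    ``per_window`` rescales each window independently. A constant stretch
    maps to all zeros.
    """
    w = windows.windows
    if scope == "per_record":
        lo, hi = float(w.min()), float(w.max())
        span = hi - lo
        out = np.zeros_like(w) if span == 0 else (w - lo) / span
    elif scope == "per_window":
        lo = w.min(axis=1, keepdims=True)
        hi = w.max(axis=1, keepdims=True)
        span = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(span == 0, 0.0, (w - lo) / np.where(span == 0, 1.0, span))
    else:
        raise ParameterError("scope must be 'per_record' or 'per_window'")
    return WindowSet(windows.participant_id, out, windows.window_start_hours.copy())


def preprocess_record(
    record: ActigraphyRecord,
    window_len: int = 24,
    step: int = 12,
    norm_scope: str = "per_record",
    alignment: str = "record",
) -> WindowSet:
    """Run the full fixed-order preprocessing pipeline for one record."""
    trimmed = trim_offwrist_edges(record)
    filled = forward_fill(trimmed)
    hourly = downsample_hourly(filled, alignment)
    windows = make_windows(hourly, window_len, step)
    return minmax_normalize(windows, norm_scope)
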