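"""Sleep/wake scoring and the two composite sleep metrics.

Epoch scoring uses the classic one-minute weighted-window rule of Cole,
Kripke et al. (1992): the weighted sum

    D = 0.001 * (106 A[t-4] + 54 A[t-3] + 58 A[t-2] + 76 A[t-1]
                 + 230 A[t] + 74 A[t+1] + 67 A[t+2])

scores epoch t as sleep when D < threshold (default 1.0). Optional
Webster-style rescoring (off by default) reclassifies short sleep runs
surrounded by long wake as wake.

Per-night parameters (onset, latency, WASO, duration, efficiency, circular
midpoint) are summarized inside a detected rest interval — the longest
low-activity span in an 18:00-to-noon nocturnal search window — since
actigraphy alone carries no diary or event-marker channel.

Two weekly metrics are derived:

* **SleepQualWeek** (range 0-12, lower is better): each of efficiency,
  latency, WASO and duration is averaged over the week, banded to a
  PSQI-style 0-3 subscore, and the four subscores are summed.
  Classes: < 5 Good, 5-8 Average, > 8 Poor.
* **SleepCons** (minutes-scale, lower is better):
  ``0.4 * SleepVar + 0.3 * WeekendDiff + 0.3 * MidpointVar`` where SleepVar
  is the night-to-night SD of sleep duration, WeekendDiff the absolute
  weekday-vs-weekend gap in mean sleep midpoint, and MidpointVar the
  circular SD of the midpoint, all in minutes.
  Classes: < 50 Good, [50, 200) Average, [200, 400) Poor, >= 400 Very Poor.
"""

from __future__ import annotations

import logging
import math
from datetime import timedelta

import numpy as np

from .config import ScoringConfig
from .types import ActigraphyRecord, NightSummary, ParameterError, SleepLabel

logger = logging.getLogger(__name__)

COLE_WEIGHTS = np.array([106.0, 54.0, 58.0, 76.0, 230.0, 74.0, 67.0])
COLE_SCALE = 0.001
_CENTER = 4  # index of the current epoch within the 7-epoch kernel

SQW_CLASS_NAMES = {0: "Good", 1: "Average", 2: "Poor"}
CONS_CLASS_NAMES = {0: "Good", 1: "Average", 2: "Poor", 3: "VeryPoor"}


class TooShortError(ParameterError):
    pass


def score_sleep_wake(record: ActigraphyRecord, cfg: ScoringConfig | None = None) -> np.ndarray:
    """Label every epoch sleep (1) or wake (0); requires a gap-free record."""
    cfg = cfg or ScoringConfig()
    counts = record.counts
    if np.isnan(counts).any():
        raise ParameterError("sleep/wake scoring requires a gap-free record (forward fill first)")
    if counts.size < COLE_WEIGHTS.size:
        raise TooShortError(f"record shorter than the {COLE_WEIGHTS.size}-epoch scoring window")
    padded = np.concatenate([np.zeros(_CENTER), counts, np.zeros(COLE_WEIGHTS.size - 1 - _CENTER)])
    d = COLE_SCALE * np.convolve(padded, COLE_WEIGHTS[::-1], mode="valid")
    asleep = (d < cfg.cole_threshold).astype(np.int8)
    if cfg.webster_rescoring:
        asleep = _webster_rescore(asleep)
    return asleep


def _webster_rescore(asleep: np.ndarray) -> np.ndarray:
    """Wake-extension rescoring: after >=4 min of wake, the first minute scored
    sleep is rescored wake; 1-min sleep islands inside wake become wake."""
    out = asleep.copy()
    run_wake = 0
    for i in range(out.size):
        if out[i] == 0:
            run_wake += 1
        else:
            isolated = (i + 1 == out.size or out[i + 1] == 0) and run_wake >= 1
            if run_wake >= 4 or (isolated and run_wake >= 3):
                out[i] = 0
                run_wake += 1
            else:
                run_wake = 0
    return out


def _runs(values: np.ndarray, target: int):
    """Yield (start, end) half-open runs where values == target."""
    flag = np.concatenate([[0], (values == target).astype(int), [0]])
    idx = np.flatnonzero(np.diff(flag))
    for s, e in zip(idx[::2], idx[1::2]):
        yield int(s), int(e)


def detect_rest_interval(
    record: ActigraphyRecord,
    night_index: int,
    cfg: ScoringConfig | None = None,
    smooth_minutes: int = 21,
) -> tuple[int, int] | None:
    """Locate the night's rest interval as the longest low-activity span.

    The search window runs from ``cfg.search_window[0]`` on calendar day
    ``night_index`` of the record to ``cfg.search_window[1]`` the next day.
    Activity is smoothed with a centered moving average and thresholded at
    half the record-wide median of the smoothed series (floor 5 counts/min),
    which separates in-bed stillness from ambulatory daytime activity.
    Returns half-open epoch bounds, or None when no span of at least 60 min
    exists in the window.
    """
    cfg = cfg or ScoringConfig()
    counts = record.counts
    if np.isnan(counts).any():
        raise ParameterError("rest detection requires a gap-free record")
    k = smooth_minutes
    kernel = np.ones(k) / k
    smoothed = np.convolve(np.pad(counts, k // 2, mode="edge"), kernel, mode="valid")[: counts.size]
    threshold = max(5.0, 0.5 * float(np.median(smoothed)))

    start_clock = record.start_time.hour + record.start_time.minute / 60.0
    # epoch of midnight starting calendar day `night_index` relative to record start
    day0_midnight = -start_clock * 60.0
    w_start = int(round(day0_midnight + night_index * 1440 + cfg.search_window[0] * 60))
    w_end = int(round(day0_midnight + (night_index + 1) * 1440 + cfg.search_window[1] * 60))
    w_start = max(w_start, 0)
    w_end = min(w_end, counts.size)
    if w_end - w_start < 60:
        return None

    low = (smoothed[w_start:w_end] < threshold).astype(np.int8)
    best = None
    for s, e in _runs(low, 1):
        if best is None or (e - s) > (best[1] - best[0]):
            best = (s, e)
    if best is None or best[1] - best[0] < 60:
        return None
    return (w_start + best[0], w_start + best[1])


def _clock_hours(record: ActigraphyRecord, epoch: float) -> float:
    start = record.start_time.hour + record.start_time.minute / 60.0
    return (start + epoch / 60.0) % 24.0


def circular_midpoint(onset_h: float, offset_h: float) -> float:
    """Clock time halfway from onset to offset going forward on a 24-h wheel."""
    span = (offset_h - onset_h) % 24.0
    return (onset_h + span / 2.0) % 24.0


def circular_mean_hours(hours: np.ndarray) -> float:
    theta = np.asarray(hours, dtype=float) / 24.0 * 2 * np.pi
    return float(np.arctan2(np.mean(np.sin(theta)), np.mean(np.cos(theta))) % (2 * np.pi) / (2 * np.pi) * 24.0)


def circular_sd_minutes(hours: np.ndarray) -> float:
    """Circular standard deviation of clock times, expressed in minutes."""
    theta = np.asarray(hours, dtype=float) / 24.0 * 2 * np.pi
    r = float(np.hypot(np.mean(np.sin(theta)), np.mean(np.cos(theta))))
    r = min(max(r, 1e-12), 1.0)
    sd_rad = math.sqrt(max(0.0, -2.0 * math.log(r)))
    return sd_rad / (2 * np.pi) * 24.0 * 60.0


def circular_diff_minutes(a_hours: float, b_hours: float) -> float:
    d = abs(a_hours - b_hours) % 24.0
    return min(d, 24.0 - d) * 60.0


def summarize_night(
    sleep_wake: np.ndarray,
    rest_interval: tuple[int, int],
    record: ActigraphyRecord,
    night_index: int,
    cfg: ScoringConfig | None = None,
) -> NightSummary:
    """Summarize one night's sleep inside a rest interval (half-open epochs).

    Latency is the time from rest start to the first run of at least
    ``persistent_sleep_run`` consecutive sleep epochs; WASO counts wake
    epochs strictly between onset and final awakening; efficiency is
    100 * duration / (latency + duration + WASO).
    """
    cfg = cfg or ScoringConfig()
    s, e = rest_interval
    if not (0 <= s < e <= sleep_wake.size):
        raise ParameterError("rest interval out of record bounds")
    if (e - s) > 24 * 60:
        raise ParameterError("rest interval must span at most 24 h")
    night = sleep_wake[s:e]

    onset_rel = None
    run = 0
    for i, v in enumerate(night):
        run = run + 1 if v == 1 else 0
        if run >= cfg.persistent_sleep_run:
            onset_rel = i - cfg.persistent_sleep_run + 1
            break
    if onset_rel is None:
        start_clock = _clock_hours(record, s)
        return NightSummary(
            night_index=night_index, onset=start_clock, offset=start_clock,
            duration=0.0, latency=float(e - s), waso=0.0, efficiency=0.0,
            midpoint=start_clock,
        )

    sleep_idx = np.flatnonzero(night == 1)
    offset_rel = int(sleep_idx[-1]) + 1  # one past the final sleep epoch
    duration = float(np.sum(night[onset_rel:offset_rel]))
    waso = float((offset_rel - onset_rel) - duration)
    latency = float(onset_rel)
    tib = latency + duration + waso
    efficiency = 100.0 * duration / tib if tib > 0 else 0.0

    onset_h = _clock_hours(record, s + onset_rel)
    offset_h = _clock_hours(record, s + offset_rel)
    return NightSummary(
        night_index=night_index,
        onset=onset_h,
        offset=offset_h,
        duration=duration,
        latency=latency,
        waso=waso,
        efficiency=min(efficiency, 100.0),
        midpoint=circular_midpoint(onset_h, offset_h),
    )


def summarize_record(
    record: ActigraphyRecord, cfg: ScoringConfig | None = None
) -> tuple[list[NightSummary], list[str]]:
    """Score a gap-free record and summarize every detectable night.

    Returns night summaries and their day types ("weekday"/"weekend"),
    where a night belongs to the calendar day it starts on (Saturday and
    Sunday evenings count as weekend nights).
    """
    cfg = cfg or ScoringConfig()
    sleep_wake = score_sleep_wake(record, cfg)
    n_days = int(np.ceil(len(record) / 1440))
    nights: list[NightSummary] = []
    day_types: list[str] = []
    for d in range(n_days):
        interval = detect_rest_interval(record, d, cfg)
        if interval is None:
            continue
        summary = summarize_night(sleep_wake, interval, record, d, cfg)
        nights.append(summary)
        # day type from the calendar day the search window starts on
        window_day = record.start_time + timedelta(minutes=interval[0])
        if window_day.hour < 12:  # slipped past midnight: night belongs to previous day
            window_day -= timedelta(days=1)
        day_types.append("weekend" if window_day.weekday() >= 5 else "weekday")
    return nights, day_types


def _band(value: float, edges: tuple[float, float, float], higher_is_better: bool) -> int:
    """Map a component value onto a 0-3 subscore given three band edges."""
    a, b, c = edges
    if higher_is_better:  # edges descending, e.g. efficiency >=85 -> 0
        if value >= a:
            return 0
        if value >= b:
            return 1
        if value >= c:
            return 2
        return 3
    if value <= a:
        return 0
    if value <= b:
        return 1
    if value <= c:
        return 2
    return 3


def component_subscore(component: str, value: float, cfg: ScoringConfig | None = None) -> int:
    """PSQI-style 0-3 subscore for one averaged weekly component.

    Monotone by construction: a worse value never gets a lower subscore.
    """
    cfg = cfg or ScoringConfig()
    if value < 0:
        raise ParameterError(f"{component} must be non-negative")
    if component == "efficiency":
        if value > 100.0 + 1e-9:
            raise ParameterError("efficiency cannot exceed 100%")
        return _band(value, cfg.efficiency_bands, higher_is_better=True)
    if component == "latency":
        return _band(value, cfg.latency_bands, higher_is_better=False)
    if component == "waso":
        return _band(value, cfg.waso_bands, higher_is_better=False)
    if component == "duration":
        return _band(value, cfg.duration_bands, higher_is_better=True)
    raise ParameterError(f"unknown component '{component}'")


def sqw_class(score: float) -> int:
    if score < 5:
        return 0
    if score <= 8:
        return 1
    return 2


def cons_class(score: float) -> int:
    if score < 50:
        return 0
    if score < 200:
        return 1
    if score < 400:
        return 2
    return 3


def sleep_qual_week(nights: list[NightSummary], cfg: ScoringConfig | None = None) -> SleepLabel:
    """Weekly sleep-quality composite: sum of four banded subscores, 0-12."""
    cfg = cfg or ScoringConfig()
    if not nights:
        raise ParameterError("sleep_qual_week requires at least one night")
    score = float(
        component_subscore("efficiency", float(np.mean([n.efficiency for n in nights])), cfg)
        + component_subscore("latency", float(np.mean([n.latency for n in nights])), cfg)
        + component_subscore("waso", float(np.mean([n.waso for n in nights])), cfg)
        + component_subscore("duration", float(np.mean([n.duration for n in nights])), cfg)
    )
    cid = sqw_class(score)
    return SleepLabel("SleepQualWeek", score, cid, SQW_CLASS_NAMES[cid])


def sleep_cons(
    nights: list[NightSummary],
    day_types: list[str],
    cfg: ScoringConfig | None = None,
) -> SleepLabel:
    """Sleep-consistency composite (minutes scale); lower is more regular."""
    cfg = cfg or ScoringConfig()
    if len(nights) < 2:
        raise ParameterError("sleep_cons requires at least two nights")
    if len(day_types) != len(nights):
        raise ParameterError("day_types must match nights")

    durations = np.array([n.duration for n in nights])
    midpoints = np.array([n.midpoint for n in nights])

    sleep_var = float(np.std(durations, ddof=1))
    midpoint_var = circular_sd_minutes(midpoints)
    if cfg.cons_dispersion == "variance":
        sleep_var = sleep_var**2
        midpoint_var = midpoint_var**2

    is_weekend = np.array([t == "weekend" for t in day_types])
    if is_weekend.any() and (~is_weekend).any():
        if cfg.weekend_diff_mode == "midpoint":
            weekend_diff = circular_diff_minutes(
                circular_mean_hours(midpoints[~is_weekend]),
                circular_mean_hours(midpoints[is_weekend]),
            )
        else:
            weekend_diff = abs(float(durations[~is_weekend].mean() - durations[is_weekend].mean()))
    else:
        logger.warning("no weekday/weekend contrast available; WeekendDiff set to 0")
        weekend_diff = 0.0

    w1, w2, w3 = cfg.cons_weights
    score = w1 * sleep_var + w2 * weekend_diff + w3 * midpoint_var
    cid = cons_class(score)
    return SleepLabel("SleepCons", score, cid, CONS_CLASS_NAMES[cid])


def score_record(record: ActigraphyRecord, cfg: ScoringConfig | None = None):
    """Convenience: nights, day types and both metric labels for one record."""
    nights, day_types = summarize_record(record, cfg)
    if not nights:
        raise ParameterError(f"no rest intervals detected for {record.participant_id}")
    sqw = sleep_qual_week(nights, cfg)
    cons = sleep_cons(nights, day_types, cfg) if len(nights) >= 2 else None
    return nights, day_types, sqw, cons
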