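"""Synthetic actigraphy cohorts with known nightly ground truth.

The generator emulates the statistical shape of wrist actigraphy: a diurnal
count rhythm (high ambulatory daytime counts, near-zero counts during sleep),
per-night sleep windows with controllable latency, WASO, duration and
night-to-night variability, a weekday/weekend bedtime shift, and
overdispersed non-negative count noise (negative binomial; Poisson when the
dispersion is 0). Wake inside the rest interval (latency and awakening bouts)
is drawn at an intermediate activity level so epoch scoring can see it.

Records start at midday (default Monday 2024-01-01 12:00) so every night
spans midnight; day index d runs 0..n_days-1 and d % 7 in {5, 6} is a
weekend night, which drives the weekend-shift term of the consistency score.

All randomness flows through one seeded generator per participant; identical
(profile, n_days, seed) triples produce bit-identical records.
"""

from __future__ import annotations

from datetime import datetime

import numpy as np

from . import scoring
from .types import (
    ActigraphyRecord,
    GroundTruth,
    NightSummary,
    ParameterError,
    SleepProfile,
    derive_seed,
)

DEFAULT_START = datetime(2024, 1, 1, 12, 0)  # a Monday, midday start

# state codes used while assembling a day of epochs
_DAY, _BED_WAKE, _SLEEP = 0, 1, 2


def _draw_counts(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Non-negative overdispersed counts: NB with var = m(1 + a m); Poisson at a=0."""
    if size == 0:
        return np.zeros(0)
    if mean <= 0:
        return np.zeros(size)
    if dispersion <= 0:
        return rng.poisson(mean, size).astype(float)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size).astype(float)


def _split_sleep(rng: np.random.Generator, duration: int, n_bouts: int, min_run: int = 5) -> list[int]:
    """Split total sleep into n_bouts+1 segments, each at least min_run epochs."""
    n_seg = n_bouts + 1
    if duration < n_seg * min_run:
        return [duration]
    free = duration - n_seg * min_run
    props = rng.dirichlet(np.ones(n_seg))
    extra = np.floor(props * free).astype(int)
    extra[0] += free - extra.sum()
    return [min_run + int(e) for e in extra]


def generate_participant(
    profile: SleepProfile,
    n_days: int,
    seed: int,
    participant_id: str = "P000",
    start_time: datetime = DEFAULT_START,
) -> tuple[ActigraphyRecord, GroundTruth]:
    """Generate one participant's 1-min epoch record plus nightly ground truth.

    The record has exactly ``n_days * 1440`` epochs. Ground-truth night
    parameters are the drawn pre-noise values; the ground-truth labels are
    the scoring module applied to that noiseless parameter list.
    """
    profile.validate()
    if n_days < 1:
        raise ParameterError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    n_epochs = n_days * 1440
    state = np.full(n_epochs, _DAY, dtype=np.int8)
    start_clock = start_time.hour + start_time.minute / 60.0

    nights: list[NightSummary] = []
    day_types: list[str] = []
    for d in range(n_days):
        weekend = d % 7 in (5, 6)
        bedtime = profile.mean_bedtime + (profile.weekend_shift / 60.0 if weekend else 0.0)
        bedtime += rng.normal(0.0, profile.midpoint_sd / 60.0)
        latency = int(round(rng.gamma(2.0, profile.latency_mean / 2.0))) if profile.latency_mean > 0 else 0
        duration = int(round(np.clip(rng.normal(profile.mean_duration, profile.duration_sd), 60, 1200)))
        waso_total = (
            int(round(max(0.0, rng.normal(profile.waso_mean, 0.25 * profile.waso_mean))))
            if profile.waso_mean > 0
            else 0
        )
        n_bouts = 0 if waso_total < 1 else max(1, int(rng.poisson(waso_total / 20.0)))
        segments = _split_sleep(rng, duration, n_bouts)
        n_bouts = len(segments) - 1
        bout_lens = []
        if n_bouts > 0:
            props = rng.dirichlet(np.ones(n_bouts))
            bout_lens = np.maximum(1, np.round(props * waso_total).astype(int)).tolist()
            waso_total = int(sum(bout_lens))

        bed_epoch = d * 1440 + int(round(((bedtime - start_clock) % 24.0) * 60.0))
        cursor = bed_epoch
        spans: list[tuple[int, int, int]] = [(cursor, cursor + latency, _BED_WAKE)]
        cursor += latency
        for i, seg in enumerate(segments):
            spans.append((cursor, cursor + seg, _SLEEP))
            cursor += seg
            if i < len(bout_lens):
                spans.append((cursor, cursor + bout_lens[i], _BED_WAKE))
                cursor += bout_lens[i]
        for s, e, code in spans:
            state[max(s, 0) : min(e, n_epochs)] = code

        onset_h = (bedtime + latency / 60.0) % 24.0
        offset_h = (bedtime + (latency + duration + waso_total) / 60.0) % 24.0
        tib = latency + duration + waso_total
        nights.append(
            NightSummary(
                night_index=d,
                onset=onset_h,
                offset=offset_h,
                duration=float(duration),
                latency=float(latency),
                waso=float(waso_total),
                efficiency=100.0 * duration / tib if tib else 0.0,
                midpoint=scoring.circular_midpoint(onset_h, offset_h),
            )
        )
        day_types.append("weekend" if weekend else "weekday")

    counts = np.empty(n_epochs)
    for code, mean in (
        (_DAY, profile.day_activity_mean),
        (_BED_WAKE, profile.wake_in_bed_activity_mean),
        (_SLEEP, profile.night_activity_mean),
    ):
        idx = np.flatnonzero(state == code)
        counts[idx] = _draw_counts(rng, mean, profile.count_dispersion, idx.size)

    record = ActigraphyRecord(participant_id, start_time, counts, np.zeros(n_epochs, dtype=np.int8))
    sqw = scoring.sleep_qual_week(nights)
    cons = (
        scoring.sleep_cons(nights, day_types)
        if len(nights) >= 2
        else scoring.SleepLabel("SleepCons", 0.0, 0, "Good")
    )
    truth = GroundTruth(participant_id, nights, day_types, sqw, cons)
    return record, truth


def generate_cohort(
    class_spec: dict[int, tuple[SleepProfile, int]],
    n_days: int = 7,
    seed: int = 0,
    start_time: datetime = DEFAULT_START,
    calibrate_metric: str | None = None,
    max_attempts: int = 25,
) -> tuple[list[ActigraphyRecord], list[GroundTruth]]:
    """Generate a labeled cohort; participant i uses derived seed ``seed + i``.

    With ``calibrate_metric`` set ("SleepQualWeek" or "SleepCons"), a
    participant whose noiseless ground-truth class misses the requested one
    is redrawn deterministically (attempt-indexed derived seeds) — the
    7-night sample of an extreme profile occasionally lands outside its
    class band, and cohort labels must be exact for supervised experiments.
    """
    if not class_spec:
        raise ParameterError("class_spec must name at least one class")
    if len(class_spec) < 1 or any(n < 1 for _, n in class_spec.values()):
        raise ParameterError("each class needs n_participants >= 1")
    records, truths = [], []
    index = 0
    for class_id in sorted(class_spec):
        prof, n = class_spec[class_id]
        for _ in range(n):
            pid = f"P{index:03d}_c{class_id}"
            for attempt in range(max_attempts):
                pseed = seed + index if attempt == 0 else derive_seed(seed + index, "redraw", attempt)
                rec, gt = generate_participant(prof, n_days, pseed, pid, start_time)
                if calibrate_metric is None:
                    break
                got = gt.sqw_label if calibrate_metric == "SleepQualWeek" else gt.cons_label
                if got.class_id == class_id:
                    break
            records.append(rec)
            truths.append(gt)
            index += 1
    return records, truths


def inject_offwrist(
    record: ActigraphyRecord,
    segments: list[tuple[int, int]],
    seed: int = 0,
) -> ActigraphyRecord:
    """Flag half-open epoch segments as off-wrist (count becomes missing)."""
    out = record.copy()
    seen: list[tuple[int, int]] = []
    for s, e in segments:
        if not (0 <= s < e <= len(record)):
            raise ParameterError(f"segment [{s}, {e}) outside record bounds")
        for ps, pe in seen:
            if s < pe and ps < e:
                raise ParameterError(f"segment [{s}, {e}) overlaps [{ps}, {pe})")
        seen.append((s, e))
        out.offwrist[s:e] = 1
        out.counts[s:e] = np.nan
    return out


# ---------------------------------------------------------------------------
# Shipped class profiles, calibrated so that scoring the generated records
# reproduces the requested class for nearly all participants at default noise.
# ---------------------------------------------------------------------------

DEFAULT_SQW_PROFILES: dict[int, SleepProfile] = {
    0: SleepProfile(  # Good: efficient, quick-onset, consolidated sleep
        mean_bedtime=23.0, mean_duration=450, latency_mean=8, waso_mean=10,
        efficiency_target=96.0, duration_sd=25, midpoint_sd=20, weekend_shift=20,
        day_activity_mean=250, night_activity_mean=0.01,
        wake_in_bed_activity_mean=80, count_dispersion=0.5,
    ),
    1: SleepProfile(  # Average: moderate latency/WASO, somewhat short sleep
        mean_bedtime=23.5, mean_duration=380, latency_mean=35, waso_mean=45,
        efficiency_target=82.0, duration_sd=30, midpoint_sd=25, weekend_shift=30,
        day_activity_mean=250, night_activity_mean=0.01,
        wake_in_bed_activity_mean=80, count_dispersion=0.5,
    ),
    2: SleepProfile(  # Poor: long latency, fragmented, short sleep
        mean_bedtime=23.5, mean_duration=280, latency_mean=80, waso_mean=90,
        efficiency_target=62.0, duration_sd=35, midpoint_sd=30, weekend_shift=30,
        day_activity_mean=250, night_activity_mean=0.01,
        wake_in_bed_activity_mean=80, count_dispersion=0.5,
    ),
}

DEFAULT_CONS_PROFILES: dict[int, SleepProfile] = {
    0: SleepProfile(  # highly regular sleeper
        mean_bedtime=23.0, mean_duration=440, latency_mean=10, waso_mean=15,
        efficiency_target=94.0, duration_sd=15, midpoint_sd=12, weekend_shift=15,
        day_activity_mean=250, night_activity_mean=0.01,
        wake_in_bed_activity_mean=80, count_dispersion=0.5,
    ),
    1: SleepProfile(  # moderate variability
        mean_bedtime=23.0, mean_duration=420, latency_mean=15, waso_mean=20,
        efficiency_target=92.0, duration_sd=140, midpoint_sd=60, weekend_shift=150,
        day_activity_mean=250, night_activity_mean=0.01,
        wake_in_bed_activity_mean=80, count_dispersion=0.5,
    ),
    2: SleepProfile(  # irregular
        mean_bedtime=23.0, mean_duration=420, latency_mean=20, waso_mean=25,
        efficiency_target=90.0, duration_sd=420, midpoint_sd=120, weekend_shift=420,
        day_activity_mean=250, night_activity_mean=0.01,
        wake_in_bed_activity_mean=80, count_dispersion=0.5,
    ),
    3: SleepProfile(  # severely irregular (shift-work-like schedule swings)
        mean_bedtime=22.5, mean_duration=560, latency_mean=25, waso_mean=30,
        efficiency_target=88.0, duration_sd=900, midpoint_sd=150, weekend_shift=700,
        day_activity_mean=250, night_activity_mean=0.01,
        wake_in_bed_activity_mean=80, count_dispersion=0.5,
    ),
}

# Consolidated, near-unfragmented sleep: the regime where epoch scoring can
# recover the drawn night parameters almost exactly (parameter-recovery tests).
LOW_NOISE_PROFILE = SleepProfile(
    mean_bedtime=23.0, mean_duration=450, latency_mean=3, waso_mean=0,
    efficiency_target=99.0, duration_sd=15, midpoint_sd=10, weekend_shift=15,
    day_activity_mean=250, night_activity_mean=0.01,
    wake_in_bed_activity_mean=30, count_dispersion=0.3,
)

# Cohort shapes used throughout: 28 participants (10/10/8) for the weekly
# quality metric and 40 (10 per class) for the consistency metric.
DEFAULT_SQW_COUNTS = {0: 10, 1: 10, 2: 8}
DEFAULT_CONS_COUNTS = {0: 10, 1: 10, 2: 10, 3: 10}


def default_cohort_spec(metric: str) -> dict[int, tuple[SleepProfile, int]]:
    if metric == "SleepQualWeek":
        return {c: (DEFAULT_SQW_PROFILES[c], n) for c, n in DEFAULT_SQW_COUNTS.items()}
    if metric == "SleepCons":
        return {c: (DEFAULT_CONS_PROFILES[c], n) for c, n in DEFAULT_CONS_COUNTS.items()}
    raise ParameterError(f"unknown metric '{metric}'")
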