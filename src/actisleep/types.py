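"""Core data containers shared by every pipeline stage.

Epoch-level actigraphy is stored as dense numpy arrays (one slot per 1-minute
epoch); a missing activity count is NaN, never a sentinel number.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np

EPOCH_SECONDS = 60
EPOCHS_PER_DAY = 1440
EPOCHS_PER_HOUR = 60


class ParameterError(ValueError):
    """A caller-supplied parameter violates a documented precondition."""


class FormatError(ValueError):
    """An input file does not conform to the declared dialect."""


class StateError(RuntimeError):
    """An operation was invoked on an object in the wrong state."""


class ConfigError(ValueError):
    """A configuration value violates an invariant."""


@dataclass
class ActigraphyRecord:
    """One participant's 1-minute-epoch activity series.

    Attributes
    ----------
    participant_id : str
    start_time : datetime
        Timestamp of epoch 0 (timezone-naive local clock time).
    counts : np.ndarray
        Activity count per epoch; NaN marks a missing count.
    offwrist : np.ndarray
        0/1 flag per epoch; 1 means the device was not worn.
    """

    participant_id: str
    start_time: datetime
    counts: np.ndarray
    offwrist: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.offwrist = np.asarray(self.offwrist, dtype=np.int8)
        if self.counts.ndim != 1 or self.counts.size == 0:
            raise ParameterError("record must contain at least one epoch")
        if self.offwrist.shape != self.counts.shape:
            raise ParameterError("counts and offwrist must have equal length")
        if not np.all((self.offwrist == 0) | (self.offwrist == 1)):
            raise ParameterError("offwrist flags must be 0 or 1")
        valid = self.counts[~np.isnan(self.counts)]
        if valid.size and (valid < 0).any():
            raise ParameterError("activity counts must be non-negative")

    def __len__(self) -> int:
        return self.counts.size

    @property
    def timestamps(self) -> list[datetime]:
        return [self.start_time + timedelta(minutes=i) for i in range(len(self))]

    def timestamp_at(self, epoch_index: int) -> datetime:
        return self.start_time + timedelta(minutes=int(epoch_index))

    def copy(self) -> "ActigraphyRecord":
        return ActigraphyRecord(
            self.participant_id, self.start_time, self.counts.copy(), self.offwrist.copy()
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ActigraphyRecord):
            return NotImplemented
        return (
            self.participant_id == other.participant_id
            and self.start_time == other.start_time
            and np.array_equal(self.counts, other.counts, equal_nan=True)
            and np.array_equal(self.offwrist, other.offwrist)
        )


@dataclass(frozen=True)
class NightSummary:
    """Derived sleep parameters for one night.

    Clock times (onset/offset/midpoint) are hours since midnight on a circular
    24-h wheel; duration/latency/waso are minutes; efficiency is a percentage.
    """

    night_index: int
    onset: float
    offset: float
    duration: float
    latency: float
    waso: float
    efficiency: float
    midpoint: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.efficiency <= 100.0 + 1e-9):
            raise ParameterError("efficiency must lie in [0, 100]")
        for name in ("duration", "latency", "waso"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")

    @property
    def time_in_bed(self) -> float:
        return self.latency + self.duration + self.waso


@dataclass(frozen=True)
class SleepLabel:
    """A scored sleep metric with its discrete class."""

    metric: str  # "SleepQualWeek" | "SleepCons"
    score: float
    class_id: int
    class_name: str


@dataclass(frozen=True)
class SleepProfile:
    """Generative description of one participant's habitual sleep.

    Clock quantities are hours since midnight; durations are minutes; activity
    means are counts/minute. ``count_dispersion`` controls the negative-binomial
    overdispersion of counts (0 reduces to Poisson).
    """

    mean_bedtime: float = 23.0
    mean_duration: float = 440.0
    latency_mean: float = 12.0
    waso_mean: float = 20.0
    efficiency_target: float = 93.0
    duration_sd: float = 25.0
    midpoint_sd: float = 20.0
    weekend_shift: float = 30.0
    day_activity_mean: float = 250.0
    night_activity_mean: float = 3.0
    wake_in_bed_activity_mean: float = 60.0
    count_dispersion: float = 0.5

    def validate(self) -> None:
        if not (0.0 < self.efficiency_target <= 100.0):
            raise ParameterError("efficiency_target must lie in (0, 100]")
        for name in ("mean_duration", "latency_mean", "waso_mean", "duration_sd",
                     "midpoint_sd", "day_activity_mean", "night_activity_mean",
                     "wake_in_bed_activity_mean"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.count_dispersion < 0:
            raise ParameterError("count_dispersion must be >= 0")
        if not self.night_activity_mean < self.day_activity_mean:
            raise ParameterError(
                "night_activity_mean must be strictly below day_activity_mean"
            )


@dataclass
class GroundTruth:
    """Noise-free nightly parameters and the labels they imply."""

    participant_id: str
    nights: list[NightSummary]
    day_types: list[str]  # "weekday" | "weekend" per night
    sqw_label: SleepLabel
    cons_label: SleepLabel


@dataclass
class HourlySeries:
    """Hourly-mean activity series for one participant (gap-free)."""

    participant_id: str
    values: np.ndarray
    start_time: datetime

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return self.values.size


@dataclass
class WindowSet:
    """Sliding 24-h windows over an hourly series (step 12 h)."""

    participant_id: str
    windows: np.ndarray  # (n_windows, 24)
    window_start_hours: np.ndarray  # offset in hours from series start

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.window_start_hours = np.asarray(self.window_start_hours, dtype=int)
        if self.windows.ndim != 2 or self.windows.shape[1] != 24:
            raise ParameterError("every window must have length 24")

    def __len__(self) -> int:
        return self.windows.shape[0]


@dataclass
class FeatureMatrix:
    """Windows-by-features table with per-column provenance tags.

    ``provenance`` holds "deep" or "stat" per column; row metadata ties each
    window back to its participant so folds can be grouped.
    """

    values: np.ndarray
    feature_names: list[str]
    provenance: list[str]
    participant_ids: np.ndarray
    window_start_hours: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ParameterError("feature values must be 2-D")
        if self.values.shape[0] == 0:
            raise ParameterError("feature matrix must have at least one row")
        if np.isnan(self.values).any():
            raise ParameterError("feature matrix must have no missing cells")
        if len(self.feature_names) != self.values.shape[1]:
            raise ParameterError("feature_names length must match column count")
        if len(self.provenance) != self.values.shape[1]:
            raise ParameterError("provenance length must match column count")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def deep_columns(self) -> np.ndarray:
        return np.array([p == "deep" for p in self.provenance])

    def select(self, column_mask: np.ndarray) -> "FeatureMatrix":
        column_mask = np.asarray(column_mask, dtype=bool)
        return FeatureMatrix(
            self.values[:, column_mask],
            [n for n, keep in zip(self.feature_names, column_mask) if keep],
            [p for p, keep in zip(self.provenance, column_mask) if keep],
            self.participant_ids,
            self.window_start_hours,
            self.labels,
        )


@dataclass
class FeatureSubset:
    """A bitmask over deep-feature indices with its wrapper fitness."""

    mask: np.ndarray
    fitness: float
    provenance: str  # "genetic" | "pso" | "union"
    eval_config: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 1:
            raise ParameterError("mask must be 1-D")

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    @property
    def size(self) -> int:
        return int(self.mask.sum())


def derive_seed(seed: int, *streams: int | str) -> int:
    """Fan one top-level seed out to a per-stage/per-participant seed.

    Deterministic, collision-resistant enough for simulation use, and kept
    below 2**31 so downstream libraries accept it.
    """
    mask = 0xFFFFFFFFFFFFFFFF
    h = (int(seed) * 0x9E3779B97F4A7C15) & mask
    for s in streams:
        if isinstance(s, str):
            s = sum((i + 1) * b for i, b in enumerate(s.encode()))
        h ^= ((int(s) & mask) + 0x9E3779B97F4A7C15 + ((h << 6) & mask) + (h >> 2)) & mask
        h &= mask
    return h % (2**31 - 1)
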