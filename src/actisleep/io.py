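"""Epoch-level actigraphy CSV I/O (two dialects) and config loading.

Dialects
--------
``simple``
    Header ``participant_id,timestamp,activity,offwrist`` with ISO-8601
    minute-resolution timestamps. The package's native format.
``mesa_like``
    Columns modeled on public MESA actigraphy exports
    (``mesaid,line,dayofweek,linetime,activity,offwrist``); ``line`` is the
    1-based epoch number and ``linetime`` the local clock time. The export
    carries no calendar date, so reading anchors epoch 0 to an arbitrary
    fixed date (2000-01-01) at the first row's clock time.

Missing counts serialize as empty fields, never sentinel numbers. Paths
ending in ``.gz`` are transparently compressed.
"""

from __future__ import annotations

import logging
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig, load_config  # noqa: F401  (re-exported)
from .types import ActigraphyRecord, FormatError, ParameterError

logger = logging.getLogger(__name__)

_MESA_ANCHOR = datetime(2000, 1, 1)


def _parse_counts(raw: pd.Series) -> np.ndarray:
    counts = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float)
    bad = np.isnan(counts) & raw.notna().to_numpy() & (raw.astype(str).str.strip() != "").to_numpy()
    if bad.any():
        logger.warning("%d unparseable activity values treated as missing", int(bad.sum()))
    return counts


def read_epochs(source, dialect: str = "simple") -> ActigraphyRecord:
    """Read one participant's epoch CSV into a validated record.

    Rows with unparseable counts become missing-count epochs (warning logged).
    Raises FormatError for an empty file or non-monotone timestamps.
    """
    try:
        df = pd.read_csv(source, dtype={"activity": "object"})
    except (pd.errors.EmptyDataError, ValueError) as exc:
        raise FormatError(f"could not parse epoch CSV: {exc}") from exc
    if df.empty:
        raise FormatError("epoch file contains no rows")

    if dialect == "simple":
        required = {"participant_id", "timestamp", "activity", "offwrist"}
        if not required.issubset(df.columns):
            raise FormatError(f"simple dialect requires columns {sorted(required)}")
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
        deltas = ts.diff().dropna()
        if not (deltas == pd.Timedelta(minutes=1)).all():
            raise FormatError("timestamps must be strictly increasing at 1-minute spacing")
        participant = str(df["participant_id"].iloc[0])
        start = ts.iloc[0].to_pydatetime()
    elif dialect == "mesa_like":
        required = {"mesaid", "line", "linetime", "activity", "offwrist"}
        if not required.issubset(df.columns):
            raise FormatError(f"mesa_like dialect requires columns {sorted(required)}")
        lines = df["line"].to_numpy()
        if not np.all(np.diff(lines) == 1):
            raise FormatError("mesa_like 'line' numbers must increase by 1")
        participant = str(df["mesaid"].iloc[0])
        first = datetime.strptime(str(df["linetime"].iloc[0]), "%H:%M:%S")
        start = _MESA_ANCHOR.replace(hour=first.hour, minute=first.minute)
    else:
        raise ParameterError(f"unknown dialect '{dialect}'")

    counts = _parse_counts(df["activity"])
    offwrist = pd.to_numeric(df["offwrist"]).to_numpy(dtype=np.int8)
    return ActigraphyRecord(participant, start, counts, offwrist)


def write_epochs(record: ActigraphyRecord, sink, dialect: str = "simple") -> None:
    """Write a record as epoch CSV; round-trips through :func:`read_epochs`."""
    if len(record) == 0:
        raise ParameterError("cannot write an empty record")
    counts = record.counts
    activity = pd.Series(counts).map(
        lambda v: "" if np.isnan(v) else (f"{int(v)}" if float(v).is_integer() else f"{v!r}")
    )
    if dialect == "simple":
        df = pd.DataFrame(
            {
                "participant_id": record.participant_id,
                "timestamp": [t.strftime("%Y-%m-%dT%H:%M") for t in record.timestamps],
                "activity": activity,
                "offwrist": record.offwrist,
            }
        )
    elif dialect == "mesa_like":
        df = pd.DataFrame(
            {
                "mesaid": record.participant_id,
                "line": np.arange(1, len(record) + 1),
                "dayofweek": [(t.weekday() + 1) for t in record.timestamps],
                "linetime": [t.strftime("%H:%M:%S") for t in record.timestamps],
                "activity": activity,
                "offwrist": record.offwrist,
            }
        )
    else:
        raise ParameterError(f"unknown dialect '{dialect}'")
    df.to_csv(sink, index=False)


def write_ground_truth(truths, sink) -> None:
    """Write the generator's nightly ground truth as a sidecar CSV."""
    rows = []
    for gt in truths:
        for night, day_type in zip(gt.nights, gt.day_types):
            rows.append(
                {
                    "participant_id": gt.participant_id,
                    "night_index": night.night_index,
                    "day_type": day_type,
                    "efficiency": night.efficiency,
                    "latency": night.latency,
                    "waso": night.waso,
                    "duration": night.duration,
                    "midpoint": night.midpoint,
                    "sqw_score": gt.sqw_label.score,
                    "sqw_class": gt.sqw_label.class_id,
                    "cons_score": gt.cons_label.score,
                    "cons_class": gt.cons_label.class_id,
                }
            )
    pd.DataFrame(rows).to_csv(sink, index=False)


def read_ground_truth_labels(source, metric: str) -> dict[str, int]:
    """Map participant_id -> class for the requested metric from a sidecar CSV."""
    df = pd.read_csv(source, dtype={"participant_id": str})
    col = "sqw_class" if metric == "SleepQualWeek" else "cons_class"
    return df.groupby("participant_id")[col].first().astype(int).to_dict()
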