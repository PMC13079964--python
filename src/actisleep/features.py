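"""Dual feature extraction: LSTM deep features fused with statistical features.

Each 24-h window yields (a) a deep feature vector — the last LSTM layer's
final-time-step output, 15-dimensional for the weekly-quality network and
40-dimensional for the consistency network — and (b) three hand-crafted
statistics: mean, population standard deviation, and the fraction of hours
with exactly zero activity. Deep columns come first in the fused matrix and
every column carries a provenance tag ("deep" / "stat").
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ExtractorSpec
from .lstm import LSTMFeatureExtractor
from .types import FeatureMatrix, ParameterError, WindowSet


def statistical_features(window: np.ndarray) -> tuple[float, float, float]:
    """(mean, SD with denominator n, fraction of exactly-zero values)."""
    window = np.asarray(window, dtype=float)
    if window.shape != (24,):
        raise ParameterError(f"window must have length 24, got shape {window.shape}")
    mean = float(window.mean())
    sd = float(window.std(ddof=0))
    zero_percent = float(np.count_nonzero(window == 0) / window.size)
    return mean, sd, zero_percent


def statistical_block(windows: np.ndarray) -> np.ndarray:
    """Vectorized statistical features for an (n, 24) window stack."""
    windows = np.asarray(windows, dtype=float)
    if windows.ndim != 2 or windows.shape[1] != 24:
        raise ParameterError("expected an (n_windows, 24) array")
    return np.column_stack(
        [
            windows.mean(axis=1),
            windows.std(axis=1, ddof=0),
            (windows == 0).sum(axis=1) / windows.shape[1],
        ]
    )


def train_extractor(
    spec: ExtractorSpec, windows: np.ndarray, labels: np.ndarray
) -> LSTMFeatureExtractor:
    """Train the LSTM with a temporary softmax head on the window labels.

    The head supervises training only; downstream stages read the recurrent
    features via :func:`extract_deep_features`.
    """
    windows = np.asarray(windows, dtype=float)
    if windows.ndim != 2 or windows.shape[1] != 24:
        raise ParameterError("expected an (n_windows, 24) array of hourly counts")
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ParameterError("training requires windows from at least two classes")
    return LSTMFeatureExtractor(spec).fit(windows[:, :, None], labels)


def extract_deep_features(extractor: LSTMFeatureExtractor, windows: np.ndarray) -> np.ndarray:
    """One deep feature row per window; deterministic (dropout disabled)."""
    windows = np.asarray(windows, dtype=float)
    if windows.ndim != 2 or windows.shape[1] != 24:
        raise ParameterError("expected an (n_windows, 24) array of hourly counts")
    return extractor.transform(windows[:, :, None])


def fuse_features(
    deep: np.ndarray,
    stat: np.ndarray,
    participant_ids: np.ndarray,
    window_start_hours: np.ndarray,
    labels: np.ndarray | None = None,
) -> FeatureMatrix:
    """Column-wise concatenation, deep columns first, with provenance tags."""
    deep = np.asarray(deep, dtype=float)
    stat = np.asarray(stat, dtype=float)
    if deep.ndim != 2 or stat.ndim != 2:
        raise ParameterError("feature blocks must be 2-D")
    if deep.shape[0] != stat.shape[0]:
        raise ParameterError(
            f"row mismatch: {deep.shape[0]} deep rows vs {stat.shape[0]} stat rows"
        )
    if deep.shape[0] == 0:
        raise ParameterError("feature blocks must have at least one row")
    stat_names = (
        ["stat_mean", "stat_sd", "stat_zero_percent"]
        if stat.shape[1] == 3
        else [f"stat_{i}" for i in range(stat.shape[1])]
    )
    names = [f"deep_{i}" for i in range(deep.shape[1])] + stat_names
    provenance = ["deep"] * deep.shape[1] + ["stat"] * stat.shape[1]
    return FeatureMatrix(
        np.hstack([deep, stat]),
        names,
        provenance,
        np.asarray(participant_ids),
        np.asarray(window_start_hours),
        None if labels is None else np.asarray(labels),
    )


def build_feature_matrix(
    window_sets: list[WindowSet],
    labels_by_participant: dict[str, int],
    spec: ExtractorSpec,
    extractor: LSTMFeatureExtractor | None = None,
    stat_on_normalized: bool = True,
    raw_window_sets: list[WindowSet] | None = None,
) -> tuple[FeatureMatrix, LSTMFeatureExtractor]:
    """Assemble the fused matrix for a cohort of preprocessed window sets.

    Trains the extractor on all windows unless a fitted one is supplied.
    ``raw_window_sets`` feeds the statistical block when
    ``stat_on_normalized`` is False (zero-percent is scale-invariant, but
    mean and SD are not).
    """
    all_windows = np.vstack([ws.windows for ws in window_sets])
    pids = np.concatenate([[ws.participant_id] * len(ws) for ws in window_sets])
    starts = np.concatenate([ws.window_start_hours for ws in window_sets])
    labels = np.array([labels_by_participant[p] for p in pids])

    if extractor is None:
        extractor = train_extractor(spec, all_windows, labels)
    deep = extract_deep_features(extractor, all_windows)

    if stat_on_normalized or raw_window_sets is None:
        stat_src = all_windows
    else:
        stat_src = np.vstack([ws.windows for ws in raw_window_sets])
    stat = statistical_block(stat_src)
    return fuse_features(deep, stat, pids, starts, labels), extractor


def feature_matrix_to_csv(fm: FeatureMatrix, sink) -> None:
    """Round-trippable CSV; the header encodes provenance as name@tag."""
    cols = {f"{n}@{p}": fm.values[:, i] for i, (n, p) in enumerate(zip(fm.feature_names, fm.provenance))}
    df = pd.DataFrame(cols)
    df.insert(0, "participant_id", fm.participant_ids)
    df.insert(1, "window_start_hour", fm.window_start_hours)
    if fm.labels is not None:
        df["label"] = fm.labels
    df.to_csv(sink, index=False)


def feature_matrix_from_csv(source) -> FeatureMatrix:
    df = pd.read_csv(source, dtype={"participant_id": str})
    feat_cols = [c for c in df.columns if "@" in c]
    names = [c.split("@")[0] for c in feat_cols]
    provenance = [c.split("@")[1] for c in feat_cols]
    labels = df["label"].to_numpy() if "label" in df.columns else None
    return FeatureMatrix(
        df[feat_cols].to_numpy(dtype=float),
        names,
        provenance,
        df["participant_id"].to_numpy(),
        df["window_start_hour"].to_numpy(),
        labels,
    )
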