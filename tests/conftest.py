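"""Shared fixtures: small synthetic cohorts and fast training configs."""

from __future__ import annotations

import numpy as np
import pytest

from actisleep import synth
from actisleep.config import ExtractorSpec, PipelineConfig
from actisleep.preprocess import preprocess_record


@pytest.fixture(scope="session")
def sqw_cohort():
    """12-participant weekly-quality cohort (4 per class), 7 days each."""
    spec = {c: (synth.DEFAULT_SQW_PROFILES[c], 4) for c in range(3)}
    records, truths = synth.generate_cohort(spec, n_days=7, seed=11,
                                            calibrate_metric="SleepQualWeek")
    return records, truths


@pytest.fixture(scope="session")
def sqw_windows(sqw_cohort):
    """Pooled normalized windows + per-window labels/groups for the cohort."""
    records, truths = sqw_cohort
    stacks, pids, labels = [], [], []
    for rec, gt in zip(records, truths):
        ws = preprocess_record(rec)
        stacks.append(ws.windows)
        pids += [rec.participant_id] * len(ws)
        labels += [gt.sqw_label.class_id] * len(ws)
    return np.vstack(stacks), np.array(pids), np.array(labels)


@pytest.fixture()
def tiny_spec():
    """A fast LSTM spec for unit tests (architecture-agnostic behavior)."""
    return ExtractorSpec(layer_sizes=(6, 5), epochs=5, batch_size=16,
                         patience=5, seed=3)


@pytest.fixture()
def fast_config():
    """Pipeline config scaled for smoke tests."""
    cfg = PipelineConfig()
    cfg.extractor_sqw = ExtractorSpec(layer_sizes=(8, 6), epochs=4, patience=4, seed=0)
    cfg.genetic.population = 6
    cfg.genetic.generations = 3
    cfg.pso.population = 6
    cfg.pso.iterations = 3
    cfg.cv_folds = 3
    cfg.wrapper_cv_folds = 3
    return cfg
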