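"""End-to-end orchestration: simulate -> preprocess -> score -> extract ->
select -> classify -> explain, with a reproducibility manifest.

One top-level seed fans out to per-stage seeds through a documented hash
(:func:`actisleep.types.derive_seed`), so a manifest fully determines a
rerun. Outputs are assembled in a temporary directory and moved into place
only on success, so a failed run leaves no partial artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
import tempfile
import time
from pathlib import Path

import numpy as np

from . import __version__
from .classify import cross_validate, prepare_design_matrix, run_variant
from .config import PipelineConfig
from .features import feature_matrix_to_csv, fuse_features
from .importance import ImportanceRow, ImportanceTable, permutation_importance, plot_importance
from .io import read_epochs, read_ground_truth_labels, write_epochs, write_ground_truth
from .preprocess import preprocess_record
from .scoring import score_record
from .synth import default_cohort_spec, generate_cohort
from .types import ParameterError, derive_seed

logger = logging.getLogger(__name__)


def make_demo_dataset(metric: str, out_dir: str | Path, seed: int = 7) -> list[Path]:
    """Write a synthetic demo cohort (epoch CSVs + ground-truth sidecar).

    The cohort shape follows the study design this package mirrors:
    28 participants (10/10/8 across three classes) for SleepQualWeek and
    40 (10 per class) for SleepCons. Deterministic for a fixed seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, truths = generate_cohort(
        default_cohort_spec(metric), n_days=7, seed=seed, calibrate_metric=metric
    )
    paths = []
    for rec in records:
        p = out_dir / f"{rec.participant_id}.csv"
        write_epochs(rec, p)
        paths.append(p)
    write_ground_truth(truths, out_dir / "ground_truth.csv")
    return paths


def _load_cohort(input_dir: Path):
    files = sorted(p for p in input_dir.glob("*.csv") if p.name != "ground_truth.csv")
    if not files:
        raise ParameterError(f"no epoch CSV files found in {input_dir}")
    return [read_epochs(p) for p in files]


def cv_permutation_importance(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    names: list[str],
    provenance: list[str],
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    C: float = 0.1,
) -> ImportanceTable:
    """Permutation importance measured on CV test folds (held-out data)."""
    from sklearn.model_selection import StratifiedGroupKFold
    from sklearn.svm import SVC

    from .classify import _resolve_folds

    n_folds = _resolve_folds(y, groups, folds)
    splitter = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    sums = np.zeros(X.shape[1])
    sq_sums = np.zeros(X.shape[1])
    count = 0
    baseline_sum = 0.0
    for fold_idx, (tr, te) in enumerate(splitter.split(X, y, groups)):
        clf = SVC(kernel="linear", C=C, decision_function_shape="ovr", random_state=seed)
        clf.fit(X[tr], y[tr])
        table = permutation_importance(
            clf, X[te], y[te], names, provenance, repeats=repeats,
            seed=derive_seed(seed, "importance", fold_idx),
        )
        vals = np.array([r.mean_importance for r in table.rows])
        sums += vals
        sq_sums += vals**2
        baseline_sum += table.baseline_score
        count += 1
    means = sums / count
    sds = np.sqrt(np.maximum(0.0, sq_sums / count - means**2))
    rows = [ImportanceRow(n, p, float(m), float(s))
            for n, p, m, s in zip(names, provenance, means, sds)]
    order = sorted(range(len(rows)), key=lambda i: (-rows[i].mean_importance, rows[i].name))
    for rank, i in enumerate(order, start=1):
        rows[i].rank = rank
    return ImportanceTable(rows, baseline_sum / count, repeats * count)


def run_pipeline(
    config: PipelineConfig,
    input_dir: str | Path,
    out_dir: str | Path,
    variant: str = "full",
    label_source: str = "ground_truth",  # "ground_truth" | "scored"
    make_figures: bool = False,
) -> dict:
    """Execute the full pipeline on a directory of epoch CSVs.

    Returns the run manifest (also written to ``out_dir/manifest.json``
    along with the evaluation report, importance table, fused features and
    per-night scores).
    """
    config.validate()
    input_dir = Path(input_dir)
    out_dir = Path(out_dir)
    if not input_dir.is_dir():
        raise ParameterError(f"input directory {input_dir} does not exist")
    seed = config.seed
    t0 = time.time()
    stage_log: dict = {}
    tmp = Path(tempfile.mkdtemp(prefix="actisleep_run_"))
    try:
        # ---- load ---------------------------------------------------------
        records = _load_cohort(input_dir)
        stage_log["load"] = {"n_participants": len(records),
                             "n_epochs": int(sum(len(r) for r in records))}

        # ---- labels -------------------------------------------------------
        gt_path = input_dir / "ground_truth.csv"
        scored_rows = []
        if label_source == "ground_truth" and gt_path.exists():
            labels_by_pid = read_ground_truth_labels(gt_path, config.metric)
        else:
            labels_by_pid = {}
            for rec in records:
                nights, day_types, sqw, cons = score_record(rec, config.scoring)
                label = sqw if config.metric == "SleepQualWeek" else cons
                labels_by_pid[rec.participant_id] = label.class_id
                for n in nights:
                    scored_rows.append((rec.participant_id, n))
        stage_log["labels"] = {"source": label_source,
                               "classes": sorted(set(labels_by_pid.values()))}

        # ---- preprocess ---------------------------------------------------
        window_sets = [
            preprocess_record(r, config.window_len, config.step,
                              config.norm_scope, config.hour_alignment)
            for r in records
        ]
        windows = np.vstack([ws.windows for ws in window_sets])
        pids = np.concatenate([[ws.participant_id] * len(ws) for ws in window_sets])
        labels = np.array([labels_by_pid[p] for p in pids])
        stage_log["preprocess"] = {"n_windows": int(windows.shape[0]),
                                   "window_len": config.window_len, "step": config.step}

        # ---- features + selection + classification ------------------------
        fit_seed = derive_seed(seed, "fit")
        if variant == "pure_lstm":
            report = run_variant(variant, windows, pids, labels, config, fit_seed)
        else:
            X, names, prov, extractor, subsets = prepare_design_matrix(
                variant, windows, labels, config, fit_seed, groups=pids
            )
            if variant == "random_forest":
                from sklearn.ensemble import RandomForestClassifier

                clf = RandomForestClassifier(n_estimators=100, random_state=fit_seed)
            elif variant == "gradient_boosting":
                from sklearn.ensemble import GradientBoostingClassifier

                clf = GradientBoostingClassifier(n_estimators=100, random_state=fit_seed)
            else:
                clf = None
            report = cross_validate(
                X, labels, folds=config.cv_folds, seed=fit_seed, groups=pids,
                classifier=clf, C=config.svm_c,
            )
            report.selected_features = names
            report.config_hash = f"{variant}/C{config.svm_c}/folds{config.cv_folds}"
        stage_log["evaluate"] = {"variant": variant,
                                 "selection_skipped": variant in ("no_optimization", "pure_lstm"),
                                 "n_folds": report.n_folds}

        # ---- interpretability ---------------------------------------------
        importance_table = None
        if variant != "pure_lstm":
            importance_table = cv_permutation_importance(
                X, labels, pids, names, prov, folds=config.cv_folds,
                seed=derive_seed(seed, "perm"), C=config.svm_c,
            )
            starts = np.concatenate([ws.window_start_hours for ws in window_sets])
            deep_cols = [i for i, p in enumerate(prov) if p == "deep"]
            stat_cols = [i for i, p in enumerate(prov) if p == "stat"]
            fm = fuse_features(X[:, deep_cols], X[:, stat_cols], pids, starts, labels)
            feature_matrix_to_csv(fm, tmp / "features.csv")
            if subsets is not None:
                with open(tmp / "selected_features.json", "w") as fh:
                    json.dump(
                        {k: {"indices": v.indices.tolist(), "fitness": v.fitness,
                             "provenance": v.provenance} for k, v in subsets.items()},
                        fh, indent=2, default=float,
                    )
            importance_table.to_frame().to_csv(tmp / "importance.csv", index=False)
            if make_figures:
                plot_importance(importance_table, str(tmp / "importance.png"))

        # ---- persist ------------------------------------------------------
        with open(tmp / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, default=float)
        np.savetxt(tmp / "confusion.csv", report.confusion, fmt="%d", delimiter=",")
        if scored_rows:
            import pandas as pd

            pd.DataFrame(
                [
                    {"participant_id": pid, "night_index": n.night_index,
                     "onset": n.onset, "offset": n.offset, "duration": n.duration,
                     "latency": n.latency, "waso": n.waso,
                     "efficiency": n.efficiency, "midpoint": n.midpoint}
                    for pid, n in scored_rows
                ]
            ).to_csv(tmp / "nightly_scores.csv", index=False)

        manifest = {
            "package_version": __version__,
            "config": dataclasses.asdict(config),
            "seed": seed,
            "derived_seeds": {"fit": fit_seed, "perm": derive_seed(seed, "perm")},
            "variant": variant,
            "label_source": label_source,
            "stages": stage_log,
            "metrics": {
                "accuracy": report.accuracy,
                "f1_macro": report.f1_macro,
                "auc_macro_ovr": report.auc_macro_ovr,
                "participant_accuracy": report.participant_accuracy,
            },
            "elapsed_seconds": round(time.time() - t0, 2),
            "output_dir": str(out_dir),
        }
        with open(tmp / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=float)

        if out_dir.exists():
            shutil.rmtree(out_dir)
        out_dir.parent.mkdir(parents=True, exist_ok=True)
        shutil.move(str(tmp), str(out_dir))
        return manifest
    except Exception:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
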