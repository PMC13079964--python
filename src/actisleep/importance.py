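"""Permutation feature importance over the fused feature set.

Importance of a feature is the drop in held-out score when that feature's
column is shuffled, breaking its association with the label:

    importance_f = baseline_score - mean(score after permuting f)

The baseline is computed once; each feature is shuffled ``repeats`` times
with seeded draws. Importances may legitimately be negative, and their sum
has no particular meaning. Importance should be measured on data the
classifier was not fitted to — the pipeline feeds it the CV test folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import ParameterError, StateError


@dataclass
class ImportanceRow:
    name: str
    provenance: str
    mean_importance: float
    sd_importance: float
    rank: int = 0


@dataclass
class ImportanceTable:
    rows: list[ImportanceRow]
    baseline_score: float
    repeats: int

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "feature": r.name,
                    "provenance": r.provenance,
                    "mean_importance": r.mean_importance,
                    "sd_importance": r.sd_importance,
                    "rank": r.rank,
                }
                for r in self.rows
            ]
        )


def permutation_importance(
    classifier,
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str] | None = None,
    provenance: list[str] | None = None,
    metric: str = "accuracy",
    repeats: int = 10,
    seed: int = 0,
) -> ImportanceTable:
    """Seeded permutation importance of every column on held-out data."""
    if metric != "accuracy":
        raise ParameterError("only the accuracy metric is supported")
    if repeats < 1:
        raise ParameterError("repeats must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    try:
        baseline = float(np.mean(classifier.predict(X) == y))
    except Exception as exc:  # unfitted sklearn estimators raise NotFittedError
        raise StateError(f"classifier must be fitted: {exc}") from exc

    n_features = X.shape[1]
    names = feature_names or [f"f{i}" for i in range(n_features)]
    tags = provenance or ["unknown"] * n_features
    rng = np.random.default_rng(seed)

    rows = []
    for j in range(n_features):
        drops = np.empty(repeats)
        for r in range(repeats):
            perm = rng.permutation(X.shape[0])
            Xp = X.copy()
            Xp[:, j] = X[perm, j]
            drops[r] = baseline - float(np.mean(classifier.predict(Xp) == y))
        rows.append(
            ImportanceRow(names[j], tags[j], float(drops.mean()),
                          float(drops.std(ddof=0)))
        )

    # descending importance, ties broken by name for determinism
    order = sorted(range(len(rows)), key=lambda i: (-rows[i].mean_importance, rows[i].name))
    for rank, i in enumerate(order, start=1):
        rows[i].rank = rank
    return ImportanceTable(rows, baseline, repeats)


def rank_features(table: ImportanceTable, top_k: int | None = None) -> list[ImportanceRow]:
    """Top-k rows by descending mean importance (ties by name)."""
    if not table.rows:
        raise ParameterError("importance table is empty")
    if top_k is not None and top_k <= 0:
        raise ParameterError("top_k must be positive")
    ordered = sorted(table.rows, key=lambda r: (-r.mean_importance, r.name))
    return ordered if top_k is None else ordered[: min(top_k, len(ordered))]


def plot_importance(table: ImportanceTable, path: str, top_k: int = 20) -> None:
    """Horizontal bar chart of the top-k importances."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = rank_features(table, top_k)[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(rows) + 1.5))
    colors = ["tab:blue" if r.provenance == "deep" else "tab:orange" for r in rows]
    ax.barh([r.name for r in rows], [r.mean_importance for r in rows],
            xerr=[r.sd_importance for r in rows], color=colors)
    ax.set_xlabel("permutation importance (accuracy drop)")
    ax.set_title("Feature importance (blue = deep, orange = statistical)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
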