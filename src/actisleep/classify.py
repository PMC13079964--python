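"""Final classification and cross-validated evaluation.

The production classifier is a linear SVM with C = 0.1 (one-vs-rest for
multi-class) evaluated by stratified 10-fold cross-validation. Folds are
grouped by participant — all windows of one participant stay in one fold —
because window-level splits would leak participant identity. Metrics:
accuracy, precision/recall/F1 (macro and weighted), one-vs-rest macro AUC
from decision scores, and the confusion matrix; a participant-level report
aggregates window predictions by majority vote (ties go to the worst
class).

Ablation variants mirror the method's published baselines: end-to-end LSTM
classification, no metaheuristic optimization, no statistical features, and
random-forest / gradient-boosting classifiers on the same fused features.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import (
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.svm import SVC

from .config import PipelineConfig
from .features import statistical_block
from .lstm import LSTMFeatureExtractor
from .selection import genetic_search, pso_search, subset_union
from .types import ParameterError

logger = logging.getLogger(__name__)

VARIANTS = (
    "full",
    "pure_lstm",
    "no_optimization",
    "no_stat_features",
    "random_forest",
    "gradient_boosting",
)


@dataclass
class EvalReport:
    accuracy: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    precision_weighted: float
    recall_weighted: float
    f1_weighted: float
    auc_macro_ovr: float
    confusion: np.ndarray
    classes: np.ndarray
    per_fold: list = field(default_factory=list)
    participant_accuracy: float | None = None
    n_folds: int = 0
    seed: int = 0
    config_hash: str = ""
    selected_features: list | None = None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision_macro": self.precision_macro,
            "recall_macro": self.recall_macro,
            "f1_macro": self.f1_macro,
            "precision_weighted": self.precision_weighted,
            "recall_weighted": self.recall_weighted,
            "f1_weighted": self.f1_weighted,
            "auc_macro_ovr": self.auc_macro_ovr,
            "confusion": self.confusion.tolist(),
            "classes": self.classes.tolist(),
            "per_fold": self.per_fold,
            "participant_accuracy": self.participant_accuracy,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "selected_features": self.selected_features,
        }


def train_svm(X: np.ndarray, y: np.ndarray, C: float = 0.1, seed: int = 0) -> SVC:
    """Linear-kernel SVM; multi-class handled one-vs-rest via decision shape."""
    if C <= 0:
        raise ParameterError("C must be > 0")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ParameterError("training requires at least two classes")
    if np.isnan(X).any():
        raise ParameterError("feature matrix must have no missing cells")
    clf = SVC(kernel="linear", C=C, decision_function_shape="ovr", random_state=seed)
    clf.fit(X, y)
    return clf


def ovr_auc(y_true: np.ndarray, scores: np.ndarray, classes: np.ndarray) -> float:
    """One-vs-rest AUC, macro-averaged over classes, from decision scores."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:  # binary decision function: score for classes[1]
        scores = np.column_stack([-scores, scores])
    aucs = []
    for k, c in enumerate(classes):
        mask = y_true == c
        if mask.all() or not mask.any():
            continue
        aucs.append(roc_auc_score(mask, scores[:, k]))
    return float(np.mean(aucs)) if aucs else float("nan")


def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray | None,
    classes: np.ndarray,
) -> dict:
    """All evaluation metrics from pooled held-out predictions."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    acc = float(np.mean(y_true == y_pred))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p_mac, r_mac, f_mac, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=classes, average="macro", zero_division=0
        )
        p_w, r_w, f_w, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=classes, average="weighted", zero_division=0
        )
    auc = ovr_auc(y_true, scores, classes) if scores is not None else float("nan")
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    return {
        "accuracy": acc,
        "precision_macro": float(p_mac),
        "recall_macro": float(r_mac),
        "f1_macro": float(f_mac),
        "precision_weighted": float(p_w),
        "recall_weighted": float(r_w),
        "f1_weighted": float(f_w),
        "auc_macro_ovr": auc,
        "confusion": cm,
    }


def _resolve_folds(y: np.ndarray, groups: np.ndarray | None, folds: int) -> int:
    if groups is None:
        _, counts = np.unique(y, return_counts=True)
        cap = int(counts.min())
    else:
        pairs = {(g, c) for g, c in zip(groups, y)}
        per_class: dict = {}
        for _, c in pairs:
            per_class[c] = per_class.get(c, 0) + 1
        cap = min(per_class.values())
    if cap < 2:
        raise ParameterError("every class needs at least two members (or groups) for CV")
    if cap < folds:
        logger.warning("reducing CV folds from %d to %d (smallest class size)", folds, cap)
        return cap
    return folds


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    groups: np.ndarray | None = None,
    classifier=None,
    C: float = 0.1,
) -> EvalReport:
    """Stratified (optionally participant-grouped) k-fold evaluation.

    Metrics are computed from the pooled held-out predictions; per-fold
    accuracies are retained. Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    n_folds = _resolve_folds(y, groups, folds)
    if groups is None:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(X, y)
    else:
        splitter = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(X, y, groups)

    y_pred = np.empty_like(y)
    score_rows = np.full((y.size, classes.size), np.nan)
    per_fold = []
    for fold_idx, (tr, te) in enumerate(split_iter):
        if classifier is None:
            clf = SVC(kernel="linear", C=C, decision_function_shape="ovr", random_state=seed)
        else:
            from sklearn.base import clone

            clf = clone(classifier)
        if np.unique(y[tr]).size < 2:
            raise ParameterError("degenerate fold: training split has a single class")
        clf.fit(X[tr], y[tr])
        pred = clf.predict(X[te])
        y_pred[te] = pred
        if hasattr(clf, "decision_function"):
            sc = clf.decision_function(X[te])
            if sc.ndim == 1:
                sc = np.column_stack([-sc, sc])
        else:
            sc = clf.predict_proba(X[te])
        # align columns to the global class list
        fold_classes = clf.classes_
        for j, c in enumerate(fold_classes):
            score_rows[te, np.flatnonzero(classes == c)[0]] = sc[:, j]
        per_fold.append({"fold": fold_idx, "accuracy": float(np.mean(pred == y[te])),
                         "n_test": int(te.size)})

    scores = score_rows if not np.isnan(score_rows).any() else None
    metrics = compute_metrics(y, y_pred, scores, classes)
    report = EvalReport(
        accuracy=metrics["accuracy"],
        precision_macro=metrics["precision_macro"],
        recall_macro=metrics["recall_macro"],
        f1_macro=metrics["f1_macro"],
        precision_weighted=metrics["precision_weighted"],
        recall_weighted=metrics["recall_weighted"],
        f1_weighted=metrics["f1_weighted"],
        auc_macro_ovr=metrics["auc_macro_ovr"],
        confusion=metrics["confusion"],
        classes=classes,
        per_fold=per_fold,
        n_folds=n_folds,
        seed=seed,
    )
    if groups is not None:
        report.participant_accuracy = _participant_accuracy(y, y_pred, groups)
    return report


def _participant_accuracy(y: np.ndarray, y_pred: np.ndarray, groups: np.ndarray) -> float:
    """Majority vote over each participant's window predictions (tie -> worst)."""
    correct = 0
    uniq = np.unique(groups)
    for g in uniq:
        idx = groups == g
        votes, counts = np.unique(y_pred[idx], return_counts=True)
        winners = votes[counts == counts.max()]
        vote = winners.max()  # tie -> highest class id = worst
        correct += int(vote == y[idx][0])
    return correct / uniq.size


def prepare_design_matrix(
    variant: str,
    windows: np.ndarray,
    labels: np.ndarray,
    config: PipelineConfig,
    seed: int = 0,
    groups: np.ndarray | None = None,
):
    """Build the variant's design matrix from preprocessed windows.

    Returns (X, names, provenance, extractor, selection_subsets). Handles
    extractor training, statistical features, and (for optimizing variants)
    the dual metaheuristic selection with Eq.-style union of the two masks.
    """
    windows = np.asarray(windows, dtype=float)
    labels = np.asarray(labels)
    spec = config.extractor
    spec = type(spec)(**{**spec.__dict__, "seed": seed})

    extractor = LSTMFeatureExtractor(spec).fit(windows[:, :, None], labels)
    deep = extractor.transform(windows[:, :, None])
    stat = statistical_block(windows)

    subsets = None
    if variant in ("full", "no_stat_features", "random_forest", "gradient_boosting"):
        ga_cfg = type(config.genetic)(**{**config.genetic.__dict__})
        pso_cfg = type(config.pso)(**{**config.pso.__dict__})
        ga_cfg.seed = config.genetic.seed + seed
        pso_cfg.seed = config.pso.seed + seed
        wrapper_folds = config.wrapper_cv_folds
        if groups is not None:
            pairs = {(g, c) for g, c in zip(groups, labels)}
            per_class: dict = {}
            for _, c in pairs:
                per_class[c] = per_class.get(c, 0) + 1
            wrapper_folds = min(wrapper_folds, min(per_class.values()))
        sub_ga = genetic_search(deep, labels, ga_cfg, classifier="svm",
                                cv_folds=wrapper_folds, groups=groups)
        sub_pso = pso_search(deep, labels, pso_cfg, cv_folds=wrapper_folds, groups=groups)
        union = subset_union(sub_ga, sub_pso)
        subsets = {"genetic": sub_ga, "pso": sub_pso, "union": union}
        deep_used = deep[:, union.mask]
        names = [f"deep_{i}" for i in union.indices]
    else:  # no_optimization keeps the whole deep block
        deep_used = deep
        names = [f"deep_{i}" for i in range(deep.shape[1])]

    provenance = ["deep"] * deep_used.shape[1]
    if variant == "no_stat_features":
        X = deep_used
    else:
        X = np.hstack([deep_used, stat])
        names = names + ["stat_mean", "stat_sd", "stat_zero_percent"]
        provenance = provenance + ["stat"] * stat.shape[1]
    return X, names, provenance, extractor, subsets


def run_variant(
    variant: str,
    windows: np.ndarray,
    participant_ids: np.ndarray,
    labels: np.ndarray,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> EvalReport:
    """Run one pipeline variant from preprocessed windows to an EvalReport.

    ``windows`` is the pooled (n_windows, 24) normalized window stack;
    ``labels`` holds the per-window class (inherited from the participant).
    """
    if variant not in VARIANTS:
        raise ParameterError(f"unknown variant '{variant}' (choose from {VARIANTS})")
    config = config or PipelineConfig()
    config.validate()
    windows = np.asarray(windows, dtype=float)
    participant_ids = np.asarray(participant_ids)
    labels = np.asarray(labels)

    if variant == "pure_lstm":
        spec = type(config.extractor)(**{**config.extractor.__dict__, "seed": seed})
        return _cv_pure_lstm(windows, labels, participant_ids, spec, config, seed)

    X, names, _, _, _ = prepare_design_matrix(
        variant, windows, labels, config, seed, groups=participant_ids
    )

    if variant == "random_forest":
        clf = RandomForestClassifier(n_estimators=100, random_state=seed)
    elif variant == "gradient_boosting":
        clf = GradientBoostingClassifier(n_estimators=100, random_state=seed)
    else:
        clf = None  # linear SVM default inside cross_validate

    report = cross_validate(
        X, labels, folds=config.cv_folds, seed=seed, groups=participant_ids,
        classifier=clf, C=config.svm_c,
    )
    report.selected_features = names
    report.config_hash = f"{variant}/C{config.svm_c}/folds{config.cv_folds}"
    return report


def _cv_pure_lstm(windows, labels, groups, spec, config, seed) -> EvalReport:
    """End-to-end LSTM classification, retrained inside each grouped fold."""
    classes = np.unique(labels)
    n_folds = _resolve_folds(labels, groups, config.cv_folds)
    splitter = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    y_pred = np.empty_like(labels)
    score_rows = np.zeros((labels.size, classes.size))
    per_fold = []
    for fold_idx, (tr, te) in enumerate(splitter.split(windows, labels, groups)):
        fold_spec = type(spec)(**{**spec.__dict__, "seed": seed + fold_idx})
        net = LSTMFeatureExtractor(fold_spec).fit(windows[tr][:, :, None], labels[tr])
        probs = net.predict_proba(windows[te][:, :, None])
        for j, c in enumerate(net.classes_):
            score_rows[te, np.flatnonzero(classes == c)[0]] = probs[:, j]
        y_pred[te] = net.predict(windows[te][:, :, None])
        per_fold.append({"fold": fold_idx, "accuracy": float(np.mean(y_pred[te] == labels[te])),
                         "n_test": int(te.size)})
    metrics = compute_metrics(labels, y_pred, score_rows, classes)
    return EvalReport(
        accuracy=metrics["accuracy"],
        precision_macro=metrics["precision_macro"],
        recall_macro=metrics["recall_macro"],
        f1_macro=metrics["f1_macro"],
        precision_weighted=metrics["precision_weighted"],
        recall_weighted=metrics["recall_weighted"],
        f1_weighted=metrics["f1_weighted"],
        auc_macro_ovr=metrics["auc_macro_ovr"],
        confusion=metrics["confusion"],
        classes=classes,
        per_fold=per_fold,
        participant_accuracy=_participant_accuracy(labels, y_pred, groups),
        n_folds=n_folds,
        seed=seed,
        config_hash="pure_lstm",
    )
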