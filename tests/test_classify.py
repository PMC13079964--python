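"""SVM training, cross-validated metrics, and ablation variant wiring."""

import numpy as np
import pytest

from actisleep import classify as cl
from actisleep.types import ParameterError


def test_linear_svm_separates_separable_toy():
    X = np.array([[0, 0], [0.5, 0.5], [1, 1], [5, 5], [5.5, 5.5], [6, 6]], dtype=float)
    y = np.array([0, 0, 0, 1, 1, 1])
    clf = cl.train_svm(X, y)
    assert np.mean(clf.predict(X) == y) == 1.0


def test_train_svm_parameter_errors():
    X = np.zeros((4, 2))
    with pytest.raises(ParameterError):
        cl.train_svm(X, np.zeros(4))
    with pytest.raises(ParameterError):
        cl.train_svm(X, np.array([0, 0, 1, 1]), C=0.0)


def test_conflicting_duplicates_are_irreducible():
    X = np.tile([[1.0, 2.0]], (10, 1))
    y = np.array([0, 1] * 5)
    clf = cl.train_svm(X, y)
    assert np.mean(clf.predict(X) == y) <= 0.5


def test_perfect_features_give_perfect_cv():
    rng = np.random.default_rng(0)
    y = np.arange(60) % 3
    X = np.column_stack([y.astype(float), rng.normal(size=60)])
    report = cl.cross_validate(X, y, folds=10, seed=1)
    assert report.accuracy == 1.0
    assert report.auc_macro_ovr == 1.0


def test_cross_validate_deterministic():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(60, 4))
    y = np.arange(60) % 3
    r1 = cl.cross_validate(X, y, folds=5, seed=3)
    r2 = cl.cross_validate(X, y, folds=5, seed=3)
    assert r1.accuracy == r2.accuracy
    assert r1.per_fold == r2.per_fold
    assert np.array_equal(r1.confusion, r2.confusion)


def test_fold_reduction_warns_and_runs(caplog):
    rng = np.random.default_rng(2)
    X = rng.normal(size=(12, 3))
    y = np.array([0] * 4 + [1] * 4 + [2] * 4)
    report = cl.cross_validate(X, y, folds=10, seed=0)
    assert report.n_folds == 4


def test_grouped_folds_keep_participants_together():
    rng = np.random.default_rng(3)
    groups = np.repeat([f"P{i}" for i in range(12)], 13)
    y = np.repeat(np.arange(12) % 3, 13)
    X = rng.normal(size=(y.size, 4)) + y[:, None]
    report = cl.cross_validate(X, y, folds=4, seed=0, groups=groups)
    assert report.participant_accuracy is not None
    assert report.accuracy > 0.8  # class signal present


def test_stratification_preserves_class_proportions():
    from sklearn.model_selection import StratifiedKFold

    y = np.array([0] * 40 + [1] * 30 + [2] * 30)
    skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
    for _, te in skf.split(np.zeros((100, 1)), y):
        counts = np.bincount(y[te], minlength=3)
        assert abs(counts[0] - 4) <= 1 and abs(counts[1] - 3) <= 1 and abs(counts[2] - 3) <= 1


def test_auc_invariant_to_monotone_score_transform():
    rng = np.random.default_rng(4)
    y = np.array([0] * 10 + [1] * 10 + [2] * 10)
    scores = rng.normal(size=(30, 3)) + np.eye(3)[y] * 1.5
    a1 = cl.ovr_auc(y, scores, np.array([0, 1, 2]))
    a2 = cl.ovr_auc(y, np.exp(scores * 2.0), np.array([0, 1, 2]))
    assert a1 == pytest.approx(a2)


def test_majority_vote_tie_goes_to_worst_class():
    y = np.array([2, 2, 2, 2])
    y_pred = np.array([0, 0, 2, 2])
    groups = np.array(["A", "A", "A", "A"])
    assert cl._participant_accuracy(y, y_pred, groups) == 1.0  # tie -> class 2


def test_unknown_variant_rejected(fast_config):
    with pytest.raises(ParameterError):
        cl.run_variant("boosted_trees", np.zeros((4, 24)), np.array(["a"] * 4),
                       np.array([0, 0, 1, 1]), fast_config)


def test_run_variant_full_and_ablations_on_cohort(sqw_windows, fast_config):
    windows, pids, labels = sqw_windows
    reports = {}
    for variant in ("full", "no_optimization", "no_stat_features"):
        reports[variant] = cl.run_variant(variant, windows, pids, labels,
                                          fast_config, seed=0)
    assert all(0.0 <= r.accuracy <= 1.0 for r in reports.values())
    full_names = reports["full"].selected_features
    assert "stat_zero_percent" in full_names
    assert all(n.startswith("deep_") for n in reports["no_stat_features"].selected_features)
    deep_dim = fast_config.extractor.layer_sizes[-1]
    assert len(reports["no_optimization"].selected_features) == deep_dim + 3


def test_pure_lstm_with_random_labels_is_near_chance(fast_config):
    rng = np.random.default_rng(5)
    windows = rng.uniform(0, 1, (60, 24))
    pids = np.repeat([f"P{i}" for i in range(12)], 5)
    labels = np.repeat(np.arange(12) % 2, 5)
    report = cl.run_variant("pure_lstm", windows, pids, labels, fast_config, seed=0)
    assert 0.2 <= report.accuracy <= 0.8  # chance-band for 2 balanced classes
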