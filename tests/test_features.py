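"""Statistical features (with brute-force oracle), LSTM extractor contracts,
feature fusion and CSV round-trip."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actisleep import features as ft
from actisleep.config import ExtractorSpec
from actisleep.lstm import LSTMFeatureExtractor
from actisleep.types import ConfigError, ParameterError, StateError


# ---- statistical features --------------------------------------------------

def test_statistical_feature_examples():
    assert ft.statistical_features(np.zeros(24)) == (0.0, 0.0, 1.0)
    assert ft.statistical_features(np.ones(24)) == (1.0, 0.0, 0.0)
    half = np.array([0.0] * 12 + [1.0] * 12)
    assert ft.statistical_features(half) == (0.5, 0.5, 0.5)


def test_statistical_features_rejects_wrong_length():
    with pytest.raises(ParameterError):
        ft.statistical_features(np.zeros(23))


@settings(max_examples=50, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_statistical_features_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    w = np.round(rng.uniform(0, 3, 24) * rng.integers(0, 2, 24), 3)
    mean, sd, zp = ft.statistical_features(w)
    assert mean == pytest.approx(sum(w) / 24)
    assert sd == pytest.approx((sum((x - mean) ** 2 for x in w) / 24) ** 0.5)
    assert zp == pytest.approx(sum(1 for x in w if x == 0) / 24)


def test_statistical_block_matches_scalar_path():
    rng = np.random.default_rng(3)
    W = rng.uniform(0, 1, (10, 24))
    block = ft.statistical_block(W)
    for i in range(10):
        assert tuple(block[i]) == pytest.approx(ft.statistical_features(W[i]))


# ---- extractor -------------------------------------------------------------

def _toy_windows(n=60, seed=0):
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    X = rng.normal(0, 0.1, (n, 24)) + y[:, None] * np.linspace(0, 1, 24)
    return X, y


def test_deep_feature_dimension_tracks_last_layer(tiny_spec):
    X, y = _toy_windows()
    net = ft.train_extractor(tiny_spec, X, y)
    feats = ft.extract_deep_features(net, X)
    assert feats.shape == (60, tiny_spec.layer_sizes[-1])


@pytest.mark.parametrize("sizes,dim", [((75, 50, 25, 15), 15), ((100, 80, 60, 40), 40)])
def test_published_architectures_yield_stated_dimensions(sizes, dim):
    spec = ExtractorSpec(layer_sizes=sizes, epochs=1, patience=1, seed=0)
    X, y = _toy_windows(n=24)
    net = ft.train_extractor(spec, X, y)
    assert ft.extract_deep_features(net, X).shape[1] == dim


def test_dropout_one_rejected():
    with pytest.raises(ConfigError):
        ExtractorSpec(dropout=1.0).validate()


def test_single_class_labels_rejected(tiny_spec):
    X, _ = _toy_windows()
    with pytest.raises(ParameterError):
        ft.train_extractor(tiny_spec, X, np.zeros(60))


def test_inference_is_deterministic(tiny_spec):
    X, y = _toy_windows()
    net = ft.train_extractor(tiny_spec, X, y)
    assert np.array_equal(ft.extract_deep_features(net, X), ft.extract_deep_features(net, X))


def test_untrained_extractor_rejected(tiny_spec):
    net = LSTMFeatureExtractor(tiny_spec)
    with pytest.raises(StateError):
        net.transform(np.zeros((2, 24, 1)))


def test_wrong_window_length_rejected(tiny_spec):
    X, y = _toy_windows()
    net = ft.train_extractor(tiny_spec, X, y)
    with pytest.raises(ParameterError):
        ft.extract_deep_features(net, np.zeros((3, 23)))


def test_retraining_same_seed_reproduces_features(tiny_spec):
    X, y = _toy_windows()
    f1 = ft.train_extractor(tiny_spec, X, y).transform(X[:, :, None])
    f2 = ft.train_extractor(tiny_spec, X, y).transform(X[:, :, None])
    assert np.allclose(f1, f2)


# ---- fusion ----------------------------------------------------------------

def _fm(n_deep, n_rows=5):
    rng = np.random.default_rng(0)
    deep = rng.normal(size=(n_rows, n_deep))
    stat = rng.normal(size=(n_rows, 3))
    pids = np.array(["P"] * n_rows)
    starts = np.arange(n_rows)
    return ft.fuse_features(deep, stat, pids, starts)


@pytest.mark.parametrize("n_deep,total", [(15, 18), (40, 43)])
def test_fusion_column_counts(n_deep, total):
    fm = _fm(n_deep)
    assert fm.n_features == total
    assert fm.provenance[:n_deep] == ["deep"] * n_deep
    assert fm.provenance[n_deep:] == ["stat"] * 3


def test_fusion_rejects_row_mismatch_and_empty():
    with pytest.raises(ParameterError, match="row mismatch"):
        ft.fuse_features(np.zeros((4, 2)), np.zeros((5, 3)), np.array([]), np.array([]))
    with pytest.raises(ParameterError):
        ft.fuse_features(np.zeros((0, 2)), np.zeros((0, 3)), np.array([]), np.array([]))


def test_feature_matrix_csv_round_trip(tmp_path):
    fm = _fm(4)
    fm.labels = np.array([0, 1, 0, 1, 0])
    path = tmp_path / "fm.csv"
    ft.feature_matrix_to_csv(fm, path)
    back = ft.feature_matrix_from_csv(path)
    assert np.allclose(back.values, fm.values)
    assert back.provenance == fm.provenance
    assert back.feature_names == fm.feature_names
    assert np.array_equal(back.labels, fm.labels)
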