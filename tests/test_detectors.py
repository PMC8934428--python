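"""Detectors: architecture tables, input transforms, strides, training."""

import numpy as np
import pytest

from seizenergy.detectors import (
    CnnArchitecture,
    CnnDetector,
    RfConfig,
    RnnArchitecture,
    TrainConfig,
    build_cnn,
    build_rnn,
    lintanh,
    load_detector,
    make_training_windows,
    normalize_input,
    save_detector,
    smooth_probs,
    time_derivative,
    train_nn,
    train_rf,
)
from seizenergy.preprocess import ReferencedRecording
from seizenergy.synthetic import SeizureAnnotation
from seizenergy import nn


# ---------------------------------------------------------------------------
# Architecture reports
# ---------------------------------------------------------------------------

CNN_EXPECTED = [
    ("conv1", (1, 232, 15), 1515),
    ("batchnorm1", (1, 232, 15), 60),
    ("maxpool1", (1, 58, 15), 0),
    ("conv2", (1, 48, 15), 2490),
    ("batchnorm2", (1, 48, 15), 60),
    ("maxpool2", (1, 12, 15), 0),
    ("conv3", (1, 8, 10), 760),
    ("batchnorm3", (1, 8, 10), 40),
    ("dense1", (8,), 648),
    ("dense2", (4,), 36),
    ("output", (1,), 5),
]


@pytest.mark.parametrize("name,shape,n_params", CNN_EXPECTED)
def test_cnn_layer_shapes_and_parameter_counts(name, shape, n_params):
    report = CnnArchitecture().describe(4)
    assert report.shape_of(name) == shape
    assert report.params_of(name) == n_params


def test_cnn_total_parameter_count():
    assert CnnArchitecture().describe(4).total_params == 5614


@pytest.mark.parametrize(
    "name,n_params", [("lstm", 2000), ("td_dense", 420), ("output", 21)]
)
def test_rnn_parameter_counts(name, n_params):
    assert RnnArchitecture().describe(4).params_of(name) == n_params


def test_rnn_lstm_parameters_for_other_channel_counts():
    # oracle formula 4 * ((C + h) * h + h), h = 20
    for c in (1, 2, 3, 8):
        assert RnnArchitecture().describe(c).params_of("lstm") == 4 * ((c + 20) * 20 + 20)
    assert RnnArchitecture().describe(2).params_of("lstm") == 1840


def test_built_models_match_reports_and_emit_probabilities(rng):
    cnn, rep_c = build_cnn(CnnArchitecture(), 4, rng=rng)
    rnn, rep_r = build_rnn(RnnArchitecture(), 4, rng=rng)
    assert cnn.n_params() == rep_c.total_params == 5614
    assert rnn.n_params() == rep_r.total_params == 2441
    p = cnn.predict_proba(rng.normal(size=(3, 4, 256)).astype(np.float32))
    q = rnn.predict_proba(rng.normal(size=(3, 256, 4)).astype(np.float32))
    assert np.all((p >= 0) & (p <= 1)) and np.all((q >= 0) & (q <= 1))


def test_cnn_shape_chain_error_names_the_layer():
    with pytest.raises(ValueError, match="conv1"):
        CnnArchitecture(n_input_samples=10).describe(4)


# ---------------------------------------------------------------------------
# Input transforms
# ---------------------------------------------------------------------------

class TestNormalizeInput:
    def test_zero_maps_to_zero(self):
        assert normalize_input(np.zeros(4), 10.0).tolist() == [0, 0, 0, 0]

    def test_closed_form_value(self):
        # x / sd = 5 -> tanh(1.0)
        out = normalize_input(np.array([50.0]), 10.0)
        assert out[0] == pytest.approx(np.tanh(1.0), rel=1e-6)

    def test_monotone_and_bounded(self, rng):
        x = np.sort(rng.normal(scale=100, size=100))
        out = normalize_input(x, 20.0)
        assert np.all(np.diff(out) >= 0)
        assert np.all(np.abs(out) < 1.0)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            normalize_input(np.zeros(3), 0.0)


class TestLintanh:
    @pytest.mark.parametrize(
        "x,expected", [(0.0, 0.0), (2.0, 1.0), (-3.0, -1.0), (0.6, 0.5), (1.2, 1.0)]
    )
    def test_piecewise_definition(self, x, expected):
        assert float(lintanh(x)) == pytest.approx(expected, rel=1e-6)

    def test_deviation_from_tanh_bounded(self):
        g = np.linspace(-8.0, 8.0, 400001)
        assert np.abs(lintanh(g) - np.tanh(g)).max() <= 0.17


class TestTimeDerivative:
    def test_direct_example(self):
        np.testing.assert_array_equal(
            time_derivative(np.array([1.0, 2.0, 4.0, 8.0])), [1.0, 2.0, 4.0]
        )

    def test_constant_gives_zero_and_ramp_gives_slope(self):
        assert np.all(time_derivative(np.full(10, 3.3)) == 0)
        np.testing.assert_allclose(time_derivative(np.arange(10) * 2.0), 2.0)

    def test_keep_length_pads_with_first_difference(self):
        d = time_derivative(np.array([[1.0, 3.0, 6.0]]), keep_length=True)
        np.testing.assert_array_equal(d, [[2.0, 2.0, 3.0]])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            time_derivative(np.array([1.0]))


def test_smooth_probs_median_of_three():
    np.testing.assert_array_equal(smooth_probs(np.array([0.0, 1.0, 0.0]))[1], 0.0)
    mono = np.linspace(0, 1, 7)
    np.testing.assert_allclose(smooth_probs(mono), mono)
    one = np.array([0.4])
    np.testing.assert_array_equal(smooth_probs(one), one)


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------

def _flat_recording(seconds, n_channels=4):
    n = int(seconds * 256)
    rng = np.random.default_rng(0)
    return ReferencedRecording(
        samples=rng.normal(size=(n, n_channels)),
        sampling_rate=256.0,
        channel_labels=tuple(f"ch{i}" for i in range(n_channels)),
        valid_mask=np.ones(n, bool),
    )


class TestMakeTrainingWindows:
    def test_interictal_stride_16(self):
        w, labels, _ = make_training_windows(_flat_recording(10), [], "train", TrainConfig())
        assert len(w) == (2560 - 256) // 16 + 1 == 145
        assert labels.sum() == 0
        assert w.shape[1:] == (4, 256)

    def test_ictal_stride_1(self):
        ann = [SeizureAnnotation(0.0, 10.0)]
        w, labels, _ = make_training_windows(_flat_recording(10), ann, "train", TrainConfig())
        assert labels.sum() == len(labels) == 2560 - 256 + 1 == 2305

    def test_test_role_is_one_window_per_second(self):
        w, _, times = make_training_windows(_flat_recording(10), [], "test", TrainConfig())
        assert len(w) == 10
        np.testing.assert_allclose(times, np.arange(10.0))

    def test_window_label_follows_start_time(self):
        ann = [SeizureAnnotation(3.0, 6.0)]
        _, labels, times = make_training_windows(
            _flat_recording(10), ann, "test", TrainConfig()
        )
        np.testing.assert_array_equal(labels, (times >= 3.0) & (times < 6.0))

    def test_invalid_windows_are_dropped(self):
        rec = _flat_recording(10)
        rec.valid_mask[int(4.5 * 256)] = False
        _, _, times = make_training_windows(rec, [], "test", TrainConfig())
        assert 4.0 not in times and len(times) == 9


# ---------------------------------------------------------------------------
# Random forest
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(0)
    x0 = rng.normal(loc=0.0, size=(100, 64))
    x1 = rng.normal(loc=4.0, size=(100, 64))
    return np.vstack([x0, x1]), np.repeat([0, 1], 100)


class TestTrainRf:
    def test_respects_hyperparameters_by_introspection(self, toy):
        clf = train_rf(*toy, RfConfig())
        assert len(clf.estimators_) == 100
        assert clf.criterion == "entropy"
        assert clf.max_features == 4
        assert clf.bootstrap is True
        assert clf.class_weight == "balanced"
        assert max(t.tree_.max_depth for t in clf.estimators_) <= 10

    def test_separable_toy_reaches_training_accuracy_one(self, toy):
        x, y = toy
        clf = train_rf(x, y, RfConfig())
        assert (clf.predict(x) == y).mean() == 1.0

    def test_deterministic_under_fixed_seed(self, toy):
        x, y = toy
        p1 = train_rf(x, y, RfConfig(rng_seed=5)).predict_proba(x)
        p2 = train_rf(x, y, RfConfig(rng_seed=5)).predict_proba(x)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            train_rf(np.zeros((10, 64)), np.zeros(10), RfConfig())


# ---------------------------------------------------------------------------
# Network training protocol
# ---------------------------------------------------------------------------

def test_warm_start_reproduces_base_predictions_before_training(rng):
    base, _ = build_cnn(CnnArchitecture(), 4, rng=np.random.default_rng(1))
    model, _ = build_cnn(CnnArchitecture(), 4, rng=np.random.default_rng(2))
    x = rng.normal(size=(6, 4, 256)).astype(np.float32)
    train_nn(model, x[:0], np.empty(0), TrainConfig(cnn_epochs=0), kind="cnn",
             base_model=base)
    np.testing.assert_array_equal(model.predict_proba(x), base.predict_proba(x))


def test_rnn_training_requires_validation(rng):
    model, _ = build_rnn(RnnArchitecture(), 4, rng=rng)
    with pytest.raises(ValueError, match="validation"):
        train_nn(model, np.zeros((4, 256, 4), np.float32), np.zeros(4),
                 TrainConfig(), kind="rnn")


def test_cnn_lintanh_inference_close_to_tanh(tiny_records):
    """Embedded-style lintanh inference shifts probabilities only slightly."""
    cfg = TrainConfig(cnn_epochs=3, max_windows_per_class=80, rng_seed=0)
    det = CnnDetector(train_config=cfg).fit(tiny_records[:2])
    rec, _ = tiny_records[2]
    _, p_lin = det.predict_series(rec, squash=lintanh)
    _, p_tanh = det.predict_series(rec, squash=np.tanh)
    assert np.abs(p_lin - p_tanh).max() <= 0.1


def test_predict_rejects_wrong_channel_count(tiny_records):
    cfg = TrainConfig(cnn_epochs=1, max_windows_per_class=40, rng_seed=0)
    det = CnnDetector(train_config=cfg).fit(tiny_records[:2])
    rec, _ = tiny_records[2]
    bad = ReferencedRecording(
        samples=rec.samples[:, :3],
        sampling_rate=rec.sampling_rate,
        channel_labels=rec.channel_labels[:3],
        valid_mask=rec.valid_mask,
    )
    with pytest.raises(ValueError, match="channels"):
        det.predict_series(bad)


def test_detector_roundtrip_through_disk(tmp_path, tiny_records):
    from seizenergy.detectors import RandomForestDetector

    cfg = TrainConfig(cnn_epochs=1, max_windows_per_class=40, rng_seed=0)
    rec, _ = tiny_records[2]
    for det in (
        RandomForestDetector(train_config=cfg).fit(tiny_records[:2]),
        CnnDetector(train_config=cfg).fit(tiny_records[:2]),
    ):
        save_detector(det, tmp_path / det.name)
        loaded = load_detector(tmp_path / det.name)
        t0, p0 = det.predict_series(rec)
        t1, p1 = loaded.predict_series(rec)
        np.testing.assert_array_equal(t0, t1)
        np.testing.assert_allclose(p0, p1, atol=1e-6)
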