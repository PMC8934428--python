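"""The three patient-specific seizure detectors and their training protocol.

* Random forest: 100 trees, entropy criterion, depth <= 10, 4 candidate
  features per split, bootstrap sampling, inverse-class-frequency sample
  weights, fed by the 16-feature x C-channel vectors (scikit-learn).
* CNN: three valid-padding convolutional blocks with batch normalization,
  max pooling and dropout, then an 8/4/1 dense head (see
  :class:`CnnArchitecture` for the exact shape/parameter chain).  Inputs are
  raw 1 s windows divided by the training-set standard deviation and squashed
  through tanh(0.2 x); at inference the piecewise-linear ``lintanh``
  replaces tanh, as an embedded implementation would.
* LSTM-RNN: a 20-cell LSTM over the per-channel time-derivative of the
  window, a time-distributed linear dense layer, global average pooling over
  time and a sigmoid output; trained with early stopping on the validation
  loss of one reserved seizure and median-filtered (width 3) at the output.

Training windows are 256 samples with per-class strides: 16 for interictal,
1 for ictal (train/validation) and 256 (non-overlapping, 1 Hz) for test.  A
window is labelled ictal iff its start time falls inside an annotated
seizure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from . import nn
from .features import featurize_recording
from .preprocess import ReferencedRecording
from .synthetic import SeizureAnnotation

__all__ = [
    "RfConfig",
    "CnnArchitecture",
    "RnnArchitecture",
    "TrainConfig",
    "LayerReport",
    "ArchitectureReport",
    "normalize_input",
    "lintanh",
    "build_cnn",
    "build_rnn",
    "time_derivative",
    "make_training_windows",
    "train_rf",
    "train_nn",
    "smooth_probs",
    "RandomForestDetector",
    "CnnDetector",
    "RnnDetector",
    "make_detector",
]


# ---------------------------------------------------------------------------
# Configuration / architecture declarations
# ---------------------------------------------------------------------------

@dataclass
class RfConfig:
    """Random-forest hyperparameters."""

    n_trees: int = 100
    criterion: str = "entropy"
    max_depth: int = 10
    features_per_node: int = 4
    bootstrap: bool = True
    class_weight: str = "balanced"  # inverse class frequency
    rng_seed: int = 0


@dataclass
class CnnArchitecture:
    """Declarative CNN layer list: 3 conv blocks + 8/4/1 dense head.

    ``describe(C)`` chains the valid-padding output shapes and parameter
    counts for a C x ``n_input_samples`` window, and is shared by the model
    builder and the energy counter.
    """

    n_input_samples: int = 256
    conv_filters: tuple[int, ...] = (15, 15, 10)
    conv_kernels: tuple[int, ...] = (25, 11, 5)
    pool_sizes: tuple[int, ...] = (4, 4)  # after conv blocks 1 and 2
    dropout: float = 0.2
    dense_units: tuple[int, ...] = (8, 4)

    def describe(self, n_channels: int) -> "ArchitectureReport":
        rows: list[LayerReport] = []
        c = n_channels
        t = self.n_input_samples
        rows.append(LayerReport("input", f"Input ({c}x{t})", (c, t, 1), 0))
        maps_in = 1
        height = c
        for i, (f_out, k) in enumerate(zip(self.conv_filters, self.conv_kernels)):
            # first conv kernel spans all channels (height), later ones are 1 x k
            kh = height
            t_out = t - k + 1
            if t_out < 1:
                raise ValueError(f"conv{i + 1}: kernel {k} too long for input length {t}")
            n_par = f_out * (kh * maps_in * k) + f_out
            rows.append(LayerReport(f"conv{i + 1}", f"{f_out} x Conv2D ({kh}x{k})",
                                    (1, t_out, f_out), n_par))
            rows.append(LayerReport(f"batchnorm{i + 1}", "Batch Normalization",
                                    (1, t_out, f_out), 4 * f_out))
            height, t, maps_in = 1, t_out, f_out
            if i < len(self.pool_sizes):
                p = self.pool_sizes[i]
                t //= p
                rows.append(LayerReport(f"maxpool{i + 1}", f"MaxPool2D (1x{p})",
                                        (1, t, f_out), 0))
            rows.append(LayerReport(f"dropout{i + 1}", f"Dropout ({self.dropout})",
                                    (1, t, f_out), 0))
        n_in = t * maps_in
        for i, units in enumerate(self.dense_units):
            rows.append(LayerReport(f"dense{i + 1}", f"Dense ({units})", (units,),
                                    n_in * units + units))
            n_in = units
        rows.append(LayerReport("output", "Sigmoid", (1,), n_in + 1))
        return ArchitectureReport(rows)


@dataclass
class RnnArchitecture:
    """Declarative LSTM network: LSTM(20) -> dropout -> TD dense(20) -> GAP -> dense(1)."""

    n_input_samples: int = 256
    lstm_units: int = 20
    dropout: float = 0.1
    td_units: int = 20

    def describe(self, n_channels: int) -> "ArchitectureReport":
        c, t, h = n_channels, self.n_input_samples, self.lstm_units
        rows = [
            LayerReport("input", f"Input ({c}x{t})", (c, t, 1), 0),
            LayerReport("lstm", f"LSTM ({h})", (t, h), 4 * ((c + h) * h + h)),
            LayerReport("dropout", f"Dropout ({self.dropout})", (t, h), 0),
            LayerReport("td_dense", f"Time-Distributed Dense ({self.td_units})",
                        (t, self.td_units), h * self.td_units + self.td_units),
            LayerReport("gap", "Global Average Pooling 1D", (self.td_units,), 0),
            LayerReport("output", "Dense (1)", (1,), self.td_units + 1),
        ]
        return ArchitectureReport(rows)


@dataclass
class LayerReport:
    name: str
    operation: str
    output_shape: tuple[int, ...]
    n_params: int


@dataclass
class ArchitectureReport:
    rows: list[LayerReport]

    @property
    def total_params(self) -> int:
        return sum(r.n_params for r in self.rows)

    def params_of(self, name: str) -> int:
        for r in self.rows:
            if r.name == name:
                return r.n_params
        raise KeyError(name)

    def shape_of(self, name: str) -> tuple[int, ...]:
        for r in self.rows:
            if r.name == name:
                return r.output_shape
        raise KeyError(name)


@dataclass
class TrainConfig:
    """Training protocol settings for all three detectors."""

    cnn_epochs: int = 500
    cnn_batch: int = 512
    learning_rate: float = 1e-3  # Adam, both networks
    rnn_batch: int = 256
    rnn_max_epochs: int = 100
    patience: int = 10  # early stopping on validation loss (RNN)
    stride_interictal: int = 16
    stride_ictal: int = 1
    stride_test: int = 256
    window_samples: int = 256
    max_windows_per_class: int | None = None  # optional desk-scale subsampling
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.stride_interictal, self.stride_ictal, self.stride_test) < 1:
            raise ValueError("strides must be >= 1")


# ---------------------------------------------------------------------------
# Input transforms
# ---------------------------------------------------------------------------

def normalize_input(x: np.ndarray, sd_train: float, squash=np.tanh) -> np.ndarray:
    """CNN input normalization: tanh(0.2 * x / sd_train), elementwise.

    ``squash`` may be replaced by :func:`lintanh` for embedded-style inference.
    """
    if sd_train <= 0:
        raise ValueError("sd_train must be positive")
    return squash(0.2 * (np.asarray(x, dtype=np.float32) / np.float32(sd_train)))


def lintanh(x):
    """Piecewise-linear tanh approximation: x/1.2 clipped to [-1, 1]."""
    return np.clip(np.asarray(x, dtype=np.float32) / np.float32(1.2), -1.0, 1.0)


def time_derivative(x: np.ndarray, keep_length: bool = False) -> np.ndarray:
    """First difference along the last (time) axis.

    With ``keep_length`` the first difference is repeated once at the start so
    the output matches the input length (the architecture table assumes 256
    steps).
    """
    x = np.asarray(x)
    if x.shape[-1] < 2:
        raise ValueError("need at least 2 samples along the time axis")
    d = np.diff(x, axis=-1)
    if keep_length:
        d = np.concatenate([d[..., :1], d], axis=-1)
    return d


def smooth_probs(p: np.ndarray) -> np.ndarray:
    """Moving median of width 3; the edge windows shrink to the single edge
    sample, so first and last values pass through unchanged."""
    p = np.asarray(p, dtype=np.float64)
    out = p.copy()
    if p.size > 2:
        out[1:-1] = np.median(np.stack([p[:-2], p[1:-1], p[2:]]), axis=0)
    return out


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------

def _ictal_start(t0: float, annotations: list[SeizureAnnotation]) -> bool:
    return any(a.onset <= t0 < a.offset for a in annotations)


def make_training_windows(
    recording: ReferencedRecording,
    annotations: list[SeizureAnnotation],
    role: str,
    config: TrainConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract (windows, labels, start_times) for the given role.

    Train/validation use per-class strides (interictal 16, ictal 1); test uses
    non-overlapping windows (stride 256, i.e. 1 Hz).  Windows overlapping
    invalid samples are dropped.  Returns windows as (M, C, 256).
    """
    if role not in ("train", "validation", "test"):
        raise ValueError(f"unknown role {role!r}")
    n_w = config.window_samples
    n = recording.n_samples
    fs = recording.sampling_rate
    if n <= n_w:
        return (np.empty((0, recording.n_channels, n_w), np.float32),
                np.empty(0, int), np.empty(0, float))

    if role == "test":
        candidates = np.arange(0, n - n_w + 1, config.stride_test)
    else:
        ict = np.arange(0, n - n_w + 1, config.stride_ictal)
        ict = ict[[_ictal_start(s / fs, annotations) for s in ict]]
        inter = np.arange(0, n - n_w + 1, config.stride_interictal)
        inter = inter[[not _ictal_start(s / fs, annotations) for s in inter]]
        candidates = np.sort(np.concatenate([ict, inter]))

    starts, labels = [], []
    for s in candidates:
        if not recording.valid_mask[s : s + n_w].all():
            continue
        starts.append(s)
        labels.append(int(_ictal_start(s / fs, annotations)))
    starts = np.asarray(starts, dtype=int)
    labels = np.asarray(labels, dtype=int)

    windows = np.stack(
        [recording.samples[s : s + n_w].T for s in starts]
    ).astype(np.float32) if len(starts) else np.empty(
        (0, recording.n_channels, n_w), np.float32
    )
    return windows, labels, starts / fs


# ---------------------------------------------------------------------------
# Model builders
# ---------------------------------------------------------------------------

def build_cnn(
    arch: CnnArchitecture, n_channels: int, rng: np.random.Generator | None = None
) -> tuple[nn.Sequential, ArchitectureReport]:
    """Instantiate the CNN and return it with its shape/parameter report."""
    if n_channels < 1:
        raise ValueError("need at least one channel")
    report = arch.describe(n_channels)
    layers: list[nn.Layer] = []
    c_in = n_channels
    maps = 1
    for i, (f_out, k) in enumerate(zip(arch.conv_filters, arch.conv_kernels)):
        layers.append(nn.Conv1d(c_in * maps if i == 0 else maps, f_out, k))
        layers.append(nn.BatchNorm(f_out))
        layers.append(nn.ReLU())
        if i < len(arch.pool_sizes):
            layers.append(nn.MaxPool1d(arch.pool_sizes[i]))
        layers.append(nn.Dropout(arch.dropout))
        maps = f_out
    layers.append(nn.Flatten())
    n_in = report.shape_of(f"dropout{len(arch.conv_filters)}")
    n_flat = int(np.prod(n_in))
    for units in arch.dense_units:
        layers.append(nn.Dense(n_flat, units))
        layers.append(nn.ReLU())
        n_flat = units
    layers.append(nn.Dense(n_flat, 1))
    model = nn.Sequential(layers, rng=rng or np.random.default_rng(0))
    _check_counts(model, report)
    return model, report


def build_rnn(
    arch: RnnArchitecture, n_channels: int, rng: np.random.Generator | None = None
) -> tuple[nn.Sequential, ArchitectureReport]:
    """Instantiate the LSTM network and return it with its parameter report."""
    if n_channels < 1:
        raise ValueError("need at least one channel")
    report = arch.describe(n_channels)
    model = nn.Sequential(
        [
            nn.LSTM(n_channels, arch.lstm_units),
            nn.Dropout(arch.dropout),
            nn.TimeDistributedDense(arch.lstm_units, arch.td_units),
            nn.GlobalAveragePooling(),
            nn.Dense(arch.td_units, 1),
        ],
        rng=rng or np.random.default_rng(0),
    )
    _check_counts(model, report)
    return model, report


def _check_counts(model: nn.Sequential, report: ArchitectureReport) -> None:
    if model.n_params() != report.total_params:
        raise AssertionError(
            f"instantiated parameter count {model.n_params()} does not match "
            f"architecture report {report.total_params}"
        )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _subsample_balanced(
    windows: np.ndarray, labels: np.ndarray, cap: int | None, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Cap each class at ``cap`` windows (seeded, order-preserving).

    Desk-scale control for the heavily overlapping stride-1/stride-16
    training windows; ``cap=None`` keeps everything.
    """
    if cap is None:
        return windows, labels
    rng = np.random.default_rng(seed + 7919)
    keep = []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        if len(idx) > cap:
            idx = np.sort(rng.choice(idx, size=cap, replace=False))
        keep.append(idx)
    keep = np.sort(np.concatenate(keep))
    return windows[keep], labels[keep]


def _class_weights(labels: np.ndarray) -> np.ndarray:
    """Per-sample weights inversely proportional to class frequency."""
    n = len(labels)
    weights = np.ones(n, np.float32)
    for cls in (0, 1):
        m = labels == cls
        if m.any():
            weights[m] = n / (2.0 * m.sum())
    return weights


def train_rf(features: np.ndarray, labels: np.ndarray, config: RfConfig) -> RandomForestClassifier:
    """Fit the random forest; refuses single-class input."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    clf = RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion=config.criterion,
        max_depth=config.max_depth,
        max_features=config.features_per_node,
        bootstrap=config.bootstrap,
        class_weight=config.class_weight,
        random_state=config.rng_seed,
        n_jobs=1,
    )
    clf.fit(np.asarray(features), labels)
    return clf


def train_nn(
    model: nn.Sequential,
    windows: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig,
    kind: str,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
    base_model: nn.Sequential | None = None,
) -> dict:
    """Train a network in place; returns the training history.

    ``kind='cnn'``: class-weighted loss, fixed epoch budget, batch 512.
    ``kind='rnn'``: batch 256, early stopping (patience on validation loss);
    raises if no validation data is supplied.
    ``base_model`` warm-starts the weights (fine-tuning).
    """
    if base_model is not None:
        model.set_weights(base_model.get_weights())
    rng = np.random.default_rng(config.rng_seed + 104729)
    common = dict(lr=config.learning_rate, rng=rng,
                  sample_weight=_class_weights(labels))
    if kind == "cnn":
        return nn.fit(model, windows, labels, epochs=config.cnn_epochs,
                      batch_size=config.cnn_batch, validation=validation, **common)
    if kind == "rnn":
        if validation is None:
            raise ValueError("RNN early stopping requires validation data")
        return nn.fit(model, windows, labels, epochs=config.rnn_max_epochs,
                      batch_size=config.rnn_batch, validation=validation,
                      patience=config.patience, **common)
    raise ValueError(f"unknown network kind {kind!r}")


# ---------------------------------------------------------------------------
# Detector front-ends (shared fit/predict interface for the evaluation loop)
# ---------------------------------------------------------------------------

Record = tuple[ReferencedRecording, list[SeizureAnnotation]]


class _DetectorBase:
    name: str = "?"

    def fit(self, train_records: list[Record],
            validation_record: Record | None = None) -> "_DetectorBase":
        raise NotImplementedError

    def predict_series(self, recording: ReferencedRecording) -> tuple[np.ndarray, np.ndarray]:
        """(window start times, per-second seizure probabilities)."""
        raise NotImplementedError


class RandomForestDetector(_DetectorBase):
    name = "rf"

    def __init__(self, rf_config: RfConfig | None = None,
                 train_config: TrainConfig | None = None):
        self.rf_config = rf_config or RfConfig()
        self.train_config = train_config or TrainConfig()
        self.model: RandomForestClassifier | None = None

    def fit(self, train_records, validation_record=None):
        frames = [featurize_recording(rec, ann) for rec, ann in train_records]
        if validation_record is not None:
            # the RF has no early stopping; fold the reserved record back in
            frames.append(featurize_recording(*validation_record))
        import pandas as pd

        df = pd.concat(frames, ignore_index=True)
        x = df.drop(columns=["window_start_s", "label"]).to_numpy()
        self._n_features = x.shape[1]
        self.model = train_rf(x, df["label"].to_numpy(), self.rf_config)
        return self

    def predict_series(self, recording):
        df = featurize_recording(recording, [])
        x = df.drop(columns=["window_start_s", "label"]).to_numpy()
        if x.shape[1] != self._n_features:
            raise ValueError(f"expected {self._n_features} features, got {x.shape[1]}")
        probs = self.model.predict_proba(x)[:, list(self.model.classes_).index(1)]
        return df["window_start_s"].to_numpy(), probs


class CnnDetector(_DetectorBase):
    name = "cnn"

    def __init__(self, arch: CnnArchitecture | None = None,
                 train_config: TrainConfig | None = None,
                 base_model: nn.Sequential | None = None):
        self.arch = arch or CnnArchitecture()
        self.train_config = train_config or TrainConfig()
        self.base_model = base_model
        self.model: nn.Sequential | None = None
        self.sd_train: float | None = None

    def _gather(self, records: list[Record], role: str):
        ws, ls = [], []
        for rec, ann in records:
            w, l, _ = make_training_windows(rec, ann, role, self.train_config)
            ws.append(w)
            ls.append(l)
        return np.concatenate(ws), np.concatenate(ls)

    def fit(self, train_records, validation_record=None):
        if validation_record is not None:
            train_records = list(train_records) + [validation_record]
        windows, labels = self._gather(train_records, "train")
        windows, labels = _subsample_balanced(
            windows, labels, self.train_config.max_windows_per_class,
            self.train_config.rng_seed,
        )
        self.sd_train = float(windows.std())
        x = normalize_input(windows, self.sd_train, squash=np.tanh)
        self.model, self.report = build_cnn(
            self.arch, windows.shape[1],
            rng=np.random.default_rng(self.train_config.rng_seed),
        )
        self.history = train_nn(self.model, x, labels, self.train_config,
                                kind="cnn", base_model=self.base_model)
        return self

    def predict_series(self, recording, squash=lintanh):
        windows, _, times = make_training_windows(
            recording, [], "test", self.train_config
        )
        if windows.shape[1] != self.model.layers[0].c_in:
            raise ValueError(
                f"expected {self.model.layers[0].c_in} channels, got {windows.shape[1]}"
            )
        x = normalize_input(windows, self.sd_train, squash=squash)
        return times, self.model.predict_proba(x)


class RnnDetector(_DetectorBase):
    name = "rnn"

    def __init__(self, arch: RnnArchitecture | None = None,
                 train_config: TrainConfig | None = None):
        self.arch = arch or RnnArchitecture()
        self.train_config = train_config or TrainConfig()
        self.model: nn.Sequential | None = None
        self.sd_train: float | None = None

    def _prepare(self, windows: np.ndarray) -> np.ndarray:
        # (M, C, 256) -> per-channel derivative, padded to 256 steps, scaled
        # by the training-derivative SD -> (M, 256, C) for the recurrence
        d = time_derivative(windows, keep_length=True)
        return (d / np.float32(self.sd_train)).transpose(0, 2, 1).astype(np.float32)

    def fit(self, train_records, validation_record=None):
        if validation_record is None:
            raise ValueError("the RNN reserves one seizure record for validation")
        ws, ls = [], []
        for rec, ann in train_records:
            w, l, _ = make_training_windows(rec, ann, "train", self.train_config)
            ws.append(w)
            ls.append(l)
        windows, labels = np.concatenate(ws), np.concatenate(ls)
        cap = self.train_config.max_windows_per_class
        seed = self.train_config.rng_seed
        windows, labels = _subsample_balanced(windows, labels, cap, seed)
        vrec, vann = validation_record
        vwin, vlab, _ = make_training_windows(vrec, vann, "validation", self.train_config)
        vwin, vlab = _subsample_balanced(vwin, vlab, cap, seed + 1)
        self.sd_train = float(time_derivative(windows, keep_length=True).std())
        x = self._prepare(windows)
        xv = self._prepare(vwin)
        self.model, self.report = build_rnn(
            self.arch, windows.shape[1],
            rng=np.random.default_rng(self.train_config.rng_seed),
        )
        self.history = train_nn(self.model, x, labels, self.train_config,
                                kind="rnn", validation=(xv, vlab))
        return self

    def predict_series(self, recording):
        windows, _, times = make_training_windows(
            recording, [], "test", self.train_config
        )
        if windows.shape[1] != self.model.layers[0].n_in:
            raise ValueError(
                f"expected {self.model.layers[0].n_in} channels, got {windows.shape[1]}"
            )
        probs = self.model.predict_proba(self._prepare(windows))
        return times, smooth_probs(probs)


def save_detector(detector: _DetectorBase, path) -> None:
    """Persist a fitted detector: JSON manifest + weight container.

    Networks store their weights in an ``.npz`` container; the random forest
    uses pickle (the scikit-learn standard).
    """
    import json
    import pickle
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"kind": detector.name}
    if isinstance(detector, RandomForestDetector):
        manifest["n_features"] = detector._n_features
        with open(path / "rf.pkl", "wb") as fh:
            pickle.dump(detector.model, fh)
    else:
        manifest["sd_train"] = detector.sd_train
        weights = detector.model.get_weights()
        np.savez(path / "weights.npz", **{f"w{i}": w for i, w in enumerate(weights)})
        manifest["n_weights"] = len(weights)
        manifest["n_channels"] = int(
            detector.model.layers[0].c_in
            if detector.name == "cnn"
            else detector.model.layers[0].n_in
        )
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_detector(path) -> _DetectorBase:
    import json
    import pickle
    from pathlib import Path

    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    kind = manifest["kind"]
    det = make_detector(kind)
    if kind == "rf":
        with open(path / "rf.pkl", "rb") as fh:
            det.model = pickle.load(fh)
        det._n_features = manifest["n_features"]
        return det
    det.sd_train = manifest["sd_train"]
    builder = build_cnn if kind == "cnn" else build_rnn
    arch = det.arch
    det.model, det.report = builder(arch, manifest["n_channels"])
    data = np.load(path / "weights.npz")
    det.model.set_weights([data[f"w{i}"] for i in range(manifest["n_weights"])])
    return det


def make_detector(kind: str, train_config: TrainConfig | None = None,
                  rf_config: RfConfig | None = None) -> _DetectorBase:
    if kind == "rf":
        return RandomForestDetector(rf_config, train_config)
    if kind == "cnn":
        return CnnDetector(train_config=train_config)
    if kind == "rnn":
        return RnnDetector(train_config=train_config)
    raise ValueError(f"unknown detector {kind!r}")
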