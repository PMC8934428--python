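"""Schema-validated run configuration (YAML or JSON, unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .detectors import RfConfig, TrainConfig
from .synthetic import SyntheticConfig

__all__ = ["RunConfig", "SyntheticSection", "TrainSection", "RfSection", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticSection(_Strict):
    """Benchmark dataset: one record per seizure, seizure in the middle."""

    n_records: int = 5
    record_duration_s: float = 60.0
    seizure_onset_s: float = 25.0
    seizure_duration_s: float = 10.0
    sampling_rate: float = 256.0
    n_electrodes: int = 5
    ictal_band: tuple[float, float] = (4.0, 8.0)
    ictal_amplitude: float = 60.0
    background_rms: float = 20.0
    background_exponent: float = 1.0
    artifact_rate: float = 0.0
    artifact_amplitude: float = 2000.0

    def record_config(self, index: int, base_seed: int) -> SyntheticConfig:
        return SyntheticConfig(
            sampling_rate=self.sampling_rate,
            n_electrodes=self.n_electrodes,
            duration=self.record_duration_s,
            seizure_intervals=((self.seizure_onset_s,
                                self.seizure_onset_s + self.seizure_duration_s),),
            ictal_band=self.ictal_band,
            ictal_amplitude=self.ictal_amplitude,
            background_rms=self.background_rms,
            background_exponent=self.background_exponent,
            artifact_rate=self.artifact_rate,
            artifact_amplitude=self.artifact_amplitude,
            rng_seed=(base_seed * 1009 + index) % (2**31 - 1),
        )


class TrainSection(_Strict):
    cnn_epochs: int = 50
    cnn_batch: int = 512
    learning_rate: float = 1e-3
    rnn_batch: int = 256
    rnn_max_epochs: int = 60
    patience: int = 10
    stride_interictal: int = 16
    stride_ictal: int = 1
    stride_test: int = 256
    max_windows_per_class: int | None = 512

    def to_train_config(self, rng_seed: int) -> TrainConfig:
        return TrainConfig(rng_seed=rng_seed, **self.model_dump())


class RfSection(_Strict):
    n_trees: int = 100
    criterion: str = "entropy"
    max_depth: int = 10
    features_per_node: int = 4
    bootstrap: bool = True
    class_weight: str = "balanced"

    def to_rf_config(self, rng_seed: int) -> RfConfig:
        return RfConfig(rng_seed=rng_seed, **self.model_dump())


class RunConfig(_Strict):
    """End-to-end comparison run: simulate, train, evaluate, estimate energy."""

    output_dir: str = "comparison_run"
    detectors: tuple[str, ...] = ("rf", "cnn", "rnn")
    seed: int = 0
    synthetic: SyntheticSection = Field(default_factory=SyntheticSection)
    train: TrainSection = Field(default_factory=TrainSection)
    rf: RfSection = Field(default_factory=RfSection)

    @field_validator("detectors")
    @classmethod
    def _known_detectors(cls, v):
        unknown = set(v) - {"rf", "cnn", "rnn"}
        if unknown:
            raise ValueError(f"unknown detectors: {sorted(unknown)}")
        if not v:
            raise ValueError("at least one detector required")
        return tuple(v)


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    payload = yaml.safe_load(Path(path).read_text())
    return RunConfig.model_validate(payload or {})
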