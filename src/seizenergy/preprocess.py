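"""Signal conditioning chain for the seizure detectors.

The chain runs, in this fixed order:

1. ``drop_invalid`` — exclude segments flagged invalid (electrode deficiency,
   impedance measurement) from all downstream 1 s analysis windows;
2. ``bandpass`` — 10th-order Chebyshev type-II IIR bandpass, 40 dB stopband
   attenuation, stopband edges 0.1 and 48 Hz (suppresses drift, power-line
   noise and broadband EMG);
3. ``reject_high_amplitude`` — mark every 1 s period containing a sample with
   |x| > 1 mV invalid (sharp transient artifacts);
4. ``rereference`` — subtract the central electrode from each peripheral one,
   yielding C = n_electrodes - 1 analysis channels.

Filtering is causal (single-pass second-order sections), matching an online
embedded detector; no zero-phase refinement is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .synthetic import EegRecording

__all__ = [
    "FilterSpec",
    "ReferencedRecording",
    "drop_invalid",
    "bandpass",
    "reject_high_amplitude",
    "rereference",
    "preprocess_recording",
]

#: Length of the artifact-rejection / analysis grid period, seconds.
REJECTION_PERIOD_S = 1.0
#: Amplitude-rejection threshold, microvolt (strictly greater than).
REJECTION_THRESHOLD_UV = 1000.0


@dataclass
class FilterSpec:
    """Bandpass design parameters (Chebyshev type II, specified by stopband)."""

    order: int = 10
    stopband_low: float = 0.1  # Hz
    stopband_high: float = 48.0  # Hz
    stopband_attenuation: float = 40.0  # dB

    def __post_init__(self) -> None:
        if not 0 < self.stopband_low < self.stopband_high:
            raise ValueError("require 0 < stopband_low < stopband_high")
        if self.order % 2:
            raise ValueError("bandpass order must be even (order/2 per edge)")

    def design_sos(self, sampling_rate: float):
        if self.stopband_high >= sampling_rate / 2:
            raise ValueError(
                f"stopband_high {self.stopband_high} Hz not below Nyquist "
                f"({sampling_rate / 2} Hz)"
            )
        sos = signal.cheby2(
            self.order // 2,
            self.stopband_attenuation,
            [self.stopband_low, self.stopband_high],
            btype="bandpass",
            fs=sampling_rate,
            output="sos",
        )
        # Poles of every biquad must be inside the unit circle.
        _, poles, _ = signal.sos2zpk(sos)
        if np.any(np.abs(poles) >= 1.0):
            raise ValueError(
                f"unstable Chebyshev-II design at fs={sampling_rate} Hz "
                f"(|pole|max={np.abs(poles).max():.6f})"
            )
        return sos


@dataclass
class ReferencedRecording:
    """Peripheral-minus-central channels; C = n_electrodes - 1."""

    samples: np.ndarray  # (n_samples, C) uV
    sampling_rate: float
    channel_labels: tuple[str, ...]
    valid_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.samples.shape[1] != len(self.channel_labels):
            raise ValueError("one label per channel required")
        if self.valid_mask.shape != (self.samples.shape[0],):
            raise ValueError("valid_mask must match the time axis length")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


def _period_grid_invalid(
    valid_mask: np.ndarray,
    bad_samples: np.ndarray,
    sampling_rate: float,
    period: float,
) -> np.ndarray:
    """Invalidate every grid-aligned period containing a flagged sample."""
    n = len(valid_mask)
    samples_per_period = int(round(period * sampling_rate))
    out = valid_mask.copy()
    for start in range(0, n, samples_per_period):
        stop = min(start + samples_per_period, n)
        if bad_samples[start:stop].any():
            out[start:stop] = False
    return out


def drop_invalid(recording: EegRecording) -> EegRecording:
    """Expand invalid samples to whole 1 s grid periods.

    Samples themselves are kept in place (so the time axis and seizure
    annotations stay aligned); windowing stages skip any analysis window that
    overlaps an invalid period.
    """
    out = recording.copy()
    out.valid_mask = _period_grid_invalid(
        out.valid_mask,
        ~out.valid_mask,
        recording.sampling_rate,
        REJECTION_PERIOD_S,
    )
    return out


def bandpass(recording: EegRecording, spec: FilterSpec | None = None) -> EegRecording:
    """Causal Chebyshev-II bandpass, each electrode independently."""
    spec = spec or FilterSpec()
    sos = spec.design_sos(recording.sampling_rate)
    out = recording.copy()
    out.samples = signal.sosfilt(sos, recording.samples, axis=0)
    return out


def reject_high_amplitude(
    recording: EegRecording,
    threshold: float = REJECTION_THRESHOLD_UV,
    period: float = REJECTION_PERIOD_S,
) -> EegRecording:
    """Invalidate each ``period``-long grid interval with any |x| > threshold.

    The threshold is strict (a sample at exactly ``threshold`` uV is kept) and
    applied per electrode on the pre-reference signal.  Idempotent.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    bad = (np.abs(recording.samples) > threshold).any(axis=1)
    out = recording.copy()
    out.valid_mask = _period_grid_invalid(out.valid_mask, bad, recording.sampling_rate, period)
    return out


def rereference(recording: EegRecording, central_label: str | None = None) -> ReferencedRecording:
    """Subtract the central electrode from every peripheral electrode.

    Output channel order follows the peripheral electrode order of the input.
    """
    central = central_label if central_label is not None else recording.central_label
    if central not in recording.labels:
        raise ValueError(f"unknown central electrode {central!r}; labels: {recording.labels}")
    c_idx = recording.labels.index(central)
    periph = [i for i in range(recording.n_electrodes) if i != c_idx]
    ref = recording.samples[:, periph] - recording.samples[:, [c_idx]]
    return ReferencedRecording(
        samples=ref,
        sampling_rate=recording.sampling_rate,
        channel_labels=tuple(f"{recording.labels[i]}-{central}" for i in periph),
        valid_mask=recording.valid_mask.copy(),
        meta=dict(recording.meta),
    )


def preprocess_recording(
    recording: EegRecording,
    filter_spec: FilterSpec | None = None,
    threshold: float = REJECTION_THRESHOLD_UV,
    central_label: str | None = None,
) -> ReferencedRecording:
    """Run the full conditioning chain in its fixed order."""
    rec = drop_invalid(recording)
    rec = bandpass(rec, filter_spec)
    rec = reject_high_amplitude(rec, threshold=threshold)
    return rereference(rec, central_label)
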