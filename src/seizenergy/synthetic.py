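"""Synthetic multichannel EEG with seizure annotations.

Generates recordings with the statistical structure the downstream stages
assume: a 1/f-like interictal background at microvolt scale, rhythmic ictal
discharges confined to a configurable frequency band (stronger on peripheral
electrodes than on the central one, mimicking a focal source), and sparse
high-amplitude transient artifacts.  Everything is deterministic under a
single seed, which is expanded into independent per-component substreams so
that, e.g., enabling artifacts does not perturb the background noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SyntheticConfig",
    "EegRecording",
    "SeizureAnnotation",
    "generate_recording",
    "inject_artifacts",
]

#: Electrode labels for the default 5-electrode montage; the last one is the
#: centrally positioned electrode used as reference.
DEFAULT_LABELS = ("P1", "P2", "P3", "P4", "Cz")

# Seed-sequence stream indices (fixed so adding components never reshuffles
# existing ones).
_STREAM_BACKGROUND = 0
_STREAM_ICTAL = 1
_STREAM_ARTIFACT = 2


@dataclass
class SeizureAnnotation:
    """Electrographic seizure interval, in seconds from record start."""

    onset: float
    offset: float

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError(f"offset ({self.offset}) must exceed onset ({self.onset})")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class EegRecording:
    """Multichannel EEG carrier: samples in microvolt, time along axis 0."""

    samples: np.ndarray  # (n_samples, n_electrodes), float, uV
    sampling_rate: float
    labels: tuple[str, ...]
    central_label: str
    valid_mask: np.ndarray  # (n_samples,) bool
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (time x electrodes)")
        if self.samples.shape[1] != len(self.labels):
            raise ValueError("one label per electrode column required")
        if self.valid_mask.shape != (self.samples.shape[0],):
            raise ValueError("valid_mask must match the time axis length")
        if self.central_label not in self.labels:
            raise ValueError(f"central label {self.central_label!r} not among {self.labels}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def copy(self) -> "EegRecording":
        return replace(
            self,
            samples=self.samples.copy(),
            valid_mask=self.valid_mask.copy(),
            meta=dict(self.meta),
        )


@dataclass
class SyntheticConfig:
    """Study conditions for the simulator.

    Defaults mirror the recording setup the detectors are designed for:
    256 Hz sampling, five electrodes (four peripheral + one central reference),
    microvolt-scale 1/f background, and ictal rhythmic activity in the theta
    band (4-8 Hz).
    """

    sampling_rate: float = 256.0
    n_electrodes: int = 5
    duration: float = 60.0
    seizure_intervals: tuple[tuple[float, float], ...] = ()
    ictal_band: tuple[float, float] = (4.0, 8.0)
    ictal_amplitude: float = 60.0  # uV, peak of the rhythmic component
    background_rms: float = 20.0  # uV, interictal RMS per electrode
    background_exponent: float = 1.0  # spectral density ~ 1/f**exponent
    artifact_rate: float = 0.0  # events per hour
    artifact_amplitude: float = 2000.0  # uV peak, > 1 mV exercises rejection
    central_ictal_weight: float = 0.5  # ictal gain on the central electrode
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 2.0 * self.ictal_band[1]:
            raise ValueError("sampling_rate must exceed twice the ictal band's high edge")
        if self.n_electrodes < 2:
            raise ValueError("need at least one peripheral and one central electrode")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        ivals = sorted((float(a), float(b)) for a, b in self.seizure_intervals)
        for onset, offset in ivals:
            if not 0.0 <= onset < offset <= self.duration:
                raise ValueError(f"seizure interval ({onset}, {offset}) outside [0, {self.duration}]")
        for (_, off_prev), (on_next, _) in zip(ivals, ivals[1:]):
            if on_next < off_prev:
                raise ValueError("seizure intervals must not overlap")
        self.seizure_intervals = tuple(ivals)

    @property
    def labels(self) -> tuple[str, ...]:
        if self.n_electrodes == len(DEFAULT_LABELS):
            return DEFAULT_LABELS
        return tuple(f"P{i + 1}" for i in range(self.n_electrodes - 1)) + ("Cz",)

    @property
    def central_label(self) -> str:
        return self.labels[-1]


def _colored_noise(rng: np.random.Generator, n: int, exponent: float, fs: float) -> np.ndarray:
    """Zero-mean noise with one-sided spectral density proportional to 1/f**exponent.

    Synthesized by spectral shaping of white Gaussian noise: the rFFT of a
    white draw is multiplied by f**(-exponent/2) (DC forced to zero) and
    transformed back.  Output has unit RMS.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * shape, n=n)
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / rms if rms > 0 else shaped


def _ictal_waveform(
    rng: np.random.Generator,
    t: np.ndarray,
    band: tuple[float, float],
    amplitude: float,
) -> np.ndarray:
    """Amplitude-modulated sinusoid with a linear frequency chirp inside ``band``.

    The instantaneous frequency sweeps from the high to the low band edge over
    the seizure (ictal discharges typically slow down as the seizure evolves),
    and a slow (0.3 Hz) modulation waxes and wanes the envelope.  A ramp-up
    over the first second avoids an implausible step onset.
    """
    f_hi, f_lo = band[1], band[0]
    dur = t[-1] - t[0] if len(t) > 1 else 1.0
    rel = (t - t[0]) / max(dur, 1e-9)
    inst_freq = f_hi + (f_lo - f_hi) * rel
    phase = 2.0 * np.pi * np.cumsum(inst_freq) * (t[1] - t[0] if len(t) > 1 else 0.0)
    phase += rng.uniform(0.0, 2.0 * np.pi)
    envelope = 0.75 + 0.25 * np.sin(2.0 * np.pi * 0.3 * (t - t[0]) + rng.uniform(0, 2 * np.pi))
    ramp = np.clip((t - t[0]) / 1.0, 0.0, 1.0)
    return amplitude * envelope * ramp * np.sin(phase)


def generate_recording(
    config: SyntheticConfig,
) -> tuple[EegRecording, list[SeizureAnnotation]]:
    """Generate an annotated synthetic EEG recording.

    Returns the recording (all samples valid) and one annotation per
    configured seizure interval.  Identical config (including seed) yields
    bitwise-identical output.
    """
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    n_el = config.n_electrodes
    seeds = np.random.SeedSequence(config.rng_seed).spawn(3)
    rng_bg = np.random.default_rng(seeds[_STREAM_BACKGROUND])
    rng_ict = np.random.default_rng(seeds[_STREAM_ICTAL])

    samples = np.empty((n, n_el))
    for e in range(n_el):
        samples[:, e] = config.background_rms * _colored_noise(
            rng_bg, n, config.background_exponent, fs
        )

    # Ictal gain: full on peripherals, reduced on the central electrode so the
    # peripheral-minus-central re-referencing retains the discharge.
    gains = np.full(n_el, 1.0)
    gains[-1] = config.central_ictal_weight

    annotations: list[SeizureAnnotation] = []
    t = np.arange(n) / fs
    for onset, offset in config.seizure_intervals:
        i0, i1 = int(round(onset * fs)), int(round(offset * fs))
        wave = _ictal_waveform(rng_ict, t[i0:i1], config.ictal_band, config.ictal_amplitude)
        samples[i0:i1, :] += wave[:, None] * gains[None, :]
        annotations.append(SeizureAnnotation(onset=onset, offset=offset))

    rec = EegRecording(
        samples=samples,
        sampling_rate=fs,
        labels=config.labels,
        central_label=config.central_label,
        valid_mask=np.ones(n, dtype=bool),
    )
    if config.artifact_rate > 0:
        rec = inject_artifacts(
            rec,
            rate_per_hour=config.artifact_rate,
            amplitude=config.artifact_amplitude,
            rng_seed=seeds[_STREAM_ARTIFACT],
        )
    return rec, annotations


def inject_artifacts(
    recording: EegRecording,
    rate_per_hour: float,
    amplitude: float,
    rng_seed,
) -> EegRecording:
    """Add short high-amplitude transients at Poisson-distributed times.

    Each artifact is a half-sine pulse of ~60 ms peaking at ``amplitude`` uV on
    a randomly chosen electrode.  The injected event times are recorded in
    ``recording.meta['artifact_times']`` for test assertions; the input
    recording is not modified.
    """
    if amplitude <= 0:
        raise ValueError("artifact amplitude must be positive")
    out = recording.copy()
    if rate_per_hour <= 0:
        out.meta["artifact_times"] = []
        return out

    rng = np.random.default_rng(rng_seed)
    fs = recording.sampling_rate
    hours = recording.duration / 3600.0
    n_events = rng.poisson(rate_per_hour * hours)
    width = max(3, int(round(0.06 * fs)))  # < 0.1 s
    pulse = np.sin(np.pi * np.arange(width) / (width - 1))
    times: list[float] = []
    for _ in range(n_events):
        start = rng.integers(0, max(1, recording.n_samples - width))
        electrode = rng.integers(0, recording.n_electrodes)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        out.samples[start : start + width, electrode] += sign * amplitude * pulse
        times.append(start / fs)
    out.meta["artifact_times"] = sorted(times)
    return out
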