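"""The 16-feature bank computed per channel on 1 s non-overlapping windows.

Time domain (8): mean, maximum, mean absolute deviation, variance, skewness,
kurtosis, line length, amplitude entropy.  All moment features use the
population 1/N_w convention; skewness and kurtosis normalize by the population
standard deviation.  Amplitude entropy is the Shannon entropy (bits) of a
16-bin histogram of the window's samples over [min, max].

Frequency domain (8): spectral entropy, mean / maximum / variance of the
power spectrum, theta (4-8 Hz), beta (13-30 Hz) and gamma (30-45 Hz) band
power, and the epileptogenicity index (beta + gamma) / (theta + alpha), with
alpha (8-13 Hz) computed internally.  The power spectrum is the squared
magnitude of the DFT of the Hann-windowed signal, one-sided (no interior-bin
doubling: ratios, entropies and band-power comparisons are unaffected by the
overall scale convention), with 1 Hz bin spacing for a 1 s window at 256 Hz.
Band-power summation limits are the inclusive bin indices f1/df .. f2/df, so
adjacent bands share their boundary bin.

The zero-mean residuals and their squares are computed once per window and
shared across the moment features, mirroring the per-feature operation
accounting in the energy model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal.windows import hann

from .preprocess import ReferencedRecording
from .synthetic import SeizureAnnotation

__all__ = [
    "WindowSpec",
    "FEATURE_NAMES",
    "TIME_FEATURE_NAMES",
    "FREQ_FEATURE_NAMES",
    "BANDS_HZ",
    "time_features",
    "power_spectrum",
    "freq_features",
    "extract_features",
    "feature_names",
    "featurize_recording",
]

logger = logging.getLogger(__name__)

#: Histogram bins used by the amplitude-entropy feature.
ENTROPY_BINS = 16

#: Inclusive band edges in Hz; bin index = frequency / df for a 1 Hz grid.
BANDS_HZ = {
    "theta": (4, 8),
    "alpha": (8, 13),
    "beta": (13, 30),
    "gamma": (30, 45),
}

TIME_FEATURE_NAMES = (
    "mean",
    "maximum",
    "mad",
    "variance",
    "skewness",
    "kurtosis",
    "line_length",
    "entropy",
)

FREQ_FEATURE_NAMES = (
    "spectral_entropy",
    "mean_spectral_power",
    "max_spectral_power",
    "spectral_power_variance",
    "theta_power",
    "beta_power",
    "gamma_power",
    "epileptogenicity_index",
)

#: Fixed per-channel feature ordering of the feature vector.
FEATURE_NAMES = TIME_FEATURE_NAMES + FREQ_FEATURE_NAMES


@dataclass
class WindowSpec:
    """Analysis-window geometry: N_w = F_s * T_w samples per window."""

    sampling_rate: float = 256.0  # F_s, Hz
    window_s: float = 1.0  # T_w, s

    @property
    def n_samples(self) -> int:
        n = self.sampling_rate * self.window_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("window length must be an integer number of samples")
        return int(round(n))

    @property
    def n_bins(self) -> int:
        """One-sided spectrum length L = N_w/2 + 1."""
        return self.n_samples // 2 + 1

    @property
    def df(self) -> float:
        """Frequency resolution 1/T_w, Hz."""
        return 1.0 / self.window_s


def time_features(x: np.ndarray, n_bins: int = ENTROPY_BINS) -> dict[str, float]:
    """Eight time-domain features of one window of one channel.

    Intermediates (mean, centered samples, their squares, population std) are
    computed once and shared.  A constant window has zero variance; skewness
    and kurtosis are then returned as 0 rather than NaN.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("window must be a 1-D array with at least 2 samples")
    n = x.size
    mean = x.sum() / n
    centered = x - mean
    squared = centered * centered
    variance = squared.sum() / n
    s = np.sqrt(variance)

    if s > 0:
        skewness = float((squared * centered).sum() / (n * s**3))
        kurtosis = float((squared * squared).sum() / (n * s**4))
    else:
        skewness = 0.0
        kurtosis = 0.0

    return {
        "mean": float(mean),
        "maximum": float(x.max()),
        "mad": float(np.abs(centered).sum() / n),
        "variance": float(variance),
        "skewness": skewness,
        "kurtosis": kurtosis,
        "line_length": float(np.abs(np.diff(x)).sum()),
        "entropy": _amplitude_entropy(x, n_bins),
    }


def _amplitude_entropy(x: np.ndarray, n_bins: int) -> float:
    """Shannon entropy (bits) of the sample-amplitude histogram over [min, max]."""
    lo, hi = x.min(), x.max()
    if hi <= lo:
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


def power_spectrum(x: np.ndarray) -> np.ndarray:
    """One-sided power spectrum |DFT(hann * x)|^2, length N_w//2 + 1."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("window must be 1-D")
    w = hann(x.size, sym=False)
    spec = np.fft.rfft(w * x)
    return (spec.real**2 + spec.imag**2).astype(np.float64)


def band_power(p: np.ndarray, band: tuple[float, float], df: float = 1.0) -> float:
    """Sum of spectrum bins from f1/df to f2/df inclusive."""
    lo = int(round(band[0] / df))
    hi = int(round(band[1] / df))
    return float(p[lo : hi + 1].sum())


def freq_features(p: np.ndarray, df: float = 1.0) -> dict[str, float]:
    """Eight frequency-domain features from a one-sided power spectrum.

    An all-zero spectrum (possible only on degenerate input) yields zero
    spectral entropy and zero epileptogenicity index.
    """
    p = np.asarray(p, dtype=np.float64)
    total = p.sum()
    n = p.size

    if total > 0:
        q = p / total
        nz = q[q > 0]
        spectral_entropy = float(-(nz * np.log2(nz)).sum())
    else:
        spectral_entropy = 0.0

    mean_p = total / n
    theta = band_power(p, BANDS_HZ["theta"], df)
    alpha = band_power(p, BANDS_HZ["alpha"], df)
    beta = band_power(p, BANDS_HZ["beta"], df)
    gamma = band_power(p, BANDS_HZ["gamma"], df)
    denom = theta + alpha
    if denom > 0:
        epi = (beta + gamma) / denom
    else:
        if beta + gamma > 0:
            logger.warning("epileptogenicity index denominator is zero; returning 0")
        epi = 0.0

    return {
        "spectral_entropy": spectral_entropy,
        "mean_spectral_power": float(mean_p),
        "max_spectral_power": float(p.max()),
        "spectral_power_variance": float(((p - mean_p) ** 2).sum() / n),
        "theta_power": theta,
        "beta_power": beta,
        "gamma_power": gamma,
        "epileptogenicity_index": float(epi),
    }


def extract_features(window: np.ndarray) -> np.ndarray:
    """16 features per channel, concatenated in channel order.

    ``window`` is (N_w, C); the result has length 16 * C with the per-channel
    blocks ordered as :data:`FEATURE_NAMES`.
    """
    window = np.asarray(window, dtype=np.float64)
    if window.ndim == 1:
        window = window[:, None]
    blocks = []
    for c in range(window.shape[1]):
        x = window[:, c]
        feats = time_features(x)
        feats.update(freq_features(power_spectrum(x)))
        blocks.append([feats[name] for name in FEATURE_NAMES])
    return np.asarray(blocks, dtype=np.float64).ravel()


def feature_names(channel_labels: tuple[str, ...] | int) -> list[str]:
    """Column names ``<channel>_<feature>`` matching :func:`extract_features`."""
    if isinstance(channel_labels, int):
        channel_labels = tuple(f"ch{i}" for i in range(channel_labels))
    return [f"{ch}_{name}" for ch in channel_labels for name in FEATURE_NAMES]


def window_starts(n_samples: int, spec: WindowSpec) -> np.ndarray:
    """Start sample of every complete non-overlapping window."""
    n_w = spec.n_samples
    return np.arange(0, n_samples - n_w + 1, n_w)


def featurize_recording(
    recording: ReferencedRecording,
    annotations: list[SeizureAnnotation] | None = None,
    spec: WindowSpec | None = None,
) -> pd.DataFrame:
    """Feature matrix over all fully valid non-overlapping 1 s windows.

    One row per window with columns ``window_start_s``, ``label`` (1 iff the
    window start lies inside an annotated seizure) and the 16 * C features.
    Windows overlapping invalid samples are skipped and logged.
    """
    spec = spec or WindowSpec(sampling_rate=recording.sampling_rate)
    annotations = annotations or []
    n_w = spec.n_samples
    rows, starts_s, labels = [], [], []
    n_skipped = 0
    for start in window_starts(recording.n_samples, spec):
        if not recording.valid_mask[start : start + n_w].all():
            n_skipped += 1
            continue
        t0 = start / recording.sampling_rate
        rows.append(extract_features(recording.samples[start : start + n_w]))
        starts_s.append(t0)
        labels.append(int(any(a.onset <= t0 < a.offset for a in annotations)))
    if n_skipped:
        logger.info("skipped %d windows overlapping invalid samples", n_skipped)
    cols = feature_names(tuple(recording.channel_labels))
    df = pd.DataFrame(rows if rows else np.empty((0, len(cols))), columns=cols)
    df.insert(0, "window_start_s", np.asarray(starts_s, dtype=float))
    df.insert(1, "label", np.asarray(labels, dtype=int))
    return df
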