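"""File formats: EDF signals, CSV annotations/masks/features/probabilities.

EDF writing is implemented here directly (a compact 16-bit encoder for the
standard European Data Format header + data-record layout) and is round-trip
validated against MNE's independent EDF reader in the test suite.  Reading
goes through MNE.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ReferencedRecording
from .synthetic import EegRecording, SeizureAnnotation

__all__ = [
    "write_edf",
    "read_edf",
    "write_annotations_csv",
    "read_annotations_csv",
    "write_valid_mask_csv",
    "read_valid_mask_csv",
    "write_probabilities_csv",
    "read_probabilities_csv",
    "write_json",
]


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(path, recording: EegRecording | ReferencedRecording) -> Path:
    """Write a recording as 16-bit EDF (physical dimension uV, 1 s records).

    The sampling rate must be an integer and the recording is truncated to a
    whole number of 1 s data records.
    """
    path = Path(path)
    fs = recording.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    labels = list(getattr(recording, "labels", None) or recording.channel_labels)
    data = recording.samples  # (n, C) uV
    n_records = data.shape[0] // fs
    if n_records < 1:
        raise ValueError("recording shorter than one 1 s data record")
    data = data[: n_records * fs]
    n_sig = data.shape[1]

    phys_max = float(np.max(np.abs(data))) if data.size else 1.0
    phys_max = max(phys_max, 1.0) * 1.01  # avoid zero range / clipping
    phys_min = -phys_max
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((data - phys_min) * scale + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    start = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),  # patient id (anonymous)
        _pad("Startdate 01-JAN-2000 X X X", 80),
        _pad(start.strftime("%d.%m.%y"), 8),
        _pad(start.strftime("%H.%M.%S"), 8),
        _pad(str(256 + 256 * n_sig), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),  # record duration, s
        _pad(str(n_sig), 4),
    ])
    fields = [
        ("%s", 16, labels),
        ("", 80, [""] * n_sig),  # transducer
        ("uV", 8, ["uV"] * n_sig),
        ("%.8s", 8, [f"{phys_min:.6g}"[:8]] * n_sig),
        ("%.8s", 8, [f"{phys_max:.6g}"[:8]] * n_sig),
        ("", 8, [str(dig_min)] * n_sig),
        ("", 8, [str(dig_max)] * n_sig),
        ("", 80, [""] * n_sig),  # prefiltering
        ("", 8, [str(fs)] * n_sig),
        ("", 32, [""] * n_sig),
    ]
    sig_header = b"".join(
        b"".join(_pad(str(v), width) for v in values) for _, width, values in fields
    )
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_records):
            block = digital[r * fs : (r + 1) * fs]  # (fs, C)
            fh.write(block.T.tobytes())  # signal-major within the record
    return path


def read_edf(path, central_label: str | None = None) -> EegRecording:
    """Read an EDF file into an :class:`EegRecording` (uV) via MNE."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    samples = raw.get_data().T * 1e6  # V -> uV
    labels = tuple(raw.ch_names)
    central = central_label or labels[-1]
    return EegRecording(
        samples=samples,
        sampling_rate=float(raw.info["sfreq"]),
        labels=labels,
        central_label=central,
        valid_mask=np.ones(samples.shape[0], dtype=bool),
    )


def write_annotations_csv(path, annotations: list[SeizureAnnotation]) -> Path:
    path = Path(path)
    pd.DataFrame(
        [{"onset_s": a.onset, "offset_s": a.offset} for a in annotations],
        columns=["onset_s", "offset_s"],
    ).to_csv(path, index=False)
    return path


def read_annotations_csv(path) -> list[SeizureAnnotation]:
    df = pd.read_csv(path)
    if df.empty:
        return []
    return [
        SeizureAnnotation(onset=float(r.onset_s), offset=float(r.offset_s))
        for r in df.itertuples()
    ]


def write_valid_mask_csv(path, valid_mask: np.ndarray, sampling_rate: float,
                         reason: str = "invalid") -> Path:
    """Serialize invalid intervals as (start_s, end_s, reason) rows."""
    path = Path(path)
    mask = np.asarray(valid_mask, dtype=bool)
    edges = np.flatnonzero(np.diff(np.concatenate([[True], mask, [True]])))
    rows = [
        {"start_s": a / sampling_rate, "end_s": b / sampling_rate, "reason": reason}
        for a, b in zip(edges[::2], edges[1::2])
    ]
    pd.DataFrame(rows, columns=["start_s", "end_s", "reason"]).to_csv(path, index=False)
    return path


def read_valid_mask_csv(path, n_samples: int, sampling_rate: float) -> np.ndarray:
    df = pd.read_csv(path)
    mask = np.ones(n_samples, dtype=bool)
    for r in df.itertuples():
        a = int(round(r.start_s * sampling_rate))
        b = int(round(r.end_s * sampling_rate))
        mask[a:b] = False
    return mask


def write_probabilities_csv(path, times: np.ndarray, probs: np.ndarray) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": times, "probability": probs}).to_csv(path, index=False)
    return path


def read_probabilities_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["time_s"].to_numpy(), df["probability"].to_numpy()


def write_json(path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=default))
    return path
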