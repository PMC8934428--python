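"""Seizure-detection evaluation protocol.

Window level (1 s, threshold-free): AUC-ROC and AUC-PR, plus "early seizure"
variants in which only windows within the first 10 s after onset count as
detectable ictal activity (later in-seizure windows are excluded from the
early metric).

Event level (threshold-dependent): sensitivity (a seizure counts as detected
if at least one detection falls inside its ictal phase), false detections per
hour with 5 s deduplication (after a counted false detection, further false
detections within the following 5 s are suppressed, greedily from the
earliest), and mean detection delay from onset to the first in-seizure
detection.  Thresholds are chosen by maximizing the window-level F1 score.

Cross-validation is leave-one-seizure-out: with one record per seizure, each
fold trains on all remaining records (the RNN additionally reserves one
training record for validation-loss early stopping) and tests on the held-out
record; metrics are averaged over folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .synthetic import SeizureAnnotation

__all__ = [
    "DetectionEvent",
    "EvalReport",
    "window_labels",
    "auc",
    "threshold_detections",
    "event_metrics",
    "f1_optimal_threshold",
    "leave_one_seizure_out",
    "EARLY_WINDOW_S",
    "DEDUP_WINDOW_S",
]

#: Only detections within this many seconds of onset count as "early".
EARLY_WINDOW_S = 10.0
#: False detections within this window after a counted one are suppressed.
DEDUP_WINDOW_S = 5.0


@dataclass
class DetectionEvent:
    time: float  # s, window start
    inside_seizure: bool
    suppressed: bool = False  # deduplicated false detections


@dataclass
class EvalReport:
    """Per-patient aggregate of the evaluation metrics."""

    auc_roc: float
    auc_pr: float
    early_auc_roc: float
    early_auc_pr: float
    sensitivity: float
    fdr_per_hour: float
    mean_delay_s: float
    threshold: float
    per_fold: list[dict] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "auc_roc": self.auc_roc,
            "auc_pr": self.auc_pr,
            "early_auc_roc": self.early_auc_roc,
            "early_auc_pr": self.early_auc_pr,
            "sensitivity": self.sensitivity,
            "fdr_per_hour": self.fdr_per_hour,
            "mean_delay_s": self.mean_delay_s,
            "threshold": self.threshold,
        }


def _in_seizure(t: float, annotations: list[SeizureAnnotation]) -> bool:
    return any(a.onset <= t < a.offset for a in annotations)


def window_labels(
    times: np.ndarray,
    annotations: list[SeizureAnnotation],
    early: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """(labels, keep-mask) for the given window start times.

    Standard labels: 1 iff the window starts inside a seizure.  Early labels:
    1 only within [onset, onset + 10 s); in-seizure windows beyond that are
    masked out of the early metrics (keep=False) rather than counted as
    false.  Early positive windows are a subset of the standard ones.
    """
    times = np.asarray(times, dtype=float)
    labels = np.array([int(_in_seizure(t, annotations)) for t in times])
    keep = np.ones(len(times), dtype=bool)
    if early:
        early_pos = np.array([
            int(any(a.onset <= t < min(a.onset + EARLY_WINDOW_S, a.offset) for a in annotations))
            for t in times
        ])
        keep = ~((labels == 1) & (early_pos == 0))
        labels = early_pos
    return labels, keep


def auc(probs: np.ndarray, labels: np.ndarray, curve: str = "roc") -> float:
    """Threshold-free window-level AUC; NaN marker if only one class present."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        return float("nan")
    if curve == "roc":
        return float(roc_auc_score(labels, probs))
    if curve == "pr":
        return float(average_precision_score(labels, probs))
    raise ValueError(f"unknown curve {curve!r}")


def threshold_detections(
    probs: np.ndarray,
    theta: float,
    annotations: list[SeizureAnnotation],
    times: np.ndarray | None = None,
) -> list[DetectionEvent]:
    """One detection event per second with probability >= theta."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    probs = np.asarray(probs, dtype=float)
    times = np.arange(len(probs), dtype=float) if times is None else np.asarray(times, float)
    return [
        DetectionEvent(time=float(t), inside_seizure=_in_seizure(float(t), annotations))
        for t, p in zip(times, probs)
        if p >= theta
    ]


def _dedup_false_events(events: list[DetectionEvent]) -> int:
    """Count false detections with greedy earliest-first 5 s suppression.

    After a counted false event at t, false events in (t, t + 5 s] are marked
    suppressed.  Flags are written back onto the events.
    """
    counted = 0
    last_counted = -np.inf
    for ev in sorted((e for e in events if not e.inside_seizure), key=lambda e: e.time):
        if ev.time - last_counted <= DEDUP_WINDOW_S and counted > 0:
            ev.suppressed = True
        else:
            ev.suppressed = False
            counted += 1
            last_counted = ev.time
    return counted


def event_metrics(
    events: list[DetectionEvent],
    annotations: list[SeizureAnnotation],
    record_hours: float,
) -> tuple[float, float, float]:
    """(sensitivity, false detections per hour, mean detection delay in s).

    Delay averages over detected seizures only; with no detected seizure it is
    NaN.  Suppressed duplicates never change the FDR.
    """
    if record_hours <= 0:
        raise ValueError("record_hours must be positive")
    n_false = _dedup_false_events(events)
    fdr = n_false / record_hours

    if not annotations:
        return float("nan"), fdr, float("nan")

    delays = []
    detected = 0
    for a in annotations:
        hits = [e.time for e in events if a.onset <= e.time < a.offset]
        if hits:
            detected += 1
            delays.append(min(hits) - a.onset)
    sensitivity = detected / len(annotations)
    mean_delay = float(np.mean(delays)) if delays else float("nan")
    return sensitivity, fdr, mean_delay


def f1_optimal_threshold(probs: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing window-level F1 over the observed probability
    values; ties broken toward the higher threshold."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required to optimize F1")
    best_theta, best_f1 = None, -1.0
    for theta in np.unique(probs):
        pred = probs >= theta
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if f1 >= best_f1:  # >= walks ties toward higher theta (sorted ascending)
            best_f1, best_theta = f1, float(theta)
    return best_theta


def _fold_metrics(times, probs, annotations, duration_s) -> dict:
    labels, _ = window_labels(times, annotations)
    early_labels, early_keep = window_labels(times, annotations, early=True)
    theta = (
        f1_optimal_threshold(probs, labels)
        if len(np.unique(labels)) == 2
        else float("nan")
    )
    if np.isfinite(theta):
        events = threshold_detections(probs, theta, annotations, times)
        sens, fdr, delay = event_metrics(events, annotations, duration_s / 3600.0)
    else:
        sens = fdr = delay = float("nan")
    return {
        "auc_roc": auc(probs, labels, "roc"),
        "auc_pr": auc(probs, labels, "pr"),
        "early_auc_roc": auc(probs[early_keep], early_labels[early_keep], "roc"),
        "early_auc_pr": auc(probs[early_keep], early_labels[early_keep], "pr"),
        "sensitivity": sens,
        "fdr_per_hour": fdr,
        "mean_delay_s": delay,
        "threshold": theta,
    }


def leave_one_seizure_out(
    records,
    detector_factory,
    needs_validation: bool | None = None,
) -> EvalReport:
    """Leave-one-seizure-out cross-validation over single-seizure records.

    ``records`` is a list of (ReferencedRecording, [SeizureAnnotation]), one
    per seizure; ``detector_factory()`` returns a fresh unfitted detector for
    each fold.  Per-fold window times never overlap the fold's training
    records (they are distinct recordings).  Metrics are averaged over folds
    (NaN-aware for degenerate folds).
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("leave-one-seizure-out requires at least 2 seizures")
    per_fold = []
    for i, (test_rec, test_ann) in enumerate(records):
        train = [r for j, r in enumerate(records) if j != i]
        det = detector_factory()
        needs_val = (
            needs_validation if needs_validation is not None else det.name == "rnn"
        )
        if needs_val and len(train) >= 2:
            det.fit(train[:-1], validation_record=train[-1])
        else:
            det.fit(train)
        times, probs = det.predict_series(test_rec)
        fold = _fold_metrics(times, probs, test_ann, test_rec.duration)
        fold["fold"] = i
        per_fold.append(fold)

    def agg(key):
        vals = np.asarray([f[key] for f in per_fold], dtype=float)
        return float(np.nanmean(vals)) if np.isfinite(vals).any() else float("nan")

    return EvalReport(
        auc_roc=agg("auc_roc"),
        auc_pr=agg("auc_pr"),
        early_auc_roc=agg("early_auc_roc"),
        early_auc_pr=agg("early_auc_pr"),
        sensitivity=agg("sensitivity"),
        fdr_per_hour=agg("fdr_per_hour"),
        mean_delay_s=agg("mean_delay_s"),
        threshold=agg("threshold"),
        per_fold=per_fold,
    )
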