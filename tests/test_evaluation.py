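"""Evaluation protocol: AUCs vs exhaustive oracles, dedup, thresholds, LOSO."""

import numpy as np
import pytest

from seizenergy.detectors import TrainConfig, make_detector
from seizenergy.evaluation import (
    DetectionEvent,
    auc,
    event_metrics,
    f1_optimal_threshold,
    leave_one_seizure_out,
    threshold_detections,
    window_labels,
)
from seizenergy.synthetic import SeizureAnnotation


# ---------------------------------------------------------------------------
# Exhaustive oracles (independent of the implementations under test)
# ---------------------------------------------------------------------------

def roc_auc_oracle(probs, labels):
    """Pairwise concordance statistic with 0.5 credit for ties."""
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def pr_auc_oracle(probs, labels):
    """Step integration over all observed thresholds (descending)."""
    n_pos = int(labels.sum())
    thresholds = np.unique(probs)[::-1]
    ap = 0.0
    prev_recall = 0.0
    for theta in thresholds:
        pred = probs >= theta
        tp = int(np.sum(pred & (labels == 1)))
        precision = tp / pred.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def dedup_oracle(times):
    """Greedy earliest-first suppression: a counted event at t suppresses
    (t, t + 5]."""
    counted = []
    for t in sorted(times):
        if not counted or t - counted[-1] > 5.0:
            counted.append(t)
    return len(counted)


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

class TestAuc:
    def test_perfect_separation(self):
        labels = np.array([0, 0, 0, 1, 1])
        probs = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        assert auc(probs, labels, "roc") == 1.0
        assert auc(probs, labels, "pr") == 1.0

    def test_null_case_is_half_on_average(self):
        vals = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            probs = rng.random(60)
            labels = rng.integers(0, 2, 60)
            if len(np.unique(labels)) == 2:
                vals.append(auc(probs, labels, "roc"))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.03)

    def test_single_class_returns_nan_marker(self):
        assert np.isnan(auc(np.array([0.1, 0.9]), np.array([1, 1]), "roc"))

    def test_matches_exhaustive_oracles_on_random_instances(self):
        """500 random instances of <= 20 windows, both curves, exact match."""
        checked = 0
        seed = 0
        while checked < 500:
            rng = np.random.default_rng(seed)
            seed += 1
            n = int(rng.integers(2, 21))
            # coarse grid probabilities force plenty of ties
            probs = rng.integers(0, 6, n) / 5.0
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            checked += 1
            assert auc(probs, labels, "roc") == pytest.approx(
                roc_auc_oracle(probs, labels), abs=1e-12
            )
            assert auc(probs, labels, "pr") == pytest.approx(
                pr_auc_oracle(probs, labels), abs=1e-12
            )


# ---------------------------------------------------------------------------
# Events, dedup, thresholds
# ---------------------------------------------------------------------------

class TestThresholdDetections:
    def test_zero_threshold_fires_every_second(self):
        events = threshold_detections(np.array([0.0, 0.5, 1.0]), 0.0, [])
        assert len(events) == 3

    def test_threshold_above_max_fires_never(self):
        assert threshold_detections(np.array([0.2, 0.3]), 0.9, []) == []

    def test_worked_example(self):
        events = threshold_detections(np.array([0.2, 0.7, 0.4]), 0.5, [])
        assert len(events) == 1 and events[0].time == 1.0

    def test_inside_seizure_flagging(self):
        ann = [SeizureAnnotation(1.0, 3.0)]
        events = threshold_detections(np.array([0.9, 0.9, 0.9, 0.9]), 0.5, ann)
        assert [e.inside_seizure for e in events] == [False, True, True, False]


class TestEventMetrics:
    def test_five_second_dedup_worked_example(self):
        events = [
            DetectionEvent(t, inside_seizure=False) for t in (100.0, 102.0, 104.0, 110.0)
        ]
        _, fdr, _ = event_metrics(events, [], record_hours=1.0)
        assert fdr == 2.0

    def test_dedup_matches_bruteforce_oracle_on_random_event_sets(self):
        for seed in range(200):
            rng = np.random.default_rng(seed)
            times = np.sort(rng.uniform(0, 120, rng.integers(1, 40)))
            events = [DetectionEvent(float(t), inside_seizure=False) for t in times]
            _, fdr, _ = event_metrics(events, [], record_hours=1.0)
            assert fdr == dedup_oracle(times)

    def test_dedup_never_exceeds_raw_count(self):
        rng = np.random.default_rng(1)
        times = rng.uniform(0, 50, 30)
        events = [DetectionEvent(float(t), inside_seizure=False) for t in times]
        _, fdr, _ = event_metrics(events, [], record_hours=1.0)
        assert fdr <= len(times)

    def test_invariant_under_adding_suppressed_duplicates(self):
        base = [DetectionEvent(t, False) for t in (10.0, 30.0)]
        _, fdr_base, _ = event_metrics(list(base), [], 1.0)
        extra = base + [DetectionEvent(12.0, False), DetectionEvent(31.5, False)]
        _, fdr_extra, _ = event_metrics(extra, [], 1.0)
        assert fdr_base == fdr_extra == 2.0

    def test_sensitivity_and_delay(self):
        ann = [SeizureAnnotation(20.0, 40.0)]
        events = [DetectionEvent(23.0, True), DetectionEvent(30.0, True)]
        sens, fdr, delay = event_metrics(events, ann, record_hours=0.5)
        assert sens == 1.0 and delay == 3.0 and fdr == 0.0

    def test_zero_hours_rejected(self):
        with pytest.raises(ValueError):
            event_metrics([], [], record_hours=0.0)


class TestF1Threshold:
    def test_worked_six_window_case(self):
        probs = np.array([0.1, 0.2, 0.6, 0.7, 0.8, 0.9])
        labels = np.array([0, 0, 0, 1, 1, 1])
        theta = f1_optimal_threshold(probs, labels)
        assert theta == 0.7
        pred = probs >= theta
        assert np.array_equal(pred.astype(int), labels)

    def test_separable_case_reaches_f1_one(self):
        probs = np.array([0.05, 0.1, 0.9, 0.95])
        labels = np.array([0, 0, 1, 1])
        theta = f1_optimal_threshold(probs, labels)
        assert np.array_equal((probs >= theta).astype(int), labels)

    def test_identical_probs_pick_the_tie_rule_threshold(self):
        probs = np.full(6, 0.4)
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert f1_optimal_threshold(probs, labels) == 0.4

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            f1_optimal_threshold(np.array([0.1, 0.2]), np.array([0, 0]))


class TestWindowLabels:
    def test_early_positives_are_subset_of_standard(self):
        ann = [SeizureAnnotation(10.0, 40.0), SeizureAnnotation(60.0, 65.0)]
        times = np.arange(80.0)
        std, _ = window_labels(times, ann)
        early, keep = window_labels(times, ann, early=True)
        assert np.all(std[early == 1] == 1)
        # windows deep inside the first seizure are excluded, not negative
        assert not keep[25]
        assert keep[12] and early[12] == 1
        # a seizure shorter than 10 s is early-detectable throughout
        assert early[62] == 1 and keep[62]


# ---------------------------------------------------------------------------
# Leave-one-seizure-out
# ---------------------------------------------------------------------------

class TestLeaveOneSeizureOut:
    def test_one_fold_per_seizure_with_rf(self, tiny_records):
        cfg = TrainConfig(rng_seed=0)
        report = leave_one_seizure_out(
            tiny_records, lambda: make_detector("rf", train_config=cfg)
        )
        assert len(report.per_fold) == len(tiny_records)
        assert 0.0 <= report.auc_roc <= 1.0
        assert report.sensitivity >= 0.0

    def test_fewer_than_two_seizures_rejected(self, tiny_records):
        with pytest.raises(ValueError, match="at least 2"):
            leave_one_seizure_out(tiny_records[:1], lambda: make_detector("rf"))

    def test_folds_never_test_on_training_records(self, tiny_records, monkeypatch):
        """Bookkeeping check: the tested record is excluded from fit()."""
        seen = []

        class SpyDetector:
            name = "spy"

            def fit(self, train_records, validation_record=None):
                seen.append([id(r[0]) for r in train_records])
                return self

            def predict_series(self, recording):
                seen[-1].append(("test", id(recording)))
                n = int(recording.duration)
                rng = np.random.default_rng(0)
                return np.arange(n, dtype=float), rng.random(n)

        leave_one_seizure_out(tiny_records, SpyDetector, needs_validation=False)
        for fold, (rec, _) in zip(seen, tiny_records):
            train_ids = fold[:-1]
            _, test_id = fold[-1]
            assert test_id == id(rec)
            assert test_id not in train_ids
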