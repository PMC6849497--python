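"""Majority-vote fusion of the three classifiers and trial evaluation.

Each classifier reduces to a binary flag (1 = fall): the k-NN and naive
Bayes class predictions via the fall indicator, and the visual
classifier directly. The system decision is the 3-input majority gate —
fall iff at least two flags are 1. The camera only records once a
sensor sample leaves the ADL envelope, so when it was never triggered
(or frames are unavailable) the visual flag is fixed at 0 and a fall
verdict requires both sensor classifiers to agree.

Evaluation pools trial outcomes into TP/TN/FP/FN counts, from which

    sensitivity = 100 * TP / (TP + FN)
    specificity = 100 * TN / (TN + FP)
    accuracy    = 100 * (TN + TP) / (TN + TP + FN + FP)

are reported (positive = fall).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np

from .features import extract_features
from .knn import TrainingSet, knn_classify
from .naive_bayes import ClassStats, nb_classify
from .signals import DataError, MotionClass, SignalWindow
from .visual import (
    DEFAULT_VISUAL_THRESHOLD_PCT,
    FrameSequence,
    TriggerThresholds,
    camera_trigger,
    visual_classify,
)

__all__ = [
    "DetectionResult",
    "ConfusionCounts",
    "UndefinedMetricError",
    "to_fall_flag",
    "fuse",
    "detect",
    "evaluate",
    "sensitivity",
    "specificity",
    "accuracy",
    "metrics_report",
]

logger = logging.getLogger("fallfusion")


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero for these counts."""


def to_fall_flag(c: MotionClass) -> int:
    """Binary fall indicator of a class prediction: 1 iff the class is fall."""
    return c.fall_flag


def fuse(knn_flag: int, nb_flag: int, visual_flag: int) -> int:
    """3-input majority gate: 1 iff at least two of the three flags are 1."""
    for f in (knn_flag, nb_flag, visual_flag):
        if f not in (0, 1):
            raise DataError(f"flags must be binary, got {f!r}")
    return int(knn_flag + nb_flag + visual_flag >= 2)


@dataclass(frozen=True)
class DetectionResult:
    """Per-recording system decision and its constituent votes."""

    knn_flag: int
    nb_flag: int
    visual_flag: int
    camera_was_triggered: bool
    fused: int
    knn_class: MotionClass
    nb_class: MotionClass

    def __post_init__(self) -> None:
        if self.fused != fuse(self.knn_flag, self.nb_flag, self.visual_flag):
            raise DataError("fused verdict must equal the majority of the flags")
        if not self.camera_was_triggered and self.visual_flag != 0:
            raise DataError("visual_flag must be 0 when the camera was not triggered")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["knn_class"] = self.knn_class.value
        d["nb_class"] = self.nb_class.value
        return d


def detect(
    w: SignalWindow,
    frames: Optional[FrameSequence],
    train: TrainingSet,
    k: int,
    stats: ClassStats,
    thresholds: TriggerThresholds = TriggerThresholds(),
    visual_threshold_pct: float = DEFAULT_VISUAL_THRESHOLD_PCT,
) -> DetectionResult:
    """Run the full decision flow on one recording.

    Extracts the power features, queries the k-NN and naive Bayes
    classifiers, checks the camera trigger, applies the visual
    classifier to ``frames`` only when the camera was triggered and
    frames exist (otherwise the visual flag is 0 — if the camera
    triggered but frames are missing the system degrades to
    two-classifier mode with a warning), and fuses the three flags by
    majority. A fall verdict is logged as a structured event.
    """
    f = extract_features(w)
    knn_class = knn_classify(train, f, k)
    nb_class = nb_classify(f, stats)
    knn_flag = to_fall_flag(knn_class)
    nb_flag = to_fall_flag(nb_class)

    triggered = camera_trigger(w, thresholds)
    if triggered and frames is not None:
        visual_flag = visual_classify(frames, visual_threshold_pct)
    else:
        if triggered:
            logger.warning(
                "camera triggered but no frames available; "
                "degrading to two-classifier mode (visual flag = 0)"
            )
        visual_flag = 0

    fused = fuse(knn_flag, nb_flag, visual_flag)
    if fused == 1:
        logger.info(
            "FALL EVENT detected: knn=%s nb=%s visual=%d trigger=%s",
            knn_class.value, nb_class.value, visual_flag, triggered,
        )
    return DetectionResult(
        knn_flag=knn_flag,
        nb_flag=nb_flag,
        visual_flag=visual_flag,
        camera_was_triggered=triggered,
        fused=fused,
        knn_class=knn_class,
        nb_class=nb_class,
    )


@dataclass(frozen=True)
class ConfusionCounts:
    """Pooled binary trial outcomes (positive = fall)."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise DataError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


def evaluate(
    results: Sequence[DetectionResult | int],
    truth: Sequence[int],
) -> ConfusionCounts:
    """Pool fused verdicts against ground truth into confusion counts.

    ``results`` may hold :class:`DetectionResult` objects or bare binary
    predictions; ``truth`` is the matching binary ground truth (1 = fall).
    """
    if len(results) != len(truth):
        raise DataError(
            f"got {len(results)} predictions but {len(truth)} truth labels"
        )
    tp = tn = fp = fn = 0
    for r, y in zip(results, truth):
        pred = r.fused if isinstance(r, DetectionResult) else int(r)
        if pred not in (0, 1) or int(y) not in (0, 1):
            raise DataError("predictions and truth must be binary")
        if int(y) == 1:
            tp, fn = (tp + 1, fn) if pred == 1 else (tp, fn + 1)
        else:
            tn, fp = (tn + 1, fp) if pred == 0 else (tn, fp + 1)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def sensitivity(c: ConfusionCounts) -> float:
    """Percent of actual falls detected: 100 * TP / (TP + FN)."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive trials")
    return 100.0 * c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """Percent of non-falls correctly rejected: 100 * TN / (TN + FP)."""
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative trials")
    return 100.0 * c.tn / (c.tn + c.fp)


def accuracy(c: ConfusionCounts) -> float:
    """Percent of all trials decided correctly: 100 * (TN + TP) / total."""
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined: no trials")
    return 100.0 * (c.tn + c.tp) / c.total


def metrics_report(c: ConfusionCounts) -> dict:
    """Machine-readable report: raw counts, exact fractions, rounded percents.

    Rounded values use one decimal place (the reporting convention);
    the exact fractions are preserved alongside. Metrics whose
    denominator is zero are reported as None.
    """
    def safe(fn):
        try:
            return fn(c)
        except UndefinedMetricError:
            return None

    sens, spec, acc = safe(sensitivity), safe(specificity), safe(accuracy)
    return {
        "counts": {"tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn, "total": c.total},
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "sensitivity_rounded": None if sens is None else round(sens, 1),
        "specificity_rounded": None if spec is None else round(spec, 1),
        "accuracy_rounded": None if acc is None else round(acc, 1),
    }
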