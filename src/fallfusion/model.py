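"""Model/Results interface over the fall-detection pipeline.

:class:`FallDetectionModel` holds the labelled training features and the
configuration (k or its candidate list, fold count, trigger thresholds,
visual threshold); ``fit()`` selects k by cross-validation where needed,
fits the naive Bayes class statistics, and returns a
:class:`FallDetectionResults` that carries the fitted state and exposes
``detect`` / ``detect_many`` / ``evaluate`` / ``summary`` and JSON
persistence.

Typical use::

    corpus = generate_corpus(trials_per_class=40, params=MotionModelParams(seed=0))
    res = FallDetectionModel.from_corpus(corpus).fit()
    print(res.summary())
    outcome = res.detect(window, frames)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, extract_features
from .fusion import (
    ConfusionCounts,
    DetectionResult,
    detect,
    evaluate,
    metrics_report,
)
from .knn import DEFAULT_K_CANDIDATES, TrainingSet, select_k
from .naive_bayes import ClassStats, fit_gaussian_nb
from .signals import FormatError, MotionClass, ParameterError, SignalWindow
from .visual import DEFAULT_VISUAL_THRESHOLD_PCT, FrameSequence, TriggerThresholds

__all__ = ["FallDetectionModel", "FallDetectionResults"]


class FallDetectionModel:
    """The three-classifier fall-detection system, before fitting.

    Parameters
    ----------
    train : TrainingSet
        Labelled 6-D power features; every class needs >= 2 points for
        the naive Bayes fit.
    k : int, optional
        Fixed neighbour count for k-NN. When omitted, ``fit`` selects k
        by stratified cross-validation over ``k_candidates``.
    k_candidates : sequence of int
        Candidate k values (default odd 1..15).
    n_folds : int
        Folds for k selection (default 5).
    thresholds : TriggerThresholds
        Camera-trigger envelopes (default ±120 rad/s, ±1.5 m/s²).
    visual_threshold_pct : float
        Frame-difference fall threshold, percent (default 7).
    cv_seed : int
        Seed for the stratified fold split.
    """

    def __init__(
        self,
        train: TrainingSet,
        k: Optional[int] = None,
        k_candidates: Sequence[int] = DEFAULT_K_CANDIDATES,
        n_folds: int = 5,
        thresholds: TriggerThresholds = TriggerThresholds(),
        visual_threshold_pct: float = DEFAULT_VISUAL_THRESHOLD_PCT,
        cv_seed: int = 0,
    ) -> None:
        self.train = train
        self.k = None if k is None else int(k)
        self.k_candidates = tuple(int(c) for c in k_candidates)
        self.n_folds = int(n_folds)
        self.thresholds = thresholds
        self.visual_threshold_pct = float(visual_threshold_pct)
        self.cv_seed = int(cv_seed)

    @classmethod
    def from_corpus(
        cls,
        corpus: Sequence[tuple[SignalWindow, Optional[MotionClass]]],
        **kwargs,
    ) -> "FallDetectionModel":
        """Build from labelled recordings (features are extracted here)."""
        return cls(TrainingSet.from_corpus(corpus), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "FallDetectionModel":
        """Build from a feature table with the six power columns and ``label``."""
        missing = [c for c in (*FEATURE_NAMES, "label") if c not in df.columns]
        if missing:
            raise FormatError(f"feature table is missing columns {missing}")
        labels = df["label"].astype(str).str.strip()
        if (labels == "").any():
            raise ParameterError("feature table contains unlabelled rows")
        y = tuple(MotionClass.from_label(v) for v in labels)
        X = df.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=float)
        return cls(TrainingSet(X, y), **kwargs)

    def fit(self) -> "FallDetectionResults":
        """Fit both sensor classifiers and return the results object."""
        if self.k is not None:
            if not 1 <= self.k <= len(self.train):
                raise ParameterError(
                    f"k must be in [1, {len(self.train)}], got {self.k}"
                )
            k, cv_errors = self.k, None
        else:
            k, cv_errors = select_k(
                self.train, n_folds=self.n_folds,
                candidates=self.k_candidates, seed=self.cv_seed,
            )
        stats = fit_gaussian_nb(self.train)
        return FallDetectionResults(self, k=k, cv_errors=cv_errors, class_stats=stats)


@dataclass
class FallDetectionResults:
    """Fitted fall-detection system.

    Carries the chosen k (and per-candidate cross-validation errors when
    k was selected), the naive Bayes class statistics, and the parent
    model (training features and thresholds).
    """

    model: FallDetectionModel
    k: int
    cv_errors: Optional[dict[int, float]]
    class_stats: ClassStats

    def detect(
        self,
        w: SignalWindow,
        frames: Optional[FrameSequence] = None,
    ) -> DetectionResult:
        """System decision for one recording (see :func:`fallfusion.fusion.detect`)."""
        return detect(
            w, frames,
            train=self.model.train,
            k=self.k,
            stats=self.class_stats,
            thresholds=self.model.thresholds,
            visual_threshold_pct=self.model.visual_threshold_pct,
        )

    def detect_many(
        self,
        windows: Sequence[SignalWindow],
        frames: Optional[Sequence[Optional[FrameSequence]]] = None,
    ) -> list[DetectionResult]:
        if frames is None:
            frames = [None] * len(windows)
        if len(frames) != len(windows):
            raise ParameterError("windows and frames lengths differ")
        return [self.detect(w, f) for w, f in zip(windows, frames)]

    def evaluate(
        self,
        results: Sequence[DetectionResult | int],
        truth: Sequence[int],
    ) -> dict:
        """Confusion counts plus sensitivity/specificity/accuracy report."""
        return metrics_report(evaluate(results, truth))

    def summary(self) -> str:
        """Human-readable fit summary: k selection and per-class Gaussians."""
        lines = ["Fall detection system — fitted summary",
                 "=" * 46,
                 f"training recordings : {len(self.model.train)}",
                 f"classes             : "
                 f"{', '.join(c.value for c in self.class_stats.classes)}",
                 f"chosen k            : {self.k}"
                 + ("" if self.cv_errors is None else " (cross-validated)")]
        if self.cv_errors is not None:
            lines.append(f"CV folds            : {self.model.n_folds}")
            lines.append("CV error by k       : "
                         + ", ".join(f"k={k}: {e:.3f}"
                                     for k, e in sorted(self.cv_errors.items())))
        lines.append(f"camera trigger      : |gyro| > "
                     f"{self.model.thresholds.gyro_limit:g} rad/s or |accel| > "
                     f"{self.model.thresholds.accel_limit:g} m/s²")
        lines.append(f"visual threshold    : {self.model.visual_threshold_pct:g}%")
        lines.append("")
        lines.append("Naive Bayes class statistics (prior; per-feature mean):")
        for i, c in enumerate(self.class_stats.classes):
            mus = ", ".join(f"{m:.3g}" for m in self.class_stats.means[i])
            lines.append(f"  {c.value:<12s} prior={self.class_stats.priors[i]:.3f}  "
                         f"mean=[{mus}]")
        return "\n".join(lines)

    # --- persistence -------------------------------------------------

    def save(self, path: Union[str, Path]) -> Path:
        """Write the fitted system (training table, k, NB stats) as JSON."""
        path = Path(path)
        payload = {
            "format": "fallfusion-model",
            "version": 1,
            "k": self.k,
            "cv_errors": (None if self.cv_errors is None
                          else {str(k): v for k, v in self.cv_errors.items()}),
            "knn": {
                "features": self.model.train.X.tolist(),
                "labels": [c.value for c in self.model.train.y],
            },
            "naive_bayes": {
                "classes": [c.value for c in self.class_stats.classes],
                "priors": self.class_stats.priors.tolist(),
                "means": self.class_stats.means.tolist(),
                "sds": self.class_stats.sds.tolist(),
                "sigma_floor": self.class_stats.sigma_floor.tolist(),
            },
            "config": {
                "gyro_limit": self.model.thresholds.gyro_limit,
                "accel_limit": self.model.thresholds.accel_limit,
                "visual_threshold_pct": self.model.visual_threshold_pct,
                "n_folds": self.model.n_folds,
                "k_candidates": list(self.model.k_candidates),
                "cv_seed": self.model.cv_seed,
            },
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def load(cls, path: Union[str, Path]) -> "FallDetectionResults":
        """Reconstruct a fitted system from :meth:`save` output."""
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "fallfusion-model":
            raise FormatError(f"{path}: not a fallfusion model artefact")
        cfg = payload["config"]
        train = TrainingSet(
            np.asarray(payload["knn"]["features"], dtype=float),
            tuple(MotionClass(v) for v in payload["knn"]["labels"]),
        )
        model = FallDetectionModel(
            train,
            k=payload["k"],
            k_candidates=cfg["k_candidates"],
            n_folds=cfg["n_folds"],
            thresholds=TriggerThresholds(cfg["gyro_limit"], cfg["accel_limit"]),
            visual_threshold_pct=cfg["visual_threshold_pct"],
            cv_seed=cfg["cv_seed"],
        )
        nb = payload["naive_bayes"]
        stats = ClassStats(
            classes=tuple(MotionClass(v) for v in nb["classes"]),
            priors=np.asarray(nb["priors"]),
            means=np.asarray(nb["means"]),
            sds=np.asarray(nb["sds"]),
            sigma_floor=np.asarray(nb["sigma_floor"]),
        )
        cv = payload.get("cv_errors")
        return cls(
            model=model,
            k=int(payload["k"]),
            cv_errors=None if cv is None else {int(k): v for k, v in cv.items()},
            class_stats=stats,
        )
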