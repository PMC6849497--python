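"""Frame-difference visual classifier and the camera-trigger gate.

The wearable camera records only after a sensor sample exceeds the
trigger envelope (any gyro axis beyond ±120 rad/s or any accel axis
beyond ±1.5 m/s², the envelopes that bound all activities of daily
living). The recorded video, split into grayscale frames, is classified
by the percentage difference between consecutive frames: a gradual
change of surroundings (ADL) stays small, an abrupt change (fall)
exceeds a 7% threshold.

"Percentage difference" is the mean absolute pixel difference
normalised by the full intensity range, times 100 — bounded in
[0, 100] and independent of frame size, so one threshold serves any
resolution. An alternative metric (fraction of pixels changing by more
than a per-pixel delta) is pluggable via ``metric=``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence, Union

import numpy as np

from .signals import DataError, ParameterError, SignalWindow

__all__ = [
    "I_MAX",
    "FrameSequence",
    "TriggerThresholds",
    "frame_difference",
    "changed_pixel_fraction",
    "visual_classify",
    "camera_trigger",
    "to_grayscale",
    "load_frames",
    "save_frames",
]

#: Full-scale intensity of 8-bit grayscale frames.
I_MAX = 255.0

#: Visual fall threshold, percent: consecutive-frame differences above
#: this indicate an abrupt scene change.
DEFAULT_VISUAL_THRESHOLD_PCT = 7.0


@dataclass(frozen=True)
class FrameSequence:
    """An ordered stack of same-shape grayscale frames, intensities in [0, 255]."""

    frames: np.ndarray  # (n_frames, h, w) float

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames, dtype=float)
        if arr.ndim != 3:
            raise DataError(f"frames must stack to (n, h, w); got shape {arr.shape}")
        if arr.shape[0] < 2:
            raise DataError("a frame sequence needs at least 2 frames")
        object.__setattr__(self, "frames", arr)

    def __len__(self) -> int:
        return self.frames.shape[0]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class TriggerThresholds:
    """Sensor envelopes beyond which the camera starts recording."""

    gyro_limit: float = 120.0  # rad/s
    accel_limit: float = 1.5  # m/s²

    def __post_init__(self) -> None:
        if not (self.gyro_limit > 0 and self.accel_limit > 0):
            raise ParameterError("trigger thresholds must be strictly positive")


def frame_difference(a: np.ndarray, b: np.ndarray) -> float:
    """Percentage difference between two frames, in [0, 100].

    100 x mean over pixels of |a - b| / 255. Symmetric; 0 for identical
    frames, 100 between an all-black and an all-white frame.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DataError(f"frame shapes differ: {a.shape} vs {b.shape}")
    return float(100.0 * np.mean(np.abs(a - b)) / I_MAX)


def changed_pixel_fraction(a: np.ndarray, b: np.ndarray, delta: float = 10.0) -> float:
    """Alternative metric: percent of pixels whose intensity moved by more than ``delta``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DataError(f"frame shapes differ: {a.shape} vs {b.shape}")
    return float(100.0 * np.mean(np.abs(a - b) > delta))


def visual_classify(
    seq: FrameSequence,
    threshold_pct: float = DEFAULT_VISUAL_THRESHOLD_PCT,
    metric: Callable[[np.ndarray, np.ndarray], float] = frame_difference,
) -> int:
    """Binary fall flag from a frame sequence.

    Returns 1 iff any consecutive-frame difference strictly exceeds
    ``threshold_pct`` ("exceeds" is a strict inequality), else 0.
    Monotone in the threshold: raising it can only clear the flag.
    """
    diffs = (metric(seq[i], seq[i + 1]) for i in range(len(seq) - 1))
    return int(any(d > threshold_pct for d in diffs))


def camera_trigger(w: SignalWindow, th: TriggerThresholds = TriggerThresholds()) -> bool:
    """True iff any sample leaves the ADL envelope.

    Fires when any gyro sample satisfies |value| > gyro_limit OR any
    accel sample satisfies |value| > accel_limit. Non-fall motions stay
    inside both envelopes, so the camera (and hence the visual
    classifier) only engages on candidate falls.
    """
    return bool(
        np.any(np.abs(w.gyro()) > th.gyro_limit)
        or np.any(np.abs(w.accel()) > th.accel_limit)
    )


#: ITU-R BT.601 luma weights for colour-to-grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse an (h, w, 3) colour image to grayscale by luma weighting."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] in (3, 4):
        return image[..., :3] @ _LUMA
    raise DataError(f"cannot interpret image of shape {image.shape} as a frame")


def load_frames(directory: Union[str, Path]) -> FrameSequence:
    """Read a frame sequence from a directory of PNG/PGM files.

    Files are taken in lexicographic order; colour images are converted
    to grayscale by luma weighting.
    """
    import imageio.v3 as iio

    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in (".png", ".pgm")
    )
    if len(paths) < 2:
        raise DataError(f"{directory}: found {len(paths)} frame file(s); need >= 2")
    return FrameSequence(np.stack([to_grayscale(iio.imread(p)) for p in paths]))


def save_frames(seq: FrameSequence, directory: Union[str, Path]) -> Path:
    """Write a sequence as zero-padded 8-bit PNGs readable by :func:`load_frames`."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i in range(len(seq)):
        frame = np.clip(np.round(seq[i]), 0, 255).astype(np.uint8)
        iio.imwrite(directory / f"frame{i:04d}.png", frame)
    return directory
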