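"""Seeded synthetic motion recordings and frame sequences.

No public dataset accompanies the original fall-detection study, so
this module generates labelled recordings with the statistical
structure the classifiers rely on:

* every non-fall (ADL) recording stays inside the ±1.5 m/s² and
  ±120 rad/s envelopes that bound real ADLs on every axis, so the
  camera trigger never fires on one;
* every fall carries a short transient whose gyroscope peak exceeds the
  ±120 rad/s envelope by a large margin (default 2.5x), which both
  dominates the gyro-power features and fires the camera trigger;
* frame sequences show gradual inter-frame change (well under the 7%
  visual threshold) for ADLs and one abrupt scene shift (far above it)
  for falls.

Non-fall waveforms are raised-cosine bumps — one smooth push per
channel with a class-specific amplitude and sign pattern — plus white
Gaussian noise. The family is deliberately minimal: it honours the
envelopes and makes signal power analytically checkable, but it does
not attempt biomechanical realism.

Everything is deterministic given the seed; per-recording seeds are
derived from (base seed, class index, trial index) via
``numpy.random.SeedSequence`` and are stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .signals import GYRO_CHANNELS, MotionClass, ParameterError, SignalWindow
from .visual import FrameSequence

__all__ = [
    "MotionModelParams",
    "TrialRecord",
    "FALL_SCENARIOS",
    "SCENARIOS",
    "generate_motion",
    "generate_corpus",
    "generate_frames",
    "generate_trial_protocol",
]

#: Default per-class bump amplitudes as a fraction of the channel bound,
#: ordered still < lying_down < sitting_up < bending < standing_up so
#: the ADL classes remain mutually distinguishable in feature space.
DEFAULT_CLASS_AMPLITUDES: Mapping[MotionClass, float] = {
    MotionClass.STILL: 0.0,
    MotionClass.LYING_DOWN: 0.25,
    MotionClass.SITTING_UP: 0.45,
    MotionClass.BENDING: 0.65,
    MotionClass.STANDING_UP: 0.85,
}

# Per-class channel sign patterns (ax ay az gx gy gz): a crude stand-in
# for each motion's direction signature.
_SIGNS: Mapping[MotionClass, tuple[int, ...]] = {
    MotionClass.LYING_DOWN: (1, -1, 1, -1, 1, -1),
    MotionClass.SITTING_UP: (1, 1, -1, 1, -1, 1),
    MotionClass.STANDING_UP: (-1, 1, 1, 1, 1, -1),
    MotionClass.BENDING: (1, -1, -1, -1, 1, 1),
}

_NONFALL = tuple(c for c in MotionClass if not c.is_fall)

# Samples are clipped just inside the envelope so ADL recordings can
# never fire the (strictly greater-than) camera trigger.
_CLIP_MARGIN = 0.999


@dataclass(frozen=True)
class MotionModelParams:
    """Generator parameters; defaults reproduce the study conditions.

    ``noise_sd`` is the white-noise standard deviation expressed as a
    fraction of each channel's bound (one scalar cannot serve both a
    1.5 m/s² accelerometer envelope and a 120 rad/s gyroscope envelope
    in raw units), i.e. 0.02 means sigma = 0.03 m/s² on accel channels
    and 2.4 rad/s on gyro channels.
    """

    rate: float = 10.0  # samples/second
    duration: float = 5.0  # seconds per recording
    accel_bound: float = 1.5  # m/s², ADL envelope
    gyro_bound: float = 120.0  # rad/s, ADL envelope
    class_amplitudes: Mapping[MotionClass, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_AMPLITUDES)
    )
    fall_spike_factor: float = 2.5  # fall gyro peak, multiples of gyro_bound
    fall_spike_width: float = 0.5  # seconds
    noise_sd: float = 0.02  # fraction of each channel bound
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.rate > 0 and self.duration > 0):
            raise ParameterError("rate and duration must be positive")
        if round(self.rate * self.duration) < 2:
            raise ParameterError("duration x rate must yield at least 2 samples")
        if not (self.accel_bound > 0 and self.gyro_bound > 0):
            raise ParameterError("channel bounds must be positive")
        for c in _NONFALL:
            a = self.class_amplitudes.get(c, 0.0)
            if not 0.0 <= a < 1.0:
                raise ParameterError(
                    f"amplitude for {c.value!r} must be in [0, 1), got {a}"
                )
        if not self.fall_spike_factor > 1.0:
            raise ParameterError("fall_spike_factor must exceed 1")
        if not 0 < self.fall_spike_width <= self.duration:
            raise ParameterError("fall_spike_width must be in (0, duration]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.rate * self.duration))


def _bump(t: np.ndarray, start: float, width: float) -> np.ndarray:
    """Raised-cosine pulse: 0 outside [start, start+width], peak 1 at centre."""
    u = (t - start) / width
    return np.where((u >= 0) & (u <= 1), 0.5 * (1 - np.cos(2 * np.pi * u)), 0.0)


def _bounds(params: MotionModelParams) -> np.ndarray:
    return np.array([params.accel_bound] * 3 + [params.gyro_bound] * 3)


def _nonfall_channels(
    cls: MotionClass, params: MotionModelParams, t: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """(6, n) ADL waveform: class bump + noise, clipped inside the envelopes."""
    bounds = _bounds(params)
    x = rng.normal(0.0, params.noise_sd, size=(6, t.size)) * bounds[:, None]
    if cls is not MotionClass.STILL:
        amp = params.class_amplitudes.get(cls, 0.0)
        signs = np.array(_SIGNS[cls], dtype=float)
        width = 0.4 * params.duration
        start = rng.uniform(0.15, 0.45) * params.duration
        jitter = rng.uniform(0.9, 1.1, size=6)
        x += (signs * amp * jitter * bounds)[:, None] * _bump(t, start, width)[None, :]
    lim = _CLIP_MARGIN * bounds[:, None]
    return np.clip(x, -lim, lim)


def generate_motion(
    cls: MotionClass,
    params: MotionModelParams = MotionModelParams(),
    *,
    seed: Optional[int] = None,
    fall_from: Optional[MotionClass] = None,
) -> SignalWindow:
    """Generate one recording of the given motion class.

    ``still`` is zero-mean noise; the other ADLs add one raised-cosine
    bump per channel with the class's amplitude and sign pattern. All
    ADL samples stay strictly inside ±accel_bound / ±gyro_bound. A
    ``fall`` is an ADL baseline (``fall_from``, default drawn among the
    ADL classes) plus a transient spike of width ``fall_spike_width``
    whose gyroscope peak reaches at least
    ``fall_spike_factor x gyro_bound`` on one axis.

    Identical arguments (including the seed, which defaults to
    ``params.seed``) give bit-identical output.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    t = np.arange(params.n_samples) / params.rate

    if cls.is_fall:
        if fall_from is None:
            fall_from = _NONFALL[rng.integers(len(_NONFALL))]
        elif fall_from.is_fall:
            raise ParameterError("fall_from must be a non-fall class")
        x = _nonfall_channels(fall_from, params, t, rng)
        axis = 3 + int(rng.integers(3))  # one of the gyro channels
        sign = float(rng.choice([-1.0, 1.0]))
        peak = params.fall_spike_factor * params.gyro_bound
        lo = 0.3 * params.duration
        hi = max(lo, 0.6 * params.duration - params.fall_spike_width)
        start = rng.uniform(lo, hi) if hi > lo else lo
        spike = sign * peak * _bump(t, start, params.fall_spike_width)
        x[axis] += spike
        # The sample grid may miss the pulse apex; pin the largest spike
        # sample so the peak magnitude is exactly reached.
        ipk = int(np.argmax(np.abs(spike)))
        if abs(x[axis, ipk]) < peak:
            x[axis, ipk] = sign * peak
    else:
        x = _nonfall_channels(cls, params, t, rng)

    return SignalWindow(t=t, ax=x[0], ay=x[1], az=x[2], gx=x[3], gy=x[4], gz=x[5],
                        rate=params.rate)


def _derived_seed(base: int, *path: int) -> int:
    """Stable per-recording seed from (base seed, indices...)."""
    return int(np.random.SeedSequence((int(base),) + tuple(int(p) for p in path))
               .generate_state(1)[0])


def generate_corpus(
    trials_per_class: int,
    params: MotionModelParams = MotionModelParams(),
) -> list[tuple[SignalWindow, MotionClass]]:
    """Generate a balanced labelled corpus: trials_per_class recordings per class.

    Recordings are ordered class-major in enumeration order. Each
    recording's seed derives deterministically from
    (params.seed, class index, trial index), so two calls with the same
    parameters produce identical corpora.
    """
    trials_per_class = int(trials_per_class)
    if trials_per_class < 1:
        raise ParameterError("trials_per_class must be >= 1")
    corpus = []
    for ci, cls in enumerate(MotionClass):
        for ti in range(trials_per_class):
            w = generate_motion(cls, params, seed=_derived_seed(params.seed, ci, ti))
            corpus.append((w, cls))
    return corpus


def generate_frames(
    is_fall: bool,
    n_frames: int = 10,
    shape: tuple[int, int] = (32, 32),
    seed: int = 0,
) -> FrameSequence:
    """Generate a grayscale frame sequence seen by the wearable camera.

    Non-fall: the scene luminance drifts by a small global offset
    (1–8 intensity units, i.e. 0.4–3.1%) between consecutive frames —
    every consecutive-pair percentage difference stays below 7.
    Fall: one mid-sequence step shifts the whole scene by 64 units
    (25.1%) — an abrupt change well above 7. Offsets alternate in sign
    and the base image lives mid-range, so no pixel ever clips and the
    differences are exact.
    """
    n_frames = int(n_frames)
    if n_frames < 2:
        raise ParameterError(f"n_frames must be >= 2, got {n_frames}")
    h, w = int(shape[0]), int(shape[1])
    if h < 1 or w < 1:
        raise ParameterError(f"invalid frame shape {shape}")
    rng = np.random.default_rng(seed)

    # Static scene: horizontal luminance gradient plus smooth-ish texture.
    gradient = np.linspace(60.0, 160.0, w)[None, :] * np.ones((h, 1))
    base = gradient + rng.uniform(-10.0, 10.0, size=(h, w))

    frames = [base]
    jump_step = n_frames // 2 - 1 if is_fall else -1
    for i in range(n_frames - 1):
        if i == jump_step:
            offset = 64.0  # abrupt scene change: 64/255 = 25.1% > 7%
        else:
            offset = (1.0 if i % 2 == 0 else -1.0) * rng.uniform(1.0, 8.0)
        frames.append(frames[-1] + offset)
    return FrameSequence(np.stack(frames))


#: The ten trial scenarios of the evaluation protocol: each ADL
#: performed on its own, and a fall initiated from each starting
#: position.
FALL_SCENARIOS = tuple(f"fall_{c.value}" for c in _NONFALL)
SCENARIOS = tuple(c.value for c in _NONFALL) + FALL_SCENARIOS


@dataclass(frozen=True)
class TrialRecord:
    """One synthetic evaluation trial: signals, paired frames, ground truth."""

    scenario: str
    window: SignalWindow
    frames: FrameSequence
    truth: int  # 1 = fall
    label: MotionClass


def generate_trial_protocol(
    trials_per_scenario: int,
    params: MotionModelParams = MotionModelParams(),
    n_frames: int = 10,
    frame_shape: tuple[int, int] = (32, 32),
) -> list[TrialRecord]:
    """Simulate the ten-scenario evaluation protocol.

    For each of the five ADLs and each of the five fall-from-position
    scenarios, generates ``trials_per_scenario`` recordings with paired
    frame sequences (gradual change for ADLs, abrupt for falls).
    Deterministic under ``params.seed``; seeds are derived per scenario
    and trial, disjoint from :func:`generate_corpus`'s derivation.
    """
    if int(trials_per_scenario) < 1:
        raise ParameterError("trials_per_scenario must be >= 1")
    records = []
    for si, scenario in enumerate(SCENARIOS):
        is_fall = scenario.startswith("fall")
        cls = MotionClass.FALL if is_fall else MotionClass(scenario)
        fall_from = MotionClass(scenario.removeprefix("fall_")) if is_fall else None
        for ti in range(int(trials_per_scenario)):
            w = generate_motion(
                cls, params,
                seed=_derived_seed(params.seed, 1000 + si, ti),
                fall_from=fall_from,
            )
            frames = generate_frames(
                is_fall, n_frames=n_frames, shape=frame_shape,
                seed=_derived_seed(params.seed, 2000 + si, ti),
            )
            records.append(TrialRecord(scenario, w, frames, int(is_fall), cls))
    return records
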