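"""Domain types for wearable motion data and delimited-text I/O.

A recording is a fixed-rate, six-channel time series: tri-axial
acceleration (m/s²) and tri-axial angular velocity (rad/s), nominally
sampled at 10 Hz by the wearable unit. One whole recording is one
classification window; sub-windowing is out of scope.

On-disk format is a plain CSV with columns
``recording_id,t,ax,ay,az,gx,gy,gz[,label]`` — one row per sample, one
file per corpus, recordings keyed by ``recording_id``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "MotionClass",
    "SignalWindow",
    "FormatError",
    "DataError",
    "ParameterError",
    "CHANNELS",
    "ACCEL_CHANNELS",
    "GYRO_CHANNELS",
    "read_motion_csv",
    "write_motion_csv",
]

#: Channel names in canonical order: accelerometer axes then gyroscope axes.
ACCEL_CHANNELS = ("ax", "ay", "az")
GYRO_CHANNELS = ("gx", "gy", "gz")
CHANNELS = ACCEL_CHANNELS + GYRO_CHANNELS

#: Required CSV columns (the label column is optional).
CSV_COLUMNS = ("recording_id", "t") + CHANNELS


class FormatError(ValueError):
    """A file does not conform to the motion-CSV contract."""


class DataError(ValueError):
    """Data values violate an invariant (e.g. non-monotone time)."""


class ParameterError(ValueError):
    """An argument is outside its documented domain."""


class MotionClass(enum.Enum):
    """The six motion classes distinguished by the system.

    Five are activities of daily living (ADLs); ``FALL`` is the single
    positive class, the only member with binary fall indicator 1.
    Enumeration order is the deterministic tie-break order used by both
    classifiers.
    """

    STILL = "still"
    LYING_DOWN = "lying_down"
    SITTING_UP = "sitting_up"
    STANDING_UP = "standing_up"
    BENDING = "bending"
    FALL = "fall"

    @property
    def is_fall(self) -> bool:
        return self is MotionClass.FALL

    @property
    def fall_flag(self) -> int:
        """Binary fall indicator: 1 for FALL, 0 for every ADL."""
        return int(self.is_fall)

    @classmethod
    def from_label(cls, label: str) -> "MotionClass":
        try:
            return cls(str(label).strip().lower().replace(" ", "_"))
        except ValueError:
            raise DataError(f"unknown motion class label: {label!r}") from None


#: Stable index of each class in the enumeration order (tie-break order).
CLASS_ORDER = {c: i for i, c in enumerate(MotionClass)}

_TIME_TOL = 1e-6  # seconds; tolerance on uniform sample spacing


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise DataError(f"channel {name!r} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class SignalWindow:
    """A uniformly sampled six-channel motion recording.

    Parameters
    ----------
    t : array-like
        Sample times in seconds from recording start, strictly increasing
        with spacing ``1/rate`` (tolerance 1e-6 s).
    ax, ay, az : array-like
        Acceleration per axis, m/s².
    gx, gy, gz : array-like
        Angular velocity per axis, rad/s.
    rate : float
        Sampling rate in samples/second (default 10, the wearable's
        nominal rate).

    All channels must share the same length, at least 2 samples.
    Invariants are checked at construction.
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray
    rate: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", _as_float_array(self.t, "t"))
        for name in CHANNELS:
            object.__setattr__(self, name, _as_float_array(getattr(self, name), name))
        n = len(self.t)
        if n < 2:
            raise DataError("a SignalWindow needs at least 2 samples")
        for name in CHANNELS:
            if len(getattr(self, name)) != n:
                raise DataError(
                    f"channel {name!r} has length {len(getattr(self, name))}, "
                    f"expected {n}"
                )
        if not float(self.rate) > 0:
            raise ParameterError(f"rate must be positive, got {self.rate}")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise DataError("timestamps must be strictly increasing")
        if np.any(np.abs(dt - 1.0 / self.rate) > _TIME_TOL):
            raise DataError(
                f"sample spacing deviates from 1/rate = {1.0 / self.rate:.6g} s "
                f"by more than {_TIME_TOL} s"
            )

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Window span in seconds (last minus first timestamp)."""
        return float(self.t[-1] - self.t[0])

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise ParameterError(f"unknown channel {name!r}")
        return getattr(self, name)

    def channels(self) -> np.ndarray:
        """All six channels stacked as a (6, n) array in canonical order."""
        return np.stack([getattr(self, name) for name in CHANNELS])

    def accel(self) -> np.ndarray:
        """(3, n) accelerometer samples, m/s²."""
        return np.stack([self.ax, self.ay, self.az])

    def gyro(self) -> np.ndarray:
        """(3, n) gyroscope samples, rad/s."""
        return np.stack([self.gx, self.gy, self.gz])


LabelledWindow = tuple[SignalWindow, Optional[MotionClass]]


def read_motion_csv(path: Union[str, Path]) -> list[LabelledWindow]:
    """Read a motion corpus CSV into labelled signal windows.

    Rows are grouped by ``recording_id`` (groups ordered by first
    appearance) and time-sorted within each group. The optional
    ``label`` column, when present and non-empty, must be constant
    within a recording and parse to a :class:`MotionClass`.

    Raises
    ------
    FormatError
        If a required column is missing.
    DataError
        On duplicate timestamps, inconsistent labels, or any window
        invariant violation (reported with the recording id).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"recording_id": str})
    for col in CSV_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    has_label = "label" in df.columns

    out: list[LabelledWindow] = []
    for rec_id, grp in df.groupby("recording_id", sort=False):
        grp = grp.sort_values("t", kind="stable")
        t = grp["t"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise DataError(f"recording {rec_id!r}: non-monotone or duplicate timestamps")
        rate = _infer_rate(t, rec_id)
        label: Optional[MotionClass] = None
        if has_label:
            labels = grp["label"].dropna().astype(str).str.strip()
            labels = labels[labels != ""]
            uniq = labels.unique()
            if len(uniq) > 1:
                raise DataError(f"recording {rec_id!r}: conflicting labels {list(uniq)}")
            if len(uniq) == 1:
                label = MotionClass.from_label(uniq[0])
        try:
            window = SignalWindow(
                t=t,
                **{name: grp[name].to_numpy(dtype=float) for name in CHANNELS},
                rate=rate,
            )
        except (DataError, ParameterError) as exc:
            raise DataError(f"recording {rec_id!r}: {exc}") from exc
        out.append((window, label))
    return out


def _infer_rate(t: np.ndarray, rec_id: str) -> float:
    dt = np.diff(t)
    med = float(np.median(dt))
    if med <= 0:
        raise DataError(f"recording {rec_id!r}: cannot infer sampling rate")
    return 1.0 / med


def write_motion_csv(
    windows: Sequence[LabelledWindow],
    path: Union[str, Path],
) -> Path:
    """Write labelled windows to a motion CSV readable by :func:`read_motion_csv`.

    Values are written with 15 significant digits so a read-back round
    trip preserves them to well below 1e-9. Recording ids are ``r0000``,
    ``r0001``, ... in input order. Returns the written path.
    """
    if len(windows) == 0:
        raise ParameterError("cannot write an empty corpus")
    path = Path(path)
    frames = []
    for i, (w, label) in enumerate(windows):
        rec = pd.DataFrame({"recording_id": f"r{i:04d}", "t": w.t})
        for name in CHANNELS:
            rec[name] = getattr(w, name)
        rec["label"] = "" if label is None else label.value
        frames.append(rec)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.15g")
    return path
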