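"""Signal-power feature extraction.

Each recording is summarised by six numbers: the power of each
accelerometer and gyroscope axis over the whole window. "Power" here is
the mean-square value of the channel,

    P(x) = (1/n) * sum_j x_j**2,

which is invariant to window length (recordings may differ in duration)
and non-negative by construction. No detrending or gravity removal is
applied. The six powers place every recording in a 6-D feature space in
which both classifiers operate.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .signals import CHANNELS, DataError, MotionClass, SignalWindow

__all__ = ["FEATURE_NAMES", "extract_features", "features_frame"]

#: Feature names in canonical order: accel powers then gyro powers.
FEATURE_NAMES = tuple(f"p_{name}" for name in CHANNELS)

N_FEATURES = len(FEATURE_NAMES)


def extract_features(w: SignalWindow) -> np.ndarray:
    """Map a signal window to its 6-D power feature vector.

    Returns a float array of shape (6,): mean-square value of
    ``ax, ay, az`` in (m/s²)² followed by ``gx, gy, gz`` in (rad/s)²,
    ordered as :data:`FEATURE_NAMES`.
    """
    channels = w.channels()
    if channels.shape[1] == 0:  # unreachable via SignalWindow, kept for safety
        raise DataError("cannot extract features from an empty window")
    return np.mean(np.square(channels), axis=1)


def features_frame(
    corpus: Iterable[tuple[SignalWindow, Optional[MotionClass]]],
) -> pd.DataFrame:
    """Tabulate a corpus as one feature row per recording.

    Columns are ``recording_id``, the six powers of
    :data:`FEATURE_NAMES`, and ``label`` (empty string when a recording
    is unlabelled). Suitable for CSV export and for
    ``FallDetectionModel.from_dataframe``.
    """
    rows = []
    for i, (w, label) in enumerate(corpus):
        feats = extract_features(w)
        row = {"recording_id": f"r{i:04d}"}
        row.update(dict(zip(FEATURE_NAMES, feats)))
        row["label"] = "" if label is None else label.value
        rows.append(row)
    return pd.DataFrame(rows, columns=["recording_id", *FEATURE_NAMES, "label"])
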