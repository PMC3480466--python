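"""Gravity/dynamic separation by windowed median and SD.

Each 5-s window yields a per-channel median (the gravity estimate used by
all posture decisions), a per-channel SD, and a scalar dynamic-activity
magnitude: the mean over samples of the euclidean norm, across the four
channels, of the median-subtracted values.  Activity is therefore computed
on the dynamic component; raw values would read ~1 g at rest and would be
inconsistent with resting activity on the order of 0.004 g.

Windows tile the recording by default (step = window); a sliding variant
is available via ``step_s``.  A trailing partial window is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np

from .errors import ValidationError
from .signal_io import Recording

__all__ = ["WindowFeatures", "window_features", "window_activity"]


@dataclass
class WindowFeatures:
    start_time: datetime
    duration_s: float
    median_g: np.ndarray  # (4,) gravity estimate per channel
    sd_g: np.ndarray  # (4,)
    activity: float  # mean dynamic magnitude, in g

    def __post_init__(self) -> None:
        self.median_g = np.asarray(self.median_g, dtype=float)
        self.sd_g = np.asarray(self.sd_g, dtype=float)
        if self.duration_s <= 0:
            raise ValidationError("window duration must be positive")
        if np.any(self.sd_g < 0) or self.activity < 0:
            raise ValidationError("sd and activity must be non-negative")


def window_activity(samples: np.ndarray, medians: np.ndarray) -> float:
    """Mean over samples of sqrt(sum over channels of (x - median)^2).

    ``samples`` is an ``(n, 4)`` block; ``medians`` the per-channel gravity
    estimate subtracted before squaring.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[0] == 0:
        raise ValidationError("samples block must be a nonempty 2-D array")
    dyn = samples - np.asarray(medians, dtype=float)
    return float(np.mean(np.sqrt(np.sum(dyn * dyn, axis=1))))


def window_features(
    recording: Recording, window_s: float = 5.0, step_s: float | None = None
) -> list[WindowFeatures]:
    """Compute per-window gravity/SD/activity features.

    Returns an empty list (not an error) when the recording is shorter
    than one window.
    """
    if step_s is None:
        step_s = window_s
    fs = recording.sampling_rate
    n_win = int(round(window_s * fs))
    n_step = int(round(step_s * fs))
    if n_win < 2:
        raise ValidationError("window must contain at least 2 samples")
    if n_step < 1:
        raise ValidationError("step must contain at least 1 sample")
    data = recording.data
    n = data.shape[0]
    if n < n_win:
        return []

    if n_step == n_win:
        n_windows = n // n_win
        blocks = data[: n_windows * n_win].reshape(n_windows, n_win, data.shape[1])
    else:
        view = np.lib.stride_tricks.sliding_window_view(data, n_win, axis=0)
        blocks = np.transpose(view[::n_step], (0, 2, 1))  # (n_windows, n_win, 4)
        n_windows = blocks.shape[0]

    medians = np.median(blocks, axis=1)
    sds = np.std(blocks, axis=1)
    dyn = blocks - medians[:, None, :]
    activity = np.mean(np.sqrt(np.sum(dyn * dyn, axis=2)), axis=1)

    out = []
    for k in range(n_windows):
        out.append(
            WindowFeatures(
                start_time=recording.start_time
                + timedelta(seconds=k * n_step / fs),
                duration_s=n_win / fs,
                median_g=medians[k],
                sd_g=sds[k],
                activity=float(activity[k]),
            )
        )
    return out
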