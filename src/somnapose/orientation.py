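"""Torso rotation tracking and adaptive angle-based posture segmentation.

During lying windows the rotation of the torso about the longitudinal body
axis is the polar angle of the gravity median in the antero-posterior /
medio-lateral plane: 0 deg = ventral (gravity pressing on the chest),
+90 deg = right side, +/-180 deg = dorsal, -90 deg = left side.

Segmentation is adaptive rather than fixed-threshold: a sliding circular
mean over the last few seconds of angles is maintained, and a segment
boundary is set only when the current angle deviates from that mean by
more than 30 deg.  Slow drift and jitter around a fixed category boundary
therefore never split a segment, while a genuine turn does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterable, Sequence

import numpy as np

from .config import Thresholds
from .errors import UndefinedAngleError, UndefinedMeanError, ValidationError
from .windowing import WindowFeatures

__all__ = [
    "VENTRAL",
    "RIGHT",
    "DORSAL",
    "LEFT",
    "LABELS",
    "OrientationSample",
    "PostureSegment",
    "supine_angle",
    "orientation_trace",
    "circular_mean",
    "circular_diff",
    "label_from_angle",
    "segment_supine",
]

VENTRAL = "ventral"
RIGHT = "right"
DORSAL = "dorsal"
LEFT = "left"
LABELS = (VENTRAL, RIGHT, DORSAL, LEFT)

#: Minimum gravity magnitude in the ap/lat plane for a well-defined angle.
MIN_PLANAR_G = 0.2

_AP, _LAT = 1, 2  # channel indices into the median vector


def _wrap_deg(a: float) -> float:
    """Map an angle into (-180, 180]."""
    a = math.fmod(a, 360.0)
    if a <= -180.0:
        a += 360.0
    elif a > 180.0:
        a -= 360.0
    return a


def supine_angle(features: WindowFeatures, handedness: str = "right") -> float:
    """Rotation angle of a lying window from its gravity medians.

    Raises :class:`UndefinedAngleError` when the planar gravity magnitude
    is below :data:`MIN_PLANAR_G` (torso nearly along gravity), in which
    case callers carry the previous valid angle forward.
    """
    ap = float(features.median_g[_AP])
    lat = float(features.median_g[_LAT])
    if math.hypot(ap, lat) <= MIN_PLANAR_G:
        raise UndefinedAngleError(
            f"planar gravity {math.hypot(ap, lat):.3f} g <= {MIN_PLANAR_G} g"
        )
    sign = 1.0 if handedness == "right" else -1.0
    return _wrap_deg(math.degrees(math.atan2(sign * lat, ap)))


@dataclass
class OrientationSample:
    time: datetime
    angle_deg: float

    def __post_init__(self) -> None:
        if not (-180.0 < self.angle_deg <= 180.0):
            raise ValidationError(
                f"angle {self.angle_deg} outside (-180, 180]"
            )


@dataclass
class PostureSegment:
    start: datetime
    end: datetime
    mean_angle_deg: float
    label: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError("segment start must precede end")
        if self.label not in LABELS:
            raise ValidationError(f"unknown posture label {self.label!r}")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()


def orientation_trace(
    lying_windows: Sequence[WindowFeatures], handedness: str = "right"
) -> list[OrientationSample]:
    """Angle per lying window; ill-conditioned windows carry the previous
    valid angle forward, leading ill-conditioned windows are dropped."""
    out: list[OrientationSample] = []
    prev: float | None = None
    for f in lying_windows:
        try:
            prev = supine_angle(f, handedness=handedness)
        except UndefinedAngleError:
            if prev is None:
                continue
        out.append(OrientationSample(time=f.start_time, angle_deg=prev))
    return out


def circular_mean(angles: Iterable[float]) -> float:
    """Mean direction via summed unit vectors, in (-180, 180]."""
    arr = np.asarray(list(angles), dtype=float)
    if arr.size == 0:
        raise ValidationError("circular_mean of empty sequence")
    rad = np.deg2rad(arr)
    s, c = np.sum(np.sin(rad)), np.sum(np.cos(rad))
    if math.hypot(s, c) / arr.size < 1e-12:
        raise UndefinedMeanError("resultant length ~ 0: mean direction undefined")
    return _wrap_deg(math.degrees(math.atan2(s, c)))


def circular_diff(a: float, b: float) -> float:
    """Signed smallest difference a - b, in (-180, 180]."""
    return _wrap_deg(a - b)


def label_from_angle(angle: float) -> str:
    """Partition (-180, 180] into ventral / right / dorsal / left."""
    if not (-180.0 < angle <= 180.0):
        raise ValidationError(f"angle {angle} outside (-180, 180]")
    if abs(angle) < 45.0:
        return VENTRAL
    if 45.0 <= angle < 135.0:
        return RIGHT
    if -135.0 < angle <= -45.0:
        return LEFT
    return DORSAL


class _SlidingCircularMean:
    """Circular mean of the most recent ``k`` angles of the open segment."""

    def __init__(self, k: int):
        self.k = k
        self.buf: list[float] = []

    def reset(self, angle: float) -> None:
        self.buf = [angle]

    def push(self, angle: float) -> None:
        self.buf.append(angle)
        if len(self.buf) > self.k:
            del self.buf[0]

    def mean(self) -> float:
        return circular_mean(self.buf)


def _sample_spacing_s(samples: Sequence[OrientationSample], default: float) -> float:
    if len(samples) < 2:
        return default
    diffs = [
        (samples[i + 1].time - samples[i].time).total_seconds()
        for i in range(len(samples) - 1)
    ]
    spacing = float(np.median(diffs))
    if spacing <= 0:
        raise ValidationError("orientation samples must be strictly time-ordered")
    return spacing


def segment_supine(
    samples: Sequence[OrientationSample],
    thresholds: Thresholds | None = None,
    mean_window_s: float = 5.0,
) -> list[PostureSegment]:
    """Streaming adaptive segmentation of a contiguous supine angle trace.

    Maintains the circular mean of the last ``mean_window_s`` of angles
    within the open segment (warm-up: all angles since the segment start).
    When the current angle deviates from that mean by more than
    ``angle_change_deg`` the segment closes at the current sample time and
    the mean restarts from the current angle.  Segments exactly tile
    [first sample time, last sample time + spacing).
    """
    thresholds = thresholds or Thresholds()
    if not samples:
        return []
    spacing = _sample_spacing_s(samples, mean_window_s)
    k = max(1, int(round(mean_window_s / spacing)))

    segments: list[PostureSegment] = []
    seg_start = samples[0].time
    seg_angles = [samples[0].angle_deg]
    sliding = _SlidingCircularMean(k)
    sliding.reset(samples[0].angle_deg)

    def close(end: datetime) -> None:
        mean = circular_mean(seg_angles)
        segments.append(
            PostureSegment(
                start=seg_start,
                end=end,
                mean_angle_deg=mean,
                label=label_from_angle(mean),
            )
        )

    for s in samples[1:]:
        if abs(circular_diff(s.angle_deg, sliding.mean())) > thresholds.angle_change_deg:
            close(s.time)
            seg_start = s.time
            seg_angles = [s.angle_deg]
            sliding.reset(s.angle_deg)
        else:
            seg_angles.append(s.angle_deg)
            sliding.push(s.angle_deg)
    close(samples[-1].time + timedelta(seconds=spacing))
    return segments
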