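"""Night-level sleep duration and quality indices.

All indices are computed from the coarse-posture window sequence restricted
to the night window.  Conventions:

* a *supine episode* is a maximal run of lying windows lasting at least
  ``supine_min_s`` (50 s = ten 5-s windows, boundary inclusive);
* the *in-bed span* runs from the first episode start to the last episode
  end; episodes separated by more than ``max_rise_min`` of absence end the
  span (treated as getting up for the day);
* *time supine* is the sum of episode durations (the span minus sitting or
  standing interruptions);
* *total sleep time* is supine time in windows whose dynamic activity is
  strictly below ``sleep_activity_g`` (0.15 g);
* a *rise* is a maximal non-lying run strictly inside the span;
* posture changes count adaptive segment boundaries plus rises.

Rates are per hour of time supine; when time supine is zero, rates are
emitted as missing (NaN), never 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np

from .config import Thresholds
from .errors import ValidationError
from .orientation import (
    LABELS,
    PostureSegment,
    orientation_trace,
    segment_supine,
)
from .posture import LYING, classify_recording
from .signal_io import Recording
from .windowing import WindowFeatures

__all__ = [
    "SupineEpisode",
    "LatencyResult",
    "RiseStats",
    "PostureChangeStats",
    "NightSummary",
    "detect_supine_episodes",
    "time_supine",
    "total_sleep_time",
    "still_position_latency",
    "rises",
    "posture_change_stats",
    "sleep_efficiency_turning",
    "summarize_night",
]

Labeled = Sequence[tuple[WindowFeatures, str]]


@dataclass
class SupineEpisode:
    """A contiguous supine interval; indices refer to the labeled window
    sequence it was detected in (end_index exclusive)."""

    start: datetime
    end: datetime
    interrupting_nonlying_s: float
    start_index: int
    end_index: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError("episode start must precede end")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()


@dataclass
class LatencyResult:
    minutes: float
    sustained_found: bool  # False: no >=3-min still run; latency = supine time


@dataclass
class RiseStats:
    total: int
    first_hour: int
    per_hour: float


@dataclass
class PostureChangeStats:
    changes_per_hour: float
    mean_duration_min: float
    gt15_per_hour: float
    fractions: dict[str, float]
    first_posture: str
    n_boundaries: int
    n_gt15: int


@dataclass
class NightSummary:
    """The full indicator suite for one night.  Missing rates are NaN/None."""

    subject_id: str
    time_supine_h: float
    in_bed_span_h: float
    total_sleep_time_h: float
    average_activity_g: float
    still_position_latency_min: float
    latency_sustained: bool
    sleep_efficiency: float
    sleep_efficiency_supine: float
    rises_total: int
    rises_first_hour: int
    rises_per_hour: float
    posture_changes_per_hour: float
    mean_posture_duration_min: float
    postures_gt15_per_hour: float
    posture_fractions: dict[str, float] | None
    first_posture: str | None


def _window_s(labeled: Labeled) -> float:
    return labeled[0][0].duration_s


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) index pairs, end exclusive."""
    out = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def detect_supine_episodes(
    labeled: Labeled, thresholds: Thresholds | None = None
) -> list[SupineEpisode]:
    """Maximal lying runs of at least ``supine_min_s`` inside the in-bed span.

    Non-lying windows between episodes are tallied on the preceding
    episode as interrupting time.  An absence longer than ``max_rise_min``
    ends the span; later runs are discarded.
    """
    thresholds = thresholds or Thresholds()
    if not labeled:
        return []
    w = _window_s(labeled)
    lying = np.array([lab == LYING for _, lab in labeled])
    qualified = [
        (i, j) for i, j in _runs(lying) if (j - i) * w >= thresholds.supine_min_s
    ]
    if not qualified:
        return []

    kept = [qualified[0]]
    for i, j in qualified[1:]:
        prev_end = kept[-1][1]
        gap_nonlying = int(np.sum(~lying[prev_end:i]))
        if gap_nonlying * w > thresholds.max_rise_min * 60.0:
            break
        kept.append((i, j))

    episodes = []
    for n, (i, j) in enumerate(kept):
        if n + 1 < len(kept):
            nxt = kept[n + 1][0]
            interrupting = float(np.sum(~lying[j:nxt])) * w
        else:
            interrupting = 0.0
        episodes.append(
            SupineEpisode(
                start=labeled[i][0].start_time,
                end=labeled[j - 1][0].start_time + timedelta(seconds=w),
                interrupting_nonlying_s=interrupting,
                start_index=i,
                end_index=j,
            )
        )
    return episodes


def time_supine(episodes: Sequence[SupineEpisode]) -> float:
    """Total episode time in hours (0 for no episodes)."""
    return sum(ep.duration_s for ep in episodes) / 3600.0


def _in_bed_span_s(episodes: Sequence[SupineEpisode]) -> float:
    if not episodes:
        return 0.0
    return (episodes[-1].end - episodes[0].start).total_seconds()


def total_sleep_time(
    episodes: Sequence[SupineEpisode],
    labeled: Labeled,
    thresholds: Thresholds | None = None,
) -> float:
    """Hours of supine time with activity strictly below ``sleep_activity_g``."""
    thresholds = thresholds or Thresholds()
    if not episodes:
        return 0.0
    w = _window_s(labeled)
    total = 0
    for ep in episodes:
        for feats, _ in labeled[ep.start_index : ep.end_index]:
            if feats.activity < thresholds.sleep_activity_g:
                total += 1
    return total * w / 3600.0


def still_position_latency(
    episodes: Sequence[SupineEpisode],
    labeled: Labeled,
    thresholds: Thresholds | None = None,
) -> LatencyResult:
    """Minutes from supine onset to the first sustained still period.

    A sustained still period is a run of at least ``still_min_min``
    consecutive minutes of supine windows with activity below
    ``sleep_activity_g`` (interruptions by non-lying windows break the
    run).  With no such run the latency equals the full supine duration
    and ``sustained_found`` is False.
    """
    thresholds = thresholds or Thresholds()
    if not episodes:
        return LatencyResult(minutes=0.0, sustained_found=False)
    w = _window_s(labeled)
    need = int(math.ceil(thresholds.still_min_min * 60.0 / w))
    onset = episodes[0].start
    for ep in episodes:
        still = np.array(
            [
                feats.activity < thresholds.sleep_activity_g
                for feats, _ in labeled[ep.start_index : ep.end_index]
            ]
        )
        for i, j in _runs(still):
            if j - i >= need:
                start = labeled[ep.start_index + i][0].start_time
                return LatencyResult(
                    minutes=(start - onset).total_seconds() / 60.0,
                    sustained_found=True,
                )
    return LatencyResult(minutes=time_supine(episodes) * 60.0, sustained_found=False)


def rises(
    labeled: Labeled,
    episodes: Sequence[SupineEpisode],
    thresholds: Thresholds | None = None,
) -> RiseStats:
    """Maximal non-lying runs strictly inside the in-bed span."""
    thresholds = thresholds or Thresholds()
    if not episodes:
        return RiseStats(total=0, first_hour=0, per_hour=float("nan"))
    w = _window_s(labeled)
    lo, hi = episodes[0].start_index, episodes[-1].end_index
    nonlying = np.array([lab != LYING for _, lab in labeled[lo:hi]])
    run_list = _runs(nonlying)
    onset = episodes[0].start
    total = len(run_list)
    first_hour = 0
    for i, _ in run_list:
        start = labeled[lo + i][0].start_time
        if (start - onset).total_seconds() < 3600.0:
            first_hour += 1
    tsh = time_supine(episodes)
    per_hour = total / tsh if tsh > 0 else float("nan")
    return RiseStats(total=total, first_hour=first_hour, per_hour=per_hour)


def _internal_boundaries(segments: Sequence[PostureSegment]) -> list[int]:
    """Indices i such that segments[i] ends exactly where segments[i+1]
    starts (a turn within one episode, not an episode break)."""
    return [
        i
        for i in range(len(segments) - 1)
        if segments[i].end == segments[i + 1].start
    ]


def posture_change_stats(
    segments: Sequence[PostureSegment],
    episodes: Sequence[SupineEpisode],
    rises_total: int,
    thresholds: Thresholds | None = None,
) -> PostureChangeStats:
    """Turn/segment statistics; changes per hour include rises."""
    thresholds = thresholds or Thresholds()
    if not segments:
        nan = float("nan")
        return PostureChangeStats(nan, nan, nan, {}, "", 0, 0)
    tsh = time_supine(episodes)
    boundaries = len(_internal_boundaries(segments))
    durations_min = np.array([seg.duration_s / 60.0 for seg in segments])
    n_gt15 = int(np.sum(durations_min > thresholds.long_posture_min))
    per_label = {lab: 0.0 for lab in LABELS}
    for seg in segments:
        per_label[seg.label] += seg.duration_s
    total_seg = sum(per_label.values())
    fractions = {lab: t / total_seg for lab, t in per_label.items()}
    changes_per_hour = (boundaries + rises_total) / tsh if tsh > 0 else float("nan")
    gt15_per_hour = n_gt15 / tsh if tsh > 0 else float("nan")
    return PostureChangeStats(
        changes_per_hour=changes_per_hour,
        mean_duration_min=float(np.mean(durations_min)),
        gt15_per_hour=gt15_per_hour,
        fractions=fractions,
        first_posture=segments[0].label,
        n_boundaries=boundaries,
        n_gt15=n_gt15,
    )


def _charged_turn_windows(
    segments: Sequence[PostureSegment],
    episodes: Sequence[SupineEpisode],
    labeled: Labeled,
    thresholds: Thresholds,
) -> set[int]:
    """Window indices charged as turning time: ``boundary_charge_windows``
    at each internal segment boundary plus adjacent supine windows at or
    above the activity threshold."""
    if not labeled:
        return set()
    w = _window_s(labeled)
    t0 = labeled[0][0].start_time
    lying_idx = set()
    for ep in episodes:
        lying_idx.update(range(ep.start_index, ep.end_index))

    def active(i: int) -> bool:
        return (
            i in lying_idx
            and labeled[i][0].activity >= thresholds.sleep_activity_g
        )

    charged: set[int] = set()
    for i in _internal_boundaries(segments):
        b = int(round((segments[i + 1].start - t0).total_seconds() / w))
        core = [b + k for k in range(thresholds.boundary_charge_windows)]
        charged.update(j for j in core if j in lying_idx)
        j = b - 1
        while active(j):
            charged.add(j)
            j -= 1
        j = b + thresholds.boundary_charge_windows
        while active(j):
            charged.add(j)
            j += 1
    return charged


def sleep_efficiency_turning(
    segments: Sequence[PostureSegment],
    episodes: Sequence[SupineEpisode],
    labeled: Labeled,
    thresholds: Thresholds | None = None,
) -> tuple[float, float]:
    """(efficiency over the in-bed span, efficiency over time supine).

    Efficiency = (time supine - turning time) / denominator, clamped to
    [0, 1]; turning time is the charged-window total around segment
    boundaries.  The span denominator additionally counts rise time as
    inefficiency.
    """
    thresholds = thresholds or Thresholds()
    if not episodes:
        return float("nan"), float("nan")
    w = _window_s(labeled)
    supine_s = time_supine(episodes) * 3600.0
    span_s = _in_bed_span_s(episodes)
    turned_s = len(
        _charged_turn_windows(segments, episodes, labeled, thresholds)
    ) * w
    eff_span = min(1.0, max(0.0, (supine_s - turned_s) / span_s))
    eff_supine = min(1.0, max(0.0, (supine_s - turned_s) / supine_s))
    return eff_span, eff_supine


def _segments_for_episodes(
    episodes: Sequence[SupineEpisode],
    labeled: Labeled,
    thresholds: Thresholds,
    mean_window_s: float = 5.0,
    handedness: str = "right",
) -> list[PostureSegment]:
    segments: list[PostureSegment] = []
    for ep in episodes:
        windows = [f for f, _ in labeled[ep.start_index : ep.end_index]]
        trace = orientation_trace(windows, handedness=handedness)
        segments.extend(segment_supine(trace, thresholds, mean_window_s=mean_window_s))
    return segments


def _empty_summary(subject_id: str) -> NightSummary:
    nan = float("nan")
    return NightSummary(
        subject_id=subject_id,
        time_supine_h=0.0,
        in_bed_span_h=0.0,
        total_sleep_time_h=0.0,
        average_activity_g=nan,
        still_position_latency_min=0.0,
        latency_sustained=False,
        sleep_efficiency=nan,
        sleep_efficiency_supine=nan,
        rises_total=0,
        rises_first_hour=0,
        rises_per_hour=nan,
        posture_changes_per_hour=nan,
        mean_posture_duration_min=nan,
        postures_gt15_per_hour=nan,
        posture_fractions=None,
        first_posture=None,
    )


def summarize_night(
    recording: Recording,
    thresholds: Thresholds | None = None,
    window_s: float = 5.0,
    handedness: str = "right",
) -> NightSummary:
    """Run the full pipeline on one recording and return all indices.

    Deterministic for fixed input and thresholds.  With no supine episode
    inside the night window, duration indices are 0 and rates missing.
    """
    thresholds = thresholds or Thresholds()
    labeled = classify_recording(recording, thresholds, window_s=window_s)
    episodes = detect_supine_episodes(labeled, thresholds)
    if not episodes:
        return _empty_summary(recording.subject_id)

    tsh = time_supine(episodes)
    tst = total_sleep_time(episodes, labeled, thresholds)
    latency = still_position_latency(episodes, labeled, thresholds)
    rise_stats = rises(labeled, episodes, thresholds)
    segments = _segments_for_episodes(
        episodes, labeled, thresholds, mean_window_s=window_s, handedness=handedness
    )
    pcs = posture_change_stats(segments, episodes, rise_stats.total, thresholds)
    eff_span, eff_supine = sleep_efficiency_turning(
        segments, episodes, labeled, thresholds
    )
    activities = [
        labeled[i][0].activity
        for ep in episodes
        for i in range(ep.start_index, ep.end_index)
    ]
    return NightSummary(
        subject_id=recording.subject_id,
        time_supine_h=tsh,
        in_bed_span_h=_in_bed_span_s(episodes) / 3600.0,
        total_sleep_time_h=tst,
        average_activity_g=float(np.mean(activities)),
        still_position_latency_min=latency.minutes,
        latency_sustained=latency.sustained_found,
        sleep_efficiency=eff_span,
        sleep_efficiency_supine=eff_supine,
        rises_total=rise_stats.total,
        rises_first_hour=rise_stats.first_hour,
        rises_per_hour=rise_stats.per_hour,
        posture_changes_per_hour=pcs.changes_per_hour,
        mean_posture_duration_min=pcs.mean_duration_min,
        postures_gt15_per_hour=pcs.gt15_per_hour,
        posture_fractions=pcs.fractions or None,
        first_posture=pcs.first_posture or None,
    )
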