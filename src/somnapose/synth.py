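"""Synthetic recordings with known ground truth.

The measurement model projects the unit gravity vector onto the four
sensor axes per posture: standing/walking reads +1 g on the sternum
vertical axis, sitting additionally +1 g on the thigh antero-posterior
axis, and lying at rotation angle theta reads (cos theta, sin theta) on
the sternum ap/lat axes (0 deg = ventral, +90 deg = right side) and
cos theta on the thigh.

Structured dynamics (the pre-sleep restlessness burst, periodic movement
bursts, walking oscillations) are deterministic functions of the scenario
so that ground-truth indices do not depend on the seed; the seed drives
only the additive Gaussian sensor noise.  Turn and rise transitions are
constant-rate rotations *centered* on the scheduled boundary, so that
5-s windows on either side stay majority-pure and the pipeline can
recover scheduled counts exactly on grid-aligned scenarios.

Ground-truth indices are computed from the scenario's true per-window
posture/angle arrays with a direct, independent implementation of the
index definitions (not by running the analysis pipeline).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Sequence

import numpy as np

from .config import Thresholds, in_night_window, parse_clock
from .errors import ValidationError
from .indices import LatencyResult, NightSummary
from .signal_io import CHANNELS, Recording

__all__ = [
    "NightScenario",
    "GroundTruth",
    "LabeledInterval",
    "simulate_protocol",
    "simulate_night",
    "random_scenario",
    "label_windows",
]

WINDOW_S = 5.0  # analysis window the grid is aligned to

LABEL_ANGLES = {"ventral": 0.0, "right": 90.0, "dorsal": 180.0, "left": -90.0}

_LYING, _SITTING, _UPRIGHT = "lying", "sitting", "upright"


def _wrap_deg(a: float) -> float:
    a = math.fmod(a, 360.0)
    if a <= -180.0:
        a += 360.0
    elif a > 180.0:
        a -= 360.0
    return a


def _angle_label(angle: float) -> str:
    # Deliberate re-statement of the category partition, kept independent
    # of the analysis modules.
    if abs(angle) < 45.0:
        return "ventral"
    if 45.0 <= angle < 135.0:
        return "right"
    if -135.0 < angle <= -45.0:
        return "left"
    return "dorsal"


def _gravity(kind: str, angle: float | None) -> np.ndarray:
    if kind == "lying":
        a = math.radians(angle if angle is not None else 0.0)
        return np.array([0.0, math.cos(a), math.sin(a), math.cos(a)])
    if kind == "sitting":
        return np.array([1.0, 0.0, 0.0, 1.0])
    # standing / walking / stairs
    return np.array([1.0, 0.0, 0.0, 0.0])


# ---------------------------------------------------------------------------
# Calibration protocol


@dataclass
class LabeledInterval:
    start_s: float
    end_s: float
    label: str  # coarse posture label
    activity_name: str


#: The standardized laboratory motion sequence: (name, duration s, coarse
#: label, lying angle or None).
PROTOCOL = (
    ("walk_normal", 40.0, _UPRIGHT, None),
    ("stairs_up", 50.0, _UPRIGHT, None),
    ("stairs_down", 40.0, _UPRIGHT, None),
    ("walk_fast", 40.0, _UPRIGHT, None),
    ("standing", 40.0, _UPRIGHT, None),
    ("sitting", 40.0, _SITTING, None),
    ("lying_right", 40.0, _LYING, 90.0),
    ("lying_left", 40.0, _LYING, -90.0),
    ("lying_back", 180.0, _LYING, 180.0),
)

_WALK_AMPLITUDES = {
    "walk_normal": 0.25,
    "stairs_up": 0.30,
    "stairs_down": 0.30,
    "walk_fast": 0.35,
}


def simulate_protocol(
    seed: int = 0,
    noise_sd_g: float = 0.05,
    sampling_rate: float = 64.0,
    start_time: datetime | None = None,
) -> tuple[Recording, list[LabeledInterval]]:
    """Simulate the 510-s labeled calibration sequence."""
    if start_time is None:
        start_time = datetime(2024, 3, 1, 10, 0, 0)
    fs = sampling_rate
    rng = np.random.default_rng(seed)
    blocks = []
    intervals = []
    t = 0.0
    for name, dur, label, angle in PROTOCOL:
        n = int(round(dur * fs))
        kind = "lying" if label == _LYING else ("sitting" if label == _SITTING else "standing")
        block = np.tile(_gravity(kind, angle), (n, 1))
        amp = _WALK_AMPLITUDES.get(name)
        if amp is not None:
            tt = (np.arange(n) + 0.5) / fs
            osc = amp * np.sin(2 * math.pi * 2.0 * tt)  # 2 Hz gait proxy
            block[:, 0] += osc
            block[:, 1] += 0.6 * amp * np.sin(2 * math.pi * 2.0 * tt + 1.0)
            block[:, 3] += osc
        blocks.append(block)
        intervals.append(LabeledInterval(t, t + dur, label, name))
        t += dur
    data = np.concatenate(blocks)
    if noise_sd_g > 0:
        data = data + rng.normal(0.0, noise_sd_g, data.shape)
    rec = Recording(
        subject_id=f"protocol-{seed}",
        start_time=start_time,
        sampling_rate=fs,
        data=data,
    )
    return rec, intervals


def label_windows(features, intervals: Sequence[LabeledInterval], start_time: datetime):
    """Pair window features with interval labels (windows fully inside an
    interval only); used to build training data for threshold fitting."""
    out = []
    for f in features:
        a = (f.start_time - start_time).total_seconds()
        b = a + f.duration_s
        for iv in intervals:
            if iv.start_s <= a and b <= iv.end_s:
                out.append((f, iv.label))
                break
    return out


# ---------------------------------------------------------------------------
# Night scenarios


@dataclass
class NightScenario:
    """A scheduled night with known ground truth.

    ``posture_schedule`` entries are (label-or-angle, duration_min); rise
    events are (offset_min from bedtime, duration_min) and must fall
    strictly inside a single posture block.  For exact index recovery all
    block and rise boundaries should land on the 5-s window grid (minute
    granularity always does).
    """

    seed: int = 0
    start_date: str = "2024-03-01"
    night_start: str | time = "20:00"
    night_end: str | time = "10:00"
    bedtime: str | time = "23:00"
    pre_bed_min: float = 10.0
    post_rise_min: float = 10.0
    latency_min: float = 10.0
    posture_schedule: tuple = (("dorsal", 240.0), ("left", 240.0))
    rise_events: tuple = ()
    movement_burst_rate_per_h: float = 2.0
    burst_amplitude_g: float = 0.5
    sensor_noise_sd_g: float = 0.002
    transition_duration_s: float = 5.0
    sampling_rate: float = 64.0

    def __post_init__(self) -> None:
        self.night_start = parse_clock(self.night_start)
        self.night_end = parse_clock(self.night_end)
        self.bedtime = parse_clock(self.bedtime)
        if not self.posture_schedule:
            raise ValidationError("posture_schedule must be nonempty")
        for entry, dur in self.posture_schedule:
            if dur <= 0:
                raise ValidationError("schedule durations must be positive")
            self._angle_of(entry)  # validates
        if self.latency_min < 0 or self.pre_bed_min < 0 or self.post_rise_min < 0:
            raise ValidationError("durations must be non-negative")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if not in_night_window(self.bedtime, self.night_start, self.night_end):
            raise ValidationError("bedtime outside the night window")
        end = self.end_of_schedule()
        if not in_night_window(end.time(), self.night_start, self.night_end):
            raise ValidationError("schedule exceeds the night window")
        self._validate_rises()

    @staticmethod
    def _angle_of(entry) -> float:
        if isinstance(entry, str):
            try:
                return LABEL_ANGLES[entry]
            except KeyError:
                raise ValidationError(f"unknown posture label {entry!r}") from None
        a = float(entry)
        if not (-180.0 < a <= 180.0):
            raise ValidationError(f"angle {a} outside (-180, 180]")
        return a

    def bed_datetime(self) -> datetime:
        d = date.fromisoformat(self.start_date)
        return datetime.combine(d, self.bedtime)

    def total_schedule_min(self) -> float:
        return sum(dur for _, dur in self.posture_schedule)

    def end_of_schedule(self) -> datetime:
        return self.bed_datetime() + timedelta(minutes=self.total_schedule_min())

    def _validate_rises(self) -> None:
        total = self.total_schedule_min()
        margin_min = (self.transition_duration_s + WINDOW_S) / 60.0
        edges = np.cumsum([0.0] + [dur for _, dur in self.posture_schedule])
        spans = []
        for off, dur in self.rise_events:
            if dur <= 0:
                raise ValidationError("rise durations must be positive")
            if off < 0 or off + dur > total:
                raise ValidationError("rise event outside the schedule")
            # must sit strictly inside one block, clear of its edges
            block = np.searchsorted(edges, off, side="right") - 1
            if not (
                edges[block] + margin_min <= off
                and off + dur <= edges[block + 1] - margin_min
            ):
                raise ValidationError(
                    "rise events must fall strictly inside a posture block"
                )
            spans.append((off, off + dur))
        spans.sort()
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1 + margin_min:
                raise ValidationError("rise events overlap or are too close")


@dataclass
class GroundTruth:
    """True per-window trace plus analytically derived indices."""

    summary: NightSummary
    window_start: datetime
    window_s: float
    window_labels: np.ndarray  # coarse posture per window
    window_angles: np.ndarray  # scheduled rotation angle (NaN if not lying)
    window_active: np.ndarray  # bool: noiseless activity >= threshold
    window_activity: np.ndarray  # noiseless activity values
    n_turn_boundaries: int
    n_rises: int
    n_gt15: int


@dataclass
class _Piece:
    start_s: float
    end_s: float
    kind: str  # lying | sitting | standing
    angle: float | None


def _build_pieces(scenario: NightScenario) -> list[_Piece]:
    pre = scenario.pre_bed_min * 60.0
    post = scenario.post_rise_min * 60.0
    pieces = []
    if pre > 0:
        pieces.append(_Piece(0.0, pre, "standing", None))
    cur = pre
    for entry, dur_min in scenario.posture_schedule:
        pieces.append(
            _Piece(cur, cur + dur_min * 60.0, "lying", NightScenario._angle_of(entry))
        )
        cur += dur_min * 60.0
    if post > 0:
        pieces.append(_Piece(cur, cur + post, "standing", None))

    # carve rise events (standing) out of the lying pieces
    for off_min, dur_min in sorted(scenario.rise_events):
        a = pre + off_min * 60.0
        b = a + dur_min * 60.0
        for i, p in enumerate(pieces):
            if p.kind == "lying" and p.start_s < a and b < p.end_s:
                pieces[i : i + 1] = [
                    _Piece(p.start_s, a, "lying", p.angle),
                    _Piece(a, b, "standing", None),
                    _Piece(b, p.end_s, "lying", p.angle),
                ]
                break
        else:
            raise ValidationError("rise event does not fall inside a lying block")
    return pieces


def _render_signal(
    pieces: list[_Piece], scenario: NightScenario
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless channel signal and per-sample piece index."""
    fs = scenario.sampling_rate
    n = int(round(pieces[-1].end_s * fs))
    bounds = np.array([p.start_s for p in pieces] + [pieces[-1].end_s])
    sample_t = (np.arange(n) + 0.5) / fs
    piece_idx = np.clip(np.searchsorted(bounds, sample_t, side="right") - 1, 0, len(pieces) - 1)

    gvecs = np.stack([_gravity(p.kind, p.angle) for p in pieces])
    sig = gvecs[piece_idx].astype(float)

    # centered constant-rate transitions at internal boundaries
    T = scenario.transition_duration_s
    if T > 0:
        half = int(round(T * fs / 2))
        for i in range(len(pieces) - 1):
            b = int(round(pieces[i].end_s * fs))
            s0, s1 = max(0, b - half), min(n, b + half)
            if s1 <= s0:
                continue
            w = (np.arange(s1 - s0) + 0.5) / (s1 - s0)
            p, q = pieces[i], pieces[i + 1]
            if p.kind == "lying" and q.kind == "lying":
                d = _wrap_deg((q.angle or 0.0) - (p.angle or 0.0))
                theta = np.radians((p.angle or 0.0) + w * d)
                sig[s0:s1, 0] = 0.0
                sig[s0:s1, 1] = np.cos(theta)
                sig[s0:s1, 2] = np.sin(theta)
                sig[s0:s1, 3] = np.cos(theta)
            else:
                ga, gb = _gravity(p.kind, p.angle), _gravity(q.kind, q.angle)
                v = (1 - w)[:, None] * ga + w[:, None] * gb
                norm = np.linalg.norm(v[:, :3], axis=1)
                norm = np.where(norm > 1e-6, norm, 1.0)
                v[:, :3] /= norm[:, None]
                sig[s0:s1] = v
    return sig, piece_idx


def _burst_times(scenario: NightScenario, pieces: list[_Piece]) -> list[tuple[float, float]]:
    """Deterministic, evenly spaced movement bursts inside quiet lying time."""
    rate = scenario.movement_burst_rate_per_h
    if rate <= 0:
        return []
    pre = scenario.pre_bed_min * 60.0
    latency_end = pre + scenario.latency_min * 60.0
    spacing = 3600.0 / rate
    guard = 20.0 + scenario.transition_duration_s
    bursts = []
    t = latency_end + spacing
    end = pieces[-1].end_s
    while t < end:
        t0 = round(t / WINDOW_S) * WINDOW_S
        t1 = t0 + WINDOW_S  # one full analysis window
        ok = any(
            p.kind == "lying"
            and p.start_s + guard <= t0
            and t1 <= p.end_s - guard
            for p in pieces
        )
        if ok:
            bursts.append((t0, t1))
        t += spacing
    return bursts


def _add_dynamics(
    sig: np.ndarray, scenario: NightScenario, pieces: list[_Piece]
) -> list[tuple[float, float]]:
    """Add the deterministic restlessness/burst oscillations in place."""
    fs = scenario.sampling_rate
    n = sig.shape[0]

    def oscillate(t0: float, t1: float, amp: float, freq: float) -> None:
        s0, s1 = int(round(t0 * fs)), min(n, int(round(t1 * fs)))
        if s1 <= s0:
            return
        tt = (np.arange(s1 - s0) + 0.5) / fs
        for c in range(4):
            sig[s0:s1, c] += amp * np.sin(2 * math.pi * freq * tt + c * math.pi / 3)

    pre = scenario.pre_bed_min * 60.0
    if scenario.latency_min > 0:
        oscillate(pre, pre + scenario.latency_min * 60.0, scenario.burst_amplitude_g, 3.0)
    bursts = _burst_times(scenario, pieces)
    for t0, t1 in bursts:
        oscillate(t0, t1, scenario.burst_amplitude_g, 4.0)
    return bursts


# -- ground-truth index computation (independent of the pipeline) -----------


def _gt_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    out = []
    i, n = 0, len(mask)
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


def _ground_truth_summary(
    scenario: NightScenario,
    labels: np.ndarray,
    angles: np.ndarray,
    active: np.ndarray,
    activity: np.ndarray,
    window_start: datetime,
    thresholds: Thresholds,
) -> tuple[NightSummary, int, int, int]:
    w = WINDOW_S
    n = len(labels)
    nan = float("nan")
    in_night = np.array(
        [
            in_night_window(
                window_start + timedelta(seconds=i * w),
                thresholds.night_start,
                thresholds.night_end,
            )
            for i in range(n)
        ]
    )
    idx = np.flatnonzero(in_night)
    lo_n, hi_n = (idx[0], idx[-1] + 1) if idx.size else (0, 0)
    labels, angles = labels[lo_n:hi_n], angles[lo_n:hi_n]
    active, activity = active[lo_n:hi_n], activity[lo_n:hi_n]
    window_start = window_start + timedelta(seconds=lo_n * w)

    lying = labels == _LYING
    min_run = int(math.ceil(thresholds.supine_min_s / w))
    episodes = [(i, j) for i, j in _gt_runs(lying) if j - i >= min_run]
    if not episodes:
        return (
            NightSummary(
                subject_id=f"night-{scenario.seed}",
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
            ),
            0,
            0,
            0,
        )

    lo, hi = episodes[0][0], episodes[-1][1]
    ep_mask = np.zeros(len(labels), dtype=bool)
    for i, j in episodes:
        ep_mask[i:j] = True
    supine_s = float(np.sum(ep_mask)) * w
    span_s = (hi - lo) * w
    tst_s = float(np.sum(ep_mask & ~active)) * w

    # latency: first >= still_min_min run of still supine windows
    need = int(math.ceil(thresholds.still_min_min * 60.0 / w))
    latency = LatencyResult(minutes=supine_s / 60.0, sustained_found=False)
    for i, j in episodes:
        found = False
        for a, b in _gt_runs(ep_mask[i:j] & ~active[i:j]):
            if b - a >= need:
                latency = LatencyResult(minutes=(i + a - lo) * w / 60.0, sustained_found=True)
                found = True
                break
        if found:
            break

    rise_runs = _gt_runs(~lying[lo:hi])
    n_rises = len(rise_runs)
    rises_first_hour = sum(1 for a, _ in rise_runs if a * w < 3600.0)

    # segments: runs of constant angle within each episode
    seg_durs: list[float] = []
    seg_labels: list[str] = []
    n_boundaries = 0
    boundary_windows: list[int] = []
    for i, j in episodes:
        a = i
        for k in range(i + 1, j):
            if angles[k] != angles[k - 1]:
                d = _wrap_deg(angles[k] - angles[k - 1])
                if abs(d) > thresholds.angle_change_deg:
                    seg_durs.append((k - a) * w)
                    seg_labels.append(_angle_label(angles[a]))
                    n_boundaries += 1
                    boundary_windows.append(k)
                    a = k
        seg_durs.append((j - a) * w)
        seg_labels.append(_angle_label(angles[a]))

    n_gt15 = sum(1 for d in seg_durs if d / 60.0 > thresholds.long_posture_min)
    per_label = {lab: 0.0 for lab in ("ventral", "right", "dorsal", "left")}
    for lab, d in zip(seg_labels, seg_durs):
        per_label[lab] += d
    total_seg = sum(per_label.values())
    fractions = {lab: t / total_seg for lab, t in per_label.items()}

    charged: set[int] = set()
    for b in boundary_windows:
        charged.add(b)
        k = b - 1
        while k >= 0 and ep_mask[k] and active[k]:
            charged.add(k)
            k -= 1
        k = b + 1
        while k < len(labels) and ep_mask[k] and active[k]:
            charged.add(k)
            k += 1
    turned_s = len([c for c in charged if ep_mask[c]]) * w
    eff_span = min(1.0, max(0.0, (supine_s - turned_s) / span_s))
    eff_supine = min(1.0, max(0.0, (supine_s - turned_s) / supine_s))

    tsh = supine_s / 3600.0
    summary = NightSummary(
        subject_id=f"night-{scenario.seed}",
        time_supine_h=tsh,
        in_bed_span_h=span_s / 3600.0,
        total_sleep_time_h=tst_s / 3600.0,
        average_activity_g=float(np.mean(activity[ep_mask])),
        still_position_latency_min=latency.minutes,
        latency_sustained=latency.sustained_found,
        sleep_efficiency=eff_span,
        sleep_efficiency_supine=eff_supine,
        rises_total=n_rises,
        rises_first_hour=rises_first_hour,
        rises_per_hour=n_rises / tsh,
        posture_changes_per_hour=(n_boundaries + n_rises) / tsh,
        mean_posture_duration_min=float(np.mean(seg_durs)) / 60.0,
        postures_gt15_per_hour=n_gt15 / tsh,
        posture_fractions=fractions,
        first_posture=seg_labels[0],
    )
    return summary, n_boundaries, n_rises, n_gt15


def simulate_night(
    scenario: NightScenario, thresholds: Thresholds | None = None
) -> tuple[Recording, GroundTruth]:
    """Render a scenario into a Recording plus its GroundTruth."""
    thresholds = thresholds or Thresholds(
        night_start=scenario.night_start, night_end=scenario.night_end
    )
    fs = scenario.sampling_rate
    if (WINDOW_S * fs) != int(WINDOW_S * fs):
        raise ValidationError("sampling_rate must make 5-s windows integral")
    pieces = _build_pieces(scenario)
    sig, piece_idx = _render_signal(pieces, scenario)
    _add_dynamics(sig, scenario, pieces)

    # true per-window arrays (majority piece per window)
    wlen = int(round(WINDOW_S * fs))
    n_w = sig.shape[0] // wlen
    kinds = np.array([p.kind for p in pieces])
    angles_by_piece = np.array(
        [p.angle if p.angle is not None else np.nan for p in pieces]
    )
    coarse_id = np.select(
        [kinds == "lying", kinds == "sitting"], [0, 1], default=2
    )[piece_idx]
    block = coarse_id[: n_w * wlen].reshape(n_w, wlen)
    counts = np.stack([(block == c).sum(axis=1) for c in (0, 1, 2)], axis=1)
    maj = counts.argmax(axis=1)
    window_labels = np.array([_LYING, _SITTING, _UPRIGHT])[maj]
    center_piece = piece_idx[: n_w * wlen].reshape(n_w, wlen)[:, wlen // 2]
    window_angles = np.where(
        window_labels == _LYING, angles_by_piece[center_piece], np.nan
    )

    # noiseless per-window activity (median-subtracted dynamic magnitude)
    wb = sig[: n_w * wlen].reshape(n_w, wlen, 4)
    med = np.median(wb, axis=1)
    dyn = wb - med[:, None, :]
    window_activity = np.mean(np.sqrt(np.sum(dyn * dyn, axis=2)), axis=1)
    window_active = window_activity >= thresholds.sleep_activity_g

    start_time = scenario.bed_datetime() - timedelta(minutes=scenario.pre_bed_min)
    summary, n_bound, n_rises, n_gt15 = _ground_truth_summary(
        scenario,
        window_labels,
        window_angles,
        window_active,
        window_activity,
        start_time,
        thresholds,
    )

    rng = np.random.default_rng(scenario.seed)
    data = sig
    if scenario.sensor_noise_sd_g > 0:
        data = data + rng.normal(0.0, scenario.sensor_noise_sd_g, sig.shape)
    recording = Recording(
        subject_id=f"night-{scenario.seed}",
        start_time=start_time,
        sampling_rate=fs,
        data=data,
    )
    gt = GroundTruth(
        summary=summary,
        window_start=start_time,
        window_s=WINDOW_S,
        window_labels=window_labels,
        window_angles=window_angles,
        window_active=window_active,
        window_activity=window_activity,
        n_turn_boundaries=n_bound,
        n_rises=n_rises,
        n_gt15=n_gt15,
    )
    return recording, gt


def random_scenario(
    seed: int,
    min_h: float = 8.0,
    max_h: float = 13.5,
    max_rises: int = 3,
    sampling_rate: float = 64.0,
) -> NightScenario:
    """A random grid-aligned scenario with turns >= 40 deg and >= 5 min apart.

    The first block always outlasts the latency period by enough for the
    first sustained still run to complete inside it, so the scheduled
    latency is recovered exactly.  Bedtime is fixed at 20:15 so that even
    the longest schedule stays inside the 20:00-10:00 night window.
    """
    rng = np.random.default_rng(seed)
    total_min = float(rng.integers(int(min_h * 60), int(max_h * 60) + 1))
    latency_min = float(rng.integers(0, 26))
    first_block = min(latency_min + float(rng.integers(6, 16)), total_min)
    blocks = [first_block]
    remaining = total_min - first_block
    while remaining > 0:
        if remaining <= 45.0:
            dur = remaining  # leaves no short tail; blocks stay >= 6 min
        else:
            dur = float(rng.integers(6, 40))
        blocks.append(dur)
        remaining -= dur

    canonical = ("ventral", "right", "dorsal", "left")
    schedule: list[tuple[str, float]] = []
    prev = None
    for dur in blocks:
        choices = [c for c in canonical if c != prev]
        lab = choices[int(rng.integers(len(choices)))]
        schedule.append((lab, dur))
        prev = lab

    edges = np.cumsum([0.0] + [d for _, d in schedule])
    rises: list[tuple[float, float]] = []
    for _ in range(int(rng.integers(0, max_rises + 1))):
        big = [
            k
            for k in range(len(schedule))
            if edges[k + 1] - edges[k] >= 12.0 and edges[k] >= first_block
        ]
        if not big:
            break
        k = big[int(rng.integers(len(big)))]
        dur = float(rng.integers(1, 6))
        lo = edges[k] + 3.0
        hi = edges[k + 1] - 3.0 - dur
        if hi <= lo:
            continue
        off = float(int(rng.uniform(lo, hi)))
        if all(abs(off - o) > dur + o_d + 7.0 for o, o_d in rises):
            rises.append((off, dur))

    return NightScenario(
        seed=seed,
        bedtime="20:15",
        pre_bed_min=10.0,
        post_rise_min=10.0,
        latency_min=latency_min,
        posture_schedule=tuple(schedule),
        rise_events=tuple(sorted(rises)),
        movement_burst_rate_per_h=2.0,
        sampling_rate=sampling_rate,
    )
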