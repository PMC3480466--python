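"""Decision constants and the night-window clock logic.

The default constants are the operative values of the classification
method: the torso-inclination split at 0.66 g, the thigh split at 0.5 g,
the 30 degree adaptive posture-change threshold, the 50 s minimum supine
run, the 0.15 g stillness threshold, the 3 min sustained-stillness run,
the 15 min long-posture cut, and the 20:00-10:00 night window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from datetime import datetime, time
from pathlib import Path
from typing import Any

import yaml

from .errors import ValidationError

__all__ = ["Thresholds", "parse_clock", "in_night_window"]

#: Accepted conventions for the vertical-axis lying rule.
VERTICAL_SIGN_MODES = ("abs", "up_positive", "up_negative")


def parse_clock(value: str | time) -> time:
    """Parse ``"HH:MM"`` (or ``"HH:MM:SS"``) into a :class:`datetime.time`."""
    if isinstance(value, time):
        return value
    try:
        parts = [int(p) for p in str(value).split(":")]
    except ValueError as exc:
        raise ValidationError(f"unparseable clock time: {value!r}") from exc
    if not 1 <= len(parts) <= 3:
        raise ValidationError(f"unparseable clock time: {value!r}")
    while len(parts) < 3:
        parts.append(0)
    h, m, s = parts
    if not (0 <= h < 24 and 0 <= m < 60 and 0 <= s < 60):
        raise ValidationError(f"clock time out of range: {value!r}")
    return time(h, m, s)


def in_night_window(t: datetime | time, start: time, end: time) -> bool:
    """True if the clock time of ``t`` falls in [start, end).

    The window may span midnight (e.g. 20:00 -> 10:00); ``start == end``
    is rejected at :class:`Thresholds` construction.
    """
    tod = t.time() if isinstance(t, datetime) else t
    if start < end:
        return start <= tod < end
    return tod >= start or tod < end


@dataclass(frozen=True)
class Thresholds:
    """All decision constants of the method, with their standard defaults."""

    vertical_g: float = 0.66
    thigh_g: float = 0.5
    angle_change_deg: float = 30.0
    supine_min_s: float = 50.0
    sleep_activity_g: float = 0.15
    still_min_min: float = 3.0
    long_posture_min: float = 15.0
    night_start: time = time(20, 0)
    night_end: time = time(10, 0)
    # Artifact knobs, not printed constants:
    vertical_sign: str = "abs"  # abs | up_positive | up_negative
    max_rise_min: float = 30.0  # a longer absence ends the in-bed span
    boundary_charge_windows: int = 1  # windows charged per turn boundary

    def __post_init__(self) -> None:
        for name in (
            "vertical_g",
            "thigh_g",
            "angle_change_deg",
            "supine_min_s",
            "sleep_activity_g",
            "still_min_min",
            "long_posture_min",
            "max_rise_min",
        ):
            v = getattr(self, name)
            if not (v > 0):
                raise ValidationError(f"threshold {name} must be positive, got {v!r}")
        object.__setattr__(self, "night_start", parse_clock(self.night_start))
        object.__setattr__(self, "night_end", parse_clock(self.night_end))
        if self.night_start == self.night_end:
            raise ValidationError("night window must have nonzero length")
        if self.vertical_sign not in VERTICAL_SIGN_MODES:
            raise ValidationError(
                f"vertical_sign must be one of {VERTICAL_SIGN_MODES}"
            )
        if self.boundary_charge_windows < 0:
            raise ValidationError("boundary_charge_windows must be >= 0")

    # -- (de)serialisation ------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {}
        for f in fields(self):
            v = getattr(self, f.name)
            d[f.name] = v.strftime("%H:%M:%S") if isinstance(v, time) else v
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Thresholds":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown threshold field(s): {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Thresholds":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValidationError(f"threshold file {path} is not a mapping")
        return cls.from_dict(data)

    def replace(self, **kw: Any) -> "Thresholds":
        return replace(self, **kw)

    # Convenience used by the lying rule: the g-threshold expressed as a
    # deviation angle from upright (cos(theta) = vertical_g).
    @property
    def lying_angle_deg(self) -> float:
        import math

        return math.degrees(math.acos(min(1.0, self.vertical_g)))
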