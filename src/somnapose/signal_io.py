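"""Reading and writing recordings, segment tables, and night summaries.

Canonical on-disk form of a recording is a CSV channel table: ``#``-prefixed
metadata lines (``key=value``), then a header row naming the four channels,
then one sample per row in units of g.  EDF input is supported when
``pyedflib`` is installed.  Readers never rescale silently; pass
``unit="ms2"`` to convert m/s^2 input to g explicitly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, ValidationError

__all__ = [
    "CHANNELS",
    "Recording",
    "read_recording",
    "write_recording",
    "write_segments",
    "read_segments",
    "write_summary",
    "read_summary",
]

#: Canonical channel order: sternum vertical, antero-posterior and
#: medio-lateral axes, then the thigh antero-posterior axis.
CHANNELS = ("sternum_vertical", "sternum_ap", "sternum_lat", "thigh_ap")

STANDARD_GRAVITY = 9.81  # m/s^2 per g
MAX_ABS_G = 16.0  # sensor range sanity bound


@dataclass
class Recording:
    """Four synchronized acceleration channels in g with a start clock time.

    ``data`` is an ``(n, 4)`` float array whose columns follow
    :data:`CHANNELS`.
    """

    subject_id: str
    start_time: datetime
    sampling_rate: float
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(CHANNELS):
            raise ValidationError(
                f"data must be (n, {len(CHANNELS)}), got shape {self.data.shape}"
            )
        if self.data.shape[0] < 1:
            raise ValidationError("recording must contain at least one sample")
        if not (self.sampling_rate > 0):
            raise ValidationError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("recording contains non-finite values")
        peak = float(np.max(np.abs(self.data)))
        if peak > MAX_ABS_G:
            raise ValidationError(
                f"|value| exceeds {MAX_ABS_G} g (max {peak:.3f} g) - wrong units?"
            )
        if not isinstance(self.start_time, datetime):
            raise ValidationError("start_time must be a datetime")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[:, CHANNELS.index(name)]
        except ValueError:
            raise KeyError(name) from None

    def time_at(self, i: int) -> datetime:
        """Timestamp of sample ``i`` on the grid start + i / rate."""
        return self.start_time + timedelta(seconds=i / self.sampling_rate)


# ---------------------------------------------------------------------------
# Recording CSV


def _parse_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    return meta


def read_recording(
    path: str | Path,
    format: str = "csv",
    *,
    sampling_rate: float | None = None,
    start_time: datetime | str | None = None,
    unit: str = "g",
) -> Recording:
    """Read a recording from ``path``.

    ``sampling_rate``/``start_time`` override (or supply, if absent) the
    file metadata.  ``unit="ms2"`` divides values by 9.81.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "edf":
        return _read_edf(path, unit=unit)
    if format != "csv":
        raise FormatError(f"unknown recording format: {format!r}")

    meta = _parse_metadata(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # malformed beyond repair
        raise ParseError(f"cannot parse CSV {path}: {exc}") from exc

    missing = [c for c in CHANNELS if c not in df.columns]
    if missing:
        raise FormatError(f"missing channel column(s): {', '.join(missing)} in {path}")
    df = df[list(CHANNELS)]

    for col in CHANNELS:
        series = df[col]
        if series.dtype == object:
            coerced = pd.to_numeric(series, errors="coerce")
            bad = coerced.isna() & series.notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ParseError(
                    f"non-numeric value {series.iloc[row]!r} in column {col},"
                    f" data row {row}",
                    row=row,
                )
            df[col] = coerced
        if df[col].isna().any():
            row = int(np.flatnonzero(df[col].isna().to_numpy())[0])
            raise ValidationError(
                f"missing value in column {col}, data row {row} (length mismatch?)"
            )

    rate = sampling_rate
    if rate is None:
        if "sampling_rate" not in meta:
            raise FormatError(f"sampling_rate missing from metadata of {path}")
        rate = float(meta["sampling_rate"])
    if start_time is None:
        if "start_time" not in meta:
            raise FormatError(f"start_time missing from metadata of {path}")
        start_time = meta["start_time"]
    if isinstance(start_time, str):
        start_time = datetime.fromisoformat(start_time)

    values = df.to_numpy(dtype=float)
    if unit == "ms2":
        values = values / STANDARD_GRAVITY
    elif unit != "g":
        raise ValidationError(f"unknown unit {unit!r} (expected 'g' or 'ms2')")

    return Recording(
        subject_id=meta.get("subject_id", "unknown"),
        start_time=start_time,
        sampling_rate=float(rate),
        data=values,
    )


def write_recording(recording: Recording, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# somnapose-recording v1\n")
        fh.write(f"# subject_id={recording.subject_id}\n")
        fh.write(f"# start_time={recording.start_time.isoformat()}\n")
        fh.write(f"# sampling_rate={recording.sampling_rate:g}\n")
        pd.DataFrame(recording.data, columns=list(CHANNELS)).to_csv(
            fh, index=False, float_format="%.12g"
        )


def _read_edf(path: Path, unit: str = "g") -> Recording:
    try:
        import pyedflib  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise FormatError(
            "EDF support requires the optional 'pyedflib' dependency"
        ) from exc
    with pyedflib.EdfReader(str(path)) as reader:  # pragma: no cover
        labels = reader.getSignalLabels()
        missing = [c for c in CHANNELS if c not in labels]
        if missing:
            raise FormatError(f"missing channel(s) in EDF: {', '.join(missing)}")
        idx = [labels.index(c) for c in CHANNELS]
        rates = {reader.getSampleFrequency(i) for i in idx}
        if len(rates) != 1:
            raise ValidationError("EDF channels have differing sampling rates")
        data = np.column_stack([reader.readSignal(i) for i in idx])
        if unit == "ms2":
            data = data / STANDARD_GRAVITY
        return Recording(
            subject_id=reader.getPatientCode() or "unknown",
            start_time=reader.getStartdatetime(),
            sampling_rate=float(rates.pop()),
            data=data,
        )


# ---------------------------------------------------------------------------
# Segment tables

SEGMENT_COLUMNS = ("start", "end", "duration_s", "mean_angle_deg", "label")


def write_segments(segments: Sequence, path: str | Path) -> None:
    """Write posture segments as CSV (timestamps ISO-8601, angles in deg)."""
    prev_end = None
    for seg in segments:
        if seg.start >= seg.end:
            raise ValidationError(f"segment with start >= end: {seg}")
        if prev_end is not None and seg.start < prev_end:
            raise ValidationError("segments must be ordered and non-overlapping")
        prev_end = seg.end
    rows = [
        {
            "start": seg.start.isoformat(),
            "end": seg.end.isoformat(),
            "duration_s": (seg.end - seg.start).total_seconds(),
            "mean_angle_deg": seg.mean_angle_deg,
            "label": seg.label,
        }
        for seg in segments
    ]
    pd.DataFrame(rows, columns=list(SEGMENT_COLUMNS)).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_segments(path: str | Path):
    from .orientation import LABELS, PostureSegment

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing segment column(s): {', '.join(missing)}")
    out = []
    for i, row in df.iterrows():
        if row["label"] not in LABELS:
            raise ValidationError(f"unknown posture label {row['label']!r} in row {i}")
        out.append(
            PostureSegment(
                start=datetime.fromisoformat(row["start"]),
                end=datetime.fromisoformat(row["end"]),
                mean_angle_deg=float(row["mean_angle_deg"]),
                label=str(row["label"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Night summaries


def _summary_to_dict(summary) -> dict:
    d = dataclasses.asdict(summary)
    for k, v in d.items():
        if isinstance(v, float) and math.isnan(v):
            d[k] = None
    return d


def write_summary(
    summary, path: str | Path, format: str = "json", thresholds=None
) -> None:
    """Write a night summary as JSON (default) or a one-row CSV."""
    d = _summary_to_dict(summary)
    if thresholds is not None:
        d["_thresholds"] = thresholds.to_dict()
    if format == "json":
        Path(path).write_text(json.dumps(d, indent=2, default=str) + "\n")
    elif format == "csv":
        flat = dict(d)
        fractions = flat.pop("posture_fractions", None)
        flat.pop("_thresholds", None)
        if fractions:
            for lab, frac in fractions.items():
                flat[f"posture_fraction_{lab}"] = frac
        pd.DataFrame([flat]).to_csv(path, index=False, float_format="%.12g")
    else:
        raise FormatError(f"unknown summary format: {format!r}")


def read_summary(path: str | Path):
    from .indices import NightSummary

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    d = json.loads(path.read_text())
    d.pop("_thresholds", None)
    valid = {f.name for f in dataclasses.fields(NightSummary)}
    unknown = set(d) - valid
    if unknown:
        raise FormatError(f"unknown summary field(s): {sorted(unknown)}")
    return NightSummary(**d)
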