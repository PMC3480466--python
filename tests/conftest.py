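import math
from datetime import datetime, timedelta

import numpy as np
import pytest

from somnapose import Thresholds
from somnapose.windowing import WindowFeatures

NIGHT_T0 = datetime(2024, 3, 1, 22, 0, 0)


@pytest.fixture
def thresholds():
    return Thresholds()


def _median_for(label: str, angle_deg: float | None) -> np.ndarray:
    if label == "lying":
        a = math.radians(angle_deg if angle_deg is not None else 180.0)
        return np.array([0.0, math.cos(a), math.sin(a), math.cos(a)])
    if label == "sitting":
        return np.array([1.0, 0.0, 0.0, 1.0])
    return np.array([1.0, 0.0, 0.0, 0.0])


def build_windows(entries, start=NIGHT_T0, window_s=5.0):
    """Build a labeled window sequence from (label, angle_deg, activity)
    triples; the building block for index-level tests."""
    out = []
    for i, (label, angle, activity) in enumerate(entries):
        f = WindowFeatures(
            start_time=start + timedelta(seconds=i * window_s),
            duration_s=window_s,
            median_g=_median_for(label, angle),
            sd_g=np.zeros(4),
            activity=float(activity),
        )
        out.append((f, label))
    return out


def repeat(label, angle, activity, n):
    return [(label, angle, activity)] * n


@pytest.fixture
def make_windows():
    return build_windows
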