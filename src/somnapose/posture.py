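"""Hierarchical two-split posture tree and cross-validated threshold fitting.

The tree decides on window gravity medians only.  First split: the window
is *lying* when the torso is far from upright, i.e. the magnitude of the
vertical-axis gravity median is below ``vertical_g`` (0.66 g, equivalent
to a torso deviation beyond ~48.7 degrees).  Second split, on non-lying
windows: *sitting* when the thigh antero-posterior gravity magnitude is
above ``thigh_g`` (0.5 g), else *upright* (standing/walking, which the
method does not distinguish).  Both inequalities are strict; boundary
values fall to upright/standing.

The magnitude form of the vertical rule is deliberate: it reproduces the
intended geometry for either mounting polarity of the sternum sensor.
A signed convention can be pinned via ``Thresholds.vertical_sign``.
"""

from __future__ import annotations

import warnings

import numpy as np

from .config import Thresholds, in_night_window
from .errors import FittingError, ValidationError
from .signal_io import Recording
from .windowing import WindowFeatures, window_features

__all__ = [
    "LYING",
    "SITTING",
    "UPRIGHT",
    "COARSE_LABELS",
    "classify_window",
    "classify_medians",
    "classify_recording",
    "fit_thresholds",
]

LYING = "lying"
SITTING = "sitting"
UPRIGHT = "upright"
COARSE_LABELS = (LYING, SITTING, UPRIGHT)

_VERT, _THIGH = 0, 3  # channel indices into the median vector


def _vertical_is_lying(vertical_median: np.ndarray, thresholds: Thresholds):
    if thresholds.vertical_sign == "abs":
        return np.abs(vertical_median) < thresholds.vertical_g
    if thresholds.vertical_sign == "up_positive":
        return vertical_median < thresholds.vertical_g
    return vertical_median > -thresholds.vertical_g  # up_negative


def classify_medians(medians: np.ndarray, thresholds: Thresholds) -> np.ndarray:
    """Vectorized tree over an ``(n, 4)`` array of gravity medians."""
    medians = np.asarray(medians, dtype=float)
    if medians.ndim == 1:
        medians = medians[None, :]
    if not np.all(np.isfinite(medians)):
        raise ValidationError("gravity medians must be finite")
    lying = _vertical_is_lying(medians[:, _VERT], thresholds)
    sitting = np.abs(medians[:, _THIGH]) > thresholds.thigh_g
    out = np.where(lying, LYING, np.where(sitting, SITTING, UPRIGHT))
    return out


def classify_window(features: WindowFeatures, thresholds: Thresholds) -> str:
    """Classify one window as lying / sitting / upright from its medians."""
    return str(classify_medians(features.median_g, thresholds)[0])


def classify_recording(
    recording: Recording,
    thresholds: Thresholds | None = None,
    window_s: float = 5.0,
    step_s: float | None = None,
    night_only: bool = True,
) -> list[tuple[WindowFeatures, str]]:
    """Window the recording and classify every (night) window.

    Windows are restricted to the configured night window by their start
    clock time; an empty result outside the window triggers a warning.
    """
    thresholds = thresholds or Thresholds()
    feats = window_features(recording, window_s=window_s, step_s=step_s)
    if night_only:
        feats = [
            f
            for f in feats
            if in_night_window(f.start_time, thresholds.night_start, thresholds.night_end)
        ]
    if not feats:
        warnings.warn(
            "no windows fall inside the configured night window", stacklevel=2
        )
        return []
    medians = np.stack([f.median_g for f in feats])
    labels = classify_medians(medians, thresholds)
    return list(zip(feats, (str(l) for l in labels)))


# ---------------------------------------------------------------------------
# Threshold fitting by 10-fold cross-validation


def _candidate_midpoints(values: np.ndarray) -> np.ndarray:
    """Midpoints between sorted unique values, plus outside sentinels."""
    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.empty(0)
    return np.concatenate(([uniq[0] - 1e-9], mids, [uniq[-1] + 1e-9]))


def _fit_split(values: np.ndarray, positive: np.ndarray, direction: str) -> float:
    """Best threshold c maximizing accuracy of (values < c) or (values > c)."""
    best_c, best_acc = float(values[0]), -1.0
    for c in _candidate_midpoints(values):
        pred = values < c if direction == "lt" else values > c
        acc = float(np.mean(pred == positive))
        if acc > best_acc:
            best_acc, best_c = acc, float(c)
    return best_c


def _fit_tree(medians: np.ndarray, labels: np.ndarray, base: Thresholds) -> Thresholds:
    v = np.abs(medians[:, _VERT])
    th = np.abs(medians[:, _THIGH])
    is_lying = labels == LYING
    vertical_g = _fit_split(v, is_lying, "lt")
    nonlying = ~is_lying
    if np.any(nonlying) and len(np.unique(labels[nonlying])) > 1:
        thigh_g = _fit_split(th[nonlying], labels[nonlying] == SITTING, "gt")
    else:
        thigh_g = base.thigh_g
    # A fitted split can legitimately sit at 0 - epsilon; clamp into validity.
    return base.replace(vertical_g=max(vertical_g, 1e-9), thigh_g=max(thigh_g, 1e-9))


def fit_thresholds(
    labeled: list[tuple[WindowFeatures, str]],
    folds: int = 10,
    seed: int = 0,
    base: Thresholds | None = None,
) -> tuple[Thresholds, float]:
    """Fit the two tree splits by exhaustive midpoint search with k-fold CV.

    Returns thresholds refit on all data and the mean held-out accuracy.
    Fold assignment is a seeded shuffle, so results are deterministic per
    seed.
    """
    base = base or Thresholds()
    n = len(labeled)
    if folds < 2:
        raise FittingError("need at least 2 folds")
    if n < folds:
        raise FittingError(f"need at least {folds} labeled windows, got {n}")
    labels = np.array([lab for _, lab in labeled])
    bad = set(labels) - set(COARSE_LABELS)
    if bad:
        raise FittingError(f"unknown label(s): {sorted(bad)}")
    if len(np.unique(labels)) < 2:
        raise FittingError("need at least two classes to fit thresholds")
    medians = np.stack([f.median_g for f, _ in labeled])

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_ids = np.arange(n) % folds  # balanced folds over the shuffled order
    accs = []
    for k in range(folds):
        test_idx = order[fold_ids == k]
        train_idx = order[fold_ids != k]
        if len(np.unique(labels[train_idx])) < 2:
            continue  # degenerate fold; skip rather than fit a one-class tree
        fitted = _fit_tree(medians[train_idx], labels[train_idx], base)
        pred = classify_medians(medians[test_idx], fitted)
        accs.append(float(np.mean(pred == labels[test_idx])))
    if not accs:
        raise FittingError("every fold was single-class; cannot cross-validate")
    final = _fit_tree(medians, labels, base)
    return final, float(np.mean(accs))
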