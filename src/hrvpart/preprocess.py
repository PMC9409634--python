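"""From raw signal to a clean NN-interval series.

The chain is: QRS detection on a single-lead ECG (second-derivative
energy detector), automatic artifact/ectopy rejection on the RR series,
and selection of a fixed-length contiguous segment (300 beats by
default) for index computation.

Artifact rejection is rule-based rather than manual: an interval is kept
only if it lies inside an absolute physiological band and within a
relative tolerance of the running median of the last accepted beats.
Rejected intervals are dropped, never interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter1d

from .errors import DataQualityError, ParameterError

__all__ = ["NNSeries", "detect_qrs", "clean_rr", "select_segment"]


@dataclass
class NNSeries:
    """A cleaned sequence of sinus-beat (NN) intervals in milliseconds."""

    intervals: np.ndarray
    posture: str | None = None  # "supine" | "standing"
    subject_id: str | None = None
    n_removed: int = 0

    def __post_init__(self):
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.posture not in (None, "supine", "standing"):
            raise ParameterError(f"unknown posture {self.posture!r}")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def beat_times_s(self) -> np.ndarray:
        """Cumulative end-time of each interval, in seconds."""
        return np.cumsum(self.intervals) / 1000.0


def detect_qrs(
    ecg,
    fs: float,
    smooth_ms: float = 10.0,
    stencil_ms: float = 20.0,
    threshold_frac: float = 0.4,
    window_s: float = 2.0,
    refractory_ms: float = 200.0,
) -> np.ndarray:
    """Locate R waves with a second-derivative energy detector.

    Pipeline: moving-average smoothing -> discrete second derivative on
    a stencil scaled to QRS width (``s[i-k] - 2 s[i] + s[i+k]`` with
    ``k = stencil_ms``), which keeps the sharp R deflection while
    rejecting sample-level noise -> squared magnitude -> adaptive
    threshold (``threshold_frac`` of the running maximum over a
    ``window_s`` window) -> refractory-period suppression keeping the
    strongest candidate per burst.

    Returns R-wave sample indices; an empty array (with a warning) when
    nothing crosses threshold.
    """
    ecg = np.asarray(ecg, dtype=float)
    if fs < 100:
        raise ParameterError(f"sampling rate must be >= 100 Hz, got {fs}")
    if len(ecg) < 2 * fs:
        raise ParameterError("ECG shorter than 2 s")

    win = max(1, int(round(smooth_ms / 1000.0 * fs)))
    kernel = np.ones(win) / win
    smooth = np.convolve(ecg, kernel, mode="same")
    k = max(1, int(round(stencil_ms / 1000.0 * fs)))
    d2 = np.zeros_like(smooth)
    d2[k:-k] = smooth[2 * k :] - 2 * smooth[k:-k] + smooth[: -2 * k]
    feature = d2 * d2

    wlen = max(1, int(round(window_s * fs)))
    running_max = maximum_filter1d(feature, size=wlen, mode="nearest")
    thresh = threshold_frac * running_max
    above = feature > np.maximum(thresh, 1e-12 * feature.max() if feature.max() > 0 else 0)

    if not above.any():
        warnings.warn("detect_qrs: no beats found", stacklevel=2)
        return np.array([], dtype=int)

    refr = max(1, int(round(refractory_ms / 1000.0 * fs)))
    candidates = np.flatnonzero(above)
    peaks: list[int] = []
    # greedy left-to-right: within each supra-threshold burst keep the
    # feature maximum, then suppress anything inside the refractory span
    i = 0
    while i < len(candidates):
        j = i
        while j + 1 < len(candidates) and candidates[j + 1] - candidates[j] <= 1:
            j += 1
        burst = candidates[i : j + 1]
        peak = burst[np.argmax(feature[burst])]
        if not peaks or peak - peaks[-1] >= refr:
            peaks.append(int(peak))
        elif feature[peak] > feature[peaks[-1]]:
            peaks[-1] = int(peak)
        i = j + 1
    return np.asarray(peaks, dtype=int)


def rr_from_beats(beat_indices: np.ndarray, fs: float) -> np.ndarray:
    """Successive beat-index differences converted to milliseconds."""
    beat_indices = np.asarray(beat_indices)
    return np.diff(beat_indices) / fs * 1000.0


def clean_rr(
    raw_rr,
    lo_ms: float = 300.0,
    hi_ms: float = 2000.0,
    rel_tol: float = 0.20,
    median_window: int = 5,
    max_removed_frac: float = 0.20,
    subject_id: str | None = None,
    posture: str | None = None,
) -> NNSeries:
    """Reject artifact/ectopic intervals from a raw RR series.

    An interval is accepted when it lies in ``[lo_ms, hi_ms]`` and
    deviates at most ``rel_tol`` from the median of the previous
    ``median_window`` accepted intervals (no relative test until one
    interval has been accepted).  Rejected intervals are dropped.

    Raises :class:`DataQualityError` when more than
    ``max_removed_frac`` of the input is rejected.
    """
    raw = np.asarray(raw_rr, dtype=float)
    if len(raw) < 2:
        raise ParameterError("clean_rr needs at least 2 intervals")

    accepted: list[float] = []
    for v in raw:
        if not (lo_ms <= v <= hi_ms):
            continue
        if accepted:
            ref = float(np.median(accepted[-median_window:]))
            if abs(v - ref) > rel_tol * ref:
                continue
        accepted.append(float(v))

    n_removed = len(raw) - len(accepted)
    if n_removed > max_removed_frac * len(raw):
        name = subject_id or "<unnamed series>"
        raise DataQualityError(
            f"{name}: {n_removed}/{len(raw)} intervals removed "
            f"(> {max_removed_frac:.0%} quality limit)"
        )
    return NNSeries(
        np.asarray(accepted), posture=posture, subject_id=subject_id, n_removed=n_removed
    )


def select_segment(nn: NNSeries, n: int = 300, skip: int = 0) -> NNSeries:
    """Contiguous ``n`` intervals starting after ``skip`` accepted beats."""
    if skip < 0 or n < 1:
        raise ParameterError("skip must be >= 0 and n >= 1")
    if len(nn) < skip + n:
        raise ParameterError(
            f"need {skip + n} intervals (skip={skip}, n={n}), have {len(nn)}"
        )
    return NNSeries(
        nn.intervals[skip : skip + n],
        posture=nn.posture,
        subject_id=nn.subject_id,
        n_removed=nn.n_removed,
    )
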