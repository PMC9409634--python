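"""The eleven HRV indices and their supine-minus-standing deltas.

Time domain: meanNN, SDNN (n-1 denominator), RMSSD, pNN20 (successive
absolute differences strictly greater than 20 ms).

Frequency domain: the tachogram (interval value located at its
cumulative end-time) is linearly resampled at 3 Hz, mean-removed, and a
Welch periodogram is integrated over the LF band [0.04, 0.15) Hz and the
HF band [0.15, 0.4] Hz.  LFn = 100*LF/(LF+HF), HFn its complement, plus
the LF/HF ratio.

Nonlinear: the short-term detrended-fluctuation exponent alpha1 over box
sizes 4-11 beats (order-1 detrending, non-overlapping boxes) and sample
entropy SampEn(m=2, r=0.2*SD, Chebyshev distance, self-matches
excluded).

Plain order-1 DFA restricted to boxes of 4-11 samples has a known
finite-size bias (a white-noise input reads ~0.62, not 0.5).  The
estimator therefore applies the modified-DFA correction by default:
F(s) is divided by the closed-form white-noise expectation
sqrt(E[F^2(s)]/s), which is computable exactly from the detrending
projector, so that an uncorrelated series reads 0.5 in expectation.
Pass ``corrected=False`` for the classic uncorrected estimator.

Indices that are undefined for an input (constant series, empty band
power) are flagged with NaN; NaN propagates through deltas.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from functools import lru_cache

import numpy as np
from scipy import signal

from .errors import ParameterError, SubjectMismatchError
from .preprocess import NNSeries

__all__ = [
    "HRVIndexSet",
    "DeltaIndexSet",
    "SpectralEstimate",
    "time_domain",
    "resample_tachogram",
    "spectral_indices",
    "dfa_alpha1",
    "sampen",
    "hrv_indices",
    "delta",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

INDEX_NAMES = (
    "mean_nn",
    "sdnn",
    "rmssd",
    "pnn20",
    "lf",
    "hf",
    "lfn",
    "hfn",
    "lf_hf",
    "alpha1",
    "sampen",
)


@dataclass
class HRVIndexSet:
    """The 11 indices for one NN series (ms, ms², n.u., dimensionless)."""

    mean_nn: float
    sdnn: float
    rmssd: float
    pnn20: float
    lf: float
    hf: float
    lfn: float
    hfn: float
    lf_hf: float
    alpha1: float
    sampen: float
    subject_id: str | None = None
    posture: str | None = None

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in INDEX_NAMES}


@dataclass
class DeltaIndexSet:
    """Supine minus standing, per index, same units as the index."""

    d_mean_nn: float
    d_sdnn: float
    d_rmssd: float
    d_pnn20: float
    d_lf: float
    d_hf: float
    d_lfn: float
    d_hfn: float
    d_lf_hf: float
    d_alpha1: float
    d_sampen: float
    subject_id: str | None = None

    @property
    def d_mean_nn_s(self) -> float:
        """Delta of meanNN expressed in seconds (reporting convention)."""
        return self.d_mean_nn / 1000.0

    def as_dict(self) -> dict:
        return {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if f.name != "subject_id"
        }


@dataclass
class SpectralEstimate:
    """Welch PSD of the resampled tachogram plus its provenance."""

    frequencies: np.ndarray
    psd: np.ndarray
    resample_rate: float
    nperseg: int
    noverlap: int
    window: str


def time_domain(nn: NNSeries | np.ndarray) -> tuple[float, float, float, float]:
    """(meanNN, SDNN, RMSSD, pNN20) of an NN series.

    SDNN is the sample standard deviation (n-1); pNN20 counts successive
    absolute differences strictly greater than 20 ms.
    """
    x = _intervals(nn)
    if len(x) < 2:
        raise ParameterError("time_domain needs at least 2 intervals")
    diffs = np.diff(x)
    mean_nn = float(np.mean(x))
    sdnn = float(np.std(x, ddof=1))
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    pnn20 = float(100.0 * np.count_nonzero(np.abs(diffs) > 20.0) / len(diffs))
    return mean_nn, sdnn, rmssd, pnn20


def resample_tachogram(
    nn: NNSeries | np.ndarray, rate: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Evenly resample the tachogram by linear interpolation.

    Each interval is located at its cumulative end-time; the uniform
    grid is anchored at the first beat's end-time and spans to the last
    beat time.  Returns ``(grid_times_s, values_ms)``.
    """
    x = _intervals(nn)
    if len(x) < 2:
        raise ParameterError("resample_tachogram needs at least 2 intervals")
    if rate <= 0:
        raise ParameterError("rate must be positive")
    t = np.cumsum(x) / 1000.0
    n_grid = int(np.floor((t[-1] - t[0]) * rate)) + 1
    grid = t[0] + np.arange(n_grid) / rate
    return grid, np.interp(grid, t, x)


def spectral_indices(
    nn: NNSeries | np.ndarray,
    rate: float = 3.0,
    nperseg: int = 256,
    window: str = "hann",
    min_duration_s: float = 64.0,
    band_mean: bool = False,
) -> tuple[float, float, float, float, float, SpectralEstimate]:
    """(LF, HF, LFn, HFn, LF/HF, spectrum) from the resampled tachogram.

    Band values are integrated PSD (ms²) by default; ``band_mean=True``
    reports the mean PSD level over each band instead.  Normalized units
    and the ratio are NaN-flagged when their denominator is zero.
    """
    grid, values = resample_tachogram(nn, rate)
    if grid[-1] - grid[0] < min_duration_s:
        raise ParameterError(
            f"need >= {min_duration_s} s of resampled data, have {grid[-1] - grid[0]:.1f} s"
        )
    nper = min(nperseg, len(values))
    freqs, psd = signal.welch(
        values - values.mean(),
        fs=rate,
        window=window,
        nperseg=nper,
        noverlap=nper // 2,
        detrend="constant",
    )
    lf = _band_value(freqs, psd, LF_BAND, closed_right=False, mean=band_mean)
    hf = _band_value(freqs, psd, HF_BAND, closed_right=True, mean=band_mean)
    total = lf + hf
    if total > 0:
        lfn = 100.0 * lf / total
        hfn = 100.0 * hf / total
    else:
        lfn = hfn = float("nan")
    lf_hf = lf / hf if hf > 0 else float("nan")
    est = SpectralEstimate(freqs, psd, rate, nper, nper // 2, window)
    return lf, hf, lfn, hfn, lf_hf, est


def _band_value(freqs, psd, band, closed_right: bool, mean: bool) -> float:
    lo, hi = band
    mask = (freqs >= lo) & ((freqs <= hi) if closed_right else (freqs < hi))
    if mask.sum() < 2:
        return 0.0
    if mean:
        return float(np.mean(psd[mask]))
    return float(np.trapezoid(psd[mask], freqs[mask]))


@lru_cache(maxsize=64)
def _white_noise_ef2(s: int) -> float:
    """Exact E[F²(s)] of order-1 DFA applied to unit-variance white noise.

    The integrated profile of white noise inside a box has covariance
    C_ij = min(i, j) + 1; with H the residual-maker of the per-box linear
    fit, E[F²] = tr(H C Hᵀ)/s.
    """
    t = np.arange(s, dtype=float)
    A = np.column_stack([t, np.ones(s)])
    H = np.eye(s) - A @ np.linalg.solve(A.T @ A, A.T)
    C = np.minimum.outer(np.arange(s), np.arange(s)) + 1.0
    return float(np.trace(H @ C @ H.T) / s)


def dfa_alpha1(
    nn: NNSeries | np.ndarray,
    scales: range | tuple = range(4, 12),
    corrected: bool = True,
) -> float:
    """Short-term detrended-fluctuation exponent over box sizes 4-11.

    Integrate the mean-subtracted series, split into non-overlapping
    boxes per scale (remainder discarded), detrend each box with a
    least-squares line, take the RMS residual F(s), and return the
    least-squares slope of log F(s) vs log s.  With ``corrected=True``
    (default) each F(s) is divided by the analytic white-noise
    expectation so the estimator is unbiased at these short scales.

    Returns NaN for a constant input (zero fluctuation).
    """
    x = _intervals(nn)
    scales = tuple(scales)
    if len(x) < 100:
        raise ParameterError("dfa_alpha1 needs at least 100 intervals")
    y = np.cumsum(x - x.mean())
    log_f = []
    for s in scales:
        nb = len(y) // s
        boxes = y[: nb * s].reshape(nb, s).T  # (s, nb)
        t = np.arange(s, dtype=float)
        A = np.column_stack([t, np.ones(s)])
        coef, *_ = np.linalg.lstsq(A, boxes, rcond=None)
        resid = boxes - A @ coef
        f2 = float(np.mean(resid**2))
        if f2 <= 0:
            return float("nan")
        if corrected:
            f2 *= s / _white_noise_ef2(s)
        log_f.append(0.5 * np.log(f2))
    slope = np.polyfit(np.log(scales), log_f, 1)[0]
    return float(slope)


def sampen(
    nn: NNSeries | np.ndarray, m: int = 2, r_factor: float = 0.2
) -> float:
    """Sample entropy with tolerance r = r_factor * sample SD.

    B counts ordered template pairs (i != j) of length m within
    Chebyshev distance r, A the same for length m+1; both use the same
    N-m template start positions (Richman-Moorman convention) and
    SampEn = -ln(A/B).  NaN-flagged when r = 0 or either count is zero.
    """
    x = _intervals(nn)
    if len(x) < m + 2:
        raise ParameterError(f"sampen needs at least {m + 2} intervals")
    sd = np.std(x, ddof=1)
    if sd == 0:
        return float("nan")
    r = r_factor * sd
    a, b = _sampen_counts(x, m, r)
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))


def _sampen_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Ordered-pair match counts (A for m+1, B for m), vectorized."""
    n = len(x)
    n_templates = n - m
    tm = np.lib.stride_tricks.sliding_window_view(x, m)[:n_templates]
    tm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:n_templates]
    b = _chebyshev_pairs(tm, r)
    a = _chebyshev_pairs(tm1, r)
    return a, b


def _chebyshev_pairs(templates: np.ndarray, r: float) -> int:
    n = len(templates)
    count = 0
    for i in range(n):
        d = np.max(np.abs(templates - templates[i]), axis=1)
        count += int(np.count_nonzero(d <= r)) - 1  # exclude self-match
    return count


def hrv_indices(
    nn: NNSeries,
    sampen_m: int = 2,
    sampen_r_factor: float = 0.2,
    dfa_corrected: bool = True,
    **spectral_kwargs,
) -> HRVIndexSet:
    """All 11 indices for one series."""
    mean_nn, sdnn, rmssd, pnn20 = time_domain(nn)
    lf, hf, lfn, hfn, lf_hf, _ = spectral_indices(nn, **spectral_kwargs)
    alpha1 = dfa_alpha1(nn, corrected=dfa_corrected)
    se = sampen(nn, m=sampen_m, r_factor=sampen_r_factor)
    return HRVIndexSet(
        mean_nn, sdnn, rmssd, pnn20, lf, hf, lfn, hfn, lf_hf, alpha1, se,
        subject_id=getattr(nn, "subject_id", None),
        posture=getattr(nn, "posture", None),
    )


def delta(supine: HRVIndexSet, standing: HRVIndexSet) -> DeltaIndexSet:
    """Element-wise supine minus standing; NaN flags propagate."""
    if supine.subject_id != standing.subject_id:
        raise SubjectMismatchError(
            f"subject mismatch: {supine.subject_id!r} vs {standing.subject_id!r}"
        )
    diffs = {
        f"d_{name}": getattr(supine, name) - getattr(standing, name)
        for name in INDEX_NAMES
    }
    return DeltaIndexSet(**diffs, subject_id=supine.subject_id)


def _intervals(nn) -> np.ndarray:
    if isinstance(nn, NNSeries):
        return nn.intervals
    return np.asarray(nn, dtype=float)
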