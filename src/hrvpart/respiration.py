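"""Mean breathing frequency (MBF) from a respiration waveform.

MBF is the frequency of maximum power in the discrete Fourier spectrum
of the mean-removed signal, searched inside a physiological band
(default 0.05-1.0 Hz) to keep baseline drift and DC out of the argmax.
A single whole-record periodogram is used (no segment averaging), so
the resolution is fs/N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

__all__ = ["RespEstimate", "mbf"]


@dataclass
class RespEstimate:
    mbf: float  # Hz; NaN when undefined (all-zero signal)
    resolution: float  # frequency-bin width, Hz
    band: tuple[float, float]
    fs: float
    n_samples: int


def mbf(
    resp,
    fs: float = 25.0,
    band: tuple[float, float] = (0.05, 1.0),
    min_duration_s: float = 60.0,
) -> RespEstimate:
    x = np.asarray(resp, dtype=float)
    if fs <= 0:
        raise ParameterError("fs must be positive")
    if len(x) == 0:
        raise ParameterError("empty respiration signal")
    if len(x) / fs < min_duration_s:
        raise ParameterError(
            f"need >= {min_duration_s} s of respiration, have {len(x) / fs:.1f} s"
        )
    lo, hi = band
    if not (0 < lo < hi <= fs / 2):
        raise ParameterError(f"search band {band} must lie in (0, fs/2]")

    spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    mask = (freqs >= lo) & (freqs <= hi)
    resolution = fs / len(x)
    if not mask.any() or spec[mask].max() == 0:
        peak = float("nan")
    else:
        peak = float(freqs[mask][np.argmax(spec[mask])])
    return RespEstimate(peak, resolution, (lo, hi), fs, len(x))
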