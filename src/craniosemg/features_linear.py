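"""Linear time-domain and frequency-domain sEMG features.

Time-domain features are computed on 100-ms burst-centered segments and
averaged across segments:

- MAV:  mean absolute value, (1/N) * sum |x_i|
- WL:   waveform length, sum |x_{i+1} - x_i|
- ZR:   zero crossings with a deadband threshold (sign change AND
        |x_i - x_{i+1}| >= thr), suppressing noise-induced crossings
- SSC:  slope sign changes with the same deadband
        ((x_i - x_{i-1})(x_i - x_{i+1}) > 0 AND the larger adjacent
        excursion >= thr)

The deadband defaults to 4 gained mV (4 uV p-p intrinsic system noise
x 2000 gain / 2); when the signal is in %MVC the caller converts the
threshold by the per-channel MVC reference.

The frequency-domain feature is the mean power spectral frequency (MNF),
the power-weighted mean of a Welch spectrum (100-ms, 50%-overlap Hamming
windows, 1024-point FFT), computed on the full preprocessed signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .config import WelchConfig

__all__ = [
    "mav",
    "waveform_length",
    "zero_crossings",
    "slope_sign_changes",
    "segment_average",
    "welch_psd",
    "mean_frequency",
    "Spectrum",
]


def mav(segment: np.ndarray) -> float:
    """Mean absolute value of the segment."""
    x = np.asarray(segment, dtype=float)
    if x.size == 0:
        raise ValueError("empty segment")
    return float(np.mean(np.abs(x)))


def waveform_length(segment: np.ndarray) -> float:
    """Cumulative absolute sample-to-sample excursion."""
    x = np.asarray(segment, dtype=float)
    if x.size < 2:
        raise ValueError("waveform length requires >= 2 samples")
    return float(np.sum(np.abs(np.diff(x))))


def zero_crossings(segment: np.ndarray, threshold: float) -> int:
    """Count zero crossings exceeding the deadband threshold."""
    x = np.asarray(segment, dtype=float)
    if x.size < 2:
        return 0
    a, b = x[:-1], x[1:]
    crossing = np.sign(a) != np.sign(b)
    big = np.abs(a - b) >= threshold
    return int(np.count_nonzero(crossing & big))


def slope_sign_changes(segment: np.ndarray, threshold: float) -> int:
    """Count slope sign changes whose larger adjacent excursion exceeds
    the deadband threshold."""
    x = np.asarray(segment, dtype=float)
    if x.size < 3:
        raise ValueError("slope sign changes require >= 3 samples")
    prev = x[1:-1] - x[:-2]
    nxt = x[1:-1] - x[2:]
    extremum = prev * nxt > 0
    big = np.maximum(np.abs(prev), np.abs(nxt)) >= threshold
    return int(np.count_nonzero(extremum & big))


def segment_average(feature_fn, segments) -> float:
    """Unweighted mean of a per-segment feature; NaN when no segments."""
    vals = [feature_fn(seg) for seg in segments]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


@dataclass
class Spectrum:
    """One-sided power spectral density."""

    frequencies: np.ndarray
    power: np.ndarray
    params: dict

    def __post_init__(self):
        f, p = np.asarray(self.frequencies, float), np.asarray(self.power, float)
        if np.any(p < -1e-12):
            raise ValueError("negative power")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        self.frequencies, self.power = f, np.maximum(p, 0.0)


def welch_psd(x: np.ndarray, fs: float, config: WelchConfig | None = None) -> Spectrum:
    """Welch averaged modified periodogram (Hamming taper, one-sided)."""
    config = config or WelchConfig()
    x = np.asarray(x, dtype=float)
    nperseg = int(round(config.window_s * fs))
    if x.size < nperseg:
        raise ValueError(f"signal shorter than one {config.window_s*1e3:.0f}-ms window")
    noverlap = int(round(nperseg * config.overlap))
    f, p = sps.welch(
        x,
        fs=fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=noverlap,
        nfft=max(config.nfft, nperseg),
        detrend=False,
    )
    return Spectrum(
        frequencies=f,
        power=p,
        params={
            "window": nperseg,
            "overlap": config.overlap,
            "nfft": max(config.nfft, nperseg),
            "taper": "hamming",
        },
    )


def mean_frequency(spectrum: Spectrum) -> float:
    """Power-weighted mean frequency; NaN when total power is zero."""
    total = float(np.sum(spectrum.power))
    if total <= 0:
        return float("nan")
    return float(np.sum(spectrum.frequencies * spectrum.power) / total)
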