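"""Myoelectric burst detection and epoch extraction.

DDK syllable repetitions produce trains of myoelectric bursts. The
time-domain features are computed on 100-ms segments centered on these
bursts; recurrence and coherence analyses consume stationary 1-s epochs
centered on the same bursts.

Burst detection itself (envelope, adaptive threshold, merge gap) is this
module's own recipe, with all constants configurable: an RMS envelope
(25-ms moving window) is thresholded at baseline + k*SD above a
low-percentile baseline level, nearby supra-threshold regions are merged,
and each region's envelope argmax is the burst center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import BurstConfig, SegmentConfig
from .signal_io import EmgRecording

__all__ = [
    "BurstSet",
    "EpochSet",
    "NoBurstsError",
    "detect_bursts",
    "extract_epochs",
    "consensus_centers",
]


class NoBurstsError(ValueError):
    """Raised when no usable epoch can be carved from a channel."""


@dataclass
class BurstSet:
    """Per-channel burst center indices (samples)."""

    centers: dict = field(default_factory=dict)  # label -> int array
    params: BurstConfig = field(default_factory=BurstConfig)

    def __getitem__(self, ch: str) -> np.ndarray:
        return self.centers[ch]


@dataclass
class EpochSet:
    """Per-channel fixed-length windows [(start, length), ...]."""

    windows: dict = field(default_factory=dict)  # label -> list of (start, length)
    length: int = 0  # samples

    def __getitem__(self, ch: str):
        return self.windows[ch]

    def slices(self, ch: str):
        return [slice(s, s + n) for s, n in self.windows[ch]]


def _rms_envelope(x: np.ndarray, win: int) -> np.ndarray:
    """Centered moving-window RMS envelope, same length as x."""
    win = max(1, win)
    kernel = np.ones(win) / win
    return np.sqrt(np.convolve(x.astype(float) ** 2, kernel, mode="same"))


def detect_bursts(rec: EmgRecording, params: BurstConfig | None = None) -> BurstSet:
    """Detect burst centers per channel.

    Candidate regions are where the RMS envelope exceeds
    ``baseline + k * SD(baseline)``, with the baseline level taken as a low
    percentile of the envelope and its SD estimated over the sub-median
    envelope samples. Regions closer than the minimum inter-burst gap are
    merged; the burst center is the envelope argmax within each region.
    The threshold is relative, so burst counts are invariant under
    amplitude scaling.
    """
    params = params or BurstConfig()
    win = int(round(params.envelope_window_ms / 1000.0 * rec.fs))
    min_gap = int(round(params.min_gap_ms / 1000.0 * rec.fs))
    centers: dict = {}
    for i, ch in enumerate(rec.channels):
        env = _rms_envelope(rec.signal[i], win)
        base = np.percentile(env, params.baseline_percentile)
        quiet = env[env <= np.percentile(env, params.baseline_region_percentile)]
        sd = float(np.std(quiet)) if quiet.size else 0.0
        thr = base + params.threshold_k * sd
        above = env > thr
        if not above.any() or sd == 0.0:
            centers[ch] = np.array([], dtype=int)
            continue
        # contiguous supra-threshold regions
        idx = np.flatnonzero(above)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        region_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
        region_ends = np.concatenate([idx[breaks], [idx[-1]]])
        # prune sub-minimum-duration blips (noise crossings) before merging
        min_dur = int(round(params.min_duration_ms / 1000.0 * rec.fs))
        long_enough = (region_ends - region_starts + 1) >= min_dur
        if not long_enough.any():
            centers[ch] = np.array([], dtype=int)
            continue
        region_starts = region_starts[long_enough]
        region_ends = region_ends[long_enough]
        # merge regions closer than min_gap
        merged = [[region_starts[0], region_ends[0]]]
        for s, e in zip(region_starts[1:], region_ends[1:]):
            if s - merged[-1][1] < min_gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        # dual-threshold criterion: a genuine burst must also peak well
        # above baseline, rejecting stationary-noise excursions
        peak_thr = base + params.peak_k * sd
        ctrs = []
        for s, e in merged:
            if env[s : e + 1].max() < peak_thr:
                continue
            ctrs.append(s + int(np.argmax(env[s : e + 1])))
        centers[ch] = np.asarray(ctrs, dtype=int)
    return BurstSet(centers=centers, params=params)


def _retile(intervals: list, length: int) -> list:
    """Merge overlapping intervals and re-tile each union into
    non-overlapping windows of ``length`` samples (trailing partial
    stretches dropped unless the union is shorter than one window, in
    which case the union came from a single burst and is kept as-is)."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        n = (e - s) // length
        for k in range(n):
            out.append((s + k * length, length))
    return out


def extract_epochs(
    rec: EmgRecording,
    bursts: BurstSet,
    length_s: float,
    config: SegmentConfig | None = None,
) -> EpochSet:
    """Carve fixed-length windows centered on burst centers.

    Windows that would overrun the signal are dropped (never padded).
    For 1-s epochs, overlapping windows of adjacent bursts are merged into
    their union and re-tiled into non-overlapping epochs, so no sample is
    double-weighted in coherence estimation (configurable off).
    """
    config = config or SegmentConfig()
    n = int(round(length_s * rec.fs))
    half = n // 2
    windows: dict = {}
    for ch in rec.channels:
        ctrs = bursts[ch] if ch in bursts.centers else np.array([], dtype=int)
        raw = []
        for c in ctrs:
            s = int(c) - half
            if s < 0 or s + n > rec.n_samples:
                continue  # clipped: dropped rather than padded
            raw.append((s, s + n))
        if config.merge_overlapping_epochs and length_s >= 0.5:
            windows[ch] = _retile(raw, n)
        else:
            windows[ch] = [(s, n) for s, _ in raw]
    return EpochSet(windows=windows, length=n)


def consensus_centers(bursts: BurstSet, pair: tuple) -> np.ndarray:
    """Union of burst centers across a channel pair (for coherence, both
    channels must share identical epoch windows)."""
    a = bursts.centers.get(pair[0], np.array([], dtype=int))
    b = bursts.centers.get(pair[1], np.array([], dtype=int))
    return np.unique(np.concatenate([a, b]))
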