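"""Recording I/O, MVC normalization, filtering, and crosstalk attenuation.

Signals are stored channels x samples. Raw signals carry hardware gain
(x2000) and are expressed in "gained mV"; after normalization by the
per-channel maximum-voluntary-contraction (MVC) RMS reference they are in
%MVC units (1.0 = MVC-level RMS).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

from .config import CHANNELS, FilterConfig, MvcConfig

__all__ = [
    "EmgRecording",
    "MvcReference",
    "read_recording",
    "write_recording",
    "compute_mvc_reference",
    "normalize_to_mvc",
    "preprocess_filter",
    "attenuate_crosstalk",
]

UNITS = ("mV_gained", "pct_mvc")


@dataclass
class EmgRecording:
    """A multichannel craniofacial sEMG recording.

    Attributes
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Signal matrix in ``units``.
    fs : float
        Sampling rate in Hz.
    channels : tuple of str
        Ordered channel labels, a subset of the canonical six
        (RTEMP, LTEMP, RMAS, LMAS, RSM, LSM).
    units : str
        ``"mV_gained"`` or ``"pct_mvc"``.
    """

    signal: np.ndarray
    fs: float = 2000.0
    channels: tuple = CHANNELS
    units: str = "mV_gained"
    subject_id: str = ""
    task: str = ""
    group: str = "unknown"

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D channels x samples matrix")
        self.channels = tuple(self.channels)
        if len(self.channels) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channels)} labels for {self.signal.shape[0]} signal rows"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.units not in UNITS:
            raise ValueError(f"units must be one of {UNITS}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.signal[self.channels.index(label)]

    def validate(self) -> None:
        """Post-preprocessing invariants: finite samples, >=1 s, fs headroom."""
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains NaN or Inf")
        if self.n_samples < self.fs:
            raise ValueError("recording shorter than 1 s")
        if self.fs < 120.0:
            raise ValueError("fs must exceed twice the highest analysis band (60 Hz)")


@dataclass
class MvcReference:
    """Per-channel MVC RMS reference values (gained mV)."""

    values: dict = field(default_factory=dict)
    n_trials: int = 0
    window_ms: float = 500.0
    stable_interval_s: float = 3.0

    def __post_init__(self):
        for ch, v in self.values.items():
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"MVC reference for channel {ch!r} must be > 0")

    def __getitem__(self, ch: str) -> float:
        return self.values[ch]


# ---------------------------------------------------------------------------
# I/O


def _read_sidecar(meta_path) -> dict:
    meta_path = Path(meta_path)
    text = meta_path.read_text()
    if meta_path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def read_recording(signal_path, meta_path) -> EmgRecording:
    """Read a delimited-text recording with a YAML/JSON metadata sidecar.

    The signal file has one header row of channel labels and one column per
    channel; the sidecar supplies ``fs``, ``units`` and subject metadata.
    Columns are reordered to the canonical channel order.
    """
    meta = _read_sidecar(meta_path)
    for key in ("fs",):
        if key not in meta:
            raise ValueError(f"metadata sidecar missing required field {key!r}")
    fs = float(meta["fs"])
    if fs <= 0:
        raise ValueError(f"invalid fs in sidecar: {fs}")
    sep = "\t" if str(signal_path).endswith(".tsv") else ","
    try:
        df = pd.read_csv(signal_path, sep=sep, float_precision="round_trip")
    except ValueError as exc:
        raise ValueError(f"cannot parse signal file {signal_path}: {exc}") from exc
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        bad = [c for c, dt in df.dtypes.items() if not np.issubdtype(dt, np.number)]
        raise ValueError(f"non-numeric cells in column(s) {bad}")
    declared = meta.get("channels")
    if declared is not None:
        missing = [c for c in declared if c not in df.columns]
        if missing:
            raise ValueError(f"declared channel(s) absent from signal file: {missing}")
    present = [c for c in CHANNELS if c in df.columns]
    extra = [c for c in df.columns if c not in CHANNELS]
    if extra:
        raise ValueError(f"unknown channel label(s): {extra}")
    if not present:
        raise ValueError("no recognized channel labels in signal file")
    rec = EmgRecording(
        signal=df[present].to_numpy().T,
        fs=fs,
        channels=tuple(present),
        units=meta.get("units", "mV_gained"),
        subject_id=str(meta.get("subject", "")),
        task=str(meta.get("task", "")),
        group=str(meta.get("group", "unknown")),
    )
    return rec


def write_recording(rec: EmgRecording, signal_path, meta_path) -> None:
    """Write a recording as delimited text plus a YAML/JSON sidecar."""
    sep = "\t" if str(signal_path).endswith(".tsv") else ","
    df = pd.DataFrame(rec.signal.T, columns=list(rec.channels))
    df.to_csv(signal_path, sep=sep, index=False)  # default repr round-trips exactly
    meta = {
        "fs": rec.fs,
        "units": rec.units,
        "channels": list(rec.channels),
        "subject": rec.subject_id,
        "task": rec.task,
        "group": rec.group,
    }
    meta_path = Path(meta_path)
    if meta_path.suffix == ".json":
        meta_path.write_text(json.dumps(meta, indent=1))
    else:
        meta_path.write_text(yaml.safe_dump(meta, sort_keys=False))


# ---------------------------------------------------------------------------
# MVC reference


def _moving_rms(x: np.ndarray, win: int, hop: int) -> tuple[np.ndarray, np.ndarray]:
    """RMS of sliding windows; returns (starts, rms)."""
    n = len(x)
    starts = np.arange(0, n - win + 1, hop)
    sq = np.concatenate([[0.0], np.cumsum(x.astype(float) ** 2)])
    rms = np.sqrt((sq[starts + win] - sq[starts]) / win)
    return starts, rms


def compute_mvc_reference(
    trials, fs: float, config: MvcConfig | None = None
) -> float:
    """MVC reference from repeated single-channel contraction trials.

    Per trial, 500-ms moving RMS windows are computed; the 3-s interval
    whose contained window-RMS values have minimum variance is taken as the
    most stable interval, and its overall RMS is the trial value. The
    reference is the mean across trials.
    """
    config = config or MvcConfig()
    if len(trials) == 0:
        raise ValueError("at least one MVC trial is required")
    win = int(round(config.window_ms / 1000.0 * fs))
    hop = max(1, int(round(config.hop_ms / 1000.0 * fs)))
    interval = int(round(config.stable_interval_s * fs))
    trial_rms = []
    for k, trial in enumerate(trials):
        x = np.asarray(trial, dtype=float).ravel()
        if len(x) < interval:
            raise ValueError(
                f"MVC trial {k} is {len(x)/fs:.2f} s, shorter than the "
                f"{config.stable_interval_s:.0f}-s stable interval"
            )
        starts, wrms = _moving_rms(x, win, hop)
        # candidate 3-s intervals: those window positions fully inside
        best_var, best_start = np.inf, 0
        for s0 in range(0, len(x) - interval + 1, hop):
            inside = (starts >= s0) & (starts + win <= s0 + interval)
            if inside.sum() < 2:
                continue
            v = float(np.var(wrms[inside]))
            if v < best_var:
                best_var, best_start = v, s0
        seg = x[best_start : best_start + interval]
        r = float(np.sqrt(np.mean(seg**2)))
        if r <= 0:
            raise ValueError(f"MVC trial {k} has zero RMS in its stable interval")
        trial_rms.append(r)
    return float(np.mean(trial_rms))


def compute_mvc_reference_multichannel(
    trials_by_channel: dict, fs: float, config: MvcConfig | None = None
) -> MvcReference:
    """Build an :class:`MvcReference` from per-channel trial lists."""
    config = config or MvcConfig()
    values = {
        ch: compute_mvc_reference(trials, fs, config)
        for ch, trials in trials_by_channel.items()
    }
    n_trials = min((len(t) for t in trials_by_channel.values()), default=0)
    return MvcReference(
        values=values,
        n_trials=n_trials,
        window_ms=config.window_ms,
        stable_interval_s=config.stable_interval_s,
    )


def normalize_to_mvc(rec: EmgRecording, ref: MvcReference) -> EmgRecording:
    """Divide each channel by its MVC RMS reference (units become %MVC)."""
    if rec.units != "mV_gained":
        raise ValueError("recording is already normalized")
    missing = [ch for ch in rec.channels if ch not in ref.values]
    if missing:
        raise ValueError(f"MVC reference missing channel(s): {missing}")
    scale = np.array([ref[ch] for ch in rec.channels], dtype=float)
    for ch, s in zip(rec.channels, scale):
        if s <= 0:
            raise ValueError(f"non-positive MVC reference for channel {ch!r}")
    return replace(rec, signal=rec.signal / scale[:, None], units="pct_mvc")


# ---------------------------------------------------------------------------
# Filtering


def preprocess_filter(
    rec: EmgRecording, config: FilterConfig | None = None
) -> EmgRecording:
    """Zero-phase 60 Hz notch + 20 Hz high-pass.

    2nd-order IIR notch (Q=30) and 4th-order Butterworth high-pass, each
    applied forward-backward (filtfilt) for zero phase distortion.
    """
    config = config or FilterConfig()
    if rec.fs < 500:
        raise ValueError("preprocess_filter requires fs >= 500 Hz")
    b_n, a_n = sps.iirnotch(config.notch_hz, config.notch_q, fs=rec.fs)
    sos_hp = sps.butter(
        config.highpass_order, config.highpass_hz, btype="highpass", fs=rec.fs, output="sos"
    )
    out = np.empty_like(rec.signal)
    for i in range(rec.n_channels):
        x = sps.filtfilt(b_n, a_n, rec.signal[i])
        out[i] = sps.sosfiltfilt(sos_hp, x)
    if not np.all(np.isfinite(out)):
        raise ValueError("filtering produced non-finite samples")
    return replace(rec, signal=out)


# ---------------------------------------------------------------------------
# Crosstalk attenuation


def attenuate_crosstalk(rec: EmgRecording, seed: int = 0) -> EmgRecording:
    """Attenuate inter-channel crosstalk by blind source separation.

    Kurtosis-based independent component estimation (FastICA with a fixed
    seed); estimated sources are re-assigned to the original channel labels
    by maximal absolute correlation with the corresponding input channel,
    sign-aligned, and re-scaled to match each input channel's RMS.
    Rank-deficient input (e.g. a duplicated channel) is passed through with
    a warning.
    """
    from scipy.optimize import linear_sum_assignment
    from sklearn.decomposition import FastICA

    if rec.n_channels < 2:
        return rec
    X = rec.signal
    if np.linalg.matrix_rank(np.cov(X)) < rec.n_channels:
        warnings.warn("rank-deficient input; crosstalk attenuation skipped")
        return rec
    ica = FastICA(
        n_components=rec.n_channels, random_state=seed, whiten="unit-variance", max_iter=500
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        S = ica.fit_transform(X.T).T  # components x samples
    # assign components to channels by max |corr|
    Xc = X - X.mean(axis=1, keepdims=True)
    Sc = S - S.mean(axis=1, keepdims=True)
    num = Xc @ Sc.T
    den = np.outer(np.sqrt((Xc**2).sum(axis=1)), np.sqrt((Sc**2).sum(axis=1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(den > 0, num / den, 0.0)
    rows, cols = linear_sum_assignment(-np.abs(corr))
    out = np.empty_like(X)
    for ch_i, comp_i in zip(rows, cols):
        s = S[comp_i] * np.sign(corr[ch_i, comp_i] or 1.0)
        rms_in = np.sqrt(np.mean(X[ch_i] ** 2))
        rms_s = np.sqrt(np.mean(s**2))
        out[ch_i] = s * (rms_in / rms_s if rms_s > 0 else 1.0)
    return replace(rec, signal=out)
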