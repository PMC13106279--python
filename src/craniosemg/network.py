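"""Graph analyses: per-channel visibility-graph density, band-limited
intermuscular coherence networks, and assembly of the 60-feature vector.

Node level: each channel is reduced to a local-standard-deviation series
(non-overlapping 100-sample blocks, i.e. 50 ms at 2 kHz) which is turned
into a natural visibility graph — two samples are connected when the
straight line between them clears every intermediate sample (strict
inequality). The graph's density 2E/(M(M-1)) indexes the visibility of
myoelectric bursts.

Edge level: intermuscular coherence of full-wave rectified signals
reconstructed from the pair's shared (consensus) 1-s burst epochs, via
Welch cross-spectra (1024-point, 75%-overlap Hamming windows, 4096-point
FFT). Coherence below the independence significance level
S = 1 - 0.05^(1/(L_hat - 1)) is zeroed; the Fisher z (atanh) of the
band-mean coherence is the edge weight. Per band, the 6-node weighted
network yields mean nodal strength and global efficiency (inverse
shortest path length with edge lengths 1/w).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.sparse.csgraph import shortest_path

from .config import BANDS, CoherenceConfig, PipelineConfig, VisibilityConfig
from .features_linear import mav, mean_frequency, segment_average, slope_sign_changes, waveform_length, welch_psd, zero_crossings
from .features_nonlinear import recurrence_plot, rqa_measures, wavelet_packet_entropy
from .segmentation import BurstSet, EpochSet, consensus_centers, extract_epochs
from .signal_io import EmgRecording, MvcReference

__all__ = [
    "local_sd_series",
    "VisibilityGraph",
    "visibility_graph",
    "band_coherence",
    "coherence_significance",
    "effective_segments",
    "edge_weights",
    "network_metrics",
    "assemble_feature_vector",
    "FEATURE_NAMES",
    "MuscleNetwork",
]

_PER_CHANNEL = ("MAV", "WL", "MNF", "ZR", "SlpSignChange", "RR", "DET", "ShanEn", "density")
_BAND_METRICS = ("nodstr", "ge")


def feature_names(channels=None, bands=None) -> list:
    from .config import CHANNELS

    channels = channels or CHANNELS
    bands = bands or list(BANDS)
    names = [f"{feat}_{ch}" for feat in _PER_CHANNEL for ch in channels]
    names += [f"{m}_{b}" for m in _BAND_METRICS for b in bands]
    return names


#: The 60 canonical feature names (9 per-channel features x 6 channels +
#: nodal strength and global efficiency x 3 bands).
FEATURE_NAMES = feature_names()


# ---------------------------------------------------------------------------
# Visibility


def local_sd_series(x: np.ndarray, block_len: int = 100) -> np.ndarray:
    """Sample SD (ddof=1) of consecutive non-overlapping blocks; the
    trailing partial block is dropped."""
    x = np.asarray(x, dtype=float)
    if x.size < 2 * block_len:
        raise ValueError(f"need >= {2 * block_len} samples for the local-SD series")
    m = x.size // block_len
    blocks = x[: m * block_len].reshape(m, block_len)
    return blocks.std(axis=1, ddof=1)


@dataclass
class VisibilityGraph:
    values: np.ndarray
    edges: set = field(default_factory=set)

    @property
    def density(self) -> float:
        m = len(self.values)
        if m < 2:
            raise ValueError("density undefined for fewer than 2 nodes")
        return 2.0 * len(self.edges) / (m * (m - 1))


def visibility_graph(series: np.ndarray) -> VisibilityGraph:
    """Natural visibility graph under the strict-inequality criterion.

    Nodes x < y are connected iff every intermediate z satisfies
    (V_z - V_x)/(z - x) < (V_y - V_x)/(y - x); adjacent nodes are
    connected vacuously.
    """
    v = np.asarray(series, dtype=float)
    m = v.size
    if m < 2:
        raise ValueError("visibility graph requires at least 2 nodes")
    edges = set()
    idx = np.arange(m, dtype=float)
    for x in range(m - 1):
        edges.add((x, x + 1))
        if x + 2 >= m:
            continue
        # running max of intermediate slopes from x
        slopes = (v[x + 1 :] - v[x]) / (idx[x + 1 :] - x)
        run_max = -np.inf
        for j, y in enumerate(range(x + 2, m)):
            run_max = max(run_max, slopes[y - 1 - x - 1])
            if slopes[y - x - 1] > run_max:
                edges.add((x, y))
    return VisibilityGraph(values=v, edges=edges)


# ---------------------------------------------------------------------------
# Coherence


def effective_segments(n_samples: int, config: CoherenceConfig | None = None) -> float:
    """Adjusted (effective) number of overlapped Welch segments.

    The raw window count is scaled down by the variance-reduction factor
    for overlapped tapered segments, 1 + 2*sum_m (1 - m/K) * c_m^2, where
    c_m is the normalized Hamming-window autocorrelation at lag m*hop.
    """
    config = config or CoherenceConfig()
    if config.l_hat_override is not None:
        return float(config.l_hat_override)
    win = config.window
    hop = int(round(win * (1.0 - config.overlap)))
    if n_samples < win:
        raise ValueError("signal shorter than one coherence window")
    k = 1 + (n_samples - win) // hop
    if k < 2:
        raise ValueError("fewer than 2 averaging windows; coherence is degenerate")
    w = np.hamming(win)
    denom = float(np.sum(w * w))
    corr_sum = 0.0
    m = 1
    while m * hop < win:
        c = float(np.sum(w[: win - m * hop] * w[m * hop :])) / denom
        corr_sum += (1.0 - m / k) * c * c
        m += 1
    return k / (1.0 + 2.0 * corr_sum)


def coherence_significance(l_hat: float, alpha: float = 0.05) -> float:
    """95% independence threshold S = 1 - alpha^(1/(L_hat - 1))."""
    if l_hat <= 1:
        raise ValueError("L_hat must exceed 1")
    return 1.0 - alpha ** (1.0 / (l_hat - 1.0))


def band_coherence(
    x: np.ndarray, y: np.ndarray, fs: float, config: CoherenceConfig | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Magnitude-squared coherence of two (already rectified/concatenated)
    signals; returns (frequencies, coherence, L_hat)."""
    config = config or CoherenceConfig()
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("signals must share epoch windows (equal length)")
    l_hat = effective_segments(x.size, config)
    noverlap = int(round(config.window * config.overlap))
    f, coh = sps.coherence(
        x,
        y,
        fs=fs,
        window="hamming",
        nperseg=config.window,
        noverlap=noverlap,
        nfft=config.nfft,
        detrend="constant",
    )
    return f, coh, l_hat


def edge_weights(
    f: np.ndarray,
    coh: np.ndarray,
    s_threshold: float,
    bands: dict | None = None,
    config: CoherenceConfig | None = None,
) -> dict:
    """Per-band Fisher-z edge weights from a significance-pruned coherence
    spectrum. In-band coherence below the threshold is zeroed; bins within
    the notch exclusion zone around 60 Hz are dropped from the band mean."""
    config = config or CoherenceConfig()
    bands = bands or BANDS
    notch = 60.0
    weights = {}
    for name, (lo, hi) in bands.items():
        sel = (f >= lo) & (f <= hi)
        if hi >= notch - config.notch_exclude_hz and lo <= notch + config.notch_exclude_hz:
            sel &= np.abs(f - notch) > config.notch_exclude_hz
        if not sel.any():
            weights[name] = 0.0
            continue
        pruned = np.where(coh[sel] >= s_threshold, coh[sel], 0.0)
        mean_coh = float(pruned.mean())
        if config.fisher_on_sqrt:
            mean_coh = float(np.sqrt(mean_coh))
        weights[name] = float(np.arctanh(min(mean_coh, 1.0 - 1e-6)))
    return weights


@dataclass
class MuscleNetwork:
    """Weighted 6-node intermuscular networks, one per frequency band."""

    channels: tuple
    weights: dict  # band -> n x n symmetric matrix

    def metrics(self) -> dict:
        out = {}
        for band, w in self.weights.items():
            nodstr, ge = network_metrics(w)
            out[band] = {"nodstr": nodstr, "ge": ge}
        return out


def network_metrics(weights: np.ndarray) -> tuple[float, float]:
    """(mean nodal strength, global efficiency) of a weighted graph.

    Nodal strength is the row sum of weights; global efficiency is the
    mean over unordered node pairs of 1/d_ij with d_ij the weighted
    shortest path under edge length 1/w (unreachable pairs contribute 0).
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(w, w.T, atol=1e-10, equal_nan=True):
        raise ValueError("weight matrix must be symmetric")
    if np.isnan(w).any():
        return float("nan"), float("nan")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if np.any(np.diag(w) != 0):
        raise ValueError("diagonal must be zero")
    n = w.shape[0]
    strength = w.sum(axis=1)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, 0.0)
    d = shortest_path(lengths, method="D", directed=False)
    iu = np.triu_indices(n, k=1)
    inv = np.where(np.isfinite(d[iu]) & (d[iu] > 0), 1.0 / d[iu], 0.0)
    ge = float(inv.mean()) if inv.size else 0.0
    return float(strength.mean()), ge


# ---------------------------------------------------------------------------
# Feature vector assembly


def _pair_concat_rectified(
    rec: EmgRecording, bursts: BurstSet, pair: tuple, config: PipelineConfig
) -> tuple[np.ndarray, np.ndarray] | None:
    """Rectify and concatenate the pair's shared 1-s consensus epochs."""
    ctrs = consensus_centers(bursts, pair)
    if ctrs.size == 0:
        return None
    shared = BurstSet(centers={pair[0]: ctrs}, params=bursts.params)
    ep = extract_epochs(rec, shared, config.segment.epoch_s, config.segment)
    sl = ep.slices(pair[0])
    if not sl:
        return None
    xi = rec.channels.index(pair[0])
    yi = rec.channels.index(pair[1])
    x = np.concatenate([np.abs(rec.signal[xi, s]) for s in sl])
    y = np.concatenate([np.abs(rec.signal[yi, s]) for s in sl])
    return x, y


def assemble_feature_vector(
    rec: EmgRecording,
    bursts: BurstSet,
    config: PipelineConfig | None = None,
    mvc_ref: MvcReference | None = None,
) -> dict:
    """Compute all 60 named features for one preprocessed recording.

    Channels without usable bursts propagate NaN for their burst-dependent
    features (never silent zeros). The ZR/SSC deadband is expressed in
    gained mV and converted by the per-channel MVC reference when the
    signal is in %MVC units.
    """
    config = config or PipelineConfig()
    feats: dict = {}
    thr_mv = config.time_domain.amplitude_threshold_mv

    seg100 = extract_epochs(rec, bursts, config.segment.burst_segment_s, config.segment)
    seg1s = extract_epochs(rec, bursts, config.segment.epoch_s, config.segment)

    for i, ch in enumerate(rec.channels):
        x = rec.signal[i]
        if rec.units == "pct_mvc":
            if mvc_ref is None:
                raise ValueError(
                    "signal is in %MVC units: an MvcReference is required to "
                    "convert the mV amplitude threshold"
                )
            thr = thr_mv / mvc_ref[ch]
        else:
            thr = thr_mv
        segs = [x[s] for s in seg100.slices(ch)]
        feats[f"MAV_{ch}"] = segment_average(mav, segs)
        feats[f"WL_{ch}"] = segment_average(waveform_length, segs)
        feats[f"ZR_{ch}"] = segment_average(lambda s: zero_crossings(s, thr), segs)
        feats[f"SlpSignChange_{ch}"] = segment_average(
            lambda s: slope_sign_changes(s, thr), segs
        )
        feats[f"MNF_{ch}"] = mean_frequency(welch_psd(x, rec.fs, config.welch))
        feats[f"ShanEn_{ch}"] = wavelet_packet_entropy(x, config.wavelet)
        epochs = [x[s] for s in seg1s.slices(ch)][: config.rqa.max_epochs]
        if epochs:
            rr_det = [rqa_measures(recurrence_plot(e, config.rqa)) for e in epochs]
            feats[f"RR_{ch}"] = float(np.mean([v[0] for v in rr_det]))
            feats[f"DET_{ch}"] = float(np.mean([v[1] for v in rr_det]))
        else:
            feats[f"RR_{ch}"] = float("nan")
            feats[f"DET_{ch}"] = float("nan")
        feats[f"density_{ch}"] = visibility_graph(
            local_sd_series(x, config.visibility.block_len)
        ).density

    # intermuscular coherence networks
    n = rec.n_channels
    wmats = {band: np.zeros((n, n)) for band in BANDS}
    for a, b in itertools.combinations(range(n), 2):
        pair = (rec.channels[a], rec.channels[b])
        concat = _pair_concat_rectified(rec, bursts, pair, config)
        if concat is None:
            for band in BANDS:
                wmats[band][a, b] = wmats[band][b, a] = np.nan
            continue
        try:
            f, coh, l_hat = band_coherence(concat[0], concat[1], rec.fs, config.coherence)
        except ValueError:
            for band in BANDS:
                wmats[band][a, b] = wmats[band][b, a] = np.nan
            continue
        s_thr = coherence_significance(l_hat, config.coherence.alpha)
        w = edge_weights(f, coh, s_thr, BANDS, config.coherence)
        for band in BANDS:
            wmats[band][a, b] = wmats[band][b, a] = w[band]

    for band in BANDS:
        nodstr, ge = network_metrics(wmats[band])
        feats[f"nodstr_{band}"] = nodstr
        feats[f"ge_{band}"] = ge

    expected = feature_names(rec.channels)
    return {k: feats[k] for k in expected}
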