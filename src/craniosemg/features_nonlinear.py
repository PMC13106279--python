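"""Nonlinear sEMG features: wavelet-packet Shannon entropy and recurrence
quantification analysis (RQA).

Shannon entropy: the signal is decomposed by a 3-level wavelet packet
transform (5th-order Symlets) into its 8 level-3 sub-bands; per sub-band
the entropy -sum s_i^2 log(s_i^2) of the coefficients is computed
(natural log, 0*log0 := 0) and the per-band entropies are summed.

RQA: 1-s stationary epochs are z-scored, delay-embedded with embedding
dimension m=30 and delay tau=5 samples, and a recurrence plot
R_ij = Theta(eps - ||x_i - x_j||) is formed with the Euclidean norm.
eps=0.1 is interpreted as a fraction of the maximum phase-space distance
(absolute mode available), making RR/DET amplitude-invariant. RR is the
fraction of recurrent state pairs (main diagonal included: R_ii = 1 by
construction); DET is the fraction of off-diagonal recurrence points
lying on diagonal lines of length >= l_min (main diagonal excluded from
numerator and denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.spatial.distance import pdist, squareform

from .config import RqaConfig, WaveletConfig

__all__ = [
    "wavelet_packet_entropy",
    "RecurrencePlot",
    "recurrence_plot",
    "rqa_measures",
]


def wavelet_packet_entropy(x: np.ndarray, config: WaveletConfig | None = None) -> float:
    """Sum of per-sub-band Shannon entropies of level-3 wavelet packet
    coefficients."""
    config = config or WaveletConfig()
    x = np.asarray(x, dtype=float)
    w = pywt.Wavelet(config.wavelet)
    min_len = (w.dec_len - 1) * (2**config.level)
    if x.size < min_len:
        raise ValueError(
            f"signal of {x.size} samples too short for level-{config.level} "
            f"decomposition with {config.wavelet}"
        )
    wp = pywt.WaveletPacket(x, config.wavelet, mode=config.mode, maxlevel=config.level)
    total = 0.0
    for node in wp.get_level(config.level, order="natural"):
        s2 = np.asarray(node.data, dtype=float) ** 2
        nz = s2[s2 > 0]
        total += float(-np.sum(nz * np.log(nz)))
    return total


@dataclass
class RecurrencePlot:
    """Binary recurrence matrix over the delay-embedded trajectory."""

    matrix: np.ndarray  # M x M bool
    epsilon_abs: float
    params: RqaConfig

    @property
    def m_states(self) -> int:
        return self.matrix.shape[0]


def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n = len(x) - (m - 1) * tau
    if n < 2:
        raise ValueError(
            f"epoch of {len(x)} samples too short for embedding "
            f"(m={m}, tau={tau} needs > {(m - 1) * tau + 1})"
        )
    idx = np.arange(n)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def recurrence_plot(epoch: np.ndarray, params: RqaConfig | None = None) -> RecurrencePlot:
    """Recurrence plot of a (z-scored) epoch."""
    params = params or RqaConfig()
    x = np.asarray(epoch, dtype=float)
    sd = x.std()
    z = (x - x.mean()) / sd if sd > 0 else x - x.mean()
    traj = _embed(z, params.embedding_dim, params.delay)
    d = pdist(traj)
    if params.epsilon_mode == "relative":
        dmax = d.max() if d.size else 0.0
        eps = params.epsilon * dmax
    else:
        eps = params.epsilon
    r = squareform(d <= eps)
    np.fill_diagonal(r, True)
    return RecurrencePlot(matrix=r, epsilon_abs=float(eps), params=params)


def _diagonal_points_ge(r_off: np.ndarray, l_min: int) -> int:
    """Recurrence points lying in diagonal runs of length >= l_min, over a
    matrix whose main diagonal is already zeroed."""
    if l_min <= 1:
        return int(r_off.sum())
    if l_min == 2:
        # a point is in a run >= 2 iff it has a diagonal neighbor
        up = np.zeros_like(r_off)
        up[1:, 1:] = r_off[:-1, :-1]
        down = np.zeros_like(r_off)
        down[:-1, :-1] = r_off[1:, 1:]
        return int(np.count_nonzero(r_off & (up | down)))
    m = r_off.shape[0]
    total = 0
    for k in range(-(m - 1), m):
        if k == 0:
            continue
        diag = np.diagonal(r_off, offset=k)
        # run lengths along the diagonal
        padded = np.concatenate([[0], diag.astype(int), [0]])
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        runs = ends - starts
        total += int(runs[runs >= l_min].sum())
    return total


def rqa_measures(rp: RecurrencePlot, l_min: int | None = None) -> tuple[float, float]:
    """(RR, DET) of a recurrence plot.

    RR = (number of recurrence points) / M^2. DET = (off-diagonal points in
    diagonal lines of length >= l_min) / (all off-diagonal points), 0 when
    there are no off-diagonal points.
    """
    l_min = l_min if l_min is not None else rp.params.l_min
    r = rp.matrix
    m = r.shape[0]
    rr = float(r.sum()) / (m * m)
    r_off = r.copy()
    np.fill_diagonal(r_off, False)
    denom = int(r_off.sum())
    if denom == 0:
        return rr, 0.0
    det = _diagonal_points_ge(r_off, l_min) / denom
    return rr, float(det)
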