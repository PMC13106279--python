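"""Synthetic sEMG recordings and cohorts with the statistical structure
the pipeline assumes.

Recording level: burst-gated, band-shaped Gaussian carriers per channel
emulate DDK syllable trains. Band-limited common drives (theta/alpha,
beta, low-gamma) are modeled as shared narrowband amplitude modulators
mixed into the channels — coherence in rectified sEMG reflects shared
modulation of motor-unit activity, not additive signal. Linear crosstalk
mixing, 60 Hz line interference, sub-20-Hz baseline wander, and
broadband measurement noise complete the acquisition model.

Cohort level: per-subject bulbar severity (0 for HC, moderate for
ALS-B, high for ALS+B) maps through an effect profile to recording
parameters (left-agonist amplitude up, right-masseter amplitude down,
submental spectrum up, common drives down, burst irregularity up —
the directions the group analyses probe) and through a linear-plus-noise
outcome model to the functional metrics (ALSFRS-R bulbar subscore,
intelligibility, speaking rate) and stiffness.

A feature-level cohort generator plants a Table-3-style 10-factor
structure directly in the 60-feature space, for testing the statistical
stages at scale without signal synthesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import BANDS, CHANNELS, TASKS
from .network import FEATURE_NAMES
from .signal_io import EmgRecording

__all__ = [
    "SimRecordingConfig",
    "SimCohortConfig",
    "simulate_recording",
    "simulate_cohort",
    "simulate_feature_cohort",
    "make_fixture_suite",
    "large_effect_shifts",
    "CANONICAL_FACTORS",
    "FACTOR_EFFECT_DIRECTIONS",
]


#: Table-3-style clustering of the 60 features into 10 interpretable
#: factors (the two low-gamma network features stay unassigned).
CANONICAL_FACTORS = {
    "AmpComp_Lag": [
        "MAV_LTEMP", "MAV_LMAS", "WL_LTEMP", "WL_LMAS", "RR_LTEMP",
        "RR_LMAS", "DET_LTEMP", "DET_LMAS", "ShanEn_LTEMP", "ShanEn_LMAS",
    ],
    "Visibility": [
        "density_RTEMP", "density_LTEMP", "density_RMAS",
        "density_LMAS", "density_RSM", "density_LSM",
    ],
    "Comp_antag": [
        "RR_RMAS", "RR_RSM", "RR_LSM", "DET_RMAS", "DET_RSM",
        "DET_LSM", "ShanEn_RMAS", "ShanEn_RSM", "ShanEn_LSM",
    ],
    "Freq_antag": [
        "MNF_RMAS", "MNF_RSM", "MNF_LSM", "ZR_RMAS", "ZR_RSM", "ZR_LSM",
        "SlpSignChange_RMAS", "SlpSignChange_RSM", "SlpSignChange_LSM",
    ],
    "Freq_Lag": [
        "MNF_LTEMP", "MNF_LMAS", "ZR_LTEMP", "ZR_LMAS",
        "SlpSignChange_LTEMP", "SlpSignChange_LMAS",
    ],
    "AmpComp_RTEMP": [
        "MAV_RTEMP", "WL_RTEMP", "RR_RTEMP", "DET_RTEMP", "ShanEn_RTEMP",
    ],
    "FcInt": ["nodstr_theta_alpha", "nodstr_beta", "ge_theta_alpha", "ge_beta"],
    "Amp_RMAS": ["MAV_RMAS", "WL_RMAS"],
    "Freq_RTEMP": ["MNF_RTEMP", "ZR_RTEMP", "SlpSignChange_RTEMP"],
    "Amp_SM": ["MAV_RSM", "MAV_LSM", "WL_RSM", "WL_LSM"],
}

#: Direction each latent construct moves with increasing bulbar severity.
FACTOR_EFFECT_DIRECTIONS = {
    "AmpComp_Lag": +1.0,
    "Visibility": +1.0,
    "Comp_antag": -1.0,
    "Freq_antag": +1.0,
    "Freq_Lag": -1.0,
    "AmpComp_RTEMP": +1.0,
    "FcInt": -1.0,
    "Amp_RMAS": -1.0,
    "Freq_RTEMP": -1.0,
    "Amp_SM": +1.0,
}


# ---------------------------------------------------------------------------
# Recording-level simulation


@dataclass
class SimRecordingConfig:
    fs: float = 2000.0
    duration: float = 8.0
    burst_rate: float = 5.0  # DDK syllable rate, Hz
    burst_width_ms: float = 12.0  # Gaussian SD of the burst envelope
    burst_jitter: float = 0.03  # timing jitter, fraction of the period
    burst_amp_cv: float = 0.1  # burst-to-burst amplitude variability
    carrier_band: tuple = (80.0, 450.0)
    channel_amplitudes: dict = field(
        default_factory=lambda: {ch: 100.0 for ch in CHANNELS}
    )  # gained mV
    channel_bands: dict = field(default_factory=dict)  # per-channel override
    drive_gains: dict = field(
        default_factory=lambda: {"theta_alpha": 0.6, "beta": 0.4, "low_gamma": 0.2}
    )
    crosstalk: np.ndarray | None = None  # default mild symmetric mixing
    line_amp: float = 2.0  # 60 Hz interference, gained mV
    wander_amp: float = 5.0  # < 20 Hz baseline wander, gained mV
    noise_pp: float = 8.0  # intrinsic noise peak-to-peak, gained mV (4 uV p-p x 2000)
    seed: int = 0


def _bandpass_noise(rng, n, fs, lo, hi, order=4) -> np.ndarray:
    hi = min(hi, 0.49 * fs)
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_recording(config: SimRecordingConfig) -> tuple[EmgRecording, dict]:
    """Generate one six-channel recording plus ground truth.

    Ground truth carries the true burst center samples per channel and
    the per-band common-drive gains."""
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs
    period = 1.0 / config.burst_rate
    width = config.burst_width_ms / 1000.0

    # shared burst schedule with per-channel jitter (muscles co-activate)
    base_times = np.arange(period, config.duration - period, period)

    # shared narrowband amplitude modulators (common drives)
    drives = {}
    for band, (lo, hi) in BANDS.items():
        drives[band] = _bandpass_noise(rng, n, fs, lo, hi)

    signals = np.empty((len(CHANNELS), n))
    burst_truth = {}
    for i, ch in enumerate(CHANNELS):
        jitter = rng.normal(0.0, config.burst_jitter * period, size=base_times.size)
        times = np.clip(base_times + jitter, width * 2, config.duration - width * 2)
        amps = np.maximum(
            rng.normal(1.0, config.burst_amp_cv, size=times.size), 0.1
        )
        env = np.zeros(n)
        for bt, ba in zip(times, amps):
            lo_i = max(0, int((bt - 3 * width) * fs))
            hi_i = min(n, int((bt + 3 * width) * fs))
            env[lo_i:hi_i] += ba * np.exp(-0.5 * ((t[lo_i:hi_i] - bt) / width) ** 2)
        band = config.channel_bands.get(ch, config.carrier_band)
        carrier = _bandpass_noise(rng, n, fs, band[0], band[1])
        # common drives modulate the recruited (burst) activity, not the
        # quiescent muscle-tone floor
        mod = np.ones(n)
        for bname, g in config.drive_gains.items():
            mod *= np.maximum(1.0 + g * drives[bname], 0.0)
        amp = config.channel_amplitudes.get(ch, 100.0)
        signals[i] = amp * carrier * (0.02 + env * mod)
        burst_truth[ch] = np.round(times * fs).astype(int)

    A = config.crosstalk
    if A is None:
        A = np.eye(len(CHANNELS)) + 0.05 * (np.ones((6, 6)) - np.eye(6))
    signals = np.asarray(A, dtype=float) @ signals

    phase = rng.uniform(0, 2 * np.pi)
    signals += config.line_amp * np.sin(2 * np.pi * 60.0 * t + phase)
    wander_sos = sps.butter(2, 2.0, btype="lowpass", fs=fs, output="sos")
    for i in range(len(CHANNELS)):
        w = sps.sosfiltfilt(wander_sos, rng.standard_normal(n))
        sd = w.std()
        signals[i] += config.wander_amp * (w / sd if sd > 0 else w)
        signals[i] += (config.noise_pp / 6.0) * rng.standard_normal(n)

    rec = EmgRecording(signal=signals, fs=fs, channels=CHANNELS, units="mV_gained")
    truth = {"burst_centers": burst_truth, "drive_gains": dict(config.drive_gains)}
    return rec, truth


def simulate_mvc_trials(
    amplitude: float = 500.0,
    fs: float = 2000.0,
    n_trials: int = 3,
    duration: float = 5.0,
    seed: int = 0,
) -> list:
    """Sustained maximal-contraction trials for MVC referencing."""
    rng = np.random.default_rng(seed)
    n = int(duration * fs)
    trials = []
    for _ in range(n_trials):
        x = _bandpass_noise(rng, n, fs, 20.0, 450.0)
        ramp = np.minimum(np.arange(n) / (0.5 * fs), 1.0)  # 0.5-s rise
        trials.append(amplitude * ramp * x)
    return trials


# ---------------------------------------------------------------------------
# Cohort-level simulation


@dataclass
class SimCohortConfig:
    n_per_group: tuple = (9, 7, 10)  # ALS+B, ALS-B, HC
    recordings_per_subject: int = 4
    duration: float = 8.0
    effect_scale: float = 1.0  # scales the whole severity -> parameter map
    severity_means: dict = field(
        default_factory=lambda: {"ALS+B": 2.0, "ALS-B": 0.8, "HC": 0.0}
    )
    severity_sd: float = 0.3
    seed: int = 0


def _severity_to_recording_config(
    severity: float, duration: float, scale: float, seed: int
) -> SimRecordingConfig:
    s = severity * scale
    amps = {
        "RTEMP": 100.0 * (1.0 + 0.10 * s),
        "LTEMP": 100.0 * (1.0 + 0.25 * s),
        "RMAS": 100.0 * max(1.0 - 0.20 * s, 0.2),
        "LMAS": 100.0 * (1.0 + 0.25 * s),
        "RSM": 100.0 * (1.0 + 0.20 * s),
        "LSM": 100.0 * (1.0 + 0.20 * s),
    }
    bands = {
        "LTEMP": (80.0, max(450.0 - 60.0 * s, 200.0)),
        "LMAS": (80.0, max(450.0 - 60.0 * s, 200.0)),
        "RSM": (80.0 + 25.0 * s, 450.0),
        "LSM": (80.0 + 25.0 * s, 450.0),
    }
    gains = {
        "theta_alpha": max(0.6 * (1.0 - 0.30 * s), 0.05),
        "beta": max(0.4 * (1.0 - 0.20 * s), 0.05),
        "low_gamma": 0.2,
    }
    return SimRecordingConfig(
        duration=duration,
        burst_jitter=0.03 + 0.04 * s,
        burst_amp_cv=0.10 + 0.10 * s,
        channel_amplitudes=amps,
        channel_bands=bands,
        drive_gains=gains,
        seed=seed,
    )


def _covariates(rng, group: str, group_linked: bool = True) -> dict:
    if not group_linked:
        # confounder-free: one covariate distribution for all groups
        return {
            "age": float(np.clip(rng.normal(62.0, 14.0), 30, 90)),
            "sex": "F" if rng.random() < 0.5 else "M",
            "MoCA": float(np.clip(rng.normal(26.5, 2.5), 15, 30)),
        }
    if group == "HC":
        age = rng.normal(66.8, 13.0)
        female = rng.random() < 0.70
        moca = rng.normal(26.8, 1.3)
    else:
        age = rng.normal(58.8, 14.6)
        female = rng.random() < 0.375
        moca = rng.normal(25.6, 3.3)
    return {
        "age": float(np.clip(age, 30, 90)),
        "sex": "F" if female else "M",
        "MoCA": float(np.clip(moca, 15, 30)),
    }


def _outcomes(rng, group: str, severity: float) -> dict:
    if group == "HC":
        bulb = 12.0
        intell = float(np.clip(rng.normal(99.4, 0.5), 0, 100))
        sr = float(max(rng.normal(183.7, 20.0), 60.0))
    else:
        bulb = float(np.clip(round(12.0 - 1.3 * severity - 0.4 * severity**2 + rng.normal(0, 0.7)), 0, 12))
        intell = float(np.clip(100.0 - 7.0 * max(severity - 0.6, 0.0) ** 2 + rng.normal(0, 2.0), 0, 100))
        sr = float(max(rng.normal(180.0 - 24.0 * severity, 14.0), 60.0))
    stiffness = float(max(rng.normal(1.0 - 0.25 * severity, 0.08), 0.05))
    return {"Bulb_ALSFRS": bulb, "Intell": intell, "SR": sr, "stiffness": stiffness}


def simulate_cohort(config: SimCohortConfig) -> tuple[list, pd.DataFrame]:
    """Simulate a full recording-level cohort.

    Returns ``(recordings, meta)`` where ``recordings`` is a list of
    (EmgRecording, ground-truth) tuples, one per row of ``meta``."""
    rng = np.random.default_rng(config.seed)
    groups = ["ALS+B"] * config.n_per_group[0] + ["ALS-B"] * config.n_per_group[1] + (
        ["HC"] * config.n_per_group[2]
    )
    recordings = []
    rows = []
    for si, group in enumerate(groups):
        subject = f"S{si + 1:03d}"
        if group == "HC":
            severity = 0.0
        else:
            severity = float(
                max(rng.normal(config.severity_means[group], config.severity_sd), 0.05)
            )
        cov = _covariates(rng, group)
        out = _outcomes(rng, group, severity)
        for ti in range(config.recordings_per_subject):
            task = TASKS[ti % len(TASKS)]
            rc = _severity_to_recording_config(
                severity,
                config.duration,
                config.effect_scale,
                seed=int(rng.integers(2**31 - 1)),
            )
            rec, truth = simulate_recording(rc)
            rec.subject_id, rec.task, rec.group = subject, task, group
            truth["severity"] = severity
            recordings.append((rec, truth))
            rows.append(
                {
                    "subject_id": subject,
                    "task": task,
                    "group": group,
                    "severity": severity,
                    **cov,
                    **out,
                }
            )
    return recordings, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Feature-level cohort generation


def simulate_feature_cohort(
    n_per_group: tuple = (9, 7, 10),
    recordings_per_subject: int = 4,
    factor_effect_size: float = 0.0,
    feature_shifts: np.ndarray | None = None,
    loading_range: tuple = (0.8, 0.95),
    factor_corr: float = 0.0,
    subject_share: float = 0.3,
    group_covariates: bool = True,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Plant a 10-factor structure directly in the 60-feature space.

    Each feature loads on its Table-3-style factor with a loading drawn
    from ``loading_range``; unassigned features are unique noise. Factor
    scores are correlated across factors (``factor_corr``) and shared
    within subject (``subject_share`` of the variance). Group effects
    enter either as per-factor standardized shifts
    (``factor_effect_size`` x direction x severity) or as direct
    per-feature standardized shifts (``feature_shifts``, a 60-vector
    multiplied by severity). Severity is 0 / 1 / 2 for HC / ALS-B /
    ALS+B. Returns the cohort table and the ground truth (true loading
    matrix, severities, shifts)."""
    rng = np.random.default_rng(seed)
    p = len(FEATURE_NAMES)
    k = len(CANONICAL_FACTORS)
    factor_names = list(CANONICAL_FACTORS)
    # true loading matrix
    L = np.zeros((p, k))
    for j, fn in enumerate(factor_names):
        feats_j = CANONICAL_FACTORS[fn]
        # small factors need strong marker loadings to be recoverable at
        # this cohort size (standard practice in factor-recovery designs)
        lo, hi = (0.9, 0.95) if len(feats_j) <= 3 else loading_range
        for feat in feats_j:
            L[FEATURE_NAMES.index(feat), j] = rng.uniform(lo, hi)
    phi = np.full((k, k), factor_corr)
    np.fill_diagonal(phi, 1.0)
    chol = np.linalg.cholesky(phi)

    groups = ["ALS+B"] * n_per_group[0] + ["ALS-B"] * n_per_group[1] + ["HC"] * n_per_group[2]
    sev_map = {"HC": 0.0, "ALS-B": 1.0, "ALS+B": 2.0}
    dirs = np.array([FACTOR_EFFECT_DIRECTIONS[fn] for fn in factor_names])

    rows = []
    feats = []
    for si, group in enumerate(groups):
        subject = f"S{si + 1:03d}"
        severity = sev_map[group]
        cov = _covariates(rng, group, group_linked=group_covariates)
        out = _outcomes(rng, group, severity)
        eta_subj = chol @ rng.standard_normal(k)
        for ti in range(recordings_per_subject):
            eta = np.sqrt(subject_share) * eta_subj + np.sqrt(1 - subject_share) * (
                chol @ rng.standard_normal(k)
            )
            eta_shifted = eta + factor_effect_size * dirs * severity
            unique_sd = np.sqrt(np.clip(1.0 - (L**2).sum(axis=1), 0.05, 1.0))
            x = L @ eta_shifted + unique_sd * rng.standard_normal(p)
            if feature_shifts is not None:
                x = x + np.asarray(feature_shifts, float) * severity
            feats.append(x)
            rows.append(
                {
                    "subject_id": subject,
                    "task": TASKS[ti % len(TASKS)],
                    "group": group,
                    "severity": severity,
                    **cov,
                    **out,
                }
            )
    table = pd.concat(
        [
            pd.DataFrame(np.asarray(feats), columns=FEATURE_NAMES),
            pd.DataFrame(rows),
        ],
        axis=1,
    )
    truth = {
        "loadings": pd.DataFrame(L, index=FEATURE_NAMES, columns=factor_names),
        "phi": phi,
        "severity": {f"S{i + 1:03d}": sev_map[g] for i, g in enumerate(groups)},
        "feature_shifts": feature_shifts,
        "factor_effect_size": factor_effect_size,
    }
    return table, truth


def large_effect_shifts(magnitude: float = 1.5) -> np.ndarray:
    """Standardized per-feature group shifts on 20 features, aligned with
    the canonical factor structure (disease effects act on constructs, so
    the shifted features of a factor move coherently in its declared
    direction)."""
    shifts = np.zeros(len(FEATURE_NAMES))
    for fac in ("Visibility", "Freq_Lag", "AmpComp_RTEMP", "Freq_RTEMP"):
        for f in CANONICAL_FACTORS[fac]:
            shifts[FEATURE_NAMES.index(f)] = magnitude * FACTOR_EFFECT_DIRECTIONS[fac]
    return shifts


# ---------------------------------------------------------------------------
# Fixtures


def make_fixture_suite(out_dir, seed: int = 0) -> dict:
    """Write a small deterministic fixture set: 3 recordings with sidecars,
    per-channel MVC trials, and a feature-level cohort table."""
    from pathlib import Path

    from .signal_io import write_recording

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict = {"recordings": []}
    for i, (group, sev) in enumerate([("HC", 0.0), ("ALS-B", 0.8), ("ALS+B", 2.0)]):
        rc = _severity_to_recording_config(sev, duration=6.0, scale=1.0, seed=seed + i)
        rec, _ = simulate_recording(rc)
        rec.subject_id, rec.task, rec.group = f"S{i + 1:03d}", "pa", group
        sig = out / f"rec_{i + 1}.csv"
        meta = out / f"rec_{i + 1}.yaml"
        write_recording(rec, sig, meta)
        paths["recordings"].append((str(sig), str(meta)))
    mvc = {
        ch: np.column_stack(simulate_mvc_trials(seed=seed + 10 + j))
        for j, ch in enumerate(CHANNELS)
    }
    mvc_path = out / "mvc_trials.csv"
    stacked = pd.DataFrame(
        {f"{ch}_trial{k + 1}": mvc[ch][:, k] for ch in CHANNELS for k in range(3)}
    )
    stacked.to_csv(mvc_path, index=False, float_format="%.8g")
    paths["mvc"] = str(mvc_path)
    cohort, _ = simulate_feature_cohort(factor_effect_size=0.8, seed=seed)
    cohort_path = out / "cohort.tsv"
    cohort.to_csv(cohort_path, sep="\t", index=False, float_format="%.10g")
    paths["cohort"] = str(cohort_path)
    return paths
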