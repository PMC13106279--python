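"""Pipeline configuration: every tunable constant of the extraction and
analysis pipeline in one schema-versioned structure.

Defaults follow the acquisition and analysis settings the pipeline was
designed around: 2 kHz sampling, 60 Hz notch + 20 Hz high-pass, 100-ms
burst segments, 1-s stationary epochs, Welch spectra with 100-ms/50%
Hamming windows (1024-point FFT), RQA at (m=30, tau=5, eps=0.1),
intermuscular coherence with 1024-point/75% Hamming windows (4096-point
FFT) in the theta/alpha (4-12 Hz), beta (12-30 Hz) and low-gamma
(30-60 Hz) bands, Tukey 1.5*IQR outlier fences, a 0.40 factor-loading
cutoff, and a MoCA cutoff of 26 for cognitive status.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

SCHEMA_VERSION = 1

#: Canonical channel order: right/left temporalis, right/left masseter,
#: right/left submental complex.
CHANNELS = ("RTEMP", "LTEMP", "RMAS", "LMAS", "RSM", "LSM")

#: Coherence bands (Hz): low-frequency common drive (theta/alpha),
#: cortical beta, and low-gamma.
BANDS = {
    "theta_alpha": (4.0, 12.0),
    "beta": (12.0, 30.0),
    "low_gamma": (30.0, 60.0),
}

GROUPS = ("ALS+B", "ALS-B", "HC")
TASKS = ("pa", "ta", "ka", "pataka")


@dataclass
class FilterConfig:
    notch_hz: float = 60.0
    notch_q: float = 30.0
    highpass_hz: float = 20.0
    highpass_order: int = 4


@dataclass
class MvcConfig:
    window_ms: float = 500.0
    hop_ms: float = 100.0
    stable_interval_s: float = 3.0


@dataclass
class BurstConfig:
    envelope_window_ms: float = 25.0
    threshold_k: float = 3.0
    baseline_percentile: float = 10.0
    baseline_region_percentile: float = 50.0
    min_gap_ms: float = 80.0
    min_duration_ms: float = 30.0  # prune shorter supra-threshold blips
    peak_k: float = 10.0  # regions must peak this many SDs above baseline


@dataclass
class SegmentConfig:
    burst_segment_s: float = 0.1
    epoch_s: float = 1.0
    merge_overlapping_epochs: bool = True


@dataclass
class TimeDomainConfig:
    #: Deadband for zero crossings / slope sign changes, in gained mV
    #: (4 uV p-p intrinsic noise x 2000 gain / 2). Converted by the
    #: per-channel MVC reference when signals are in %MVC.
    amplitude_threshold_mv: float = 4.0


@dataclass
class WelchConfig:
    window_s: float = 0.1
    overlap: float = 0.5
    nfft: int = 1024


@dataclass
class RqaConfig:
    embedding_dim: int = 30
    delay: int = 5
    epsilon: float = 0.1
    epsilon_mode: str = "relative"  # fraction of max phase-space distance
    l_min: int = 2
    max_epochs: int = 6  # RR/DET averaged over at most this many 1-s epochs


@dataclass
class WaveletConfig:
    wavelet: str = "sym5"
    level: int = 3
    mode: str = "symmetric"  # boundary extension


@dataclass
class VisibilityConfig:
    block_len: int = 100  # samples per local-SD block (50 ms at 2 kHz)


@dataclass
class CoherenceConfig:
    window: int = 1024
    overlap: float = 0.75
    nfft: int = 4096
    alpha: float = 0.05
    l_hat_override: float | None = None
    notch_exclude_hz: float = 1.0  # half-width around the notch to drop
    fisher_on_sqrt: bool = False  # atanh of MSC itself by default


@dataclass
class CrosstalkConfig:
    enabled: bool = True
    seed: int = 0


@dataclass
class StatsConfig:
    iqr_multiplier: float = 1.5
    loading_cutoff: float = 0.40
    moca_cutoff: float = 26.0
    impute_max_depth: int = 5
    impute_min_leaf: int = 5
    impute_max_sweeps: int = 5
    impute_tol: float = 1e-3
    pa_n_sims: int = 100
    pa_percentile: float = 95.0
    n_boot: int = 500


@dataclass
class ClassifierConfig:
    algo: str = "mda"
    n_subclasses: int = 2
    svm_c: float = 1.0
    max_iter: int = 200
    tol: float = 1e-6
    loocv_level: str = "recording"  # or "subject"


@dataclass
class PipelineConfig:
    """Aggregate configuration for the full pipeline."""

    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    filter: FilterConfig = field(default_factory=FilterConfig)
    mvc: MvcConfig = field(default_factory=MvcConfig)
    burst: BurstConfig = field(default_factory=BurstConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    time_domain: TimeDomainConfig = field(default_factory=TimeDomainConfig)
    welch: WelchConfig = field(default_factory=WelchConfig)
    rqa: RqaConfig = field(default_factory=RqaConfig)
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    visibility: VisibilityConfig = field(default_factory=VisibilityConfig)
    coherence: CoherenceConfig = field(default_factory=CoherenceConfig)
    crosstalk: CrosstalkConfig = field(default_factory=CrosstalkConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        kwargs: dict[str, Any] = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for key, value in d.items():
            if key not in fields:
                raise ValueError(f"unknown config key: {key!r}")
            f = fields[key]
            if dataclasses.is_dataclass(f.default_factory() if f.default_factory is not dataclasses.MISSING else None):  # type: ignore[misc]
                sub_cls = type(f.default_factory())  # type: ignore[misc]
                sub_fields = {sf.name for sf in dataclasses.fields(sub_cls)}
                unknown = set(value) - sub_fields
                if unknown:
                    raise ValueError(f"unknown config key(s) in {key}: {sorted(unknown)}")
                kwargs[key] = sub_cls(**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
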