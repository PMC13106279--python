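import warnings

import numpy as np
import pytest

from craniosemg.pipeline import preprocess_recording
from craniosemg.segmentation import detect_bursts
from craniosemg.synthetic_data import SimRecordingConfig, simulate_feature_cohort, simulate_recording

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def sim_recording():
    """One simulated DDK recording with ground truth (raw)."""
    rec, truth = simulate_recording(SimRecordingConfig(duration=8.0, seed=7))
    return rec, truth


@pytest.fixture(scope="session")
def clean_recording(sim_recording):
    """The same recording, filtered and crosstalk-attenuated."""
    rec, truth = sim_recording
    return preprocess_recording(rec), truth


@pytest.fixture(scope="session")
def burst_set(clean_recording):
    rec, _ = clean_recording
    return detect_bursts(rec)


@pytest.fixture(scope="session")
def feature_cohort():
    """Feature-level cohort with the planted 10-factor structure, no
    group effects."""
    table, truth = simulate_feature_cohort(seed=11)
    return table, truth
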