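import numpy as np
import pytest

from msdeeg.evaluation import ClassifierSpec
from msdeeg.pipeline import ExperimentConfig, extract_cohort_features
from msdeeg.signal_io import CANONICAL_CHANNELS, Recording
from msdeeg.synthetic_data import GeneratorConfig, iter_cohort


def make_recording(samples, fs=500.0, channels=None, subject_id="S01",
                   state="rest", group="low_stress"):
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if channels is None:
        channels = list(CANONICAL_CHANNELS[: samples.shape[0]])
    return Recording(subject_id=subject_id, channels=channels, fs=fs,
                     samples=samples, state=state, group=group)


def sinusoid(freq, fs=500.0, duration=4.0, amplitude=1.0, phase=0.0):
    t = np.arange(int(round(duration * fs))) / fs
    return amplitude * np.sin(2 * np.pi * freq * t + phase)


def amplitude_at(x, fs, freq):
    """Peak-normalised amplitude-spectrum value at (the bin nearest) freq."""
    n = len(x)
    amp = np.abs(np.fft.rfft(x)) * 2.0 / n
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return amp[np.argmin(np.abs(freqs - freq))]


@pytest.fixture(scope="session")
def small_cohort_fm():
    """Feature matrix of a small balanced synthetic cohort (default effects)."""
    cfg = ExperimentConfig(
        seed=11,
        generate=dict(n_subjects=8, group_split=(4, 4), rest_s=40.0, task_s=40.0),
    )
    recs = (r for _, r in iter_cohort(cfg.generator_config()))
    return extract_cohort_features(recs, cfg)


@pytest.fixture
def knn_spec():
    return ClassifierSpec(kind="knn", seed=0)
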