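import numpy as np
import pytest

from bssfo.io import Recording, TrialSet
from bssfo.synthetic import default_subject, gen_motor_imagery


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(n_channels=3, n_samples=1000, fs=100.0, rng=None,
                   channels=None, annotations=()):
    rng = rng or np.random.default_rng(0)
    channels = channels or [f"ch{i}" for i in range(n_channels)]
    data = rng.standard_normal((len(channels), n_samples))
    return Recording(channels, fs, data, list(annotations))


def make_tone_trials(freq, fs=100.0, n_trials=6, n_channels=2, n_samples=400,
                     amplitude=1.0):
    """Trials containing a pure sinusoid on every channel."""
    t = np.arange(n_samples) / fs
    tone = amplitude * np.sin(2 * np.pi * freq * t)
    trials = np.tile(tone, (n_trials, n_channels, 1))
    labels = np.array(["L", "R"] * (n_trials // 2) + ["L"] * (n_trials % 2))
    return TrialSet(trials, labels, fs)


def make_gaussian_trials(cov_a, cov_b, n_per_class=40, n_samples=128, rng=None):
    """Trials drawn i.i.d. from class-specific channel covariances."""
    rng = rng or np.random.default_rng(0)
    n_ch = cov_a.shape[0]
    la, lb = np.linalg.cholesky(cov_a), np.linalg.cholesky(cov_b)
    trials, labels = [], []
    for _ in range(n_per_class):
        trials.append(la @ rng.standard_normal((n_ch, n_samples)))
        labels.append("L")
        trials.append(lb @ rng.standard_normal((n_ch, n_samples)))
        labels.append("R")
    return TrialSet(np.array(trials), np.array(labels), 100.0)


@pytest.fixture(scope="session")
def planted_trials():
    """Imagery trials with a strong discriminative rhythm around 10-14 Hz."""
    spec = default_subject(seed=42)
    return gen_motor_imagery(spec)


@pytest.fixture(scope="session")
def null_trials():
    """Imagery trials with no class-dependent modulation (ERD depth 0)."""
    spec = default_subject(erd=0.0, seed=43)
    return gen_motor_imagery(spec)
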