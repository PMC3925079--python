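"""Synthetic motor-imagery and resting-state EEG with known ground truth.

Subjects are described by a :class:`SubjectSpec`: sensorimotor rhythm
components (center, width, amplitude), a 1/f background
``k1 + k2 / f**lambda``, per-class event-related desynchronization (ERD)
depths, and a spatial mixing matrix placing a left- and a right-hemisphere
source per rhythm component onto the channels.

Signals are synthesized by frequency-domain amplitude shaping of white
Gaussian noise, so every generated channel has exactly the intended
expected power spectral density: the 1/f floor per channel, plus
Gaussian-shaped rhythm peaks mixed in from the source space.  During
imagery trials the source contralateral to the imagined hand is attenuated
in amplitude by the ERD depth — the class-lateralized modulation that CSP
exploits.  A cohort generator ties resting spectra and imagery performance
to the same subject parameters, reproducing the statistical link the
resting-state predictor relies on (strong resting rhythms -> good imagery
performance).

All outputs are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Recording, TrialSet
from .montage import _CENTERS_16, channel_position

__all__ = [
    "SubjectSpec",
    "Cohort",
    "default_subject",
    "gen_resting",
    "gen_motor_imagery",
    "gen_cohort",
]

_CHANNELS_3 = ["C3", "Cz", "C4"]

#: spatial spread (lattice units) of a source's projection onto the channels
_SOURCE_SPREAD = 1.5


@dataclass
class SubjectSpec:
    """Generative description of one synthetic subject.

    ``rhythms`` lists (center Hz, width Hz, peak amplitude uV^2/Hz); each
    component owns a left- and a right-hemisphere source.  ``erd`` has shape
    (2, n_components): row 0 the ERD depth during left-hand imagery (applied
    to the right-hemisphere source), row 1 during right-hand imagery
    (applied to the left-hemisphere source).  ``mixing`` is
    (n_channels, 2 * n_components), columns ordered
    [comp0-left, comp0-right, comp1-left, ...] and full column rank.
    """

    rhythms: list[tuple[float, float, float]]
    noise: tuple[float, float, float]  # (k1, k2, lambda)
    erd: np.ndarray
    mixing: np.ndarray
    channels: list[str]
    true_performance: float = float("nan")
    seed: int = 0

    def __post_init__(self) -> None:
        self.erd = np.atleast_2d(np.asarray(self.erd, dtype=float))
        self.mixing = np.asarray(self.mixing, dtype=float)
        n_comp = len(self.rhythms)
        if self.erd.shape != (2, n_comp):
            raise ValueError(f"erd must be (2, {n_comp})")
        if np.any(self.erd < 0) or np.any(self.erd > 1):
            raise ValueError("ERD depths must lie in [0, 1]")
        if any(a < 0 or w <= 0 for _, w, a in self.rhythms):
            raise ValueError("rhythm amplitudes must be >= 0 and widths > 0")
        if self.mixing.shape != (len(self.channels), 2 * n_comp):
            raise ValueError("mixing must be (n_channels, 2 * n_components)")
        if n_comp and np.linalg.matrix_rank(self.mixing) < min(self.mixing.shape):
            raise ValueError("mixing matrix must be full rank")


@dataclass
class Cohort:
    """A generated subject cohort with linked resting/imagery data."""

    subjects: list[SubjectSpec]
    types: list[str]
    recordings: list[Recording]
    trial_sets: list[TrialSet] | None
    performance: np.ndarray


def _source_gains(channels: list[str], source_channel: str) -> np.ndarray:
    """Geometric projection of a source under ``source_channel`` onto the cap."""
    sr, sc = channel_position(source_channel)
    gains = np.empty(len(channels))
    for i, ch in enumerate(channels):
        r, c = channel_position(ch)
        d2 = (r - sr) ** 2 + (c - sc) ** 2
        gains[i] = np.exp(-d2 / (2 * _SOURCE_SPREAD ** 2))
    return gains


def _default_mixing(channels: list[str], n_components: int) -> np.ndarray:
    left = _source_gains(channels, "C3")
    right = _source_gains(channels, "C4")
    cols = []
    for _ in range(n_components):
        cols.extend([left, right])
    return np.column_stack(cols) if cols else np.empty((len(channels), 0))


def default_subject(
    rhythms: list[tuple[float, float, float]] | None = None,
    noise: tuple[float, float, float] = (0.5, 20.0, 1.2),
    erd: float | np.ndarray = 0.8,
    n_channels: int = 16,
    true_performance: float = float("nan"),
    seed: int = 0,
) -> SubjectSpec:
    """A subject on the standard virtual cap (16 motor channels or 3).

    Defaults to a single mu rhythm at 12 Hz of width 1 Hz (discriminative
    band roughly 10-14 Hz, peak 2 uV^2/Hz above the ~1.5 uV^2/Hz floor)
    with strong bilateral ERD.
    """
    if rhythms is None:
        rhythms = [(12.0, 1.0, 2.0)]
    if n_channels == 16:
        channels = list(_CENTERS_16)
    elif n_channels == 3:
        channels = list(_CHANNELS_3)
    else:
        raise ValueError("supported channel counts: 3, 16")
    erd_arr = np.asarray(erd, dtype=float)
    if erd_arr.ndim == 0:
        erd_arr = np.full((2, len(rhythms)), float(erd_arr))
    return SubjectSpec(rhythms=rhythms, noise=noise, erd=erd_arr,
                       mixing=_default_mixing(channels, len(rhythms)),
                       channels=channels, true_performance=true_performance,
                       seed=seed)


def _shaped_noise(target_psd, n: int, fs: float,
                  rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Gaussian noise whose expected one-sided PSD is ``target_psd(f)``.

    ``target_psd`` maps a frequency array (Hz) to uV^2/Hz.  Frequencies
    below half the spectral resolution are clamped to keep 1/f targets
    finite at DC.  Returns ``(size, n)``.
    """
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    f_eval = np.maximum(freqs, 0.5 * fs / n)
    scale = np.sqrt(np.maximum(target_psd(f_eval), 0.0) * fs * n / 2.0)
    re = rng.standard_normal((size, len(freqs)))
    im = rng.standard_normal((size, len(freqs)))
    spec = (re + 1j * im) / np.sqrt(2.0) * scale
    spec[:, 0] = re[:, 0] * scale[0]  # DC real
    if n % 2 == 0:
        spec[:, -1] = re[:, -1] * scale[-1]  # Nyquist real
    return np.fft.irfft(spec, n=n, axis=-1)


def _background_psd(noise: tuple[float, float, float]):
    k1, k2, lam = noise
    return lambda f: k1 + k2 / f ** lam


def _rhythm_psd(center: float, width: float, amp: float):
    return lambda f: amp * np.exp(-0.5 * ((f - center) / width) ** 2)


def _render(spec: SubjectSpec, n: int, fs: float, rng: np.random.Generator,
            source_scale: np.ndarray | None = None,
            channel_scale: np.ndarray | None = None) -> np.ndarray:
    """One segment: per-channel 1/f floor + mixed rhythm sources."""
    n_ch = len(spec.channels)
    data = _shaped_noise(_background_psd(spec.noise), n, fs, rng, size=n_ch)
    if channel_scale is not None:
        data *= channel_scale[:, None]
    if spec.rhythms:
        sources = np.empty((2 * len(spec.rhythms), n))
        for k, (center, width, amp) in enumerate(spec.rhythms):
            sources[2 * k:2 * k + 2] = _shaped_noise(
                _rhythm_psd(center, width, amp), n, fs, rng, size=2)
        if source_scale is not None:
            sources *= source_scale[:, None]
        data += spec.mixing @ sources
    return data


def gen_resting(spec: SubjectSpec, duration: float = 150.0, fs: float = 100.0
                ) -> Recording:
    """Resting-state recording: floor plus full-amplitude rhythm sources.

    Defaults emulate the pooled resting protocol (10 periods of 15 s at the
    100 Hz preprocessed rate).
    """
    if duration < 10:
        raise ValueError("at least 10 s of resting data required")
    rng = np.random.default_rng(spec.seed)
    n = int(round(duration * fs))
    data = _render(spec, n, fs, rng)
    return Recording(list(spec.channels), fs, data)


def gen_motor_imagery(spec: SubjectSpec, n_trials_per_class: int = 75,
                      fs: float = 100.0, trial_s: float = 4.0,
                      bg_jitter: float = 0.4,
                      rhythm_jitter: float = 0.3) -> TrialSet:
    """Two-class imagery trials with contralateral ERD.

    During a left-hand trial the right-hemisphere source of component k is
    attenuated in amplitude by ``1 - erd[0, k]`` (and symmetrically for
    right-hand trials).  Labels are balanced and pseudo-randomly ordered
    under the subject seed.  Defaults follow the 4 s imagery window and the
    75-trial-per-class session structure.

    Trial-to-trial power non-stationarity, a defining feature of real EEG,
    is modelled by lognormal amplitude jitter: each trial draws an
    independent background scale per channel (sigma ``bg_jitter`` in log
    amplitude) and a scale per rhythm source (sigma ``rhythm_jitter``).
    Without it, broadband variance features would be implausibly stable
    across trials and frequency-band selection would carry no information.
    """
    if n_trials_per_class < 2:
        raise ValueError("at least 2 trials per class required")
    rng = np.random.default_rng(spec.seed + 1)
    n = int(round(trial_s * fs))
    labels = np.array(["L", "R"] * n_trials_per_class)
    rng.shuffle(labels)
    n_src = 2 * len(spec.rhythms)
    n_ch = len(spec.channels)
    trials = np.empty((len(labels), n_ch, n))
    for t, lab in enumerate(labels):
        scale = np.exp(rng.normal(0.0, rhythm_jitter, n_src))
        for k in range(len(spec.rhythms)):
            if lab == "L":
                scale[2 * k + 1] *= 1.0 - spec.erd[0, k]  # right hemisphere
            else:
                scale[2 * k] *= 1.0 - spec.erd[1, k]      # left hemisphere
        ch_scale = np.exp(rng.normal(0.0, bg_jitter, n_ch))
        trials[t] = _render(spec, n, fs, rng, source_scale=scale,
                            channel_scale=ch_scale)
    return TrialSet(trials, labels, fs, list(spec.channels))


# Cohort typology: parameter distributions per subject type.  Amplitudes in
# uV^2/Hz (peak spectral density above the floor), ERD depths dimensionless.
_TYPE_PARAMS = {
    "mu": dict(center=(10.0, 0.8, 8.0, 12.0), width=(0.8, 1.4),
               amp=(5.0, 15.0), erd=(0.6, 0.9)),
    "beta": dict(center=(19.0, 1.0, 16.0, 22.0), width=(1.2, 2.0),
                 amp=(2.0, 7.0), erd=(0.5, 0.8)),
    "flat": dict(center=(10.0, 1.5, 8.0, 12.0), width=(0.8, 1.4),
                 amp=(0.0, 0.5), erd=(0.0, 0.3)),
}

# Logistic link from modulated rhythm power to imagery accuracy:
# accuracy = 0.5 + 0.45 * sigmoid((sqrt(amp * erd) - _PERF_MID) / _PERF_SCALE),
# calibrated so the type means land near 0.9 (mu), 0.8 (beta), 0.55 (flat).
_PERF_MID = 1.46
_PERF_SCALE = 0.61


def _draw_subject(sub_type: str, rng: np.random.Generator, n_channels: int,
                  perf_noise: float, seed: int) -> SubjectSpec:
    p = _TYPE_PARAMS[sub_type]
    mu, sd, lo, hi = p["center"]
    center = float(np.clip(rng.normal(mu, sd), lo, hi))
    width = float(rng.uniform(*p["width"]))
    amp = float(rng.uniform(*p["amp"]))
    erd = float(rng.uniform(*p["erd"]))
    noise = (float(rng.uniform(0.3, 0.8)), float(rng.uniform(10.0, 30.0)),
             float(rng.uniform(0.8, 1.6)))
    spec = default_subject(rhythms=[(center, width, amp)], noise=noise,
                           erd=erd, n_channels=n_channels, seed=seed)
    strength = np.sqrt(amp * erd)
    clean = 0.5 + 0.45 / (1.0 + np.exp(-(strength - _PERF_MID) / _PERF_SCALE))
    spec.true_performance = float(np.clip(clean + rng.normal(0, perf_noise), 0.0, 1.0))
    return spec


def gen_cohort(n_subjects: int = 80,
               type_mixture: tuple[float, float, float] = (0.5, 0.3, 0.2),
               seed: int = 0, perf_noise: float = 0.05, n_channels: int = 16,
               resting_duration: float = 150.0, with_imagery: bool = False,
               n_trials_per_class: int = 75) -> Cohort:
    """Generate a linked cohort of mu-type, beta-type and flat subjects.

    ``type_mixture`` gives the (mu, beta, flat) proportions.  Each subject's
    true imagery performance is a logistic function of total rhythm
    amplitude x ERD depth plus Gaussian noise — so resting spectra (which
    expose the amplitude) statistically predict performance, the structure
    the cluster-regression predictor assumes.  Imagery trial sets are
    generated on request (``with_imagery``); resting recordings always.
    """
    if n_subjects < 3:
        raise ValueError("at least 3 subjects required")
    if abs(sum(type_mixture) - 1.0) > 1e-9:
        raise ValueError("type mixture proportions must sum to 1")
    rng = np.random.default_rng(seed)
    types = list(rng.choice(["mu", "beta", "flat"], size=n_subjects,
                            p=list(type_mixture)))
    subjects, recordings, trial_sets = [], [], [] if with_imagery else None
    for i, t in enumerate(types):
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        spec = _draw_subject(t, rng, n_channels, perf_noise, sub_seed)
        subjects.append(spec)
        recordings.append(gen_resting(spec, resting_duration))
        if with_imagery:
            trial_sets.append(gen_motor_imagery(spec, n_trials_per_class))
    performance = np.array([s.true_performance for s in subjects])
    return Cohort(subjects=subjects, types=types, recordings=recordings,
                  trial_sets=trial_sets, performance=performance)
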