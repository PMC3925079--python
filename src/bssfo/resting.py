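"""Unsupervised spectral characterization of resting-state EEG.

From two minutes of task-free EEG, the pipeline derives a subject-specific
frequency profile that predicts later sensorimotor-rhythm BCI performance:

1. Welch PSD per channel on a 0.5 Hz grid from 2 to 34 Hz (covering the mu
   8-12 Hz and beta 16-22 Hz rhythms).
2. A 1/f background model ``g(f) = k1 + k2 / f**lambda`` fitted to each PSD
   on grid points outside the rhythm bands.
3. The frequency-related information (FRI) ``S(f) = psd(f) - g(f)`` — the
   rhythm power standing above the noise floor (kept unclipped, possibly
   negative).
4. A likelihood over frequency bands: the band-mean of the positive FRI,
   summed over channels; normalized to a 2-D band pdf and reduced to a 1-D
   profile by the same membership-sum / uniform-subtraction rule used for
   the task posterior.
5. A subject weight ``eta`` (sum over channels of the peak positive FRI)
   restoring absolute power scale, and the mu/beta Gaussian-mixture
   frequency weight, giving the final unnormalized predictor profile
   ``Xi(f) = eta * weight(f) * pdf1d(f)``.

A subject whose PSD equals the fitted background exactly has zero FRI
everywhere, a uniform band pdf, an identically-zero 1-D profile and
``eta = 0`` — no spectral evidence of controllable rhythms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .core import Pdf1D, Pdf2D, frequency_grid, frequency_weight
from .io import Recording

logger = logging.getLogger(__name__)

__all__ = [
    "RestingConfig",
    "SpectralProfile",
    "SubjectSpectrum",
    "psd_estimate",
    "fit_noise_model",
    "noise_model",
    "fri_compute",
    "band_likelihood",
    "normalize_pdf2d",
    "pdf1d_rest",
    "subject_weight",
    "weighted_subject_pdf",
    "analyze_resting",
]

#: Grid points within these bands are excluded from the background fit so
#: that mu/beta peaks do not bias the floor estimate.
DEFAULT_EXCLUDE = ((7.0, 14.0), (15.0, 25.0))

#: Positive-FRI values below this fraction of max(psd) are treated as zero
#: (numerical residue of the fit, not rhythm power).
FRI_REL_TOL = 1e-9


@dataclass
class RestingConfig:
    f_min: float = 2.0
    f_max: float = 34.0
    exclude_bands: tuple[tuple[float, float], ...] = DEFAULT_EXCLUDE
    welch_seconds: float = 2.0
    mixture: list[tuple[float, float, float]] | None = None  # None -> mu/beta default
    eta_source: str = "fri"  # "fri" or "psd"


@dataclass
class SpectralProfile:
    """Per-channel PSD, fitted background and FRI on the analysis grid."""

    channel: str
    grid: np.ndarray
    psd: np.ndarray
    noise_params: tuple[float, float, float]  # (k1, k2, lambda)
    fri: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        self.fri = np.asarray(self.fri, dtype=float)
        if np.any(self.psd < 0):
            raise ValueError("PSD must be non-negative")
        if self.psd.shape != self.grid.shape or self.fri.shape != self.grid.shape:
            raise ValueError("psd/fri must match the grid")


@dataclass
class SubjectSpectrum:
    """Complete resting-state characterization of one subject."""

    profiles: list[SpectralProfile]
    likelihood: np.ndarray       # (n_grid, n_grid), start x end
    pdf2d: Pdf2D
    pdf1d: Pdf1D
    eta: float
    xi: Pdf1D
    flags: dict = field(default_factory=dict)

    @property
    def grid(self) -> np.ndarray:
        return self.profiles[0].grid


def noise_model(f: np.ndarray, k1: float, k2: float, lam: float) -> np.ndarray:
    """1/f EEG background: ``g(f) = k1 + k2 / f**lambda``."""
    return k1 + k2 / np.asarray(f, dtype=float) ** lam


def psd_estimate(rec: Recording, grid: np.ndarray | None = None,
                 welch_seconds: float = 2.0) -> np.ndarray:
    """Welch PSD of every channel evaluated on the analysis grid.

    Hann windows of ``welch_seconds`` (native 0.5 Hz resolution at 2 s),
    50% overlap, all segments pooled.  Returns ``(n_channels, n_grid)`` in
    microvolt^2 / Hz.
    """
    if grid is None:
        grid = frequency_grid(2.0, 34.0)
    nper = int(round(welch_seconds * rec.fs))
    if rec.n_samples < 2 * nper:
        raise ValueError(f"recording too short: need >= {2 * welch_seconds} s")
    if rec.fs < 2 * grid[-1]:
        raise ValueError("sampling rate below twice the top grid frequency")
    freqs, psd = signal.welch(rec.data, fs=rec.fs, nperseg=nper,
                              noverlap=nper // 2, axis=-1)
    cols = np.argmin(np.abs(freqs[None, :] - grid[:, None]), axis=1)
    if np.max(np.abs(freqs[cols] - grid)) > 0.25:
        raise ValueError("Welch resolution too coarse for the 0.5 Hz grid")
    return psd[:, cols]


def _profile_fit(psd: np.ndarray, f: np.ndarray, lam: float) -> tuple[float, float, float]:
    """Best (k1, k2 >= 0) for fixed lambda, and the residual SSE."""
    a = np.column_stack([np.ones_like(f), f ** (-lam)])
    coef, *_ = np.linalg.lstsq(a, psd, rcond=None)
    if coef[1] < 0:
        coef = np.array([psd.mean(), 0.0])
    resid = psd - a @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def fit_noise_model(psd: np.ndarray, grid: np.ndarray,
                    exclude_bands: tuple[tuple[float, float], ...] = DEFAULT_EXCLUDE,
                    ) -> tuple[float, float, float]:
    """Least-squares fit of the 1/f background to a single-channel PSD.

    Grid points inside ``exclude_bands`` (rhythm bands by default) are
    ignored so spectral peaks do not bias the floor.  ``k2 >= 0`` and
    ``lambda in [0.1, 3]`` are enforced.  The exponent is profiled: for each
    candidate lambda the (k1, k2) pair is a linear solve; a coarse lambda
    grid seeds a bounded refinement.
    """
    psd = np.asarray(psd, dtype=float)
    grid = np.asarray(grid, dtype=float)
    keep = np.ones(len(grid), dtype=bool)
    for lo, hi in exclude_bands:
        keep &= ~((grid >= lo) & (grid <= hi))
    if keep.sum() < 5:
        raise ValueError("fewer than 5 grid points outside the excluded bands")
    f, y = grid[keep], psd[keep]

    if np.ptp(y) < 1e-15 * max(1.0, np.max(np.abs(y))):
        logger.warning("flat PSD: background exponent non-identifiable")
        return float(y.mean()), 0.0, 1.0

    lams = np.linspace(0.1, 3.0, 59)
    sses = [_profile_fit(y, f, l)[2] for l in lams]
    lam0 = lams[int(np.argmin(sses))]
    k1_0, k2_0, _ = _profile_fit(y, f, lam0)

    def residual(theta):
        k1, k2, lam = theta
        return noise_model(f, k1, k2, lam) - y

    try:
        res = optimize.least_squares(
            residual, x0=[k1_0, max(k2_0, 1e-12), lam0],
            bounds=([-np.inf, 0.0, 0.1], [np.inf, np.inf, 3.0]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        k1, k2, lam = res.x
    except Exception:  # pragma: no cover - extremely pathological inputs
        logger.warning("background fit failed to converge; lambda=1 fallback used")
        k1, k2, _ = _profile_fit(y, f, 1.0)
        lam = 1.0
    return float(k1), float(k2), float(lam)


def fri_compute(psd: np.ndarray, grid: np.ndarray,
                noise_params: tuple[float, float, float]) -> np.ndarray:
    """Frequency-related information: PSD minus fitted background, unclipped."""
    return np.asarray(psd, dtype=float) - noise_model(grid, *noise_params)


def _positive_fri(profile: SpectralProfile) -> np.ndarray:
    floor = FRI_REL_TOL * max(float(profile.psd.max()), 1e-300)
    return np.where(profile.fri > floor, profile.fri, 0.0)


def band_likelihood(profiles: list[SpectralProfile]) -> tuple[np.ndarray, bool]:
    """Channel-summed band likelihood matrix L[s, e].

    Per channel, the likelihood of band [b_s, b_e] is the mean positive FRI
    over the grid points the band covers; channels combine additively.
    Entries with b_s >= b_e are zero.  Returns ``(L, informative)`` where
    ``informative`` is False when every channel's FRI is non-positive.
    """
    grid = profiles[0].grid
    n = len(grid)
    pos = np.zeros(n)
    for p in profiles:
        if p.grid.shape != grid.shape or np.any(p.grid != grid):
            raise ValueError("all profiles must share one grid")
        pos += _positive_fri(p)
    # cumulative band sums: sum over f in [grid[i], grid[j]] of pos
    csum = np.concatenate([[0.0], np.cumsum(pos)])
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    width = (j - i + 1).astype(float)
    with np.errstate(invalid="ignore"):
        L = (csum[j + 1] - csum[i]) / width
    L = np.where(i < j, L, 0.0)
    informative = bool(np.any(pos > 0))
    if not informative:
        logger.warning("no positive rhythm power in any channel; "
                       "likelihood is identically zero")
    return L, informative


def normalize_pdf2d(L: np.ndarray, grid: np.ndarray) -> Pdf2D:
    """Band pdf = L / sum(L); uniform over valid cells when L is all-zero."""
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("likelihood must be non-negative")
    valid = grid[:, None] < grid[None, :]
    total = L[valid].sum()
    if total > 0:
        mass = np.where(valid, L / total, 0.0)
    else:
        mass = np.where(valid, 1.0 / valid.sum(), 0.0)
    return Pdf2D(grid, mass)


def pdf1d_rest(pdf2d: Pdf2D) -> Pdf1D:
    """1-D profile of the band pdf (membership sum, uniform subtracted)."""
    from .core import pdf_1d

    return pdf_1d(pdf2d)


def subject_weight(profiles: list[SpectralProfile], source: str = "fri") -> float:
    """Subject weight eta: channel sum of peak power.

    With ``source="fri"`` (default) the peak of the positive FRI is used so
    the 1/f floor does not inflate the weight; ``source="psd"`` uses the raw
    PSD maximum.
    """
    if not profiles:
        raise ValueError("at least one profile required")
    if source == "fri":
        return float(sum(_positive_fri(p).max() for p in profiles))
    if source == "psd":
        return float(sum(p.psd.max() for p in profiles))
    raise ValueError(f"unknown eta source {source!r}")


def weighted_subject_pdf(pdf1d: Pdf1D, eta: float,
                         mixture: list[tuple[float, float, float]] | None = None
                         ) -> Pdf1D:
    """Final predictor profile Xi = eta * frequency_weight * pdf1d.

    Deliberately unnormalized: eta carries the absolute spectral power that
    normalization removed, making profiles comparable across subjects.
    """
    w = frequency_weight(pdf1d.grid, mixture)
    return Pdf1D(pdf1d.grid, eta * w * pdf1d.values)


def analyze_resting(rec: Recording, config: RestingConfig | None = None
                    ) -> SubjectSpectrum:
    """Full resting-state pipeline: Recording -> SubjectSpectrum."""
    cfg = config or RestingConfig()
    grid = frequency_grid(cfg.f_min, cfg.f_max)
    psd = psd_estimate(rec, grid, cfg.welch_seconds)
    profiles = []
    for ch, p in zip(rec.channels, psd):
        params = fit_noise_model(p, grid, cfg.exclude_bands)
        profiles.append(SpectralProfile(ch, grid, p, params,
                                        fri_compute(p, grid, params)))
    L, informative = band_likelihood(profiles)
    p2 = normalize_pdf2d(L, grid)
    p1 = pdf1d_rest(p2)
    if not informative:
        p1 = Pdf1D(grid, np.zeros_like(grid))
    eta = subject_weight(profiles, cfg.eta_source)
    xi = weighted_subject_pdf(p1, eta, cfg.mixture)
    return SubjectSpectrum(profiles=profiles, likelihood=L, pdf2d=p2, pdf1d=p1,
                           eta=eta, xi=xi, flags={"informative": informative})
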