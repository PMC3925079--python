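"""Band-pass + CSP + LDA decoding pipeline and fixed-band baselines.

The standard sensorimotor-rhythm decoding chain: zero-phase band-pass
filtering of the epoched trials, common spatial patterns (CSP) estimated
from class-conditional covariance matrices, log-variance features of the
spatially filtered signals, and linear discriminant analysis (LDA).
Evaluation uses chronological cross-validation: trials are split into
contiguous blocks in recording order, so the temporal structure of the
session is preserved and the estimate is conservative.

CSP solves the generalized eigenproblem ``S1 w = lam (S1 + S2) w`` where
``S_c`` is the class-c mean of trace-normalized per-trial covariances.  The
eigenvalues ``lam`` lie in [0, 1]; eigenvectors with extreme eigenvalues
maximize the variance ratio between classes.  Retained filters satisfy
``W.T (S1 + S2) W = I``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg, signal

from .io import TrialSet

logger = logging.getLogger(__name__)

__all__ = [
    "Band",
    "SpatialFilterSet",
    "LdaModel",
    "bandpass",
    "trial_covariances",
    "class_covariances",
    "csp_fit",
    "csp_from_covariances",
    "logvar_features",
    "lda_fit",
    "lda_predict",
    "lda_score",
    "chrono_cv_split",
    "fixed_band_pipeline",
    "heuristic_band",
    "BROAD_BAND",
    "MU_BAND",
    "BETA_BAND",
]

_VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class Band:
    """A frequency band [b_s, b_e] in Hz with b_s < b_e."""

    b_s: float
    b_e: float

    def __post_init__(self) -> None:
        if not self.b_s < self.b_e:
            raise ValueError(f"band start {self.b_s} must be below end {self.b_e}")

    @property
    def center(self) -> float:
        return 0.5 * (self.b_s + self.b_e)

    @property
    def width(self) -> float:
        return self.b_e - self.b_s


BROAD_BAND = Band(5.0, 30.0)
MU_BAND = Band(8.0, 12.0)
BETA_BAND = Band(16.0, 22.0)


@dataclass
class SpatialFilterSet:
    """CSP filters, column-wise, with their discriminability eigenvalues."""

    W: np.ndarray           # (n_channels, 2m)
    eigenvalues: np.ndarray  # (2m,), descending, in [0, 1]
    m: int
    classes: np.ndarray | None = None


@dataclass
class LdaModel:
    """Fisher discriminant with pooled covariance and equal priors."""

    weights: np.ndarray
    bias: float
    classes: np.ndarray  # sorted; score > 0 -> classes[1]


def bandpass(trials: TrialSet, band: Band, order: int = 5) -> TrialSet:
    """Zero-phase Butterworth band-pass of every trial and channel."""
    nyq = trials.fs / 2.0
    if band.b_e >= nyq:
        raise ValueError(f"band end {band.b_e} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, [band.b_s, band.b_e], btype="band",
                        fs=trials.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, trials.trials, axis=-1)
    return TrialSet(filtered, trials.labels, trials.fs, list(trials.channels),
                    trials.order.copy())


def trial_covariances(trials: np.ndarray) -> np.ndarray:
    """Per-trial sample covariance over time, (n_trials, n_ch, n_ch)."""
    x = trials - trials.mean(axis=-1, keepdims=True)
    return np.einsum("tcs,tds->tcd", x, x) / trials.shape[-1]


def class_covariances(trials: TrialSet, covs: np.ndarray | None = None
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Class-mean trace-normalized covariances (S1, S2) and sorted classes."""
    classes = np.unique(trials.labels)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes!r}")
    if covs is None:
        covs = trial_covariances(trials.trials)
    tr = np.trace(covs, axis1=1, axis2=2)
    tr = np.where(tr <= 0, 1.0, tr)
    normed = covs / tr[:, None, None]
    s1 = normed[trials.labels == classes[0]].mean(axis=0)
    s2 = normed[trials.labels == classes[1]].mean(axis=0)
    return s1, s2, classes


def _shrink(sigma: np.ndarray, cond_max: float = 1e10) -> np.ndarray:
    """Shrink toward scaled identity until acceptably conditioned."""
    n = sigma.shape[0]
    tr = np.trace(sigma)
    # a zero matrix (e.g. duplicated feature vectors) shrinks to the identity
    target = (tr / n if tr > 0 else 1.0) * np.eye(n)
    alpha = 0.0
    out = sigma
    while alpha < 1.0:
        try:
            cond = np.linalg.cond(out)
        except np.linalg.LinAlgError:
            cond = np.inf
        if np.isfinite(cond) and cond < cond_max:
            break
        alpha = 1e-8 if alpha == 0.0 else alpha * 10
        out = (1 - alpha) * sigma + alpha * target
    if alpha > 0:
        logger.warning("covariance ill-conditioned; shrinkage alpha=%g applied", alpha)
    return out


def csp_from_covariances(s1: np.ndarray, s2: np.ndarray, m: int,
                         classes: np.ndarray | None = None) -> SpatialFilterSet:
    """CSP filters from two class covariance matrices."""
    n = s1.shape[0]
    if 2 * m > n:
        raise ValueError(f"{2 * m} filters requested from {n} channels")
    comp = _shrink(s1 + s2)
    lam, vec = linalg.eigh(s1, comp)  # vec.T @ comp @ vec = I
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    keep = np.r_[np.arange(m), np.arange(n - m, n)]
    return SpatialFilterSet(W=vec[:, keep], eigenvalues=np.clip(lam[keep], 0.0, 1.0),
                            m=m, classes=classes)


def csp_fit(trials: TrialSet, m: int = 2) -> SpatialFilterSet:
    """Fit CSP spatial filters on a two-class trial set.

    Returns the ``m`` most class-1-dominant and ``m`` most class-2-dominant
    filters (eigenvalues sorted descending).
    """
    s1, s2, classes = class_covariances(trials)
    return csp_from_covariances(s1, s2, m, classes)


def logvar_features(trials: TrialSet, filters: SpatialFilterSet) -> np.ndarray:
    """Log-variance of each spatially filtered trial, (n_trials, 2m)."""
    if filters.W.shape[0] != trials.trials.shape[1]:
        raise ValueError("filter channel dimension does not match trials")
    covs = trial_covariances(trials.trials)
    var = np.einsum("cf,tcd,df->tf", filters.W, covs, filters.W)
    if np.any(var <= _VAR_FLOOR):
        logger.warning("zero-variance projection floored at %g", _VAR_FLOOR)
        var = np.maximum(var, _VAR_FLOOR)
    return np.log(var)


def lda_fit(features: np.ndarray, labels: np.ndarray) -> LdaModel:
    """Fisher LDA with pooled covariance and equal priors."""
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes!r}")
    x0 = features[labels == classes[0]]
    x1 = features[labels == classes[1]]
    mu0, mu1 = x0.mean(axis=0), x1.mean(axis=0)
    n0, n1 = len(x0), len(x1)
    pooled = (np.atleast_2d(np.cov(x0.T, bias=True)) * n0
              + np.atleast_2d(np.cov(x1.T, bias=True)) * n1) / (n0 + n1)
    pooled = _shrink(pooled)
    w = np.linalg.solve(pooled, mu1 - mu0)
    bias = -float(w @ (mu0 + mu1) / 2.0)
    return LdaModel(weights=w, bias=bias, classes=classes)


def lda_score(model: LdaModel, features: np.ndarray) -> np.ndarray:
    features = np.atleast_2d(features)
    if features.shape[1] != len(model.weights):
        raise ValueError("feature dimension does not match model")
    return features @ model.weights + model.bias


def lda_predict(model: LdaModel, features: np.ndarray) -> np.ndarray:
    """Predicted labels; a score of exactly 0 goes to the first sorted label."""
    score = lda_score(model, features)
    return np.where(score > 0, model.classes[1], model.classes[0])


def chrono_cv_split(n_trials: int, k: int = 8) -> list[tuple[np.ndarray, np.ndarray]]:
    """Contiguous chronological k-fold split.

    Trials are partitioned into ``k`` contiguous blocks (remainder trials go
    to the earliest blocks); each block is the test set once.
    """
    if k < 2:
        raise ValueError("at least 2 folds required")
    if k > n_trials:
        raise ValueError(f"{k} folds requested for {n_trials} trials")
    base, rem = divmod(n_trials, k)
    sizes = [base + (1 if i < rem else 0) for i in range(k)]
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    folds = []
    for i in range(k):
        test = np.arange(bounds[i], bounds[i + 1])
        train = np.concatenate([np.arange(0, bounds[i]),
                                np.arange(bounds[i + 1], n_trials)])
        folds.append((train, test))
    return folds


def _cv_error(banded: TrialSet, m: int, folds: int) -> float:
    """Mean 0-1 loss over chronological folds of CSP->logvar->LDA."""
    covs = trial_covariances(banded.trials)
    errors = []
    for train, test in chrono_cv_split(banded.n_trials, folds):
        train_labels = banded.labels[train]
        if len(np.unique(train_labels)) < 2:
            logger.warning("fold skipped: single class in training block")
            continue
        sub = banded.subset(train)
        s1, s2, classes = class_covariances(sub, covs[train])
        m_eff = min(m, sub.trials.shape[1] // 2)
        filt = csp_from_covariances(s1, s2, m_eff, classes)
        feat_tr = np.log(np.maximum(
            np.einsum("cf,tcd,df->tf", filt.W, covs[train], filt.W), _VAR_FLOOR))
        feat_te = np.log(np.maximum(
            np.einsum("cf,tcd,df->tf", filt.W, covs[test], filt.W), _VAR_FLOOR))
        model = lda_fit(feat_tr, train_labels)
        pred = lda_predict(model, feat_te)
        errors.append(np.mean(pred != banded.labels[test]))
    if not errors:
        raise ValueError("no usable folds")
    return float(np.mean(errors))


def fixed_band_pipeline(trials: TrialSet, band: Band, m: int = 2,
                        folds: int = 8) -> float:
    """Chronological-CV error of the fixed-band CSP+LDA baseline."""
    banded = bandpass(trials, band)
    return _cv_error(banded, m, folds)


def heuristic_band(trials: TrialSet, f_lo: float = 5.0, f_hi: float = 35.0,
                   step: float = 0.5, threshold: float = 0.05) -> Band:
    """Data-driven band selection from band-power/label correlations.

    Per-trial log band-power is computed on a ``step``-Hz grid for every
    channel; at each frequency the score is the maximum over channels of the
    absolute Pearson correlation between log power and the class labels.
    The band grows outward from the peak-score frequency one grid step at a
    time while the boundary score stays above ``threshold`` (5%) of the
    maximum score.
    """
    grid = np.arange(f_lo, f_hi + step / 2, step)
    nper = int(round(trials.fs / step))
    nper = min(nper, trials.trials.shape[-1])
    freqs, psd = signal.welch(trials.trials, fs=trials.fs, nperseg=nper,
                              noverlap=nper // 2, axis=-1)
    cols = np.argmin(np.abs(freqs[None, :] - grid[:, None]), axis=1)
    logp = np.log(np.maximum(psd[:, :, cols], _VAR_FLOOR))  # (trial, ch, freq)
    classes = np.unique(trials.labels)
    y = np.where(trials.labels == classes[-1], 1.0, -1.0)
    yc = y - y.mean()
    xc = logp - logp.mean(axis=0)
    denom = np.sqrt((xc ** 2).sum(axis=0) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.einsum("tcf,t->cf", xc, yc) / denom
    corr = np.nan_to_num(corr)
    score = np.abs(corr).max(axis=0)  # (freq,)
    if np.all(score == 0):
        logger.warning("all band-power/label correlations zero; default mu band used")
        return Band(8.0, 12.0)
    return _expand_band(score, grid, step, threshold)


def _expand_band(score: np.ndarray, grid: np.ndarray, step: float,
                 threshold: float) -> Band:
    """Grow a band outward from the peak score while the boundary score
    stays strictly above ``threshold`` of the maximum."""
    peak = int(np.argmax(score))
    cut = threshold * score[peak]
    lo = peak
    while lo - 1 >= 0 and score[lo - 1] > cut:
        lo -= 1
    hi = peak
    while hi + 1 < len(grid) and score[hi + 1] > cut:
        hi += 1
    b_s, b_e = grid[lo], grid[hi]
    if b_s == b_e:  # single-cell band: one grid cell around the peak
        b_s, b_e = b_s - step / 2, b_e + step / 2
    return Band(float(b_s), float(b_e))
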