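"""Cluster-based linear regression from resting spectra to BCI performance.

Each subject is summarized by an augmented feature vector: the values of
the weighted resting profile Xi on the frequency grid, its area under the
curve, and the subject weight eta.  Features are z-scored across the cohort
(so the two scalar entries are not swamped by the grid values) and reduced
by PCA.  Subjects are grouped by Ward hierarchical clustering in the
reduced space; a subject's predictor vector is its Euclidean distance to
every cluster center, and ordinary least squares maps these distance
vectors to the observed motor-imagery accuracies.  A new subject is
projected, measured against the centers and scored by the fitted linear
model — performance predicted from two minutes of resting EEG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import pearsonr
from sklearn.decomposition import PCA

from .core import auc_of_pdf
from .resting import SubjectSpectrum

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectFeature",
    "PredictorModel",
    "build_features",
    "ward_cluster",
    "distance_vector",
    "fit_regression",
    "train_predictor",
    "predict_performance",
    "loo_predictions",
    "sweep_cluster_count",
    "pearson",
]


@dataclass
class SubjectFeature:
    """Augmented and PCA-reduced feature vectors of one subject."""

    subject: int | str
    augmented: np.ndarray  # [Xi grid values, AUC(Xi), eta]
    reduced: np.ndarray


@dataclass
class _FeatureTransform:
    """Cohort z-scoring + PCA projection, frozen at training time."""

    mean: np.ndarray        # z-score center per augmented coordinate
    std: np.ndarray         # z-score scale per augmented coordinate
    center: np.ndarray      # PCA center in z-space
    components: np.ndarray  # (n_components, n_features) projection rows

    def project(self, augmented: np.ndarray) -> np.ndarray:
        z = (augmented - self.mean) / self.std
        return (z - self.center) @ self.components.T


@dataclass
class PredictorModel:
    """Serialized performance predictor: projection, centers, regression."""

    transform: _FeatureTransform
    centers: np.ndarray      # (K, reduced_dim)
    assignments: np.ndarray  # training cluster labels, 0-based
    w: np.ndarray            # (K,)
    epsilon: float
    K: int
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))


def _augment(spectrum: SubjectSpectrum) -> np.ndarray:
    return np.concatenate([spectrum.xi.values,
                           [auc_of_pdf(spectrum.xi), spectrum.eta]])


def build_features(cohort: list[SubjectSpectrum], explained: float = 0.95
                   ) -> tuple[list[SubjectFeature], _FeatureTransform]:
    """Assemble augmented vectors, z-score across the cohort, fit PCA.

    Components are retained up to ``explained`` (95%) cumulative variance,
    capped at ``n_subjects - 1``.
    """
    if len(cohort) < 2:
        raise ValueError("at least 2 subjects required")
    grid0 = cohort[0].grid
    for s in cohort[1:]:
        if s.grid.shape != grid0.shape or np.any(s.grid != grid0):
            raise ValueError("all subjects must share one frequency grid")
    aug = np.array([_augment(s) for s in cohort])
    mean = aug.mean(axis=0)
    std = aug.std(axis=0)
    std = np.where(std > 0, std, 1.0)  # constant coordinates carry no signal
    z = (aug - mean) / std
    n_max = min(len(cohort) - 1, aug.shape[1])
    pca = PCA(n_components=n_max, svd_solver="full").fit(z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_keep = int(np.searchsorted(cum, explained) + 1) if cum.size else 1
    n_keep = min(n_keep, n_max)
    pca = PCA(n_components=n_keep, svd_solver="full").fit(z)
    transform = _FeatureTransform(mean=mean, std=std, center=pca.mean_,
                                  components=pca.components_)
    reduced = pca.transform(z)
    feats = [SubjectFeature(i, a, r) for i, (a, r) in enumerate(zip(aug, reduced))]
    return feats, transform


def ward_cluster(vectors: np.ndarray, K: int) -> tuple[np.ndarray, np.ndarray]:
    """Ward agglomerative clustering cut at K clusters.

    Merges minimize the increase in total within-cluster squared Euclidean
    distance.  Returns 0-based labels and the member-mean centers, ordered
    by first appearance in the data.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    n = len(vectors)
    if not 1 <= K <= n:
        raise ValueError(f"K={K} invalid for {n} vectors")
    if K == n:
        return np.arange(n), vectors.copy()
    Z = linkage(vectors, method="ward")
    raw = fcluster(Z, t=K, criterion="maxclust")
    # relabel by first appearance so labels are deterministic in data order
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for idx, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = len(relabel)
        labels[idx] = relabel[r]
    centers = np.array([vectors[labels == k].mean(axis=0) for k in range(K)])
    return labels, centers


def distance_vector(v: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Euclidean distances from a reduced vector to every cluster center."""
    v = np.asarray(v, dtype=float)
    centers = np.atleast_2d(centers)
    if centers.shape[1] != v.shape[0]:
        raise ValueError("dimension mismatch between vector and centers")
    return np.linalg.norm(centers - v[None, :], axis=1)


def fit_regression(D: np.ndarray, acc: np.ndarray) -> tuple[np.ndarray, float]:
    """OLS of performance on cluster-distance vectors, with intercept.

    Rank-deficient designs fall back to the minimum-norm solution.
    """
    D = np.atleast_2d(np.asarray(D, dtype=float))
    acc = np.asarray(acc, dtype=float)
    n, K = D.shape
    if n <= K:
        raise ValueError(f"need more subjects ({n}) than clusters ({K})")
    X = np.column_stack([D, np.ones(n)])
    coef, _, rank, _ = np.linalg.lstsq(X, acc, rcond=None)
    if rank < X.shape[1]:
        logger.warning("rank-deficient distance design; minimum-norm solution used")
    return coef[:K], float(coef[K])


def train_predictor(cohort: list[SubjectSpectrum], acc: np.ndarray,
                    K: int = 5, explained: float = 0.95) -> PredictorModel:
    """Fit the full predictor: features -> PCA -> Ward(K) -> OLS."""
    acc = np.asarray(acc, dtype=float)
    if len(acc) != len(cohort):
        raise ValueError("one accuracy per subject required")
    feats, transform = build_features(cohort, explained)
    reduced = np.array([f.reduced for f in feats])
    labels, centers = ward_cluster(reduced, K)
    D = np.array([distance_vector(v, centers) for v in reduced])
    w, eps = fit_regression(D, acc)
    residuals = acc - (D @ w + eps)
    return PredictorModel(transform=transform, centers=centers,
                          assignments=labels, w=w, epsilon=eps, K=K,
                          residuals=residuals)


def predict_performance(model: PredictorModel, spectrum: SubjectSpectrum) -> float:
    """Predicted motor-imagery accuracy of a new subject."""
    v = model.transform.project(_augment(spectrum))
    d = distance_vector(v, model.centers)
    return float(d @ model.w + model.epsilon)


def loo_predictions(cohort: list[SubjectSpectrum], acc: np.ndarray,
                    K: int = 5, explained: float = 0.95) -> np.ndarray:
    """Leave-one-out predictions; the held-out subject never enters training."""
    acc = np.asarray(acc, dtype=float)
    preds = np.empty(len(cohort))
    for i in range(len(cohort)):
        train = [s for j, s in enumerate(cohort) if j != i]
        model = train_predictor(train, np.delete(acc, i), K, explained)
        preds[i] = predict_performance(model, cohort[i])
    return preds


def sweep_cluster_count(cohort: list[SubjectSpectrum], acc: np.ndarray,
                        K_range: range | list[int] | None = None,
                        explained: float = 0.95) -> dict[int, float]:
    """Leave-one-out predicted-vs-true Pearson correlation per cluster count.

    ``K_range`` defaults to 1..20 (clipped to n-2 so OLS stays determined).
    An undefined correlation (zero-variance target) is reported as 0.
    """
    n = len(cohort)
    if K_range is None:
        K_range = range(1, 21)
    out: dict[int, float] = {}
    for K in K_range:
        if not 1 <= K <= n - 2:
            continue
        preds = loo_predictions(cohort, acc, K, explained)
        r = pearson(preds, np.asarray(acc, dtype=float))
        out[K] = 0.0 if np.isnan(r) else r
    return out


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation; NaN (with a warning) on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D arrays, length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("Pearson correlation undefined: zero variance")
        return float("nan")
    return float(pearsonr(x, y).statistic)
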