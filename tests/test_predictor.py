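"""Ward clustering, cluster-distance regression and cohort prediction."""

import numpy as np
import pytest

from bssfo.core import Pdf1D, auc_of_pdf, frequency_grid
from bssfo.predict import (
    build_features,
    distance_vector,
    fit_regression,
    loo_predictions,
    pearson,
    predict_performance,
    sweep_cluster_count,
    train_predictor,
    ward_cluster,
)
from bssfo.resting import SubjectSpectrum, SpectralProfile
from bssfo.core import Pdf2D

GRID = frequency_grid(2.0, 34.0)


def brute_force_ward(vectors):
    """Greedy Ward merges by exhaustive recomputation of all pair costs.

    Returns the merge sequence as a list of frozensets of member indices
    (the union created at each step).  Ties break on the lowest pair index.
    """
    clusters = [frozenset([i]) for i in range(len(vectors))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca = np.mean(vectors[list(clusters[a])], axis=0)
                cb = np.mean(vectors[list(clusters[b])], axis=0)
                na, nb = len(clusters[a]), len(clusters[b])
                cost = na * nb / (na + nb) * np.sum((ca - cb) ** 2)
                if best is None or cost < best[0] - 1e-12:
                    best = (cost, a, b)
        _, a, b = best
        merged = clusters[a] | clusters[b]
        merges.append(merged)
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
    return merges


def scipy_ward_merges(vectors):
    """Merge sequence of the packaged Ward clustering, as member sets."""
    from scipy.cluster.hierarchy import linkage

    Z = linkage(vectors, method="ward")
    n = len(vectors)
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for row, (a, b, _, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + row] = merged
        merges.append(merged)
    return merges


def make_spectrum(xi_values, eta=1.0):
    """Minimal SubjectSpectrum for predictor tests."""
    xi = Pdf1D(GRID, np.asarray(xi_values, dtype=float))
    zeros = np.zeros_like(GRID)
    profile = SpectralProfile("C3", GRID, np.ones_like(GRID), (1.0, 0.0, 1.0),
                              zeros)
    n = len(GRID)
    valid = GRID[:, None] < GRID[None, :]
    uniform = np.where(valid, 1.0 / valid.sum(), 0.0)
    return SubjectSpectrum(profiles=[profile], likelihood=np.zeros((n, n)),
                           pdf2d=Pdf2D(GRID, uniform), pdf1d=xi, eta=eta, xi=xi)


def gaussian_cohort(rng, n=24, centers=(8.0, 10.0, 12.0, 19.0)):
    """Cohort whose Xi profiles vary by peak frequency and amplitude."""
    cohort, acc = [], []
    for i in range(n):
        c = centers[i % len(centers)]
        amp = rng.uniform(1.0, 6.0)
        xi = amp * np.exp(-0.5 * ((GRID - c) / 1.5) ** 2)
        xi += 0.05 * rng.standard_normal(len(GRID))
        cohort.append(make_spectrum(xi, eta=amp))
        acc.append(0.5 + 0.04 * amp + rng.normal(0, 0.01))
    return cohort, np.array(acc)


class TestFeatures:
    def test_identical_subjects_identical_reduced(self):
        xi = np.exp(-0.5 * ((GRID - 10.0) / 2.0) ** 2)
        cohort = [make_spectrum(xi), make_spectrum(xi), make_spectrum(2 * xi, 2.0)]
        feats, _ = build_features(cohort)
        np.testing.assert_allclose(feats[0].reduced, feats[1].reduced, atol=1e-9)

    def test_rank_one_variation_single_component(self, rng):
        direction = np.exp(-0.5 * ((GRID - 10.0) / 2.0) ** 2)
        cohort = [make_spectrum((1 + 0.3 * i) * direction, eta=1.0 + 0.3 * i)
                  for i in range(6)]
        feats, transform = build_features(cohort)
        assert transform.components.shape[0] == 1

    def test_augmented_tail_is_auc_and_eta(self):
        xi = np.maximum(np.sin(GRID / 4.0), 0.0)
        cohort = [make_spectrum(xi, eta=3.5), make_spectrum(2 * xi, eta=1.5)]
        feats, _ = build_features(cohort)
        s = cohort[0]
        assert feats[0].augmented[-1] == 3.5
        assert feats[0].augmented[-2] == pytest.approx(auc_of_pdf(s.xi))
        assert len(feats[0].augmented) == len(GRID) + 2

    def test_mismatched_grids_rejected(self):
        a = make_spectrum(np.zeros_like(GRID))
        b = make_spectrum(np.zeros_like(GRID))
        b.xi = Pdf1D(GRID[:-2], np.zeros(len(GRID) - 2))
        b.profiles[0].grid = GRID[:-2]
        b.profiles[0].psd = np.ones(len(GRID) - 2)
        b.profiles[0].fri = np.zeros(len(GRID) - 2)
        with pytest.raises(ValueError):
            build_features([a, b])


class TestWard:
    def test_singletons_when_K_equals_n(self, rng):
        x = rng.standard_normal((5, 3))
        labels, centers = ward_cluster(x, 5)
        assert sorted(labels) == list(range(5))
        np.testing.assert_allclose(centers[labels], x)

    def test_two_tight_groups(self, rng):
        x = np.vstack([rng.normal(0.0, 0.05, (3, 2)),
                       rng.normal(5.0, 0.05, (3, 2))])
        labels, centers = ward_cluster(x, 2)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    @pytest.mark.parametrize("seed", range(10))
    def test_merge_sequence_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        x = rng.standard_normal((n, int(rng.integers(1, 5))))
        assert scipy_ward_merges(x) == brute_force_ward(x)

    def test_K_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            ward_cluster(rng.standard_normal((4, 2)), 5)


class TestDistanceRegression:
    def test_distance_to_own_center_zero(self):
        centers = np.array([[0.0, 0.0], [3.0, 4.0]])
        d = distance_vector(np.array([0.0, 0.0]), centers)
        np.testing.assert_allclose(d, [0.0, 5.0])

    def test_permutation_equivariance(self, rng):
        centers = rng.standard_normal((4, 3))
        v = rng.standard_normal(3)
        d = distance_vector(v, centers)
        perm = [2, 0, 3, 1]
        np.testing.assert_allclose(distance_vector(v, centers[perm]), d[perm])

    def test_exact_linear_target_recovered(self, rng):
        D = rng.random((30, 4))
        w_true = np.array([0.2, -0.1, 0.4, 0.05])
        acc = D @ w_true + 0.6
        w, eps = fit_regression(D, acc)
        np.testing.assert_allclose(w, w_true, atol=1e-10)
        assert eps == pytest.approx(0.6, abs=1e-10)

    def test_noisy_recovery(self, rng):
        D = rng.random((100, 5))
        w_true = rng.normal(0, 0.3, 5)
        acc = D @ w_true + 0.7 + rng.normal(0, 0.02, 100)
        w, _ = fit_regression(D, acc)
        assert np.linalg.norm(w - w_true) / np.linalg.norm(w_true) < 0.15

    def test_constant_target(self, rng):
        D = rng.random((20, 3))
        w, eps = fit_regression(D, np.full(20, 0.75))
        np.testing.assert_allclose(w, 0.0, atol=1e-9)
        assert eps == pytest.approx(0.75)

    def test_underdetermined_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_regression(rng.random((4, 5)), np.zeros(4))


class TestPredictor:
    def test_training_subject_reproduced_in_zero_residual_model(self, rng):
        cohort, _ = gaussian_cohort(rng, n=8)
        model = train_predictor(cohort, np.zeros(8), K=2)
        # zero-residual by construction: target linear in distances
        D = np.array([distance_vector(model.transform.project(
            np.concatenate([s.xi.values, [auc_of_pdf(s.xi), s.eta]])),
            model.centers) for s in cohort])
        acc = D @ np.array([0.1, -0.2]) + 0.7
        model2 = train_predictor(cohort, acc, K=2)
        np.testing.assert_allclose(np.abs(model2.residuals), 0.0, atol=1e-9)
        for s, a in zip(cohort, acc):
            assert predict_performance(model2, s) == pytest.approx(a, abs=1e-8)

    def test_invariant_to_training_order(self, rng):
        cohort, acc = gaussian_cohort(rng, n=12)
        model = train_predictor(cohort, acc, K=3)
        perm = rng.permutation(12)
        model_p = train_predictor([cohort[i] for i in perm], acc[perm], K=3)
        probe = cohort[0]
        assert predict_performance(model, probe) == pytest.approx(
            predict_performance(model_p, probe), abs=1e-8)

    def test_loo_matches_manual_heldout_fit(self, rng):
        cohort, acc = gaussian_cohort(rng, n=10)
        preds = loo_predictions(cohort, acc, K=2)
        i = 4
        manual = train_predictor(cohort[:i] + cohort[i + 1:],
                                 np.delete(acc, i), K=2)
        assert preds[i] == pytest.approx(predict_performance(manual, cohort[i]))

    def test_sweep_constant_target_reports_zero(self, rng):
        cohort, _ = gaussian_cohort(rng, n=10)
        out = sweep_cluster_count(cohort, np.full(10, 0.8), K_range=[2, 3])
        assert out == {2: 0.0, 3: 0.0}

    def test_sweep_improves_with_structure(self, rng):
        cohort, acc = gaussian_cohort(rng, n=24)
        out = sweep_cluster_count(cohort, acc, K_range=[2, 4])
        assert max(out.values()) > 0.5


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_independent_near_zero(self, rng):
        x = rng.standard_normal(10_000)
        y = rng.standard_normal(10_000)
        assert abs(pearson(x, y)) < 0.03

    def test_zero_variance_flagged_nan(self):
        assert np.isnan(pearson(np.ones(5), np.arange(5.0)))
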