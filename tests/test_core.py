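"""Particle prior/posterior, pdf conversions and frequency weighting."""

import numpy as np
import pytest

from bssfo.core import (
    Band,
    BssfoConfig,
    BssfoModel,
    ParticleSet,
    Pdf1D,
    Pdf2D,
    _valid_cells,
    auc_of_pdf,
    bssfo_fit,
    bssfo_predict,
    frequency_grid,
    frequency_weight,
    particle_likelihood,
    pdf2d_from_particles,
    pdf_1d,
    sample_prior,
    weighted_pdf1d,
)
from bssfo.io import TrialSet
from bssfo.spatio_spectral import LdaModel, SpatialFilterSet


def brute_force_pdf1d(p2: Pdf2D) -> np.ndarray:
    """Independent oracle: explicit double loop over all valid cells."""
    grid = p2.grid
    n = len(grid)
    n_valid = sum(1 for i in range(n) for j in range(n) if grid[i] < grid[j])
    u = 1.0 / n_valid
    out = np.zeros(n)
    for fi, f in enumerate(grid):
        for i in range(n):
            for j in range(n):
                if grid[i] < grid[j] and grid[i] <= f <= grid[j]:
                    out[fi] += p2.mass[i, j] - u
    return out


class TestPrior:
    def test_single_particle_weight_one(self):
        ps = sample_prior(1, seed=0)
        assert len(ps.particles) == 1
        assert ps.weights[0] == 1.0

    def test_particles_respect_constraints(self):
        ps = sample_prior(500, f_min=4.0, f_max=40.0, min_bandwidth=2.0, seed=1)
        assert all(4.0 <= p.b_s and p.b_e <= 40.0 for p in ps.particles)
        assert all(p.b_e - p.b_s >= 2.0 for p in ps.particles)
        # everything on the 0.5 Hz grid
        assert all((2 * p.b_s) == int(2 * p.b_s) for p in ps.particles)

    def test_uniformity_matches_cell_enumeration(self):
        # empirical P(b_s < 22) vs exact count of valid grid cells
        grid = frequency_grid(4.0, 40.0)
        cells = _valid_cells(grid, 2.0)
        exact = np.mean(grid[cells[:, 0]] < 22.0)
        ps = sample_prior(10_000, min_bandwidth=2.0, seed=2)
        empirical = np.mean(ps.starts < 22.0)
        assert empirical == pytest.approx(exact, abs=0.02)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            sample_prior(10, f_min=10.0, f_max=10.5, min_bandwidth=2.0)


class TestPdfConversion:
    def test_single_particle_single_cell(self):
        ps = ParticleSet([Band(8.0, 12.0)], np.array([1.0]))
        p2 = pdf2d_from_particles(ps)
        i = list(p2.grid).index(8.0)
        j = list(p2.grid).index(12.0)
        assert p2.mass[i, j] == 1.0
        assert p2.mass.sum() == 1.0

    def test_two_equal_particles(self):
        ps = ParticleSet([Band(8.0, 12.0), Band(16.0, 22.0)],
                         np.array([0.5, 0.5]))
        p2 = pdf2d_from_particles(ps)
        assert np.count_nonzero(p2.mass) == 2
        assert p2.mass.max() == 0.5

    def test_uniform_pdf2d_gives_zero_profile(self):
        grid = frequency_grid(4.0, 10.0)
        valid = grid[:, None] < grid[None, :]
        mass = np.where(valid, 1.0 / valid.sum(), 0.0)
        p1 = pdf_1d(Pdf2D(grid, mass))
        np.testing.assert_allclose(p1.values, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        grid = frequency_grid(4.0, 12.0)
        valid = grid[:, None] < grid[None, :]
        raw = np.where(valid, rng.random(valid.shape), 0.0)
        mass = raw / raw.sum()
        p2 = Pdf2D(grid, mass)
        np.testing.assert_allclose(pdf_1d(p2).values, brute_force_pdf1d(p2),
                                   atol=1e-12)

    def test_unmassed_frequency_is_nonpositive(self):
        grid = frequency_grid(4.0, 40.0)
        mass = np.zeros((len(grid), len(grid)))
        mass[list(grid).index(8.0), list(grid).index(12.0)] = 1.0
        p1 = pdf_1d(Pdf2D(grid, mass))
        assert p1.values[list(grid).index(30.0)] <= 0.0

    def test_pdf2d_rejects_mass_below_diagonal(self):
        grid = frequency_grid(4.0, 6.0)
        mass = np.zeros((len(grid), len(grid)))
        mass[2, 1] = 1.0
        with pytest.raises(ValueError):
            Pdf2D(grid, mass)


class TestFrequencyWeight:
    def test_gaussian_peak_closed_form(self):
        w = frequency_weight(10.0, [(1.0, 10.0, 2.0)])
        assert w == pytest.approx(1.0 / (2.0 * np.sqrt(2.0 * np.pi)))

    def test_one_sigma_ratio(self):
        peak = frequency_weight(10.0, [(1.0, 10.0, 2.0)])
        at_sigma = frequency_weight(12.0, [(1.0, 10.0, 2.0)])
        assert at_sigma == pytest.approx(np.exp(-0.5) * peak)

    def test_empty_mixture_is_identity(self):
        grid = frequency_grid(4.0, 40.0)
        p1 = Pdf1D(grid, np.sin(grid))
        out = weighted_pdf1d(p1, mixture=[])
        np.testing.assert_array_equal(out.values, p1.values)

    def test_default_mixture_emphasizes_rhythm_bands(self):
        grid = np.linspace(4, 40, 1441)
        w = frequency_weight(grid)
        assert 8.0 <= grid[np.argmax(w)] <= 16.0
        # mu and beta bands outweigh the spectrum edges
        assert frequency_weight(10.0) > frequency_weight(4.0)
        assert frequency_weight(10.0) > frequency_weight(34.0)
        assert frequency_weight(19.0) > frequency_weight(30.0)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            frequency_weight(10.0, [(1.0, 10.0, 0.0)])


class TestAuc:
    def test_zero_profile(self):
        grid = frequency_grid(4.0, 40.0)
        assert auc_of_pdf(Pdf1D(grid, np.zeros_like(grid))) == 0.0

    def test_rectangle_height_one(self):
        grid = np.arange(8.0, 12.5, 0.5)
        assert auc_of_pdf(Pdf1D(grid, np.ones_like(grid))) == pytest.approx(4.0)

    def test_negative_part_ignored(self):
        grid = np.arange(0.0, 2.5, 0.5)
        vals = np.array([-1.0, -1.0, 1.0, 1.0, -1.0])
        assert auc_of_pdf(Pdf1D(grid, vals)) == pytest.approx(
            np.trapezoid(np.maximum(vals, 0.0), grid))

    def test_invariant_to_grid_refinement(self):
        coarse = np.linspace(0.0, 10.0, 11)
        vals = np.maximum(1.0 - np.abs(coarse - 5.0) / 3.0, 0.0)
        fine = np.linspace(0.0, 10.0, 101)
        vals_fine = np.interp(fine, coarse, vals)
        a1 = auc_of_pdf(Pdf1D(coarse, vals))
        a2 = auc_of_pdf(Pdf1D(fine, vals_fine))
        assert a1 == pytest.approx(a2, abs=1e-6)


class TestLikelihood:
    def test_planted_band_high_likelihood(self, planted_trials):
        lik = particle_likelihood(Band(10.0, 14.0), planted_trials)
        assert lik >= 0.9

    def test_uninformative_band_near_chance(self, planted_trials):
        lik = particle_likelihood(Band(24.0, 32.0), planted_trials)
        assert abs(lik - 0.5) <= 0.15

    def test_constant_labels_rejected(self, planted_trials):
        ts = TrialSet(planted_trials.trials[:20],
                      np.array(["L"] * 20), planted_trials.fs)
        with pytest.raises(ValueError):
            particle_likelihood(Band(8.0, 12.0), ts)


def _stub_model(bands, weights, labels=("L", "R"), n_channels=2):
    """Model whose particle classifiers always vote a fixed label."""
    classes = np.array(sorted(labels))
    filters, classifiers = [], []
    for vote in ["L", "R"][:len(bands)]:
        W = np.eye(n_channels)[:, :2]
        filters.append(SpatialFilterSet(W=W, eigenvalues=np.array([1.0, 0.0]), m=1))
        bias = 1.0 if vote == classes[1] else -1.0
        classifiers.append(LdaModel(weights=np.zeros(2), bias=bias, classes=classes))
    ps = ParticleSet(bands, np.asarray(weights))
    return BssfoModel(posterior=ps, filters=filters, classifiers=classifiers,
                      config=BssfoConfig())


class TestFitPredict:
    def test_single_particle_posterior_is_that_particle(self, planted_trials):
        short = TrialSet(planted_trials.trials[:40], planted_trials.labels[:40],
                         planted_trials.fs)
        cfg = BssfoConfig(n_particles=1, max_iterations=2, seed=0)
        model = bssfo_fit(short, cfg)
        assert len(model.posterior.particles) == 1
        assert model.posterior.weights[0] == 1.0

    def test_weighted_vote_follows_heavier_particle(self):
        model = _stub_model([Band(8.0, 12.0), Band(16.0, 22.0)], [0.7, 0.3])
        trials = TrialSet(np.random.default_rng(0).standard_normal((5, 2, 64)),
                          np.array(["L"] * 5), 100.0)
        pred = bssfo_predict(model, trials)
        assert list(pred) == ["L"] * 5  # the 0.7 particle votes L

    def test_unanimous_particles(self):
        model = _stub_model([Band(8.0, 12.0)], [1.0])
        trials = TrialSet(np.random.default_rng(0).standard_normal((3, 2, 64)),
                          np.array(["R"] * 3), 100.0)
        assert list(bssfo_predict(model, trials)) == ["L"] * 3

    def test_untrained_model_rejected(self, planted_trials):
        ps = ParticleSet([Band(8.0, 12.0)], np.array([1.0]))
        model = BssfoModel(posterior=ps, filters=[], classifiers=[],
                           config=BssfoConfig())
        with pytest.raises(ValueError):
            bssfo_predict(model, planted_trials)

    def test_constant_likelihood_preserves_prior(self, planted_trials, monkeypatch):
        # with a flat likelihood the resample/perturb loop must not move the
        # particle cloud away from the uniform prior (KS on band centers)
        from bssfo import core as core_mod

        monkeypatch.setattr(core_mod._LikelihoodCache, "accuracy",
                            lambda self, band: 0.75)
        cfg = BssfoConfig(n_particles=10_000, max_iterations=10, tol=0.0,
                          seed=7, fit_classifiers=False)
        model = bssfo_fit(planted_trials, cfg)
        assert model.at_chance is False
        centers = 0.5 * (model.posterior.starts + model.posterior.ends)
        prior = sample_prior(200_000, seed=8)
        prior_centers = 0.5 * (prior.starts + prior.ends)
        xs = np.unique(np.concatenate([centers, prior_centers]))
        emp = np.searchsorted(np.sort(centers), xs, side="right") / len(centers)
        ref = np.searchsorted(np.sort(prior_centers), xs, side="right") / len(prior_centers)
        assert np.max(np.abs(emp - ref)) < 0.05
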