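import numpy as np
import pytest

from nutspec import chemometrics as cm
from nutspec.containers import NUTRIENT_COLUMNS


def ols_fit(X, y):
    """Brute-force least-squares oracle with intercept."""
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef[0], coef[1:]


class TestFitPLS:
    def test_full_rank_equals_least_squares(self, small_full_rank_problem):
        X, y = small_full_rank_problem
        model = cm.fit_pls(X, y, k=5)
        icept, beta = ols_fit(X, y)
        assert np.allclose(model.coefficients, beta, atol=1e-8)
        yhat = cm.predict(model, X)
        assert np.allclose(yhat, icept + X @ beta, atol=1e-8)

    def test_noise_free_linear_recovery(self, noise_free_dataset):
        comps, spectra = noise_free_dataset
        y = comps["oil_pct"].to_numpy()
        model = cm.fit_pls(spectra, y, k=5)
        resid = y - cm.predict(model, spectra)
        assert np.abs(resid).max() < 1e-8

    def test_coefficients_reproduce_scores_path(self, small_full_rank_problem):
        X, y = small_full_rank_problem
        k = 3
        model = cm.fit_pls(X, y, k)
        # scores path: project deflated X onto weights sequentially
        Xc = X - model.x_mean
        yhat_scores = np.full(len(y), model.y_mean)
        Xd = Xc.copy()
        for a in range(k):
            t = Xd @ model.weights[:, a]
            yhat_scores += model.y_loadings[a] * t
            Xd -= np.outer(t, model.x_loadings[:, a])
        assert np.allclose(cm.predict(model, X), yhat_scores, atol=1e-10)

    def test_deflated_x_orthogonal_to_weights(self, small_full_rank_problem):
        X, y = small_full_rank_problem
        k = 3
        model = cm.fit_pls(X, y, k)
        Xd = X - model.x_mean
        for a in range(k):
            t = Xd @ model.weights[:, a]
            Xd = Xd - np.outer(t, model.x_loadings[:, a])
        assert np.abs(Xd @ model.weights).max() < 1e-10

    def test_matches_sklearn_reference(self, small_full_rank_problem):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = small_full_rank_problem
        model = cm.fit_pls(X, y, k=3)
        ref = sklearn.PLSRegression(n_components=3, scale=False).fit(X, y)
        assert np.allclose(model.coefficients, ref.coef_.ravel(), atol=1e-8)

    def test_k_beyond_rank_rejected(self, small_full_rank_problem):
        X, y = small_full_rank_problem
        with pytest.raises(ValueError):
            cm.fit_pls(X, y, k=6)
        with pytest.raises(ValueError, match="scans"):
            cm.fit_pls(X, y[:-1], k=2)


class TestFitPCR:
    def test_full_rank_equals_least_squares(self, small_full_rank_problem):
        X, y = small_full_rank_problem
        model = cm.fit_pcr(X, y, k=5)
        _, beta = ols_fit(X, y)
        assert np.allclose(model.coefficients, beta, atol=1e-8)

    def test_single_dominant_direction(self):
        rng = np.random.default_rng(11)
        direction = np.array([3.0, -1.0, 2.0, 0.5])
        direction /= np.linalg.norm(direction)
        t = rng.normal(0, 5, 50)
        X = np.outer(t, direction) + rng.normal(0, 1e-4, (50, 4))
        y = 2.0 * t
        model = cm.fit_pcr(X, y, k=1)
        cos = model.coefficients @ direction / np.linalg.norm(model.coefficients)
        assert abs(abs(cos) - 1.0) < 1e-4

    def test_pls_and_pcr_agree_on_noise_free_mixtures(self, noise_free_dataset):
        comps, spectra = noise_free_dataset
        y = comps["protein_pct"].to_numpy()
        yhat_pls = cm.predict(cm.fit_pls(spectra, y, 5), spectra)
        yhat_pcr = cm.predict(cm.fit_pcr(spectra, y, 5), spectra)
        assert np.allclose(yhat_pls, yhat_pcr, atol=1e-6)

    def test_sign_convention_deterministic(self, small_full_rank_problem):
        X, y = small_full_rank_problem
        a = cm.fit_pcr(X, y, k=3)
        b = cm.fit_pcr(np.array(X, copy=True), y, k=3)
        assert np.array_equal(a.x_loadings, b.x_loadings)
        for col in a.x_loadings.T:
            assert col[np.argmax(np.abs(col))] > 0


class TestPredict:
    def test_mean_spectrum_predicts_mean_value(self, small_full_rank_problem):
        X, y = small_full_rank_problem
        model = cm.fit_pls(X, y, 3)
        yhat = cm.predict(model, np.tile(model.x_mean, (4, 1)))
        assert np.allclose(yhat, model.y_mean, atol=1e-12)

    def test_grid_mismatch_rejected(self, noise_free_dataset):
        comps, spectra = noise_free_dataset
        model = cm.fit_pls(spectra, comps["oil_pct"].to_numpy(), 3)
        with pytest.raises(ValueError, match="grid"):
            cm.predict(model, np.zeros((2, spectra.wavelengths.size - 1)))


class TestValidate:
    def test_perfect_model_limits(self, noise_free_dataset):
        comps, spectra = noise_free_dataset
        y = comps["oil_pct"].to_numpy()
        split = cm.SplitSpec(n_holdout=8, seed=3)
        _, rep = cm.validate("pls", spectra, y, split, 5)
        assert rep.rmsec < 1e-8 and rep.rmsep < 1e-8
        assert rep.r2c > 1 - 1e-12 and rep.r2p > 1 - 1e-12
        assert rep.rpd > 1e6

    def test_rpd_is_holdout_sd_over_sep(self, noise_free_dataset):
        comps, spectra = noise_free_dataset
        y = comps["oil_pct"].to_numpy()
        noisy = spectra.with_absorbance(
            spectra.absorbance + np.random.default_rng(1).normal(0, 0.01, spectra.absorbance.shape)
        )
        split = cm.SplitSpec(n_holdout=10, seed=5)
        _, rep = cm.validate("pls", noisy, y, split, 4)
        hold = np.sort(np.random.default_rng(5).choice(len(y), 10, replace=False))
        assert rep.rpd == pytest.approx(np.std(y[hold], ddof=1) / rep.sep, rel=1e-9)

    def test_shuffled_labels_destroy_predictivity(self, noise_free_dataset):
        comps, spectra = noise_free_dataset
        rng = np.random.default_rng(9)
        y = rng.permutation(comps["oil_pct"].to_numpy())
        split = cm.SplitSpec(n_holdout=10, seed=2)
        _, rep = cm.validate("pls", spectra, y, split, 3)
        assert rep.r2cv < 0.4
        assert rep.rpd < 2.0

    def test_rmsep_scales_with_additive_noise(self, noise_free_dataset):
        """Prediction error grows linearly with the spectral noise level."""
        comps, spectra = noise_free_dataset
        y = comps["oil_pct"].to_numpy()
        split = cm.SplitSpec(n_holdout=10, seed=4)
        rmseps = []
        for sd in (0.001, 0.002, 0.004):
            noisy = spectra.with_absorbance(
                spectra.absorbance
                + np.random.default_rng(10).normal(0, sd, spectra.absorbance.shape)
            )
            _, rep = cm.validate("pls", noisy, y, split, 5)
            rmseps.append(rep.rmsep)
        assert rmseps[0] < rmseps[1] < rmseps[2]
        assert 2.5 < rmseps[2] / rmseps[0] < 6.0  # ideally 4x for 4x the noise

    def test_holdout_too_small_rejected(self, noise_free_dataset):
        comps, spectra = noise_free_dataset
        y = comps["oil_pct"].to_numpy()
        with pytest.raises(ValueError):
            cm.validate("pls", spectra, y, cm.SplitSpec(n_holdout=1, seed=0), 3)


class TestSelectComponents:
    def test_noise_free_mixture_needs_few_components(self, noise_free_dataset):
        comps, spectra = noise_free_dataset
        y = comps["oil_pct"].to_numpy()
        split = cm.SplitSpec(n_holdout=8, seed=1)
        k = cm.select_components(spectra, y, split, k_max=8)
        assert k <= 5

    def test_pure_noise_response_prefers_small_k(self, noise_free_dataset):
        comps, spectra = noise_free_dataset
        rng = np.random.default_rng(20)
        y = rng.normal(0, 1, len(comps))
        split = cm.SplitSpec(n_holdout=8, seed=1)
        k = cm.select_components(spectra, y, split, k_max=6)
        assert k <= 2

    def test_rmsec_nonincreasing_in_k(self, noise_free_dataset):
        comps, spectra = noise_free_dataset
        y = comps["ash_pct"].to_numpy()
        noisy = spectra.with_absorbance(
            spectra.absorbance + np.random.default_rng(2).normal(0, 0.01, spectra.absorbance.shape)
        )
        rmsecs = []
        for k in range(1, 7):
            model = cm.fit_pls(noisy, y, k)
            rmsecs.append(cm.rmse(y - cm.predict(model, noisy)))
        assert all(b <= a + 1e-12 for a, b in zip(rmsecs, rmsecs[1:]))


class TestClassifyRPD:
    @pytest.mark.parametrize(
        "rpd,label",
        [(13.208, "excellent"), (6.678, "excellent"), (2.886, "very reliable"),
         (1.7, "limited"), (1.0, "unreliable")],
    )
    def test_banding(self, rpd, label):
        assert cm.classify_rpd(rpd) == label

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cm.classify_rpd(-0.1)
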