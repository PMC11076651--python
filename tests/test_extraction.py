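"""Unit and oracle tests for the five extraction methods."""

import numpy as np
import pytest
from scipy import fft as sp_fft

from microsel import (dct_1d, extract_features, gmm_em_fit, kmeans_fit,
                      nlr_fit, pca_decompose, pca_project)
from microsel.extraction import (DCTSpectrum, Extractor, _batch_nlr_residuals,
                                 _nlr_model, idct_1d)


class TestGmmEm:
    def test_single_component_closed_form(self, rng):
        x = rng.normal(2.0, 3.0, size=500)
        fit = gmm_em_fit(x, n_components=1, seed=0)
        assert fit.weights[0] == pytest.approx(1.0, abs=1e-12)
        assert fit.means[0] == pytest.approx(x.mean(), abs=1e-9)
        assert fit.variances[0] == pytest.approx(x.var(), abs=1e-9)  # MLE, /n

    def test_two_separated_components_recovered(self, rng):
        x = np.concatenate([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        fit = gmm_em_fit(x, n_components=2, seed=3)
        # oracle: per-cluster sample means after thresholding at 5
        lo, hi = x[x < 5].mean(), x[x >= 5].mean()
        got = np.sort(fit.means)
        assert got[0] == pytest.approx(lo, abs=0.1)
        assert got[1] == pytest.approx(hi, abs=0.1)

    @pytest.mark.parametrize("n_components", [1, 2, 3])
    def test_responsibilities_and_weights_normalized(self, rng, n_components):
        x = rng.normal(size=200)
        fit = gmm_em_fit(x, n_components=n_components, seed=1)
        assert np.allclose(fit.responsibilities.sum(axis=1), 1.0, atol=1e-12)
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_log_likelihood_monotone(self, rng):
        for seed in range(5):
            x = np.concatenate([rng.normal(0, 1, 150), rng.normal(3, 2, 150)])
            fit = gmm_em_fit(x, n_components=2, seed=seed)
            diffs = np.diff(fit.log_likelihood_trace)
            assert (diffs >= -1e-9).all()

    def test_variance_collapse_floored_and_flagged(self):
        # two point masses: both component variances collapse to the floor
        x = np.repeat([0.0, 5.0], 50)
        fit = gmm_em_fit(x, n_components=2, seed=0, max_iter=500)
        assert fit.variance_floored
        assert (fit.variances > 0).all()


class TestNlr:
    def test_noise_free_recovery(self):
        truth = np.array([2.0, 0.5, 1.0])
        y = _nlr_model(truth, np.arange(50, dtype=float))
        fit = nlr_fit(y)
        assert np.allclose(fit.theta, truth, atol=1e-6)
        assert fit.residual_ss == pytest.approx(0.0, abs=1e-18)
        assert fit.converged

    def test_recovery_from_perturbed_inits(self):
        truth = np.array([2.0, 0.5, 1.0])
        y = _nlr_model(truth, np.arange(50, dtype=float))
        for scale in (0.5, 0.75, 1.25, 1.5):
            fit = nlr_fit(y, init=tuple(truth * scale))
            assert np.allclose(fit.theta, truth, atol=1e-4)

    def test_constant_signal_flags_near_singular(self):
        fit = nlr_fit(np.full(30, 4.2), init=(1.0, 0.0, 4.0))
        assert fit.near_singular

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            nlr_fit(np.array([1.0, 2.0]))

    def test_batch_residual_ranker_orders_structure_correctly(self, rng):
        """The grid-based batch ranker need not match the exact per-gene
        fit, but model-family signals must score far below pure noise
        and a constant gene must fit exactly."""
        t = np.arange(40, dtype=float)
        decaying = 3.0 * np.exp(-0.2 * t) + 1.0
        flat = np.full(40, 1.5)
        X = np.column_stack([decaying, flat, rng.normal(size=40)])
        rss = _batch_nlr_residuals(X)
        assert rss[1] == pytest.approx(0.0, abs=1e-18)
        assert rss[0] < 0.1
        assert rss[2] > 10 * rss[0]


class TestKmeans:
    def test_single_cluster_is_global_mean(self, rng):
        X = rng.normal(size=(60, 3))
        model = kmeans_fit(X, n_clusters=1, seed=0)
        assert np.allclose(model.centroids[0], X.mean(axis=0), atol=1e-12)
        assert model.inertia == pytest.approx(((X - X.mean(0)) ** 2).sum(), rel=1e-12)

    def test_two_blobs_pure_assignment(self, rng):
        a = rng.normal(0, 1, size=(100, 2))
        b = rng.normal(100, 1, size=(100, 2))
        model = kmeans_fit(np.vstack([a, b]), n_clusters=2, seed=4)
        # oracle: nearest true centre
        truth = (np.vstack([a, b]).sum(axis=1) > 100).astype(int)
        got = model.assignments
        purity = max((got == truth).mean(), (got == 1 - truth).mean())
        assert purity == 1.0

    def test_inertia_trace_non_increasing(self, rng):
        for seed in range(5):
            X = rng.normal(size=(80, 4))
            model = kmeans_fit(X, n_clusters=5, seed=seed)
            assert (np.diff(model.inertia_trace) <= 1e-9).all()

    def test_fewer_points_than_clusters_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_fit(rng.normal(size=(3, 2)), n_clusters=5)


class TestPca:
    def test_rank_one_line(self, rng):
        x = rng.normal(size=200)
        X = np.column_stack([x, 2 * x])
        model = pca_decompose(X)
        assert model.eigenvalues[0] / model.eigenvalues.sum() >= 0.99999

    def test_spectral_reconstruction(self, rng):
        X = rng.normal(size=(50, 6))
        m = pca_decompose(X)
        rebuilt = m.eigenvectors @ np.diag(m.eigenvalues) @ m.eigenvectors.T
        assert np.allclose(rebuilt, m.covariance, atol=1e-9)
        assert m.eigenvalues.sum() == pytest.approx(np.trace(m.covariance), abs=1e-9)
        assert np.allclose(m.eigenvectors.T @ m.eigenvectors, np.eye(6), atol=1e-9)

    def test_eigenvalues_match_characteristic_polynomial(self, rng):
        """Brute-force oracle: roots of det(C - λI) for a 3x3 covariance."""
        X = rng.normal(size=(40, 3))
        m = pca_decompose(X)
        C = m.covariance
        # char poly of 3x3: -λ^3 + tr λ^2 - c2 λ + det
        tr = np.trace(C)
        c2 = 0.5 * (tr**2 - np.trace(C @ C))
        roots = np.sort(np.roots([-1.0, tr, -c2, np.linalg.det(C)]))[::-1]
        assert np.allclose(np.sort(m.eigenvalues)[::-1], roots.real, atol=1e-8)

    def test_full_projection_preserves_frobenius_norm(self, rng):
        X = rng.normal(size=(30, 5))
        m = pca_decompose(X)
        Y = pca_project(m, X, k=5)
        Xc = X - X.mean(axis=0)
        assert np.linalg.norm(Y) == pytest.approx(np.linalg.norm(Xc), abs=1e-9)

    def test_embedded_line_recovered_up_to_sign(self, rng):
        t = rng.normal(size=100)
        X = np.outer(t, [1.0, -2.0, 0.5])
        m = pca_decompose(X)
        y = pca_project(m, X, k=1)[:, 0]
        scale = np.linalg.norm([1.0, -2.0, 0.5])
        tc = (t - t.mean()) * scale
        assert min(np.abs(y - tc).max(), np.abs(y + tc).max()) < 1e-9

    def test_mean_row_projects_to_zero(self, rng):
        X = rng.normal(size=(20, 4))
        m = pca_decompose(X)
        assert np.allclose(pca_project(m, m.mean, k=4), 0.0, atol=1e-12)

    def test_k_beyond_rank_rejected(self, rng):
        t = rng.normal(size=50)
        X = np.outer(t, [1.0, 2.0, 3.0])  # rank 1
        m = pca_decompose(X)
        with pytest.raises(ValueError, match="max usable k is 1"):
            pca_project(m, X, k=2)

    def test_constant_matrix_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            m = pca_decompose(np.full((5, 3), 2.0))
        assert m.degenerate
        assert np.allclose(m.eigenvalues, 0.0)


class TestDct:
    def test_constant_input_closed_form(self):
        c = 1.7
        spec = dct_1d(np.full(4, c))
        assert spec.coefficients[0] == pytest.approx(2 * c, abs=1e-12)
        assert np.allclose(spec.coefficients[1:], 0.0, atol=1e-12)
        assert spec.normalization[0] == pytest.approx(0.5)  # 1/sqrt(4)
        assert np.allclose(spec.normalization[1:], np.sqrt(2 / 4))

    def test_parseval(self, rng):
        x = rng.normal(size=64)
        spec = dct_1d(x)
        assert np.sum(x**2) == pytest.approx(np.sum(spec.coefficients**2), abs=1e-9)

    def test_single_cosine_line(self):
        N = 16
        n = np.arange(N)
        x = np.cos(np.pi / N * (n + 0.5) * 3)
        spec = dct_1d(x)
        expected = np.zeros(N)
        expected[3] = np.sqrt(N / 2)
        assert np.allclose(spec.coefficients, expected, atol=1e-9)

    def test_direct_summation_oracle(self, rng):
        """Independent O(N^2) evaluation of the transform definition."""
        x = rng.normal(size=20)
        N = x.size
        n = np.arange(N)
        alpha = np.where(n == 0, np.sqrt(1 / N), np.sqrt(2 / N))
        brute = np.array([
            alpha[k] * np.sum(x * np.cos(np.pi / N * (n + 0.5) * k))
            for k in range(N)
        ])
        assert np.allclose(dct_1d(x).coefficients, brute, atol=1e-9)

    def test_round_trip_inverse(self, rng):
        x = rng.normal(size=33)
        assert np.allclose(idct_1d(dct_1d(x)), x, atol=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dct_1d(np.array([]))


class TestExtractFeatures:
    @pytest.mark.parametrize("method", ["EM", "NLR", "KMEANS", "PCA", "DCT"])
    def test_shape_and_determinism(self, small_dataset, method):
        r1 = extract_features(small_dataset, method, k=50, seed=5)
        r2 = extract_features(small_dataset, method, k=50, seed=5)
        assert r1.features.shape == (40, 50)
        assert np.array_equal(r1.features, r2.features)
        assert np.array_equal(r1.retained_indices, r2.retained_indices)

    def test_dct_full_k_conserves_energy(self, small_dataset):
        r = extract_features(small_dataset, "DCT", k=200)
        per_sample_in = (small_dataset.matrix**2).sum(axis=1)
        per_sample_out = (r.features**2).sum(axis=1)
        assert np.allclose(per_sample_in, per_sample_out, atol=1e-9)

    @pytest.mark.parametrize("method", ["PCA", "DCT"])
    def test_sample_permutation_equivariance(self, small_dataset, method):
        """Per-sample extractors must not leak across samples: permuting
        input rows permutes output rows identically."""
        ex = Extractor(method, k=30, seed=2).fit(small_dataset.matrix,
                                                 small_dataset.y)
        perm = np.random.default_rng(0).permutation(40)
        out = ex.transform(small_dataset.matrix)
        out_perm = ex.transform(small_dataset.matrix[perm])
        assert np.allclose(out[perm], out_perm, atol=1e-12)

    def test_kmeans_retention_enriches_informative_genes(self):
        """Genes sharing the planted-shift structure cluster tightly; the
        retained set should overlap the informative set beyond chance
        (hypergeometric oracle)."""
        from scipy.stats import hypergeom

        from microsel import SyntheticConfig, generate_dataset
        ds = generate_dataset(SyntheticConfig(
            n_healthy=30, n_malignant=30, n_genes=300, n_informative=30,
            effect_size=3.0, noise_family="gaussian", seed=8))
        r = extract_features(ds, "KMEANS", k=60, seed=8)
        overlap = len(set(r.retained_indices) & set(ds.informative_indices))
        p = hypergeom.sf(overlap - 1, 300, 30, 60)
        assert p < 0.01

    def test_em_retention_ranks_informative_genes_first(self):
        from microsel import SyntheticConfig, generate_dataset
        ds = generate_dataset(SyntheticConfig(
            n_healthy=40, n_malignant=40, n_genes=200, n_informative=20,
            effect_size=3.0, noise_family="gaussian", seed=15))
        r = extract_features(ds, "EM", k=40, seed=15)
        overlap = len(set(r.retained_indices) & set(ds.informative_indices))
        assert overlap >= 15

    def test_unknown_method_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="unknown method"):
            extract_features(small_dataset, "WAVELET", k=10)

    def test_pca_projection_mode_rank_bound(self, small_dataset):
        with pytest.raises(ValueError, match="k=100 exceeds"):
            Extractor("PCA", k=100, mode="projection").fit(
                small_dataset.matrix, small_dataset.y)
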