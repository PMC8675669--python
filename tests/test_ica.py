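"""Entropy measures, Hotelling PCA, the modified ICA fit and feature maps."""

import numpy as np
import pytest

from icawave.ica import (
    ClassComponentModel,
    amari_index,
    entropy,
    extract_features,
    fit_class_components,
    hotelling_pca,
    match_sources,
    mutual_information,
    negentropy,
)
from icawave.synthetic import simulate_mixture
from icawave.wavelets import wavelet_feature_basis


class TestEntropy:
    @pytest.mark.parametrize("p,expect", [
        ([0.5, 0.5], 1.0),
        ([1.0, 0.0, 0.0], 0.0),
        ([0.5, 0.25, 0.25], 1.5),
    ])
    def test_direct_values(self, p, expect):
        assert entropy(p) == pytest.approx(expect, abs=1e-12)

    def test_bounded_by_log_k(self, rng):
        p = rng.dirichlet(np.ones(8))
        assert 0 <= entropy(p) <= 3.0 + 1e-9

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            entropy([-0.1, 1.1])
        with pytest.raises(ValueError):
            entropy([0.3, 0.3])


class TestMutualInformation:
    def test_independent_channels_near_zero(self, rng):
        X = rng.uniform(size=(100_000, 2))
        assert mutual_information(X) < 0.02

    def test_duplicated_channel_carries_self_information(self, rng):
        x = rng.uniform(size=100_000)
        X = np.column_stack([x, x])
        # oracle: marginal entropy under the same binning rule
        edges = np.histogram_bin_edges(x, bins="fd")
        counts, _ = np.histogram(x, bins=edges)
        h = entropy(counts / counts.sum())
        assert mutual_information(X) == pytest.approx(h, rel=0.05)

    def test_nonnegative_within_tolerance(self, rng):
        X = rng.standard_normal((5000, 3))
        assert mutual_information(X) > -0.05

    def test_single_channel_rejected(self, rng):
        with pytest.raises(ValueError):
            mutual_information(rng.uniform(size=(1000, 1)))


class TestNegentropy:
    def test_gaussian_limit(self, rng):
        assert negentropy(rng.standard_normal(100_000)) < 0.01

    def test_laplace_exceeds_gaussian_paired(self):
        for seed in range(10):
            r = np.random.default_rng(seed)
            g = r.standard_normal(100_000)
            l = r.laplace(size=100_000)
            assert negentropy(l) > negentropy(g), seed

    def test_affine_invariance(self, rng):
        x = rng.laplace(size=10_000)
        assert abs(negentropy(x) - negentropy(-3.7 * x + 11.0)) < 1e-10

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            negentropy(np.full(100, 2.0))


class TestHotellingPCA:
    def test_anisotropic_gaussian_first_axis_and_fraction(self, rng):
        X = rng.standard_normal((4000, 2)) * np.array([2.0, 1.0])
        res = hotelling_pca(X, var_target=1.0)
        assert abs(res.B[0, 0]) > 0.99  # first component along the high-variance axis
        assert res.explained_variance[0] == pytest.approx(0.8, abs=0.03)

    @pytest.mark.parametrize("method", ["deflation", "svd"])
    def test_matches_eigendecomposition_oracle(self, rng, method):
        X = rng.standard_normal((500, 6)) @ rng.standard_normal((6, 6))
        res = hotelling_pca(X, var_target=1.0, method=method)
        C = np.cov(X, rowvar=False)
        vals, vecs = np.linalg.eigh(C)
        vals, vecs = vals[::-1], vecs[:, ::-1]
        np.testing.assert_allclose(
            res.explained_variance, vals[:6] / vals.sum(), rtol=1e-6
        )
        for j in range(6):
            assert abs(np.dot(res.B[:, j], vecs[:, j])) == pytest.approx(1.0, abs=1e-5)

    def test_full_rank_target_gives_all_components(self, rng):
        X = rng.standard_normal((100, 5))
        assert hotelling_pca(X, var_target=1.0).B.shape == (5, 5)

    def test_one_dimensional_data(self, rng):
        res = hotelling_pca(rng.standard_normal((50, 1)), var_target=1.0)
        assert res.B.shape == (1, 1)
        assert res.explained_variance[0] == pytest.approx(1.0)

    def test_request_beyond_rank_truncates_with_warning(self, rng):
        X = np.tile(rng.standard_normal((100, 1)), (1, 3))  # rank 1
        with pytest.warns(UserWarning):
            res = hotelling_pca(X, n_components=3)
        assert res.B.shape[1] == 1

    def test_scores_uncorrelated(self, rng):
        X = rng.standard_normal((800, 4)) @ rng.standard_normal((4, 4))
        res = hotelling_pca(X, var_target=1.0)
        C = np.cov(res.S, rowvar=False)
        off = C - np.diag(np.diag(C))
        assert np.max(np.abs(off)) < 1e-8 * max(np.diag(C))


class TestAmariIndex:
    def test_zero_for_scaled_permutation(self):
        P = np.array([[0, 2.0, 0], [0, 0, -0.5], [3.0, 0, 0]])
        assert amari_index(P) == pytest.approx(0.0)

    def test_positive_otherwise(self, rng):
        assert amari_index(rng.standard_normal((4, 4))) > 0


class TestFitClassComponents:
    @pytest.mark.parametrize("noise", [0.0, 0.05])
    def test_recovers_mixture_ground_truth(self, noise):
        H = wavelet_feature_basis("db6", 162, keep="all")
        for seed in (0, 1, 2):
            X, gt = simulate_mixture(2000, 4, 162, H, noise_sd=noise, seed=seed)
            m = fit_class_components(X, H, 4, seed=seed)
            assert amari_index(m.unmixing_total @ gt.S_true.T) < 0.1
            _, mean_corr = match_sources(m.A.T, gt.A_true.T)
            assert mean_corr > 0.95

    def test_identity_basis_matches_sklearn_fastica(self):
        # independent cross-check of the plain-ICA special case
        from sklearn.decomposition import FastICA

        X, gt = simulate_mixture(3000, 3, 32, np.eye(32), noise_sd=0.0, seed=5)
        m = fit_class_components(X, None, 3, seed=5)
        sk = FastICA(n_components=3, fun="logcosh", random_state=0, whiten="unit-variance")
        S_sk = sk.fit_transform(X)
        corrs, mean_corr = match_sources(m.A.T, S_sk.T)
        assert mean_corr > 0.99

    def test_same_seed_bitwise_identical(self):
        H = wavelet_feature_basis("db4", 64, keep="all")
        X, _ = simulate_mixture(500, 3, 64, H, noise_sd=0.01, seed=9)
        m1 = fit_class_components(X, H, 3, seed=42)
        m2 = fit_class_components(X, H, 3, seed=42)
        np.testing.assert_array_equal(m1.A, m2.A)
        np.testing.assert_array_equal(m1.projection, m2.projection)

    def test_unmixing_rows_orthonormal_in_whitened_space(self):
        X, _ = simulate_mixture(800, 4, 64, np.eye(64), seed=3)
        m = fit_class_components(X, None, 4, seed=3)
        np.testing.assert_allclose(m.unmixing @ m.unmixing.T, np.eye(4), atol=1e-6)
        assert m.iterations <= 200

    def test_fitted_scores_uncorrelated(self):
        X, _ = simulate_mixture(1500, 4, 64, np.eye(64), seed=4)
        m = fit_class_components(X, None, 4, seed=4)
        C = np.corrcoef(m.A.T)
        assert np.max(np.abs(C - np.eye(4))) < 1e-6

    def test_negentropy_beats_random_projections(self):
        # fitted components are more non-Gaussian than random orthogonal
        # projections of the same whitened data, paired over seeds
        H = wavelet_feature_basis("db6", 162, keep="all")
        wins = 0
        for seed in range(5):
            X, _ = simulate_mixture(2000, 4, 162, H, noise_sd=0.0, seed=seed)
            m = fit_class_components(X, H, 4, seed=seed)
            fitted = float(np.mean(m.negentropy_per_component))
            Y = X @ H.T
            Yc = Y - Y.mean(axis=0)
            U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
            Z = np.sqrt(Y.shape[0]) * U[:, :4]
            rng = np.random.default_rng(1000 + seed)
            Q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
            rand = float(np.mean([negentropy((Z @ Q)[:, j]) for j in range(4)]))
            wins += fitted > rand
        assert wins == 5

    def test_contract_violations(self):
        X = np.random.default_rng(0).standard_normal((50, 16))
        with pytest.raises(ValueError):
            fit_class_components(X, None, 17)
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_class_components(X, None, 2)


class TestExtractFeatures:
    @pytest.fixture
    def models(self):
        H = wavelet_feature_basis("db6", 162, keep="approx")
        out = {}
        for c, q, seed in zip("NSVF", (6, 5, 5, 5), range(4)):
            X, _ = simulate_mixture(300, q, 162, H, noise_sd=0.01, seed=seed)
            out[c] = fit_class_components(X, H, q, seed=seed, class_label=c)
        return out

    def test_length_and_layout(self, models, rng):
        fv = extract_features(rng.standard_normal(162), models)
        assert len(fv.values) == 21  # 6 + 5 + 5 + 5
        assert fv.layout == {"N": (0, 6), "S": (6, 11), "V": (11, 16), "F": (16, 21)}

    def test_zero_beat_zero_features(self, models):
        fv = extract_features(np.zeros(162), models)
        np.testing.assert_array_equal(fv.values, 0.0)

    def test_linearity(self, models, rng):
        x, y = rng.standard_normal(162), rng.standard_normal(162)
        fa = extract_features(2.0 * x + 0.5 * y, models).values
        fb = 2.0 * extract_features(x, models).values + 0.5 * extract_features(y, models).values
        np.testing.assert_allclose(fa, fb, atol=1e-9)

    def test_purity(self, models, rng):
        x = rng.standard_normal(162)
        np.testing.assert_array_equal(
            extract_features(x, models).values, extract_features(x, models).values
        )

    def test_missing_or_unfitted_model_rejected(self, models, rng):
        x = rng.standard_normal(162)
        with pytest.raises(ValueError):
            extract_features(x, {k: v for k, v in models.items() if k != "F"})
        broken = dict(models)
        broken["N"] = ClassComponentModel(
            class_label="N", A=None, S=None, projection=None, unmixing=None,
            unmixing_total=None, whitening={}, q=6, converged=False,
            iterations=0, negentropy_per_component=np.zeros(6),
        )
        with pytest.raises(ValueError):
            extract_features(x, broken)
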