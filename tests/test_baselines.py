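import numpy as np
import pytest

from enoselearn.signal_io import ResponseCurve
from enoselearn.baselines import (sg_filter, wavelet_denoise,
                                  conductivity_normalize, features_m1,
                                  features_m2, assemble_features,
                                  fit_feature_scaler, apply_feature_scaler,
                                  pca_fit, pca_apply, keca_fit, keca_apply,
                                  svm_train, svm_predict, bpnn_on_features,
                                  M1_FEATURE_NAMES, M2_FEATURE_NAMES)
from enoselearn.stack import FineTuneConfig, predict


def _curve(values, rate=1.0):
    return ResponseCurve("S0", rate, np.asarray(values, dtype=float))


class TestSavitzkyGolay:
    def test_constant_unchanged(self):
        c = _curve(np.full(100, 3.2))
        np.testing.assert_allclose(sg_filter(c, 11, 3).values, 3.2)

    def test_cubic_reproduced_exactly(self):
        t = np.linspace(0, 1, 101)
        y = 2 * t**3 - t**2 + 0.5
        out = sg_filter(_curve(y), 11, 3).values
        np.testing.assert_allclose(out[5:-5], y[5:-5], atol=1e-9)

    def test_smoothing_reduces_noise(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 4 * np.pi, 400)
        clean = np.sin(t)
        noisy = clean + rng.normal(0, 0.2, t.size)
        out = sg_filter(_curve(noisy), 31, 3).values
        assert np.var(out - clean) < np.var(noisy - clean)

    def test_preconditions(self):
        c = _curve(np.arange(20.0))
        with pytest.raises(ValueError):
            sg_filter(c, 10, 3)     # even window
        with pytest.raises(ValueError):
            sg_filter(c, 11, 11)    # order >= window
        with pytest.raises(ValueError):
            sg_filter(c, 51, 3)     # window > length


class TestWaveletDenoise:
    def test_zero_curve_stays_zero(self):
        out = wavelet_denoise(_curve(np.zeros(128)), level=3).values
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_threshold_zero_is_perfect_reconstruction(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=200)
        out = wavelet_denoise(_curve(y), level=3, threshold=0.0).values
        np.testing.assert_allclose(out, y, atol=1e-9)

    def test_denoising_improves_rmse_on_noisy_step(self):
        rng = np.random.default_rng(2)
        clean = np.concatenate([np.zeros(128), np.ones(128)])
        noisy = clean + rng.normal(0, 0.3, 256)
        out = wavelet_denoise(_curve(noisy), level=4).values
        assert np.sqrt(np.mean((out - clean) ** 2)) < \
            np.sqrt(np.mean((noisy - clean) ** 2))

    def test_infeasible_level_rejected(self):
        with pytest.raises(ValueError):
            wavelet_denoise(_curve(np.zeros(16)), level=10)


class TestConductivityNormalize:
    def test_constant_baseline_gives_ones(self):
        out = conductivity_normalize(_curve(np.full(20, 4.0))).values
        np.testing.assert_allclose(out, 1.0)

    def test_gain_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.uniform(1, 2, 50)
        a = conductivity_normalize(_curve(y)).values
        b = conductivity_normalize(_curve(2 * y)).values
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_explicit_division_oracle(self):
        y = np.arange(1.0, 21.0)
        out = conductivity_normalize(_curve(y)).values
        np.testing.assert_allclose(out, y / y[:5].mean())

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            conductivity_normalize(_curve(np.zeros(10)))


class TestFeatureBanks:
    def test_m1_basic_descriptors(self):
        f = features_m1(_curve([0, 1, 3, 2, 1]))
        assert f["t_max"] == 2.0
        assert f["mean"] == pytest.approx(1.4)
        assert list(f) == M1_FEATURE_NAMES

    def test_m1_guarded_means(self):
        # all-positive short curve: plain geometric / harmonic means
        f = features_m1(_curve([1, 4, 4]))
        assert f["gmean"] == pytest.approx((1 * 4 * 4) ** (1 / 3), rel=1e-9)
        assert f["hmean"] == pytest.approx(3 / (1 + 0.25 + 0.25), rel=1e-9)

    def test_m1_straight_line(self):
        f = features_m1(_curve(2.0 * np.arange(10) + 1.0))
        assert f["mean_curvature"] == pytest.approx(0.0, abs=1e-12)
        assert f["avg_diff"] == pytest.approx(2.0)

    def test_m2_basic_descriptors(self):
        f = features_m2(_curve([0, 1, 3, 2, 1]))
        assert f["max"] == 3.0
        # central difference at index 1: (3 - 0)/2 = 1.5, first occurrence
        assert f["max_deriv"] == pytest.approx(1.5)
        assert f["value_at_max_deriv"] == 1.0
        assert list(f) == M2_FEATURE_NAMES

    def test_m2_constant_curve(self):
        f = features_m2(_curve(np.full(10, 7.0)))
        assert (f["max"], f["max_deriv"], f["value_at_max_deriv"],
                f["min_deriv"], f["max_second_deriv"]) == (7, 0, 7, 0, 0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            features_m1(_curve([1, 2]))
        with pytest.raises(ValueError):
            features_m2(_curve([1, 2]))

    def test_time_features_scale_with_sampling_interval(self):
        y = np.concatenate([np.zeros(10), np.linspace(0, 1, 20), np.ones(10)])
        f1 = features_m1(_curve(y, rate=1.0))
        f2 = features_m1(_curve(y, rate=2.0))
        assert f1["t_max"] == pytest.approx(2 * f2["t_max"])
        assert f1["t_max_deriv"] == pytest.approx(2 * f2["t_max_deriv"])


class TestAssembleFeatures:
    def test_feature_space_dimensions(self, small_set):
        fm1 = assemble_features(small_set, "m1", preprocess=False)
        fm2 = assemble_features(small_set, "m2", preprocess=False)
        n_sensors = len(small_set.panel)
        assert fm1.values.shape == (len(small_set), 10 * n_sensors)
        assert fm2.values.shape == (len(small_set), 5 * n_sensors)

    def test_ten_sensor_panel_yields_100_and_50_columns(self, default_set_1hz):
        sub = type(default_set_1hz)(default_set_1hz.samples[:4],
                                    default_set_1hz.class_names,
                                    default_set_1hz.panel)
        assert assemble_features(sub, "m1").values.shape[1] == 100
        assert assemble_features(sub, "m2").values.shape[1] == 50

    def test_zscore_round_trip(self):
        rng = np.random.default_rng(0)
        X = rng.normal(3, 5, (30, 4))
        sc = fit_feature_scaler(X)
        Z = apply_feature_scaler(sc, X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, rtol=1e-12)


class TestPCA:
    def test_exact_line_k1(self):
        t = np.linspace(-1, 1, 20)
        X = np.column_stack([t, 2 * t + 1])
        m = pca_fit(X, 1)
        R = pca_apply(m, X)
        Xc = X - X.mean(axis=0)
        recon = R @ m.pca.components_
        np.testing.assert_allclose(recon, Xc, atol=1e-12)

    def test_full_rank_projection_is_isometry(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(15, 5))
        R = pca_apply(pca_fit(X, 5), X)
        from scipy.spatial.distance import pdist
        np.testing.assert_allclose(pdist(R), pdist(X), atol=1e-9)

    def test_matches_independent_eigendecomposition_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 6))
        k = 3
        m = pca_fit(X, k)
        R = pca_apply(m, X)
        # independent oracle: eigendecomposition of the sample covariance
        Xc = X - X.mean(axis=0)
        C = Xc.T @ Xc / (X.shape[0] - 1)
        w, V = np.linalg.eigh(C)
        order = np.argsort(w)[::-1][:k]
        V = V[:, order]
        flips = np.sign(V[np.abs(V).argmax(axis=0), np.arange(k)])
        V = V * flips
        np.testing.assert_allclose(R, Xc @ V, atol=1e-9)

    def test_k_out_of_range_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(ValueError):
            pca_fit(X, 5)


class TestKECA:
    def test_resolution_of_identity(self):
        """Summed Renyi-entropy contributions over all eigenpairs equal
        1^T K 1 — the components resolve the full entropy estimate."""
        rng = np.random.default_rng(6)
        X = rng.normal(size=(25, 4))
        m = keca_fit(X, k=25, sigma_k=1.3)
        from scipy.spatial.distance import cdist
        K = np.exp(-cdist(X, X, "sqeuclidean") / (2 * 1.3**2))
        total = float(np.ones(25) @ K @ np.ones(25))
        assert float(np.sum(m.entropy_contrib)) == pytest.approx(total,
                                                                 rel=1e-10)

    def test_training_projection_rows(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(15, 3))
        m = keca_fit(X, k=4, sigma_k=1.0)
        P = keca_apply(m, X)
        np.testing.assert_allclose(P, m.eigvecs * np.sqrt(m.eigvals),
                                   atol=1e-10)

    def test_equivalence_with_kernel_pca_when_orderings_agree(self):
        """On data where the entropy ordering coincides with the eigenvalue
        ordering, KECA reproduces the (uncentered) kernel-PCA projection.
        The oracle is an independent eigendecomposition of the kernel."""
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0, 0.1, (12, 3)),
                       rng.normal(5, 0.1, (12, 3))])
        sigma = 2.0
        k = 2
        from scipy.spatial.distance import cdist
        K = np.exp(-cdist(X, X, "sqeuclidean") / (2 * sigma**2))
        lam, E = np.linalg.eigh(K)
        eig_order = np.argsort(lam)[::-1][:k]
        contrib = np.clip(lam, 0, None) * (E.sum(axis=0) ** 2)
        ent_order = np.argsort(contrib)[::-1][:k]
        assert set(eig_order) == set(ent_order)  # orderings agree here
        m = keca_fit(X, k=k, sigma_k=sigma)
        P = keca_apply(m, X)
        kpca = E[:, ent_order] * np.sqrt(lam[ent_order])
        # eigenvectors are sign-arbitrary: compare per-column up to sign
        for j in range(k):
            assert (np.allclose(P[:, j], kpca[:, j], atol=1e-9)
                    or np.allclose(P[:, j], -kpca[:, j], atol=1e-9))

    def test_two_clusters_separate_linearly(self):
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(0, 0.2, (15, 4)),
                       rng.normal(6, 0.2, (15, 4))])
        y = np.array([0] * 15 + [1] * 15)
        m = keca_fit(X, k=2)
        P = keca_apply(m, X)
        from sklearn.linear_model import LogisticRegression
        clf = LogisticRegression().fit(P, y)
        assert clf.score(P, y) == 1.0

    def test_nystrom_consistency_on_held_out_points(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(20, 3))
        m = keca_fit(X[:15], k=3, sigma_k=1.0)
        out = keca_apply(m, X[15:])
        assert out.shape == (5, 3) and np.all(np.isfinite(out))


class TestClassifierBackends:
    def test_svm_separable_and_self_prediction(self):
        rng = np.random.default_rng(11)
        X = np.vstack([rng.normal(0, 0.2, (10, 2)),
                       rng.normal(3, 0.2, (10, 2))])
        y = np.array([0] * 10 + [1] * 10)
        clf = svm_train(X, y)
        assert np.mean(svm_predict(clf, X) == y) == 1.0
        assert svm_predict(clf, X[:1])[0] == 0

    def test_svm_xor_with_rbf(self):
        rng = np.random.default_rng(12)
        centers = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        labels = np.array([0, 0, 1, 1])
        X = np.vstack([c + rng.normal(0, 0.05, (12, 2)) for c in centers])
        y = np.repeat(labels, 12)
        clf = svm_train(X, y, gamma=2.0)
        assert np.mean(svm_predict(clf, X) == y) == 1.0

    def test_svm_single_class_rejected(self):
        with pytest.raises(ValueError):
            svm_train(np.zeros((5, 2)), np.zeros(5))

    def test_bpnn_on_separable_features(self):
        rng = np.random.default_rng(13)
        X = np.vstack([rng.uniform(0, 0.3, (10, 4)),
                       rng.uniform(0.7, 1.0, (10, 4))])
        y = np.array([0] * 10 + [1] * 10)
        net, report = bpnn_on_features(
            X, y, (5,), FineTuneConfig(epochs=200, batch_size=5, seed=0))
        assert np.mean(predict(net, X) == y) == 1.0

    def test_bpnn_zero_epochs_gives_valid_probabilities(self):
        X = np.random.default_rng(14).uniform(0, 1, (6, 4))
        y = np.array([0, 1, 0, 1, 0, 1])
        net, _ = bpnn_on_features(X, y, (3,),
                                  FineTuneConfig(epochs=0, seed=0))
        from enoselearn.stack import forward_classify
        p = forward_classify(net, X)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
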