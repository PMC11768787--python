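import numpy as np
import pytest

from protonet.dpm import BasisSet, PrototypeBasis
from protonet.rbf import (
    SingleLayerRBFNet,
    TwoLayerConfig,
    TwoLayerRBFNet,
    _iso_activations,
    activations,
    embedding_gradient,
    loss_cross_entropy,
    predict,
    rbf_activation,
    select_inducing_points,
    two_layer_loss_from_embedding,
    w2_gradient,
)


def _basis(center, scale, sub="N1", cls="non_tremor"):
    return PrototypeBasis(
        center=np.asarray(center, float), scale=np.asarray(scale, float),
        sub_class=sub, class_label=cls,
    )


def _toy_basis_set(d=2):
    return BasisSet(
        bases=[
            _basis(np.zeros(d), np.ones(d), "T1", "tremor"),
            _basis(np.full(d, 4.0), np.ones(d), "N7", "non_tremor"),
        ]
    )


def _separable(n=200, d=2, seed=0):
    rng = np.random.default_rng(seed)
    X0 = rng.standard_normal((n // 2, d)) * 0.3 + 4.0
    X1 = rng.standard_normal((n // 2, d)) * 0.3
    X = np.concatenate([X0, X1])
    y = np.concatenate([np.zeros(n // 2, int), np.ones(n // 2, int)])
    return X, y


class TestActivation:
    def test_unit_at_center(self):
        b = _basis([1.0, -2.0], [0.5, 2.0])
        assert rbf_activation(np.array([1.0, -2.0]), b) == 1.0

    def test_unit_scales_reduce_to_euclidean(self):
        b = _basis(np.zeros(3), np.ones(3))
        x = np.array([1.0, 2.0, -1.0])
        assert rbf_activation(x, b) == pytest.approx(np.exp(-np.sum(x**2) / 2))

    def test_matches_per_coordinate_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            c = rng.standard_normal(45)
            s = rng.uniform(0.5, 3.0, 45)
            x = rng.standard_normal(45)
            d2 = 0.0
            for j in range(45):
                d2 += (x[j] - c[j]) ** 2 / s[j]
            assert rbf_activation(x, _basis(c, s)) == pytest.approx(
                np.exp(-d2 / 2), abs=1e-12
            )

    def test_dim_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rbf_activation(np.zeros(3), _basis(np.zeros(2), np.ones(2)))

    def test_matrix_activations_in_unit_interval(self):
        rng = np.random.default_rng(1)
        phi = activations(
            rng.standard_normal((50, 4)) * 10,
            rng.standard_normal((6, 4)),
            rng.uniform(0.1, 1.0, (6, 4)),
        )
        assert np.all((phi > 0) & (phi <= 1.0))


class TestSingleLayer:
    def test_zero_weights_give_half_probability(self):
        X, y = _separable()
        model = SingleLayerRBFNet(y, X, _toy_basis_set())
        res = model.fit()
        res.weights = np.zeros_like(res.weights)
        res.intercept = 0.0
        np.testing.assert_allclose(res.predict_proba(X), 0.5)

    def test_probability_saturates_with_large_weight(self):
        bs = BasisSet(bases=[_basis(np.zeros(2), np.ones(2), "T1", "tremor")])
        X, y = _separable()
        res = SingleLayerRBFNet(y, X, bs, bandwidth=1.0).fit()
        res.weights = np.array([50.0])
        res.intercept = 0.0
        p = res.predict_proba(np.zeros((1, 2)))
        assert p[0] > 0.99

    def test_forward_matches_score_then_sigmoid_recomputation(self):
        X, y = _separable(seed=3)
        res = SingleLayerRBFNet(y, X, _toy_basis_set()).fit()
        phi = res.model.transform(X)
        expected = 1.0 / (1.0 + np.exp(-(phi @ res.weights + res.intercept)))
        np.testing.assert_allclose(res.predict_proba(X), expected, atol=1e-12)

    def test_separable_prototype_clusters_reach_high_auroc(self):
        from sklearn.metrics import roc_auc_score

        X, y = _separable()
        res = SingleLayerRBFNet(y, X, _toy_basis_set()).fit()
        assert roc_auc_score(y, res.predict_proba(X)) >= 0.99

    def test_label_flip_negates_weights(self):
        X, y = _separable(seed=4)
        r1 = SingleLayerRBFNet(y, X, _toy_basis_set()).fit()
        r2 = SingleLayerRBFNet(1 - y, X, _toy_basis_set()).fit()
        np.testing.assert_allclose(r1.weights, -r2.weights, atol=1e-4)
        assert r1.intercept == pytest.approx(-r2.intercept, abs=1e-4)

    def test_strong_regularization_shrinks_to_prior(self):
        X, y = _separable(seed=5)
        res = SingleLayerRBFNet(y, X, _toy_basis_set()).fit(reg=1e8)
        assert np.max(np.abs(res.weights)) < 1e-3
        np.testing.assert_allclose(res.predict_proba(X), y.mean(), atol=0.01)

    def test_single_class_rejected(self):
        X, _ = _separable()
        with pytest.raises(ValueError):
            SingleLayerRBFNet(np.zeros(len(X), int), X, _toy_basis_set())

    def test_summary_mentions_bases_and_subclasses(self):
        X, y = _separable()
        res = SingleLayerRBFNet(y, X, _toy_basis_set()).fit()
        text = res.summary()
        assert "bases (K):          2" in text
        assert "T1" in text and "N7" in text


class TestInducingPoints:
    def test_all_points_selected_when_k_equals_n(self):
        X = np.random.default_rng(0).standard_normal((15, 3))
        _, _, idx = select_inducing_points(X, 15)
        assert sorted(idx) == list(range(15))

    def test_two_clusters_covered_by_two_points(self):
        rng = np.random.default_rng(1)
        X = np.concatenate(
            [rng.standard_normal((40, 2)) * 0.1, rng.standard_normal((40, 2)) * 0.1 + 20]
        )
        centers, _, _ = select_inducing_points(X, 2)
        sides = centers[:, 0] > 10
        assert sides.sum() == 1  # one from each cluster

    def test_duplicates_not_selected_while_distinct_remain(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal((10, 2))
        X = np.concatenate([base, base])  # every row duplicated
        _, _, idx = select_inducing_points(X, 10)
        assert len({tuple(X[i]) for i in idx}) == 10

    def test_k_beyond_n_rejected(self):
        with pytest.raises(ValueError):
            select_inducing_points(np.zeros((5, 2)), 6)


class TestLoss:
    def test_exact_predictions_have_zero_loss(self):
        # up to the 1e-12 probability clip
        y = np.array([0, 1, 1, 0])
        assert loss_cross_entropy(y, y.astype(float)) == pytest.approx(0.0, abs=1e-10)

    def test_uninformative_half_is_log_two(self):
        y = np.array([0, 1, 1, 0])
        assert loss_cross_entropy(y, np.full(4, 0.5)) == pytest.approx(np.log(2))

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50)
        p = rng.uniform(0.01, 0.99, 50)
        manual = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert loss_cross_entropy(y, p) == pytest.approx(manual, abs=1e-12)


class TestGradients:
    def _small_instance(self, seed=0, n=8, m=3, k2=4):
        rng = np.random.default_rng(seed)
        Xstar = rng.standard_normal((n, m))
        centers = rng.standard_normal((k2, m))
        scales = rng.uniform(0.5, 2.0, (k2, m))
        W2 = rng.standard_normal((k2 + 1, 2))
        y = rng.integers(0, 2, n)
        return Xstar, centers, scales, W2, y

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_embedding_gradient_matches_central_differences(self, seed):
        Xstar, centers, scales, W2, y = self._small_instance(seed)
        grad = embedding_gradient(Xstar, centers, scales, W2, y)
        eps = 1e-6
        fd = np.zeros_like(Xstar)
        for i in range(Xstar.shape[0]):
            for j in range(Xstar.shape[1]):
                up, dn = Xstar.copy(), Xstar.copy()
                up[i, j] += eps
                dn[i, j] -= eps
                fd[i, j] = (
                    two_layer_loss_from_embedding(up, centers, scales, W2, y)
                    - two_layer_loss_from_embedding(dn, centers, scales, W2, y)
                ) / (2 * eps)
        denom = max(np.max(np.abs(fd)), 1e-12)
        assert np.max(np.abs(grad - fd)) / denom < 1e-4

    def test_gradient_zero_at_basis_center(self):
        Xstar, centers, scales, W2, y = self._small_instance(3)
        Xstar[0] = centers[0]
        # contribution of basis 0 to row 0 vanishes: (x*-c) factor is 0
        from protonet.rbf import _softmax2, activations as acts

        phi2 = acts(Xstar, centers, scales)
        P = _softmax2(phi2 @ W2[:-1] + W2[-1])
        Y = np.stack([1 - y.astype(float), y.astype(float)], axis=1)
        T = ((P - Y) @ W2[:-1].T / len(Xstar)) * phi2
        contrib = -T[0, 0] * (Xstar[0] - centers[0]) / scales[0]
        np.testing.assert_allclose(contrib, 0.0)

    def test_zero_w2_gives_zero_embedding_gradient(self):
        Xstar, centers, scales, W2, y = self._small_instance(4)
        grad = embedding_gradient(Xstar, centers, scales, np.zeros_like(W2), y)
        np.testing.assert_allclose(grad, 0.0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_w2_gradient_matches_central_differences(self, seed):
        Xstar, centers, scales, W2, y = self._small_instance(seed)
        from protonet.rbf import activations as acts

        phi2 = acts(Xstar, centers, scales)
        grad = w2_gradient(phi2, y, W2)
        eps = 1e-6
        fd = np.zeros_like(W2)
        for i in range(W2.shape[0]):
            for j in range(W2.shape[1]):
                up, dn = W2.copy(), W2.copy()
                up[i, j] += eps
                dn[i, j] -= eps
                fd[i, j] = (
                    two_layer_loss_from_embedding(Xstar, centers, scales, up, y)
                    - two_layer_loss_from_embedding(Xstar, centers, scales, dn, y)
                ) / (2 * eps)
        denom = max(np.max(np.abs(fd)), 1e-12)
        assert np.max(np.abs(grad - fd)) / denom < 1e-4

    def test_shape_mismatch_rejected(self):
        Xstar, centers, scales, W2, y = self._small_instance(5)
        with pytest.raises(ValueError):
            embedding_gradient(Xstar[:, :2], centers, scales, W2, y)


class TestTwoLayer:
    def _toy_model(self, seed=0, **cfg_kw):
        rng = np.random.default_rng(seed)
        n = 120
        X0 = rng.standard_normal((n // 2, 6)) * 0.3
        X1 = rng.standard_normal((n // 2, 6)) * 0.3
        X0[:, 0] += 4.0
        X = np.concatenate([X0, X1])
        y = np.concatenate([np.zeros(n // 2, int), np.ones(n // 2, int)])
        groups = [
            ("N7", "non_tremor", X0[:1]),
            ("T1", "tremor", X1[:1]),
        ]
        cfg = TwoLayerConfig(
            embedding_dim=3, n_inducing=20, seed=seed, max_iter=300, **cfg_kw
        )
        return TwoLayerRBFNet(y, X, groups, config=cfg), X, y

    def test_pseudo_inverse_step_is_least_squares_optimal(self):
        """After the W1 update, no weight matrix achieves a lower residual
        (agreement with a direct solver to 1e-8)."""
        rng = np.random.default_rng(0)
        phi1 = _iso_activations(rng.standard_normal((30, 4)), rng.standard_normal((8, 4)), 1.0)
        target = rng.standard_normal((30, 3))
        W1 = np.linalg.lstsq(phi1, target, rcond=None)[0]
        direct = np.linalg.pinv(phi1) @ target
        np.testing.assert_allclose(W1, direct, atol=1e-8)
        r_mine = np.linalg.norm(phi1 @ W1 - target)
        for _ in range(20):
            other = W1 + 0.01 * rng.standard_normal(W1.shape)
            assert np.linalg.norm(phi1 @ other - target) >= r_mine - 1e-10

    def test_initial_embedding_consistency_full_rank(self):
        """With a full-column-rank first layer, Phi1 @ W1 reproduces the PCA
        initialization of the embeddings."""
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 6))
        C1, s1, _ = select_inducing_points(X, 40)
        phi1 = _iso_activations(X, C1, s1)
        assert np.linalg.matrix_rank(phi1) == 40
        Xstar0 = PCA(n_components=3, svd_solver="full").fit(C1).transform(X)
        W1 = np.linalg.lstsq(phi1, Xstar0, rcond=None)[0]
        np.testing.assert_allclose(phi1 @ W1, Xstar0, atol=1e-8)

    def test_pca_init_recovers_planted_subspace(self):
        """Data living on an M-dim linear subspace of R^D is embedded with
        near-zero reconstruction error by the PCA initialization."""
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(2)
        latent = rng.standard_normal((60, 3))
        basis, _ = np.linalg.qr(rng.standard_normal((8, 3)))
        X = latent @ basis.T
        pca = PCA(n_components=3, svd_solver="full").fit(X)
        back = pca.inverse_transform(pca.transform(X))
        assert np.max(np.abs(back - X)) < 1e-8

    def test_fixed_seed_reproduces_fit(self):
        m1, X, _ = self._toy_model(seed=7)
        m2, _, _ = self._toy_model(seed=7)
        r1, r2 = m1.fit(), m2.fit()
        np.testing.assert_array_equal(r1.W2, r2.W2)
        np.testing.assert_allclose(r1.predict_proba(X), r2.predict_proba(X))

    def test_training_reduces_loss_and_separates_toy_classes(self):
        from sklearn.metrics import roc_auc_score

        model, X, y = self._toy_model(seed=0)
        res = model.fit()
        assert res.loss_history[-1] < res.loss_history[0]
        assert roc_auc_score(y, res.predict_proba(X)) >= 0.99

    def test_zero_learning_rate_stops_immediately(self):
        model, _, _ = self._toy_model(seed=1)
        res = model.fit(eta=0.0)
        assert res.n_iter == 0
        assert len(res.loss_history) == 1

    def test_small_s1_limit_interpolates_training_points(self):
        """With K(1)=N and a tiny shared scale, the first layer approaches an
        interpolator: each training point maps to its own target row."""
        rng = np.random.default_rng(3)
        X = rng.standard_normal((25, 4))
        C1, s1, idx = select_inducing_points(X, 25)
        dmed = np.median(
            np.sqrt(
                ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)[
                    np.triu_indices(25, k=1)
                ]
            )
        )
        phi1 = _iso_activations(X, C1, 1e-3 * dmed)
        target = rng.standard_normal((25, 2))
        W1 = np.linalg.lstsq(phi1, target, rcond=None)[0]
        np.testing.assert_allclose(phi1 @ W1, target, atol=1e-6)

    def test_predict_dispatch_and_threshold(self):
        model, X, y = self._toy_model(seed=4)
        res = model.fit()
        with pytest.raises(ValueError):
            res.predict(X)
        res.threshold = 0.5
        labels = predict(res, X, proba=False)
        assert set(labels) <= {0, 1}
        probs = predict(res, X)
        np.testing.assert_array_equal(labels, (probs >= 0.5).astype(int))
        with pytest.raises(TypeError):
            predict(object(), X)

    def test_summary_reports_architecture(self):
        model, _, _ = self._toy_model(seed=5)
        res = model.fit()
        text = res.summary()
        assert "embedding dim (M):    3" in text
        assert "inducing points" in text
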