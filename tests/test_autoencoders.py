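import numpy as np
import pytest

from scgnn import (
    DenseAEConfig,
    ExpressionMatrix,
    ImputationRegularizerConfig,
    feature_ae_loss,
    imputation_ae_loss,
    train_cluster_ae,
    train_feature_ae,
    train_imputation_ae,
)
from scgnn.clustering import ClusterAssignment

CFG = DenseAEConfig(encoder_dims=(32, 8), epochs=60, seed=0)


def _expr(values, tag="preprocessed"):
    n, m = values.shape
    return ExpressionMatrix(values, [f"c{i}" for i in range(n)], [f"g{j}" for j in range(m)], tag)


class TestFeatureLoss:
    def test_zero_residual_is_zero(self, rng):
        x = rng.random((4, 3))
        w = rng.random((4, 3))
        for alpha in (0.0, 0.3, 1.0):
            assert feature_ae_loss(x, x, w, alpha) == 0.0

    def test_alpha_zero_reduces_to_sse(self, rng):
        x, xh = rng.random((5, 4)), rng.random((5, 4))
        w = rng.random((5, 4))
        assert feature_ae_loss(x, xh, w, 0.0) == pytest.approx(((x - xh) ** 2).sum(), abs=1e-12)

    def test_two_by_two_hand_enumeration(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        xh = np.array([[0.0, 2.0], [5.0, 3.0]])
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        # residuals^2: [[1,0],[4,1]]; weighted sum = 0*1+1*0+1*4+0*1 = 4
        expected = 0.5 * (1 + 0 + 4 + 1) + 0.5 * 4
        assert feature_ae_loss(x, xh, w, 0.5) == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            feature_ae_loss(rng.random((2, 2)), rng.random((2, 3)), rng.random((2, 2)), 0.5)


class TestImputationLoss:
    def test_perfect_reconstruction_zero_weights_gives_zero(self, rng):
        x = rng.random((3, 4))
        a = np.zeros((3, 3))
        b = np.zeros((3, 3))
        loss = imputation_ae_loss(x, x, np.ones_like(x), a, b, [np.zeros((2, 2))],
                                  ImputationRegularizerConfig())
        assert loss == 0.0

    def test_reduces_to_feature_loss(self, rng):
        x, xh = rng.random((4, 5)), rng.random((4, 5))
        w = rng.random((4, 5))
        reg = ImputationRegularizerConfig(alpha=0.3, beta=0.0, gamma1=0.0, gamma2=0.0)
        full = imputation_ae_loss(x, xh, w, np.zeros((4, 4)), np.zeros((4, 4)),
                                  [np.ones((3, 3))], reg)
        assert full == pytest.approx(feature_ae_loss(x, xh, w, 0.3), abs=1e-12)

    def test_three_cell_toy_hand_enumeration(self):
        x = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 2.0]])
        xh = np.zeros((3, 2))
        trs = np.ones((3, 2))
        a = np.zeros((3, 3)); a[0, 1] = a[1, 0] = 1.0            # one edge
        b = np.zeros((3, 3)); b[1, 2] = b[2, 1] = 1.0; np.fill_diagonal(b, 1.0)
        weights = [np.array([[1.0, -2.0]])]
        reg = ImputationRegularizerConfig(alpha=0.5, beta=0.5, gamma1=0.1, gamma2=0.2)
        s = (x ** 2).sum(axis=1)  # per-cell squared residual: [1, 1, 8]
        expected = (
            0.5 * (x ** 2).sum() + 0.5 * (x ** 2).sum()     # TRS weights all one
            + 0.5 * 3.0                                      # beta * sum|w|
            + 0.1 * (a.sum(axis=0) @ s)                      # graph term (literal)
            + 0.2 * (b.sum(axis=0) @ s)                      # co-cluster term
        )
        got = imputation_ae_loss(x, xh, trs, a, b, weights, reg, pair_mode="literal")
        assert got == pytest.approx(expected, abs=1e-12)

    def test_coupled_mode_matches_enumeration(self, rng):
        x, xh = rng.random((4, 3)), rng.random((4, 3))
        r = x - xh
        a = (rng.random((4, 4)) > 0.5).astype(float)
        a = np.triu(a, 1); a = a + a.T
        reg = ImputationRegularizerConfig(alpha=0.0, beta=0.0, gamma1=0.7, gamma2=0.0)
        got = imputation_ae_loss(x, xh, np.zeros_like(x), a, np.zeros((4, 4)), [], reg,
                                 pair_mode="coupled")
        expected = ((x - xh) ** 2).sum() + 0.7 * sum(
            a[i, j] * (r[i] @ r[j]) for i in range(4) for j in range(4)
        )
        assert got == pytest.approx(expected, abs=1e-10)


class TestTrainFeatureAE:
    def test_descent_shapes_and_determinism(self, rng):
        x = _expr(rng.gamma(2, 1, size=(30, 12)))
        w = rng.random((30, 12))
        emb, recon, losses, _ = train_feature_ae(x, w, CFG, alpha=0.5)
        assert losses[-1] < losses[0]
        assert emb.vectors.shape == (30, 8)
        assert recon.values.shape == x.values.shape
        emb2, recon2, _, _ = train_feature_ae(x, w, CFG, alpha=0.5)
        np.testing.assert_array_equal(emb.vectors, emb2.vectors)
        np.testing.assert_array_equal(recon.values, recon2.values)

    def test_rank_one_matrix_reconstructed(self, rng):
        u = rng.random(40)[:, None]
        v = rng.random(15)[None, :]
        x = _expr(u @ v * 5.0)
        cfg = DenseAEConfig(encoder_dims=(32, 8), epochs=400, seed=1)
        _, recon, _, _ = train_feature_ae(x, np.zeros_like(x.values), cfg, alpha=0.0)
        corr = np.corrcoef(x.values.ravel(), recon.values.ravel())[0, 1]
        assert corr > 0.95


class TestTrainClusterAE:
    def test_cluster_independence_and_order(self, rng):
        values = rng.gamma(2, 1, size=(30, 10))
        x = _expr(values, tag="reconstructed")
        labels = np.repeat([0, 1], 15)
        clusters = ClusterAssignment(labels, 2)
        out1, traces = train_cluster_ae(x, clusters, CFG, min_cells=5)
        assert out1.cell_ids == x.cell_ids
        for tr in traces.values():
            assert tr[-1] < tr[0]
        # permuting cluster-1 rows must not change cluster-0 outputs
        perm = np.arange(30)
        perm[15:] = 15 + rng.permutation(15)
        x_perm = _expr(values[perm], tag="reconstructed")
        out2, _ = train_cluster_ae(x_perm, ClusterAssignment(labels, 2), CFG, min_cells=5)
        np.testing.assert_allclose(out1.values[:15], out2.values[:15], atol=1e-6)

    def test_small_clusters_pass_through(self, rng):
        values = rng.gamma(2, 1, size=(12, 6))
        x = _expr(values, tag="reconstructed")
        labels = np.array([0] * 9 + [1] * 3)
        out, traces = train_cluster_ae(x, ClusterAssignment(labels, 2), CFG, min_cells=5)
        np.testing.assert_array_equal(out.values[9:], values[9:])
        assert 1 not in traces


class TestTrainImputationAE:
    def test_reduces_to_feature_ae_with_zero_regularizers(self, rng):
        values = rng.gamma(2, 1, size=(20, 8))
        x = _expr(values)
        trs = rng.random((20, 8))
        reg = ImputationRegularizerConfig(alpha=0.0, beta=0.0, gamma1=0.0, gamma2=0.0)
        clusters = ClusterAssignment(np.zeros(20, dtype=int), 1)
        imputed, _ = train_imputation_ae(x, trs, np.zeros((20, 20)), clusters, CFG, reg)
        _, recon, _, _ = train_feature_ae(x, trs, CFG, alpha=0.0)
        np.testing.assert_allclose(imputed.values, np.maximum(recon.values, 0.0), atol=1e-6)

    def test_output_finite_nonnegative(self, rng):
        values = rng.gamma(2, 1, size=(20, 8))
        values[rng.random(values.shape) < 0.5] = 0.0
        x = _expr(values)
        clusters = ClusterAssignment(np.repeat([0, 1], 10), 2)
        a = np.zeros((20, 20)); a[0, 1] = a[1, 0] = 1.0
        imputed, losses = train_imputation_ae(
            x, np.zeros_like(values), a, clusters, CFG, ImputationRegularizerConfig()
        )
        assert np.all(np.isfinite(imputed.values)) and np.all(imputed.values >= 0)
        assert imputed.layer_tag == "imputed"

    def test_l1_strength_does_not_increase_active_weights(self, rng):
        values = rng.gamma(2, 1, size=(25, 10))
        x = _expr(values)
        clusters = ClusterAssignment(np.zeros(25, dtype=int), 1)
        counts = {}
        for beta in (0.0, 0.5):
            reg = ImputationRegularizerConfig(alpha=0.0, beta=beta, gamma1=0.0, gamma2=0.0)
            cfg = DenseAEConfig(encoder_dims=(32, 8), epochs=150, seed=3)
            from scgnn.autoencoders import DenseAutoencoder, _GeneScaler

            scaler = _GeneScaler(values)
            ae = DenseAutoencoder(10, cfg)
            ae.fit(scaler.transform(values), l1=beta)
            counts[beta] = sum(int((np.abs(w) > 1e-3).sum()) for w in ae.W)
        assert counts[0.5] <= counts[0.0]
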