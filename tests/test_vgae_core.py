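import dataclasses

import numpy as np
import pytest

from spatialink import vgae_core
from spatialink.spatial_graph import CellGraph, build_adjacency, split_edges
from spatialink.vgae_core import (
    ModelConfig,
    decode,
    discriminator_forward,
    elbo_loss,
    encode,
    init_parameters,
    kl_divergence,
    normalize_adjacency,
    score_pairs,
    train,
)


class TestNormalizeAdjacency:
    def test_single_isolated_cell(self):
        np.testing.assert_allclose(
            normalize_adjacency(CellGraph(1, set())), [[1.0]]
        )

    def test_two_connected_cells(self):
        A = normalize_adjacency(CellGraph(2, {(0, 1)}))
        np.testing.assert_allclose(A, 0.5 * np.ones((2, 2)))

    def test_three_node_path(self):
        A = normalize_adjacency(CellGraph(3, {(0, 1), (1, 2)}))
        # degrees with self-loops: (2, 3, 2)
        assert A[0, 1] == pytest.approx(1 / np.sqrt(6))
        assert A[0, 0] == pytest.approx(1 / 2)
        assert A[1, 1] == pytest.approx(1 / 3)
        np.testing.assert_allclose(A, A.T)

    def test_isolated_cell_row_is_valid(self):
        A = normalize_adjacency(CellGraph(3, {(0, 1)}))
        np.testing.assert_allclose(A[2], [0, 0, 1.0])


class TestEncoder:
    def _setup(self, rng, n=6, g=4):
        X = rng.random((n, g))
        coords = rng.random((n, 2)) * 5
        graph = build_adjacency(coords, k=2, distance_threshold=np.inf)
        A_norm = normalize_adjacency(graph)
        cfg = ModelConfig(hidden1=5, latent=3, disc_h1=4, disc_h2=4, seed=1)
        return X, A_norm, init_parameters(g, cfg)

    def test_zero_features_give_zero_embedding(self, rng):
        X, A_norm, params = self._setup(rng)
        emb = encode(np.zeros_like(X), A_norm, params, mode="eval")
        np.testing.assert_array_equal(emb.mu, 0)
        np.testing.assert_array_equal(emb.H, 0)

    def test_matches_dense_forward_oracle(self, rng):
        """Eval-mode embedding equals an independent dense-matrix computation."""
        X, A_norm, params = self._setup(rng)
        hidden = np.maximum(A_norm @ X @ params.W0, 0)
        mu_expect = A_norm @ hidden @ params.W1_mu
        emb = encode(X, A_norm, params, mode="eval")
        np.testing.assert_allclose(emb.mu, mu_expect, rtol=1e-12)
        np.testing.assert_allclose(emb.H, mu_expect, rtol=1e-12)

    def test_eval_mode_is_deterministic(self, rng):
        X, A_norm, params = self._setup(rng)
        a = encode(X, A_norm, params, mode="eval")
        b = encode(X, A_norm, params, mode="eval")
        np.testing.assert_array_equal(a.H, b.H)

    def test_train_mode_samples_around_mu(self, rng):
        X, A_norm, params = self._setup(rng)
        emb = encode(X, A_norm, params, mode="train",
                     rng=np.random.default_rng(0))
        assert not np.array_equal(emb.H, emb.mu)


class TestDecoder:
    def test_zero_latent_gives_half_everywhere(self):
        probs = decode(np.zeros((4, 3)))
        np.testing.assert_allclose(probs, 0.5)

    def test_closed_form_values(self):
        H = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        probs = decode(H)
        assert probs[0, 1] == pytest.approx(1 / (1 + np.exp(-1)))
        assert probs[0, 2] == pytest.approx(0.5)  # orthogonal

    def test_symmetric_and_rotation_invariant(self, rng):
        H = rng.standard_normal((8, 4))
        probs = decode(H)
        np.testing.assert_allclose(probs, probs.T, atol=1e-15)
        q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        np.testing.assert_allclose(decode(H @ q), probs, atol=1e-10)

    def test_score_pairs_matches_full_matrix(self, rng):
        H = rng.standard_normal((6, 3))
        probs = decode(H)
        pairs = [(0, 1), (2, 5), (3, 4)]
        np.testing.assert_allclose(
            score_pairs(H, pairs), [probs[i, j] for i, j in pairs]
        )


class TestLosses:
    def test_kl_zero_when_posterior_is_prior(self):
        assert kl_divergence(np.zeros((3, 4)), np.zeros((3, 4))) == 0.0

    def test_kl_closed_form_unit_mean(self):
        # one cell, one dim, mu=1, sigma=1: 0.5 (1 + 1 - 1 - 0) = 0.5
        assert kl_divergence(np.array([[1.0]]), np.array([[0.0]])) == pytest.approx(0.5)

    def test_kl_nonnegative(self, rng):
        mu = rng.standard_normal((10, 5))
        ls = rng.standard_normal((10, 5))
        assert kl_divergence(mu, ls) >= 0

    def test_reconstruction_vanishes_for_perfect_probs(self):
        A = CellGraph(4, {(0, 1), (2, 3)}).adjacency()
        eps = 1e-9
        probs = np.where(A > 0, 1 - eps, eps)
        loss = elbo_loss(probs, A, np.zeros((4, 2)), np.zeros((4, 2)))
        assert loss == pytest.approx(0.0, abs=1e-6)


class TestDiscriminator:
    def test_zero_weights_output_half(self):
        cfg = ModelConfig(hidden1=4, latent=3, disc_h1=4, disc_h2=4, seed=0)
        params = init_parameters(5, cfg)
        for k, v in params.disc_items().items():
            v[...] = 0.0
        out = discriminator_forward(np.random.default_rng(0).random((7, 3)), params)
        np.testing.assert_allclose(out, 0.5)

    def test_matches_dense_forward_oracle(self, rng):
        cfg = ModelConfig(hidden1=4, latent=3, disc_h1=4, disc_h2=5, seed=2)
        params = init_parameters(5, cfg)
        h = rng.standard_normal((6, 3))
        a1 = np.maximum(h @ params.Wd1 + params.bd1, 0)
        a2 = np.maximum(a1 @ params.Wd2 + params.bd2, 0)
        expect = 1 / (1 + np.exp(-(a2 @ params.Wd3 + params.bd3)))[:, 0]
        np.testing.assert_allclose(discriminator_forward(h, params), expect, rtol=1e-12)

    def test_batch_order_preserved(self, rng):
        cfg = ModelConfig(hidden1=4, latent=3, disc_h1=4, disc_h2=4, seed=3)
        params = init_parameters(5, cfg)
        batch = rng.standard_normal((5, 3))
        out = discriminator_forward(batch, params)
        singles = [discriminator_forward(batch[i], params)[0] for i in range(5)]
        np.testing.assert_allclose(out, singles)
        assert ((out > 0) & (out < 1)).all()


def _tiny_training_setup(seed=0, n=60, g=12):
    from spatialink.data_io import simulate_tissue

    ds, _ = simulate_tissue(n_cells=n, n_types=2, n_genes=g, n_informative=6,
                            seed=seed)
    graph = build_adjacency(ds.coordinates)
    split = split_edges(graph, neg_ratio=10, seed=seed)
    return ds, split


class TestTraining:
    def test_zero_epochs_returns_initialized_parameters(self):
        ds, split = _tiny_training_setup()
        cfg = ModelConfig(hidden1=8, latent=4, disc_h1=4, disc_h2=4,
                          epochs=0, seed=9)
        result = train(ds, split, cfg)
        init = init_parameters(ds.n_genes, cfg)
        np.testing.assert_array_equal(result.params.W0, init.W0)
        assert result.log == []
        # untrained scores should not separate edges from non-edges strongly
        from spatialink.robustness import compute_auroc

        pos = score_pairs(result.embedding.H, sorted(split.test_pos))
        neg = score_pairs(result.embedding.H, sorted(split.test_neg))
        assert 0.2 < compute_auroc(pos, neg) < 0.8

    def test_training_improves_on_untrained_baseline(self):
        from spatialink.robustness import compute_auroc

        ds, split = _tiny_training_setup(seed=1, n=120, g=20)
        cfg = ModelConfig(epochs=120, seed=1, feature_scaling="log1p_zscore")
        untrained = train(ds, split, dataclasses.replace(cfg, epochs=0))
        trained = train(ds, split, cfg)

        def auroc(res):
            pos = score_pairs(res.embedding.H, sorted(split.test_pos))
            neg = score_pairs(res.embedding.H, sorted(split.test_neg))
            return compute_auroc(pos, neg)

        assert auroc(trained) > auroc(untrained)
        assert auroc(trained) > 0.6

    def test_same_seed_identical_training_log(self):
        ds, split = _tiny_training_setup(seed=2)
        cfg = ModelConfig(hidden1=8, latent=4, disc_h1=4, disc_h2=4,
                          epochs=15, seed=4)
        a = train(ds, split, cfg)
        b = train(ds, split, cfg)
        assert a.log == b.log
        np.testing.assert_array_equal(a.params.W0, b.params.W0)

    def test_log_records_loss_components(self):
        ds, split = _tiny_training_setup(seed=3)
        cfg = ModelConfig(hidden1=8, latent=4, disc_h1=4, disc_h2=4,
                          epochs=10, seed=0, eval_interval=5)
        result = train(ds, split, cfg)
        assert len(result.log) == 10
        for key in ("total", "disc_loss", "recon", "kl", "adversarial"):
            assert key in result.log[0]
        assert "test_auroc" in result.log[4]


def test_checkpoint_round_trip(tmp_path):
    ds, split = _tiny_training_setup(seed=5)
    cfg = ModelConfig(hidden1=8, latent=4, disc_h1=4, disc_h2=4, epochs=5, seed=1)
    result = train(ds, split, cfg)
    vgae_core.save_checkpoint(tmp_path / "ckpt.npz", result)
    params, cfg_back = vgae_core.load_checkpoint(tmp_path / "ckpt.npz")
    assert cfg_back == cfg
    np.testing.assert_array_equal(params.W1_mu, result.params.W1_mu)


class TestGradients:
    """Analytic gradients vs central finite differences."""

    def _instance(self):
        rng = np.random.default_rng(0)
        n, g = 5, 4
        X = rng.random((n, g))
        A = CellGraph(n, {(0, 1), (1, 2), (2, 3), (3, 4), (0, 4)}).adjacency()
        A_norm = normalize_adjacency(A)
        cfg = ModelConfig(hidden1=6, latent=3, disc_h1=4, disc_h2=5, seed=1)
        params = init_parameters(g, cfg)
        eps = rng.standard_normal((n, 3))
        return X, A, A_norm, params, eps

    @staticmethod
    def _fd(f, arr, h=1e-6):
        num = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + h
            lp = f()
            arr[idx] = orig - h
            lm = f()
            arr[idx] = orig
            num[idx] = (lp - lm) / (2 * h)
        return num

    def test_generator_gradients_match_finite_differences(self):
        X, A, A_norm, params, eps = self._instance()
        _, grads, _ = vgae_core.generator_loss_and_grads(
            params, X, A_norm, A, eps, None, 1.0, 1.0
        )
        f = lambda: vgae_core.generator_loss_and_grads(
            params, X, A_norm, A, eps, None, 1.0, 1.0
        )[0]
        for name, arr in params.encoder_items().items():
            num = self._fd(f, arr)
            rel = np.abs(num - grads[name]) / np.maximum(
                1e-8, np.abs(num) + np.abs(grads[name])
            )
            assert rel.max() < 1e-4, name

    def test_discriminator_gradients_match_finite_differences(self):
        X, A, A_norm, params, eps = self._instance()
        rng = np.random.default_rng(3)
        prior = rng.standard_normal((5, 3))
        fake = rng.standard_normal((5, 3))
        _, grads = vgae_core.discriminator_loss_and_grads(params, fake, prior)
        f = lambda: vgae_core.discriminator_loss_and_grads(params, fake, prior)[0]
        for name, arr in params.disc_items().items():
            num = self._fd(f, arr)
            rel = np.abs(num - grads[name]) / np.maximum(
                1e-8, np.abs(num) + np.abs(grads[name])
            )
            assert rel.max() < 1e-4, name
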