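"""Generator unit laws: reparameterization, KL, FPC attention, decoding,
early stopping and sampling reproducibility."""

import numpy as np
import pytest

from moldesign.generator import (
    ConditionalSmilesVAE,
    ConsecutiveAccuracyStop,
    PlateauStop,
    kl_divergence,
    reparameterize,
    vae_loss,
)


class TestReparameterize:
    def test_zero_epsilon_returns_mu(self):
        mu = np.array([1.0, -2.0, 0.5])
        assert np.array_equal(reparameterize(mu, np.zeros(3), np.zeros(3)), mu)

    def test_unit_sigma_unit_epsilon(self):
        mu = np.array([1.0, 2.0])
        out = reparameterize(mu, np.zeros(2), np.ones(2))
        np.testing.assert_allclose(out, mu + 1.0)

    def test_monte_carlo_variance(self):
        # with log_sigma = ln 2 the draw variance is exp(ln 2)^2 = 4
        rng = np.random.default_rng(0)
        eps = rng.standard_normal(10_000)
        z = reparameterize(np.zeros(10_000), np.full(10_000, np.log(2.0)), eps)
        assert z.var() == pytest.approx(4.0, rel=0.1)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            reparameterize(np.zeros(3), np.zeros(3), np.zeros(4))


class TestKlAndLoss:
    def test_standard_normal_posterior_has_zero_kl(self):
        assert kl_divergence(np.zeros(5), np.zeros(5)) == pytest.approx(0.0, abs=1e-12)

    def test_unit_mean_single_dim(self):
        assert kl_divergence(np.array([1.0]), np.array([0.0])) == pytest.approx(0.5)

    def test_kl_nonnegative_everywhere(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            mu = rng.normal(size=8) * 3
            ls = rng.normal(size=8)
            assert kl_divergence(mu, ls) >= 0.0

    def test_perfect_logits_give_zero_reconstruction(self):
        targets = np.array([[1, 2, 0]])
        mask = np.array([[1.0, 1.0, 0.0]])
        logits = np.full((1, 3, 4), -1e3)
        for t, tok in enumerate(targets[0]):
            logits[0, t, tok] = 1e3
        total, recon, kl = vae_loss(logits, targets, mask, np.zeros(2), np.zeros(2))
        assert recon == pytest.approx(0.0, abs=1e-9)
        assert total == pytest.approx(kl, abs=1e-9)


class TestFpc:
    def test_scores_are_probability_vectors(self, tiny_model):
        rng = np.random.default_rng(0)
        scores = tiny_model.fpc_scores(rng.normal(size=(7, tiny_model.latent_dim)), 0.7)
        assert scores.shape == (7, tiny_model.latent_dim)
        assert np.all(scores >= 0)
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_weights_give_uniform_scores(self, tiny_model):
        model = tiny_model.clone_fitted()
        for key in ("fpc2_w", "fpc2_b"):
            model.params_[key].data[:] = 0.0
        scores = model.fpc_scores(np.ones((1, model.latent_dim)), 0.5)
        np.testing.assert_allclose(scores, 1.0 / model.latent_dim, atol=1e-12)

    def test_closed_form_softmax(self):
        # softmax of (0, ln 3) is (0.25, 0.75)
        e = np.array([0.0, np.log(3.0)])
        s = np.exp(e) / np.exp(e).sum()
        np.testing.assert_allclose(s, [0.25, 0.75], atol=1e-12)

    def test_apply_fpc_uniform_scores(self, tiny_model):
        z = np.arange(tiny_model.latent_dim, dtype=float)
        uniform = np.full(tiny_model.latent_dim, 1.0 / tiny_model.latent_dim)
        zc = tiny_model.apply_fpc(z, uniform)
        expected = z / tiny_model.latent_dim
        if tiny_model.fpc_rescale:
            expected = z
        np.testing.assert_allclose(zc, expected)


class TestEncodeDecode:
    def test_encode_is_deterministic_with_correct_shapes(self, tiny_model):
        smiles = ["CCO", "c1ccc(C)cc1"]
        mu1, ls1 = tiny_model.encode(smiles)
        mu2, ls2 = tiny_model.encode(smiles)
        assert mu1.shape == (2, tiny_model.latent_dim)
        np.testing.assert_array_equal(mu1, mu2)
        np.testing.assert_array_equal(ls1, ls2)
        assert np.isfinite(mu1).all() and np.isfinite(ls1).all()

    def test_decode_logits_shape_and_softmax(self, tiny_model):
        teacher = np.array([tiny_model.alphabet_.start_id, 3, 4, 5])
        logits = tiny_model.decode_logits(
            np.zeros(tiny_model.latent_dim), 0.5, teacher
        )
        assert logits.shape == (1, 4, len(tiny_model.alphabet_))
        p = np.exp(logits - logits.max(-1, keepdims=True))
        p /= p.sum(-1, keepdims=True)
        np.testing.assert_allclose(p.sum(-1), 1.0, atol=1e-9)


class TestEarlyStop:
    def test_accuracy_window_fires_after_exact_window(self):
        stopper = ConsecutiveAccuracyStop(delta=0.95, window=500)
        fired_at = None
        for step in range(1, 1000):
            if stopper.update(0.96):
                fired_at = step
                break
        assert fired_at == 500

    def test_low_accuracy_never_fires(self):
        stopper = ConsecutiveAccuracyStop(delta=0.95, window=500)
        assert not any(stopper.update(0.5) for _ in range(5000))

    def test_plateau_stops_and_restores_best_epoch(self):
        stopper = PlateauStop(patience=5)
        stops = [stopper.update(loss) for loss in [3, 2, 2, 2, 2, 2, 2]]
        assert stops == [False, False, False, False, False, False, True]
        assert stopper.best_epoch == 2

    def test_strictly_decreasing_runs_to_cap(self):
        stopper = PlateauStop(patience=5)
        assert not any(stopper.update(10.0 - i) for i in range(100))
        assert stopper.best_epoch == 100


class TestTrainingAndSampling:
    def test_same_seed_gives_identical_training(self):
        from moldesign.fixtures import generate_smiles_corpus

        corpus = generate_smiles_corpus(50, seed=9)
        kwargs = dict(
            embedding_dim=8, encoder_rnn_dim=10, encoder_rnn_layers=1,
            latent_dim=4, fpc_hidden_dims=(6, 6), decoder_rnn_dim=10,
            decoder_rnn_layers=1, batch_size=25, max_epochs=2, seed=5,
        )
        runs = [ConditionalSmilesVAE(**kwargs).fit(corpus) for _ in range(2)]
        assert runs[0].log_[-1]["loss"] == runs[1].log_[-1]["loss"]
        assert [r["accuracy"] for r in runs[0].log_] == [
            r["accuracy"] for r in runs[1].log_
        ]

    def test_sampling_reproducible_and_sized(self, tiny_model):
        a = tiny_model.sample(64, condition=0.7, seed=4)
        b = tiny_model.sample(64, condition=0.7, seed=4)
        c = tiny_model.sample(64, condition=0.7, seed=5)
        assert len(a) == 64
        assert a == b
        assert a != c

    def test_overfit_single_smiles_reproduced_greedily(self):
        target = "CCOc1ccccc1"
        model = ConditionalSmilesVAE(
            embedding_dim=16, encoder_rnn_dim=32, encoder_rnn_layers=1,
            latent_dim=8, fpc_hidden_dims=(8, 8), decoder_rnn_dim=32,
            decoder_rnn_layers=1, kl_weight=1.0, batch_size=32,
            max_epochs=150, base_lr=2e-3, seed=1,
        )
        model.fit([target] * 32)
        assert model.sample(4, condition=0.6, temperature=0.0, seed=0) == [target] * 4

    def test_loss_decreases_over_first_steps(self, smoke_model):
        losses = [r["loss"] for r in smoke_model.log_[:100]]
        means = [np.mean(losses[i : i + 20]) for i in range(0, 100, 20)]
        assert all(b < a for a, b in zip(means, means[1:]))

    def test_small_corpus_warns_and_trains(self):
        with pytest.warns(UserWarning, match="smaller than one batch"):
            ConditionalSmilesVAE(
                embedding_dim=4, encoder_rnn_dim=6, encoder_rnn_layers=1,
                latent_dim=3, fpc_hidden_dims=(4, 4), decoder_rnn_dim=6,
                decoder_rnn_layers=1, batch_size=64, max_epochs=1, seed=0,
            ).fit(["CCO", "CCC"])


class TestPersistence:
    def test_save_load_round_trip(self, tiny_model, tmp_path):
        path = tmp_path / "ckpt.npz"
        tiny_model.save(str(path))
        loaded = type(tiny_model).load(str(path))
        assert loaded.sample(8, 0.5, seed=1) == tiny_model.sample(8, 0.5, seed=1)
        mu0, _ = tiny_model.encode(["CCO"])
        mu1, _ = loaded.encode(["CCO"])
        np.testing.assert_array_equal(mu0, mu1)
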