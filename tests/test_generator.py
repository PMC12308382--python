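"""ELBO components, beta schedules, VAE training behavior."""

import numpy as np
import pytest

from fluorogen.codec import build_vocabulary, encode_one_hot
from fluorogen.generator import (
    BetaSchedule,
    GeneratorModel,
    TrainConfig,
    beta_at,
    elbo_loss,
    kl_gaussian,
    reconstruction_loglik,
    reconstruction_rate,
    train_generator,
)


class TestKlGaussian:
    def test_standard_normal_is_zero(self):
        assert kl_gaussian(np.zeros(5), np.zeros(5)) == 0.0

    def test_unit_mean_shift(self):
        assert kl_gaussian(np.array([1.0]), np.array([0.0])) == pytest.approx(0.5)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            kl_gaussian(np.zeros(3), np.zeros(4))

    def test_matches_monte_carlo_estimate(self):
        """Closed form vs E_q[log q - log p] sampled from q, d=4."""
        rng = np.random.default_rng(42)
        mu = rng.normal(size=4)
        logvar = rng.normal(scale=0.5, size=4)
        n = 200_000
        std = np.exp(0.5 * logvar)
        z = mu + std * rng.standard_normal((n, 4))
        log_q = -0.5 * (((z - mu) / std) ** 2 + logvar + np.log(2 * np.pi)).sum(1)
        log_p = -0.5 * (z**2 + np.log(2 * np.pi)).sum(1)
        diffs = log_q - log_p
        se = diffs.std(ddof=1) / np.sqrt(n)
        assert abs(kl_gaussian(mu, logvar) - diffs.mean()) < 3 * se


class TestReconstructionLoglik:
    def test_sharp_logits_approach_zero(self):
        tgt = np.eye(3)[:2]  # L=2, V=3
        logits = 1e3 * tgt
        assert reconstruction_loglik(logits, tgt) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_logits(self):
        tgt = np.eye(3)[:2]
        assert reconstruction_loglik(np.zeros((2, 3)), tgt) == pytest.approx(
            2 * np.log(1 / 3))

    def test_matches_per_position_categorical_oracle(self):
        rng = np.random.default_rng(0)
        L, V = 5, 4
        logits = rng.normal(size=(L, V))
        idx = rng.integers(0, V, L)
        tgt = np.eye(V)[idx]
        expected = 0.0
        for i in range(L):
            p = np.exp(logits[i]) / np.exp(logits[i]).sum()
            expected += np.log(p[idx[i]])
        assert reconstruction_loglik(logits, tgt) == pytest.approx(expected)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            reconstruction_loglik(np.zeros((2, 3)), np.zeros((3, 3)))

    def test_padding_mask_drops_pad_positions(self):
        tgt = np.eye(3)[[1, 0, 0]]  # one real token then two pads (index 0)
        logits = np.zeros((3, 3))
        full = reconstruction_loglik(logits, tgt)
        masked = reconstruction_loglik(logits, tgt, mask_padding=True)
        assert full == pytest.approx(3 * np.log(1 / 3))
        assert masked == pytest.approx(np.log(1 / 3))


class TestElboLoss:
    @pytest.mark.parametrize("recon,kl,beta,expected", [
        (-10.0, 2.0, 1.0, 12.0),
        (-10.0, 2.0, 0.0, 10.0),   # optimized AE ignores the KL term
        (-10.0, 2.0, 0.5, 11.0),
    ])
    def test_arithmetic(self, recon, kl, beta, expected):
        comp = elbo_loss(recon, kl, beta)
        assert comp.loss == pytest.approx(expected)
        assert comp.loss == pytest.approx(-comp.recon_loglik + comp.beta * comp.kl)

    def test_negative_kl_rejected(self):
        with pytest.raises(ValueError):
            elbo_loss(-1.0, -0.1, 1.0)


class TestBetaSchedules:
    def test_exponential_values(self):
        s = BetaSchedule(kind="exponential", beta_start=1.0, beta_end=0.01,
                         rho=0.95)
        assert beta_at(s, 0) == 1.0
        assert beta_at(s, 1) == pytest.approx(0.95)
        assert beta_at(s, 10_000) == s.beta_end

    def test_exponential_exact_and_monotone(self):
        s = BetaSchedule(kind="exponential")
        vals = [beta_at(s, t) for t in range(101)]
        expected = [max(s.beta_end, s.beta_start * s.rho**t) for t in range(101)]
        assert vals == expected
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_piecewise_switches_at_t_switch(self):
        s = BetaSchedule(kind="piecewise", t_switch=5, beta_high=1.0,
                         beta_low=0.05)
        assert beta_at(s, 4) == 1.0
        assert beta_at(s, 5) == 0.05  # boundary epoch already low
        assert {beta_at(s, t) for t in range(20)} == {1.0, 0.05}

    def test_linear_is_affine_then_clamped(self):
        s = BetaSchedule(kind="linear", beta_start=1.0, beta_end=0.1,
                         horizon=9)
        vals = np.array([beta_at(s, t) for t in range(15)])
        diffs = np.diff(vals[:10])
        assert np.allclose(diffs, diffs[0])
        assert (vals[9:] == 0.1).all()

    def test_fixed_is_constant(self):
        s = BetaSchedule(kind="fixed", beta_start=0.3, beta_end=0.0)
        assert {beta_at(s, t) for t in range(10)} == {0.3}

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            BetaSchedule(kind="warp")
        with pytest.raises(ValueError):
            BetaSchedule(rho=1.5)
        with pytest.raises(ValueError):
            BetaSchedule(beta_start=0.5, beta_end=1.0)

    def test_performance_requires_monitors_and_nudges(self):
        s = BetaSchedule(kind="performance", beta_start=1.0, beta_end=0.01,
                         kl_floor=0.5, window=2, adjust_factor=2.0)
        with pytest.raises(ValueError):
            beta_at(s, 3)
        up = beta_at(s, 3, {"beta_prev": 0.4, "kl": 0.1,
                            "recon_history": [-5, -5, -5]})
        assert up == pytest.approx(0.8)
        down = beta_at(s, 3, {"beta_prev": 0.4, "kl": 2.0,
                              "recon_history": [-5, -4, -4.5, -6]})
        assert down == pytest.approx(0.2)
        clamped = beta_at(s, 3, {"beta_prev": 0.9, "kl": 0.1,
                                 "recon_history": []})
        assert clamped == 1.0  # never exceeds beta_start


class TestTraining:
    def test_history_beta_matches_schedule(self, toy_molecules):
        cfg = TrainConfig(schedule=BetaSchedule(kind="exponential"),
                          latent_dim=8, hidden_dim=32, epochs=5,
                          batch_size=20, seed=1)
        model = train_generator(toy_molecules, cfg)
        betas = [h["beta"] for h in model.history]
        assert betas == [beta_at(cfg.schedule, t) for t in range(5)]
        assert betas == pytest.approx(
            [1.0, 0.95, 0.9025, 0.857375, 0.81450625], rel=1e-12)

    def test_loss_decomposition_identity_per_epoch(self, small_model):
        for h in small_model.history:
            assert h["loss"] == pytest.approx(
                -h["recon_loglik"] + h["beta"] * h["kl"])

    def test_same_seed_is_bit_identical(self, toy_molecules):
        cfg = TrainConfig(schedule=BetaSchedule(), latent_dim=8,
                          hidden_dim=32, epochs=5, batch_size=10, seed=7)
        m1 = train_generator(toy_molecules, cfg)
        m2 = train_generator(toy_molecules, cfg)
        assert m1.history[-1]["loss"] == m2.history[-1]["loss"]
        assert m1.weights_checksum() == m2.weights_checksum()

    def test_training_loss_decreases_on_trailing_means(self, small_model):
        losses = [h["loss"] for h in small_model.history]
        first = np.mean(losses[:5])
        last = np.mean(losses[-5:])
        assert last < first

    def test_unencodable_molecule_reported(self):
        with pytest.raises(ValueError, match="record 1"):
            train_generator(["CCO", "C[S]C"], TrainConfig(epochs=1))

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_generator([], TrainConfig(epochs=1))


class TestReconstructionRate:
    def test_overfit_ae_reconstructs_training_set(self, overfit_ae, toy_molecules):
        assert reconstruction_rate(overfit_ae, toy_molecules) == 1.0

    def test_rate_equals_manual_count(self, small_model, corpus100):
        from fluorogen.codec import same_molecule

        subset = corpus100[:30]
        rate = reconstruction_rate(small_model, subset)
        hits = 0
        for rec in subset:
            out = small_model.reconstruct(rec)
            hits += bool(out) and same_molecule(out, rec.smiles)
        assert rate == hits / len(subset)
        assert 0.0 <= rate <= 1.0

    def test_empty_set_rejected(self, overfit_ae):
        with pytest.raises(ValueError):
            reconstruction_rate(overfit_ae, [])


class TestCheckpoint:
    def test_save_load_round_trip_is_bit_identical(self, tmp_path, overfit_ae,
                                                   toy_molecules):
        path = tmp_path / "model.ckpt"
        overfit_ae.save(path)
        loaded = GeneratorModel.load(path)
        assert loaded.weights_checksum() == overfit_ae.weights_checksum()
        assert loaded.vocab == overfit_ae.vocab
        assert loaded.history == overfit_ae.history
        rec = toy_molecules[0]
        assert np.array_equal(loaded.encode_mean(rec),
                              overfit_ae.encode_mean(rec))
        assert loaded.reconstruct(rec) == overfit_ae.reconstruct(rec)
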