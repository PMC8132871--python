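"""Architecture, losses, reparameterization, and the training protocol."""

import numpy as np
import pytest

from desp.errors import ConfigurationError, ShapeError
from desp.vae import (
    LatentGaussian,
    VAEConfig,
    build_vae,
    decode,
    encode,
    loss_kl,
    loss_model,
    loss_mse,
    reconstruction_mse,
    reparameterize,
    train,
    TrainedVAE,
)


class TestArchitecture:
    def test_widths_for_d28(self):
        """D=28, N=7: encoder widths floor(56/n), latent floor(56/8)."""
        cfg = VAEConfig(d_dihedrals=28)
        assert cfg.encoder_widths == [56, 28, 18, 14, 11, 9, 8]
        assert cfg.decoder_widths == [8, 9, 11, 14, 18, 28, 56]
        assert cfg.latent_dim == 7
        assert cfg.input_dim == 56

    def test_latent_dim_formula_small(self):
        assert VAEConfig(d_dihedrals=4).latent_dim == 1

    def test_too_narrow_config_rejected(self):
        with pytest.raises(ConfigurationError):
            build_vae(VAEConfig(d_dihedrals=1))  # floor(2/7) = 0 at layer 7

    def test_parameter_shapes_mirror(self):
        cfg = VAEConfig(d_dihedrals=10, seed=0)
        m = build_vae(cfg)
        assert m.params["enc_W0"].shape == (20, 20)
        assert m.params["mu_W"].shape == (cfg.latent_dim, cfg.encoder_widths[-1])
        assert m.params["out_W"].shape == (20, cfg.decoder_widths[-1])

    def test_seeded_init_reproducible(self):
        a = build_vae(VAEConfig(d_dihedrals=6, seed=5))
        b = build_vae(VAEConfig(d_dihedrals=6, seed=5))
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])


class TestEncodeDecode:
    @pytest.fixture
    def model(self):
        return build_vae(VAEConfig(d_dihedrals=6, n_hidden=3, seed=2))

    def test_encode_finite_and_deterministic(self, model):
        x = np.linspace(-1, 1, 12)
        g1 = encode(model, x)
        g2 = encode(model, x)
        assert np.all(np.isfinite(g1.mean)) and np.all(np.isfinite(g1.ln_var))
        assert np.array_equal(g1.mean, g2.mean)
        assert np.array_equal(g1.ln_var, g2.ln_var)

    def test_batch_equals_single_rows(self, model):
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, size=(5, 12))
        gb = encode(model, X)
        for i in range(5):
            gi = encode(model, X[i])
            # batched and single-row BLAS paths agree to rounding
            assert np.allclose(gb.mean[i], gi.mean, atol=1e-12)
            assert np.allclose(gb.ln_var[i], gi.ln_var, atol=1e-12)
        Z = rng.standard_normal((5, model.config.latent_dim))
        yb = decode(model, Z)
        for i in range(5):
            assert np.allclose(yb[i], decode(model, Z[i]), atol=1e-12)

    def test_shape_errors(self, model):
        with pytest.raises(ShapeError):
            encode(model, np.zeros(11))
        with pytest.raises(ShapeError):
            decode(model, np.zeros(model.config.latent_dim + 1))

    def test_save_load_round_trip_exact(self, model, tmp_path):
        p = tmp_path / "model.npz"
        model.save(p)
        loaded = TrainedVAE.load(p)
        x = np.linspace(-1, 1, 12)
        g0, g1 = encode(model, x), encode(loaded, x)
        assert np.array_equal(g0.mean, g1.mean)
        assert np.array_equal(g0.ln_var, g1.ln_var)


class TestReparameterize:
    def test_zero_variance_limit(self):
        g = LatentGaussian(np.array([1.0, -2.0]), np.array([-60.0, -60.0]))
        z = reparameterize(g, np.random.default_rng(0))
        assert np.max(np.abs(z - g.mean)) < 1e-12

    def test_seeded_determinism(self):
        g = LatentGaussian(np.zeros(3), np.zeros(3))
        z1 = reparameterize(g, np.random.default_rng(9))
        z2 = reparameterize(g, np.random.default_rng(9))
        assert np.array_equal(z1, z2)

    def test_sample_mean_approaches_mu(self):
        """Law of large numbers: mean of draws within 4 sigma/sqrt(n)."""
        mu = np.array([0.5, -1.5])
        ln_var = np.array([0.0, np.log(4.0)])
        g = LatentGaussian(mu, ln_var)
        rng = np.random.default_rng(11)
        n = 10**5
        draws = np.array([reparameterize(g, rng) for _ in range(n)])
        tol = 4.0 * np.exp(0.5 * ln_var) / np.sqrt(n)
        assert np.all(np.abs(draws.mean(axis=0) - mu) < tol)


class TestLosses:
    def test_kl_of_standard_normal_is_zero(self):
        assert loss_kl(LatentGaussian(np.zeros(3), np.zeros(3))) == 0.0

    def test_kl_unit_mean_case(self):
        g = LatentGaussian(np.array([[1.0]]), np.array([[0.0]]))
        assert loss_kl(g) == pytest.approx(0.5, abs=1e-15)

    def test_kl_inflated_variance_case(self):
        g = LatentGaussian(np.array([[0.0, 0.0]]), np.array([[1.0, 1.0]]))
        assert loss_kl(g) == pytest.approx(np.e - 2.0, abs=1e-12)

    def test_kl_nonnegative_and_zero_only_at_prior(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            g = LatentGaussian(rng.normal(size=(1, 4)), rng.normal(size=(1, 4)))
            v = loss_kl(g)
            assert v >= 0
            if v < 1e-12:
                assert np.allclose(g.mean, 0, atol=1e-6)
                assert np.allclose(g.ln_var, 0, atol=1e-6)

    def test_mse_zero_on_identical(self):
        x = np.random.default_rng(0).normal(size=(4, 6))
        assert loss_mse(x, x) == 0.0

    def test_mse_against_naive_double_loop(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=(5, 8))
        y_hat = rng.normal(size=(5, 8))
        naive = sum(
            sum((y[i, j] - y_hat[i, j]) ** 2 for j in range(8)) for i in range(5)
        ) / 5.0
        assert loss_mse(y, y_hat) == pytest.approx(naive, abs=1e-12)

    @pytest.mark.parametrize("mse,kl,w,expected", [
        (1.0, 1.0, 0.1, 1.0),
        (2.0, 0.0, 0.1, 1.8),
        (3.0, 7.0, 0.0, 3.0),
    ])
    def test_loss_model_weighting(self, mse, kl, w, expected):
        assert loss_model(mse, kl, w) == pytest.approx(expected, abs=1e-15)


class TestTraining:
    def test_patience_zero_rejected(self):
        with pytest.raises(ConfigurationError):
            build_vae(VAEConfig(d_dihedrals=4, patience=0))

    def test_patience_one_stops_at_first_non_improvement(self):
        cfg = VAEConfig(d_dihedrals=4, n_hidden=2, patience=1, max_epochs=500,
                        seed=0, batch_size=16)
        m = build_vae(cfg)
        X = np.random.default_rng(0).uniform(-1, 1, size=(16, 8))
        _, trace = train(m, X)
        lm = trace.loss_model
        # stopped exactly one epoch after the best epoch
        assert len(lm) < 500
        assert np.argmin(lm) == len(lm) - 2

    def test_constant_dataset_converges(self):
        """All rows identical: reconstruction error trends to ~0 and the
        final composite loss does not exceed the initial one."""
        cfg = VAEConfig(d_dihedrals=3, n_hidden=2, seed=1, batch_size=256,
                        max_epochs=200, patience=200, learning_rate=1e-3)
        m = build_vae(cfg)
        row = np.array([1.0, 0.0, -0.5, 0.8, 0.3, -0.9])
        X = np.tile(row, (256, 1))
        _, trace = train(m, X)
        assert trace.loss_model[-1] <= trace.loss_model[0]
        y = decode(m, encode(m, X).mean)
        assert reconstruction_mse(X, y) < 0.05

    def test_lr_schedule_column(self):
        """LR at epoch e is lr0 * gamma^(number of milestones <= e)."""
        cfg = VAEConfig(d_dihedrals=4, n_hidden=2, seed=0, batch_size=64,
                        max_epochs=100, patience=100, lr_milestones=50)
        m = build_vae(cfg)
        X = np.random.default_rng(1).uniform(-1, 1, size=(64, 8))
        _, trace = train(m, X)
        spacing = 100 // 50
        for e, lr in zip(trace.epochs, trace.learning_rate):
            n_past = min(50, e // spacing)
            assert lr == pytest.approx(cfg.learning_rate * cfg.lr_gamma**n_past, rel=1e-12)

    def test_early_stopping_returns_best(self):
        cfg = VAEConfig(d_dihedrals=4, n_hidden=2, seed=3, batch_size=32,
                        max_epochs=300, patience=20)
        m = build_vae(cfg)
        X = np.random.default_rng(2).uniform(-1, 1, size=(64, 8))
        m, trace = train(m, X)
        assert m.best_loss == pytest.approx(min(trace.loss_model), abs=0)

    def test_empty_data_rejected(self):
        m = build_vae(VAEConfig(d_dihedrals=4, n_hidden=2))
        with pytest.raises(ValueError):
            train(m, np.empty((0, 8)))


class TestTrainedOnTwoBasins:
    """Properties of the model trained with the default protocol on the
    two-basin fixture (session fixture; trained once)."""

    def test_reconstruction_mse_below_threshold(self, two_basin_data, trained_two_basin_vae):
        _, _, F = two_basin_data
        model, _ = trained_two_basin_vae
        y = decode(model, encode(model, F).mean)
        assert reconstruction_mse(F, y) < 0.05

    def test_latent_basins_separate(self, two_basin_data, trained_two_basin_vae):
        _, labels, F = two_basin_data
        model, _ = trained_two_basin_vae
        mu = encode(model, F).mean
        c0 = mu[labels == 0].mean(axis=0)
        c1 = mu[labels == 1].mean(axis=0)
        spread = 0.5 * (
            np.linalg.norm(mu[labels == 0] - c0, axis=1).mean()
            + np.linalg.norm(mu[labels == 1] - c1, axis=1).mean()
        )
        assert np.linalg.norm(c0 - c1) > 2.0 * spread

    def test_best_loss_is_trace_minimum(self, trained_two_basin_vae):
        model, trace = trained_two_basin_vae
        assert model.best_loss == pytest.approx(min(trace.loss_model), abs=0)

    def test_loss_trace_epochs_strictly_increasing(self, trained_two_basin_vae):
        _, trace = trained_two_basin_vae
        assert np.all(np.diff(trace.epochs) > 0)
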