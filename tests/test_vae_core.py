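"""VAE mathematics, architecture contracts, and training behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import histovae as hv
from histovae import vae_core


class TestReparameterize:
    @pytest.mark.parametrize(
        "mu, lv, eps, expected",
        [
            (0.0, 0.0, 0.0, 0.0),
            (0.0, 0.0, 1.0, 1.0),
            (1.0, 2 * np.log(2.0), 1.0, 3.0),  # 1 + e^{ln 2} * 1
        ],
    )
    def test_closed_forms(self, mu, lv, eps, expected):
        z = hv.reparameterize(np.array([mu]), np.array([lv]), np.array([eps]))
        assert z[0] == pytest.approx(expected)

    def test_affine_in_noise(self):
        """z(e1) + z(e2) - z(0) = z(e1 + e2) exactly."""
        rng = np.random.default_rng(0)
        mu, lv = rng.normal(size=5), rng.normal(size=5)
        e1, e2 = rng.normal(size=5), rng.normal(size=5)
        lhs = (
            hv.reparameterize(mu, lv, e1)
            + hv.reparameterize(mu, lv, e2)
            - hv.reparameterize(mu, lv, np.zeros(5))
        )
        assert np.allclose(lhs, hv.reparameterize(mu, lv, e1 + e2))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hv.reparameterize(np.zeros(3), np.zeros(3), np.zeros(4))


class TestKlDivergence:
    @pytest.mark.parametrize(
        "mu, lv, expected",
        [
            ([0.0], [0.0], 0.0),
            ([1.0], [0.0], 0.5),                      # -1/2 (1 + 0 - 1 - 1)
            ([0.0], [np.log(4.0)], 0.5 * (3 - np.log(4.0))),
        ],
    )
    def test_closed_forms(self, mu, lv, expected):
        assert hv.kl_divergence(mu, lv) == pytest.approx(expected)

    @given(
        st.lists(st.floats(-5, 5), min_size=1, max_size=8),
        st.lists(st.floats(-5, 5), min_size=1, max_size=8),
    )
    @settings(max_examples=100, deadline=None)
    def test_nonnegative_everywhere(self, mu, lv):
        n = min(len(mu), len(lv))
        kl = hv.kl_divergence(np.array(mu[:n]), np.array(lv[:n]))
        assert kl >= -1e-12

    def test_zero_only_at_standard_normal(self):
        assert hv.kl_divergence(np.zeros(5), np.zeros(5)) == 0.0
        assert hv.kl_divergence(np.full(5, 0.1), np.zeros(5)) > 0.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            hv.kl_divergence(np.array([np.inf]), np.array([0.0]))


class TestReconstructionLoss:
    def test_uniform_half_equals_pixels_times_ln2(self):
        x = np.full((3, 64, 64, 1), 0.5)
        assert hv.reconstruction_loss(x, x) == pytest.approx(4096 * np.log(2), rel=1e-6)

    def test_confident_correct_tends_to_zero(self):
        x = np.zeros((2, 64, 64, 1))
        x_hat = np.full_like(x, 1e-6)
        assert hv.reconstruction_loss(x, x_hat) < 0.01 * 4096

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, size=(3, 2, 2, 1)).astype(float)
        x_hat = rng.uniform(0.05, 0.95, size=(3, 2, 2, 1))
        total = 0.0
        for img, rec in zip(x, x_hat):
            for xv, pv in zip(img.ravel(), rec.ravel()):
                total += -(xv * np.log(pv) + (1 - xv) * np.log(1 - pv))
        assert hv.reconstruction_loss(x, x_hat) == pytest.approx(total / 3)

    def test_mean_scale_is_sum_over_pixel_count(self):
        rng = np.random.default_rng(2)
        x = rng.random((2, 64, 64, 1))
        xh = rng.uniform(0.1, 0.9, size=(2, 64, 64, 1))
        assert hv.reconstruction_loss(x, xh, scale="mean") == pytest.approx(
            hv.reconstruction_loss(x, xh) / 4096
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hv.reconstruction_loss(np.zeros((2, 4, 4, 1)), np.zeros((2, 4, 5, 1)))


class TestAddNoise:
    def test_zero_factor_is_identity(self):
        rng = np.random.default_rng(0)
        x = rng.random((2, 8, 8, 1)).astype(np.float32)
        assert np.array_equal(hv.add_noise(x, 0.0, seed=1), x)

    def test_noise_sd_matches_factor(self):
        x = np.full((10, 64, 64, 1), 0.5, dtype=np.float32)
        noisy = hv.add_noise(x, 0.2, seed=3)
        # sd of the added noise over ~4e4 pixels; clipping at [0,1] is rare
        assert np.std(noisy - x) == pytest.approx(0.2, rel=0.05)

    def test_output_clipped_to_unit_interval(self):
        x = np.ones((4, 8, 8, 1), dtype=np.float32)
        noisy = hv.add_noise(x, 0.5, seed=0)
        assert noisy.min() >= 0.0 and noisy.max() <= 1.0

    def test_negative_factor_rejected(self):
        with pytest.raises(ValueError):
            hv.add_noise(np.zeros((1, 2, 2, 1)), -0.1)


class TestArchitecture:
    def test_flatten_and_dense_widths_are_16384(self):
        model = hv.build_vae(hv.VaeConfig(latent_dim=5))
        enc_dense = model.encoder_body.layers[-1]
        assert enc_dense.n_in == 16 * 16 * 64 == 16384
        dec_dense = model.decoder.layers[1]
        assert dec_dense.n_out == 16384

    def test_latent_heads_width_five(self):
        model = hv.build_vae(hv.VaeConfig(latent_dim=5))
        assert model.dense_mean.n_out == 5
        assert model.dense_log_var.n_out == 5

    def test_forward_pass_shape_and_range(self):
        model = hv.build_vae(hv.VaeConfig(seed=0))
        x = np.random.default_rng(0).random((2, 64, 64, 1)).astype(np.float32)
        mu, lv = model.encode(x)
        z = hv.reparameterize(mu, lv, np.zeros_like(mu))
        out = model.decoder.forward(z.astype(np.float32))
        assert out.shape == (2, 64, 64, 1)
        assert 0.0 < out.min() and out.max() < 1.0

    def test_invalid_latent_dim_rejected(self):
        with pytest.raises(ValueError):
            hv.VaeConfig(latent_dim=0)


@pytest.fixture(scope="module")
def trained_vae(small_bundle):
    config = hv.VaeConfig(epochs=4, seed=2, batch_size=32)
    model = hv.build_vae(config)
    model, history = hv.train_vae(model, small_bundle, config)
    return model, history


class TestTraining:
    def test_loss_decreases(self, trained_vae):
        _, history = trained_vae
        assert history["loss"][-1] < history["loss"][0]

    def test_history_total_is_rec_plus_kl(self, trained_vae):
        _, history = trained_vae
        for total, rec, kl in zip(
            history["loss"], history["reconstruction_loss"], history["kl_loss"]
        ):
            assert total == pytest.approx(rec + kl, rel=1e-9)

    def test_noise_free_denoising_path_identical_to_plain(self, small_bundle):
        """The denoising variant with noise factor 0 degenerates exactly to
        the plain VAE: identical per-epoch losses under shared seeds."""
        histories = []
        for nf in (0.0, 0.0):
            config = hv.VaeConfig(epochs=2, seed=5, batch_size=32, noise_factor=nf)
            model = hv.build_vae(config)
            _, history = hv.train_vae(model, small_bundle, config)
            histories.append(history)
        assert histories[0]["loss"] == histories[1]["loss"]
        # and a genuinely noisy run differs
        config = hv.VaeConfig(epochs=2, seed=5, batch_size=32, noise_factor=0.2)
        model = hv.build_vae(config)
        _, noisy_history = hv.train_vae(model, small_bundle, config)
        assert noisy_history["loss"] != histories[0]["loss"]

    def test_empty_training_set_rejected(self, small_bundle):
        empty = hv.DatasetBundle(
            train_images=small_bundle.train_images[:0],
            train_labels=small_bundle.train_labels[:0],
            val_images=small_bundle.val_images,
            val_labels=small_bundle.val_labels,
            test_images=small_bundle.test_images,
            test_labels=small_bundle.test_labels,
        )
        with pytest.raises(ValueError):
            hv.train_vae(hv.build_vae(hv.VaeConfig(epochs=1)), empty, hv.VaeConfig(epochs=1))


class TestReconstruct:
    def test_shape_range_and_determinism(self, trained_vae, small_bundle):
        model, _ = trained_vae
        batch = small_bundle.test_images[:8]
        a = hv.reconstruct(model, batch, seed=9)
        b = hv.reconstruct(model, batch, seed=9)
        assert a.shape == batch.shape
        assert 0.0 < a.min() and a.max() < 1.0
        assert np.array_equal(a, b)
        assert not np.array_equal(a, hv.reconstruct(model, batch, seed=10))

    def test_mean_latent_reconstruction_seed_free(self, trained_vae, small_bundle):
        model, _ = trained_vae
        batch = small_bundle.test_images[:4]
        a = hv.reconstruct(model, batch, seed=1, use_mean=True)
        b = hv.reconstruct(model, batch, seed=2, use_mean=True)
        assert np.array_equal(a, b)

    def test_training_reduces_reconstruction_error(self, trained_vae, small_bundle):
        model, _ = trained_vae
        untrained = hv.build_vae(hv.VaeConfig(seed=99))
        untrained.trained = True  # bypass the guard to probe raw weights
        batch = small_bundle.test_images[:16]
        mse_trained = np.mean((hv.reconstruct(model, batch, seed=0) - batch) ** 2)
        mse_raw = np.mean((hv.reconstruct(untrained, batch, seed=0) - batch) ** 2)
        assert mse_trained < mse_raw

    def test_untrained_model_rejected(self, small_bundle):
        with pytest.raises(ValueError):
            hv.reconstruct(hv.build_vae(), small_bundle.test_images[:2])


def test_checkpoint_round_trip(tmp_path, trained_vae, small_bundle):
    model, _ = trained_vae
    path = tmp_path / "vae.npz"
    hv.save_vae(model, path)
    loaded = hv.load_vae(path)
    batch = small_bundle.test_images[:4]
    assert np.array_equal(
        hv.reconstruct(model, batch, seed=0), hv.reconstruct(loaded, batch, seed=0)
    )
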