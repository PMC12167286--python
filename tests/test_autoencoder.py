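import numpy as np
import pytest

from hsisynth.autoencoder import (KLAutoencoder, Latent, LatentPosterior,
                                  ae_loss, kl_term, median_relative_error,
                                  sample_latent)
from hsisynth.errors import ConfigError, ValidationError


def _posterior(mean, logvar):
    mean = np.asarray(mean, dtype=np.float32)
    return LatentPosterior(mean=mean, logvar=np.full_like(mean, logvar))


class TestKlTerm:
    def test_standard_normal_has_zero_kl(self):
        assert kl_term(_posterior(np.zeros((2, 2, 1)), 0.0)) == pytest.approx(0.0)

    def test_unit_mean_single_cell(self):
        assert kl_term(_posterior(np.ones((1, 1, 1)), 0.0)) == pytest.approx(0.5)

    def test_variance_four_single_cell(self):
        got = kl_term(_posterior(np.zeros((1, 1, 1)), np.log(4.0)))
        assert got == pytest.approx(0.5 * (4.0 - 1.0 - np.log(4.0)), abs=1e-5)

    def test_matches_monte_carlo_estimate(self):
        """KL(q||p) should agree with the E_q[log q - log p] estimator."""
        rng = np.random.default_rng(0)
        mean = rng.normal(0, 1, (4, 4, 2)).astype(np.float32)
        logvar = rng.uniform(-1, 1, (4, 4, 2)).astype(np.float32)
        post = LatentPosterior(mean=mean, logvar=logvar)
        sigma = np.exp(0.5 * logvar)
        n = 20000
        z = mean + sigma * rng.standard_normal((n,) + mean.shape)
        log_q = -0.5 * (((z - mean) / sigma) ** 2 + np.log(2 * np.pi) + logvar)
        log_p = -0.5 * (z**2 + np.log(2 * np.pi))
        per_cell = (log_q - log_p).mean(axis=0)
        mc = per_cell.mean()
        se = per_cell.std() / np.sqrt(mean.size)
        assert kl_term(post) == pytest.approx(mc, abs=3 * se + 1e-3)


class TestSampleLatent:
    def test_degenerate_variance_returns_mean(self):
        post = _posterior(np.full((3, 3, 2), 0.7), -30.0)
        lat = sample_latent(post, seed=0)
        np.testing.assert_allclose(lat.values, 0.7, atol=1e-5)

    def test_deterministic_given_seed(self):
        post = _posterior(np.zeros((2, 2, 2)), 0.0)
        a = sample_latent(post, seed=3)
        b = sample_latent(post, seed=3)
        np.testing.assert_array_equal(a.values, b.values)

    def test_unit_logvar_draws_have_unit_std(self):
        post = _posterior(np.zeros((1, 1, 1)), 0.0)
        draws = np.array([sample_latent(post, seed=s).values[0, 0, 0]
                          for s in range(10000)])
        assert draws.std() == pytest.approx(1.0, abs=0.03)


class TestAeLoss:
    def test_perfect_reconstruction_zero_lambda_is_zero(self):
        x = np.ones((2, 2, 3), np.float32)
        post = _posterior(np.ones((1, 1, 1)), 0.0)
        assert ae_loss(x, x, post, lambda_kl=0.0) == pytest.approx(0.0)

    def test_hand_l1_value(self):
        x = np.zeros((2, 2, 2), np.float32)
        r = np.ones_like(x)
        post = _posterior(np.zeros((1, 1, 1)), 0.0)
        assert ae_loss(x, r, post, lambda_kl=0.0, recon_loss="l1") == pytest.approx(1.0)

    def test_additive_in_kl_and_monotone_in_lambda(self):
        x = np.zeros((2, 2, 2), np.float32)
        r = np.full_like(x, 0.5)
        post = _posterior(np.ones((1, 1, 1)), 0.0)
        base = ae_loss(x, r, post, lambda_kl=0.0)
        one = ae_loss(x, r, post, lambda_kl=1.0)
        two = ae_loss(x, r, post, lambda_kl=2.0)
        assert one == pytest.approx(base + kl_term(post))
        assert base < one < two


@pytest.fixture(scope="module")
def tiny_trained_ae(small_dataset_module):
    cubes = [c for c, _, _ in small_dataset_module]
    ae = KLAutoencoder(spatial_factor=2, latent_channels=4, width=8, epochs=6,
                       batch_size=4, lr=3e-3, seed=0)
    return ae.fit(cubes), cubes


@pytest.fixture(scope="module")
def small_dataset_module():
    from hsisynth.phantom import PhantomConfig, make_dataset, make_spectral_library
    cfg = PhantomConfig(n_subjects=3, images_per_subject=4, H=16, W=16, C=12,
                        seed=7)
    lib = make_spectral_library(cfg.n_classes, cfg.C, seed=7)
    return make_dataset(cfg, lib)


class TestKLAutoencoderEstimator:
    def test_shape_contract(self, tiny_trained_ae):
        ae, cubes = tiny_trained_ae
        post = ae.encode(cubes[0])
        assert post.mean.shape == (8, 8, 4)
        recon = ae.decode(post.mean)
        assert recon.shape == cubes[0].data.shape
        assert np.all(np.isfinite(recon))

    def test_encode_decode_deterministic(self, tiny_trained_ae):
        ae, cubes = tiny_trained_ae
        a = ae.encode(cubes[0])
        b = ae.encode(cubes[0])
        np.testing.assert_array_equal(a.mean, b.mean)
        np.testing.assert_array_equal(ae.decode(a.mean), ae.decode(b.mean))

    def test_training_reduces_loss(self, tiny_trained_ae):
        ae, _ = tiny_trained_ae
        assert ae.loss_history_[-1] < ae.loss_history_[0]
        assert ae.val_loss_history_[-1] < ae.val_loss_history_[0]

    def test_checkpoint_round_trip_bit_exact(self, tiny_trained_ae, tmp_path):
        ae, cubes = tiny_trained_ae
        ae.save(tmp_path / "ae.npz")
        back = KLAutoencoder.load(tmp_path / "ae.npz")
        assert back.scale_factor_ == ae.scale_factor_
        np.testing.assert_array_equal(back.reconstruct(cubes[0]),
                                      ae.reconstruct(cubes[0]))

    def test_indivisible_dims_rejected(self, tiny_trained_ae):
        ae, _ = tiny_trained_ae
        with pytest.raises(ConfigError):
            ae.encode(np.ones((15, 16, 12), np.float32))

    def test_invalid_factor_rejected(self):
        with pytest.raises(ConfigError):
            KLAutoencoder(spatial_factor=3).fit(np.ones((2, 8, 8, 4), np.float32))

    def test_sklearn_param_round_trip(self):
        ae = KLAutoencoder(latent_channels=6, lambda_kl=1e-5)
        clone = KLAutoencoder(**ae.get_params())
        assert clone.get_params() == ae.get_params()


class TestMedianRelativeError:
    def test_exact_reconstruction_is_zero(self):
        x = np.full((3, 3, 2), 0.5, np.float32)
        assert median_relative_error(x, x) == 0.0

    def test_ten_percent_offset(self):
        x = np.full((3, 3, 2), 1.0, np.float32)
        assert median_relative_error(x, 1.1 * x) == pytest.approx(0.1, rel=1e-4)
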