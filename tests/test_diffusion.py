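import numpy as np
import pytest

from hsisynth.diffusion import (MaskDiffusion, NoiseSchedule, cfg_combine,
                                crop_latent, ddim_step, ddim_timesteps,
                                forward_diffuse, make_schedule, nearest_rescale,
                                pad_latent)
from hsisynth.errors import ConfigError, ValidationError


class TestSchedule:
    def test_default_thousand_step_schedule(self):
        s = make_schedule(1000)
        assert np.all(np.diff(s.alpha_bars) < 0)
        assert s.alpha_bars[-1] < 0.01
        assert s.alpha_bars[0] > 0.99

    def test_constant_beta_closed_form(self):
        s = NoiseSchedule(betas=np.full(5, 0.1),
                          alpha_bars=np.cumprod(np.full(5, 0.9)))
        np.testing.assert_allclose(s.alpha_bars, 0.9 ** np.arange(1, 6))

    def test_hand_product(self):
        s = NoiseSchedule(betas=np.array([0.5, 0.5]),
                          alpha_bars=np.cumprod([0.5, 0.5]))
        np.testing.assert_allclose(s.alpha_bars, [0.5, 0.25])
        assert s.alpha_bar(0) == 1.0

    def test_invalid_T_rejected(self):
        with pytest.raises(ConfigError):
            make_schedule(1)


class TestForwardDiffuse:
    def _schedule_with_abar(self, abar):
        # betas chosen so cumprod hits abar at t=1
        return NoiseSchedule(betas=np.array([1 - abar, 0.5]),
                             alpha_bars=np.array([abar, abar * 0.5]))

    def test_no_noise_limit(self):
        s = self._schedule_with_abar(1 - 1e-12)
        z = np.full((2, 2), 3.0)
        out = forward_diffuse(z, 1, np.ones_like(z), s)
        np.testing.assert_allclose(out, z, atol=1e-5)

    def test_hand_value(self):
        s = self._schedule_with_abar(0.25)
        out = forward_diffuse(np.array([[2.0]]), 1, np.array([[1.0]]), s)
        assert out[0, 0] == pytest.approx(0.5 * 2 + np.sqrt(0.75), abs=1e-6)
        assert out[0, 0] == pytest.approx(1.86603, abs=1e-5)

    def test_variance_preservation_monte_carlo(self):
        s = make_schedule(100)
        rng = np.random.default_rng(0)
        z0 = rng.standard_normal(100000)
        eps = rng.standard_normal(100000)
        for t in (1, 50, 100):
            zt = forward_diffuse(z0, t, eps, s)
            assert zt.var() == pytest.approx(1.0, abs=0.02)

    def test_t_out_of_range_rejected(self):
        s = make_schedule(10)
        with pytest.raises(ValidationError):
            forward_diffuse(np.zeros(2), 11, np.zeros(2), s)


class TestPadLatent:
    def test_pads_to_next_multiple(self):
        x = np.ones((30, 40, 4))
        padded, box = pad_latent(x, 3)
        assert padded.shape == (32, 40, 4)
        np.testing.assert_array_equal(crop_latent(padded, box), x)
        assert padded[30:].sum() == 0

    def test_identity_when_already_divisible(self):
        x = np.ones((120, 160, 2))
        padded, box = pad_latent(x, 3)
        assert padded.shape == (120, 160, 2)
        np.testing.assert_array_equal(crop_latent(padded, box), x)

    def test_round_trip_random_shapes(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            h, w, d = rng.integers(1, 40), rng.integers(1, 40), rng.integers(0, 4)
            x = rng.standard_normal((h, w, 3))
            padded, box = pad_latent(x, int(d))
            assert padded.shape[0] % 2**d == 0 and padded.shape[1] % 2**d == 0
            np.testing.assert_array_equal(crop_latent(padded, box), x)


class TestCfgCombine:
    def test_lambda_one_is_conditional(self):
        rng = np.random.default_rng(0)
        c, u = rng.standard_normal((2, 3, 3))
        np.testing.assert_array_equal(cfg_combine(c, u, 1.0), c)

    def test_equal_inputs_any_lambda(self):
        x = np.random.default_rng(1).standard_normal((4, 4))
        for lam in (0.0, 1.0, 2.0, 7.5):
            np.testing.assert_allclose(cfg_combine(x, x, lam), x)

    def test_hand_value(self):
        assert cfg_combine(np.array(1.0), np.array(0.0), 2.0) == pytest.approx(2.0)


class TestDdimStep:
    def _schedule(self):
        # alpha_bars [0.64, 0.25] -> t=1 has 0.64, t=2 has 0.25
        return NoiseSchedule(betas=np.array([0.36, 0.609375]),
                             alpha_bars=np.array([0.64, 0.25]))

    def test_hand_value(self):
        s = self._schedule()
        z_t = np.array(1.86603)
        out = ddim_step(z_t, np.array(1.0), t=2, t_prev=1, schedule=s)
        assert out == pytest.approx(2.2, abs=1e-4)

    def test_t_prev_zero_returns_x0(self):
        s = self._schedule()
        z0 = np.array(0.7)
        eps = np.array(-0.3)
        zt = forward_diffuse(z0, 2, eps, s)
        out = ddim_step(zt, eps, t=2, t_prev=0, schedule=s)
        assert out == pytest.approx(z0, abs=1e-8)

    def test_true_noise_inverts_forward_exactly(self):
        s = make_schedule(50)
        rng = np.random.default_rng(2)
        z0 = rng.standard_normal((4, 4, 2))
        eps = rng.standard_normal((4, 4, 2))
        for t in (1, 25, 50):
            zt = forward_diffuse(z0, t, eps, s)
            x0 = ddim_step(zt, eps, t=t, t_prev=0, schedule=s)
            np.testing.assert_allclose(x0, z0, atol=1e-10)

    def test_ordering_violation_rejected(self):
        s = make_schedule(10)
        with pytest.raises(ValidationError):
            ddim_step(np.zeros(2), np.zeros(2), t=3, t_prev=3, schedule=s)


class TestTimestepsAndRescale:
    def test_subsequence_includes_T_and_is_decreasing(self):
        ts = ddim_timesteps(200, 50)
        assert ts[0] == 200
        assert np.all(np.diff(ts) < 0)
        assert len(ts) == 50

    def test_blocky_mask_downscale_preserves_labels(self):
        block = np.array([[0, 0, 1, 1],
                          [0, 0, 1, 1],
                          [2, 2, 3, 3],
                          [2, 2, 3, 3]], dtype=float)[..., None]
        small = nearest_rescale(block, (2, 2))
        np.testing.assert_array_equal(small[..., 0], [[0, 1], [2, 3]])


@pytest.fixture(scope="module")
def toy_dm():
    """A briefly trained DM on random latents, for contract tests."""
    rng = np.random.default_rng(0)
    Z = rng.standard_normal((8, 8, 8, 2)).astype(np.float32)
    M = np.eye(3, dtype=np.float32)[rng.integers(0, 3, (8, 16, 16))]
    dm = MaskDiffusion(T=20, width=8, n_down=1, cond_channels=2, temb_dim=8,
                       p_drop=0.2, train_steps=200, batch_size=4, seed=0)
    return dm.fit(Z, M)


class TestMaskDiffusionContracts:
    def test_untrained_unet_predicts_zero_noise(self):
        from hsisynth.diffusion import _UNet
        rng = np.random.default_rng(0)
        net = _UNet(4, 2, width=8, n_down=1, temb_dim=8, rng=rng)
        from hsisynth import nn
        x = nn.Tensor(rng.standard_normal((2, 4, 8, 8)))
        np.testing.assert_array_equal(net(x, np.array([1, 5])).data, 0.0)

    def test_denoise_predict_shape_and_determinism(self, toy_dm):
        rng = np.random.default_rng(1)
        z = rng.standard_normal((2, 2, 8, 8)).astype(np.float32)
        cond = rng.standard_normal((2, 2, 8, 8)).astype(np.float32)
        a = toy_dm.denoise_predict(z, cond, 5)
        b = toy_dm.denoise_predict(z, cond, 5)
        assert a.shape == z.shape
        np.testing.assert_array_equal(a, b)

    def test_condition_tensor_shape_and_interior_constancy(self, toy_dm):
        mask_oh = np.zeros((16, 16, 3), np.float32)
        mask_oh[..., 1] = 1.0
        cond = toy_dm.encode_condition(mask_oh, (8, 8))
        assert cond.shape == (8, 8, 2)
        interior = cond[1:-1, 1:-1]
        np.testing.assert_allclose(
            interior, np.broadcast_to(interior[0, 0], interior.shape), atol=1e-5)

    def test_condition_dropout_fraction_matches_p(self):
        rng = np.random.default_rng(0)
        draws = rng.random(10000) < 0.1
        # the estimator records its own empirical dropout fraction
        Z = rng.standard_normal((4, 4, 4, 2)).astype(np.float32)
        M = np.eye(2, dtype=np.float32)[rng.integers(0, 2, (4, 8, 8))]
        dm = MaskDiffusion(T=10, width=4, n_down=0, cond_channels=2, temb_dim=4,
                           p_drop=0.25, train_steps=400, batch_size=8, seed=1)
        dm.fit(Z, M)
        assert dm.dropped_fraction_ == pytest.approx(0.25, abs=0.03)
        dm0 = MaskDiffusion(T=10, width=4, n_down=0, cond_channels=2, temb_dim=4,
                            p_drop=0.0, train_steps=50, batch_size=8, seed=1)
        dm0.fit(Z, M)
        assert dm0.dropped_fraction_ == 0.0

    def test_training_reduces_loss(self, toy_dm):
        first = np.mean(toy_dm.loss_history_[:20])
        last = np.mean(toy_dm.loss_history_[-20:])
        assert last < first

    def test_checkpoint_round_trip(self, toy_dm, tmp_path):
        toy_dm.save(tmp_path / "dm.npz")
        back = MaskDiffusion.load(tmp_path / "dm.npz")
        rng = np.random.default_rng(5)
        z = rng.standard_normal((1, 2, 8, 8)).astype(np.float32)
        np.testing.assert_array_equal(back.denoise_predict(z, None, 3),
                                      toy_dm.denoise_predict(z, None, 3))

    def test_invalid_p_drop_rejected(self):
        with pytest.raises(ConfigError):
            MaskDiffusion(p_drop=1.0).fit(
                np.zeros((2, 4, 4, 1), np.float32),
                np.ones((2, 8, 8, 1), np.float32))
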