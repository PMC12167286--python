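"""Mask-conditioned diffusion in the autoencoder's latent space.

A standard variance-preserving diffusion model (linear beta schedule,
epsilon-prediction U-Net) with three domain-specific pieces:

* conditioning: the one-hot segmentation mask is nearest-neighbour rescaled
  to the latent resolution and passed through a single learned convolution;
  the resulting condition tensor is concatenated to z_t at every denoising
  step. The null condition for classifier-free guidance is the all-zeros
  condition tensor.
* padding: non-quadratic latents are zero-padded up to the next multiple of
  2^d so every U-Net downsampling sees even resolutions; the crop box is
  recorded and applied after sampling.
* sampling: deterministic DDIM (eta = 0) over a uniformly spaced timestep
  subsequence, with classifier-free guidance
  eps = eps_uncond + lambda * (eps_cond - eps_uncond).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import nn
from .autoencoder import KLAutoencoder, Latent
from .errors import ConfigError, ValidationError
from .hsi_io import SemanticMask, one_hot

__all__ = [
    "NoiseSchedule", "SamplerConfig", "make_schedule", "forward_diffuse",
    "pad_latent", "crop_latent", "cfg_combine", "ddim_step", "MaskDiffusion",
]


# --------------------------------------------------------------------------
# schedule and closed-form pieces
# --------------------------------------------------------------------------

@dataclass
class NoiseSchedule:
    """T-step variance-preserving coefficients beta_t and alpha_bar_t."""

    betas: np.ndarray          # (T,), beta_1 .. beta_T
    alpha_bars: np.ndarray     # (T,), strictly decreasing in (0, 1]

    def __post_init__(self):
        self.betas = np.asarray(self.betas, dtype=np.float64)
        self.alpha_bars = np.asarray(self.alpha_bars, dtype=np.float64)
        if np.any(self.betas <= 0) or np.any(self.betas >= 1):
            raise ConfigError("betas must lie in (0, 1)")
        if np.any(np.diff(self.alpha_bars) >= 0):
            raise ConfigError("alpha_bar must be strictly decreasing")
        if not np.all(np.isfinite(self.alpha_bars)):
            raise ConfigError("alpha_bar must be finite")

    @property
    def T(self) -> int:
        return len(self.betas)

    def alpha_bar(self, t) -> np.ndarray | float:
        """alpha_bar_t with the convention alpha_bar_0 = 1."""
        t = np.asarray(t)
        if np.any(t < 0) or np.any(t > self.T):
            raise ValidationError(f"t out of range [0, {self.T}]")
        padded = np.concatenate([[1.0], self.alpha_bars])
        out = padded[t]
        return float(out) if out.ndim == 0 else out


def make_schedule(T: int, kind: str = "linear", beta_start: float = 1e-4,
                  beta_end: float = 2e-2) -> NoiseSchedule:
    if T < 2:
        raise ConfigError("T must be >= 2")
    if kind != "linear":
        raise ConfigError(f"unknown schedule kind: {kind!r}")
    betas = np.linspace(beta_start, beta_end, T)
    return NoiseSchedule(betas=betas, alpha_bars=np.cumprod(1.0 - betas))


def forward_diffuse(z0, t: int, eps: np.ndarray, schedule: NoiseSchedule):
    """z_t = sqrt(abar_t) z0 + sqrt(1 - abar_t) eps, 1 <= t <= T."""
    if not (1 <= t <= schedule.T):
        raise ValidationError(f"t={t} outside [1, {schedule.T}]")
    values = z0.values if isinstance(z0, Latent) else np.asarray(z0)
    eps = np.asarray(eps)
    if eps.shape != values.shape:
        raise ValidationError("eps shape must match z0")
    ab = schedule.alpha_bar(t)
    zt = np.sqrt(ab) * values + np.sqrt(1.0 - ab) * eps
    if isinstance(z0, Latent):
        return Latent(values=zt.astype(np.float32), scale_factor=z0.scale_factor)
    return zt


def pad_latent(latent: np.ndarray, n_downsamplings: int
               ) -> tuple[np.ndarray, tuple[int, int]]:
    """Zero-pad spatial dims (first two axes) up to a multiple of 2^d.

    Returns the padded array and the original (h, w) crop box.
    """
    if n_downsamplings < 0:
        raise ConfigError("n_downsamplings must be >= 0")
    arr = np.asarray(latent)
    h, w = arr.shape[0], arr.shape[1]
    mult = 2**n_downsamplings
    ph = (-h) % mult
    pw = (-w) % mult
    if ph == 0 and pw == 0:
        return arr, (h, w)
    pad_spec = [(0, ph), (0, pw)] + [(0, 0)] * (arr.ndim - 2)
    return np.pad(arr, pad_spec), (h, w)


def crop_latent(padded: np.ndarray, crop_box: tuple[int, int]) -> np.ndarray:
    h, w = crop_box
    return padded[:h, :w]


def cfg_combine(eps_cond: np.ndarray, eps_uncond: np.ndarray,
                guidance_scale: float) -> np.ndarray:
    """Classifier-free guidance: eps_u + lambda * (eps_c - eps_u)."""
    eps_cond = np.asarray(eps_cond)
    eps_uncond = np.asarray(eps_uncond)
    if eps_cond.shape != eps_uncond.shape:
        raise ValidationError("eps shapes must match")
    if guidance_scale == 1.0:  # exact identity, no float round-off
        return eps_cond.copy()
    return eps_uncond + guidance_scale * (eps_cond - eps_uncond)


def ddim_step(z_t: np.ndarray, eps_hat: np.ndarray, t: int, t_prev: int,
              schedule: NoiseSchedule, eta: float = 0.0,
              rng: np.random.Generator | None = None,
              clip_x0: float | None = None) -> np.ndarray:
    """One accelerated reverse step from t to t_prev (alpha_bar_0 = 1).

    ``clip_x0`` optionally clamps the predicted clean sample to
    [-clip_x0, clip_x0] before re-noising — the usual guard against
    guidance pushing the trajectory off the data manifold; sensible for
    standardized (unit-scale) latents.
    """
    if not (t > t_prev >= 0):
        raise ValidationError(f"need t > t_prev >= 0, got t={t}, t_prev={t_prev}")
    if not (0.0 <= eta <= 1.0):
        raise ConfigError("eta must be in [0, 1]")
    ab_t = schedule.alpha_bar(t)
    ab_p = schedule.alpha_bar(t_prev)
    x0_hat = (z_t - np.sqrt(1.0 - ab_t) * eps_hat) / np.sqrt(ab_t)
    if clip_x0 is not None:
        x0_hat = np.clip(x0_hat, -clip_x0, clip_x0)
        eps_hat = (z_t - np.sqrt(ab_t) * x0_hat) / np.sqrt(1.0 - ab_t)
    if eta == 0.0:
        return np.sqrt(ab_p) * x0_hat + np.sqrt(1.0 - ab_p) * eps_hat
    sigma = eta * np.sqrt((1.0 - ab_p) / (1.0 - ab_t)) * np.sqrt(1.0 - ab_t / ab_p)
    if rng is None:
        raise ConfigError("eta > 0 requires a seeded rng")
    noise = rng.standard_normal(np.shape(z_t))
    dir_term = np.sqrt(np.maximum(1.0 - ab_p - sigma**2, 0.0)) * eps_hat
    return np.sqrt(ab_p) * x0_hat + dir_term + sigma * noise


def ddim_timesteps(T: int, steps: int) -> np.ndarray:
    """Uniformly spaced decreasing timestep subsequence of [1, T] including T."""
    if steps > T:
        raise ConfigError(f"steps={steps} exceeds T={T}")
    ts = np.unique(np.round(np.linspace(1, T, steps)).astype(int))
    return ts[::-1]


@dataclass
class SamplerConfig:
    steps: int = 100
    guidance_scale: float = 2.0
    eta: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.guidance_scale < 0:
            raise ConfigError("guidance_scale must be >= 0")
        if not (0.0 <= self.eta <= 1.0):
            raise ConfigError("eta must be in [0, 1]")


# --------------------------------------------------------------------------
# condition encoder and denoiser
# --------------------------------------------------------------------------

def nearest_rescale(stack: np.ndarray, target_hw: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour spatial rescale of an (H, W, K) stack; labels are
    never interpolated."""
    h_t, w_t = target_hw
    h, w = stack.shape[:2]
    rows = (np.arange(h_t) * h) // h_t
    cols = (np.arange(w_t) * w) // w_t
    return stack[rows][:, cols]


class _CondEncoder(nn.Module):
    """Single learned convolution applied after nearest-neighbour rescaling."""

    def __init__(self, n_classes: int, cond_channels: int, rng):
        self.conv = nn.Conv2d(n_classes, cond_channels, 3, rng=rng)

    def forward(self, onehot_nchw: nn.Tensor) -> nn.Tensor:
        return self.conv(onehot_nchw)


class _Block(nn.Module):
    """conv -> +time bias -> silu -> conv, with residual connection."""

    def __init__(self, c_in, c_out, temb_dim, rng):
        self.norm = nn.GroupNorm(c_in, groups=min(8, c_in))
        self.conv1 = nn.Conv2d(c_in, c_out, 3, rng=rng)
        self.temb = nn.Linear(temb_dim, c_out, rng=rng)
        self.conv2 = nn.Conv2d(c_out, c_out, 3, rng=rng)
        self.skip = nn.Conv2d(c_in, c_out, 1, rng=rng) if c_in != c_out else None

    def forward(self, x, temb):
        h = self.conv1(self.norm(x).silu())
        n, c = h.shape[0], h.shape[1]
        h = h + self.temb(temb).reshape(n, c, 1, 1)
        h = self.conv2(h.silu())
        res = self.skip(x) if self.skip is not None else x
        return h + res


class _UNet(nn.Module):
    """Small epsilon-prediction U-Net; final conv zero-initialized so an
    untrained model predicts exactly zero noise."""

    def __init__(self, c_in, c_out, width, n_down, temb_dim, rng):
        self.n_down = n_down
        self.temb_dim = temb_dim
        self.temb_mlp = nn.Sequential(nn.Linear(temb_dim, temb_dim * 2, rng=rng))
        self.conv_in = nn.Conv2d(c_in, width, 3, rng=rng)
        widths = [width * 2**i for i in range(n_down + 1)]
        self.down_blocks = [_Block(widths[i], widths[i], temb_dim * 2, rng)
                            for i in range(n_down)]
        self.downsamplers = [nn.Conv2d(widths[i], widths[i + 1], 3, stride=2, rng=rng)
                             for i in range(n_down)]
        self.mid = _Block(widths[-1], widths[-1], temb_dim * 2, rng)
        self.up_convs = [nn.Conv2d(widths[i + 1], widths[i], 3, rng=rng)
                         for i in reversed(range(n_down))]
        self.up_blocks = [_Block(2 * widths[i], widths[i], temb_dim * 2, rng)
                          for i in reversed(range(n_down))]
        self.conv_out = nn.Conv2d(width, c_out, 3, zero_init=True)

    def forward(self, x: nn.Tensor, t: np.ndarray) -> nn.Tensor:
        temb = nn.Tensor(nn.timestep_embedding(t, self.temb_dim))
        temb = self.temb_mlp(temb).silu()
        h = self.conv_in(x)
        skips = []
        for block, down in zip(self.down_blocks, self.downsamplers):
            h = block(h, temb)
            skips.append(h)
            h = down(h)
        h = self.mid(h, temb)
        for up, block, skip in zip(self.up_convs, self.up_blocks, reversed(skips)):
            h = up(nn.upsample2x(h))
            h = block(nn.concat([h, skip], axis=1), temb)
        return self.conv_out(h)


# --------------------------------------------------------------------------
# estimator
# --------------------------------------------------------------------------

class MaskDiffusion(BaseEstimator):
    """Mask-conditioned latent diffusion model, scikit-learn style.

    ``fit(Z, M)`` trains the denoiser on standardized latents Z
    (N, h, w, c_lat) with one-hot masks M (N, H, W, K); ``sample`` runs
    classifier-free-guided DDIM and decodes through a fitted autoencoder.

    Condition dropout (probability ``p_drop``) replaces the condition tensor
    with zeros during training so the model also learns the unconditional
    score that guidance needs.
    """

    def __init__(self, T: int = 1000, beta_start: float = 1e-4,
                 beta_end: float = 2e-2, cond_channels: int = 4,
                 width: int = 32, n_down: int = 1, temb_dim: int = 32,
                 p_drop: float = 0.1, train_steps: int = 2000,
                 batch_size: int = 16, lr: float = 2e-3,
                 ema_decay: float = 0.0, warm_start: bool = False,
                 seed: int = 0):
        self.T = T
        self.beta_start = beta_start
        self.beta_end = beta_end
        self.cond_channels = cond_channels
        self.width = width
        self.n_down = n_down
        self.temb_dim = temb_dim
        self.p_drop = p_drop
        self.train_steps = train_steps
        self.batch_size = batch_size
        self.lr = lr
        self.ema_decay = ema_decay
        self.warm_start = warm_start
        self.seed = seed

    def _check_params(self):
        if not (0.0 <= self.p_drop < 1.0):
            raise ConfigError("p_drop must be in [0, 1)")
        if self.T < 2:
            raise ConfigError("T must be >= 2")

    # -- conditioning -----------------------------------------------------

    def encode_condition(self, mask_onehot: np.ndarray,
                         target_hw: tuple[int, int]) -> np.ndarray:
        """(H, W, K) one-hot -> (h, w, cond_channels) condition tensor."""
        check_is_fitted(self, "cond_encoder_")
        if mask_onehot.shape[-1] != self.n_classes_:
            raise ValidationError(
                f"one-hot has {mask_onehot.shape[-1]} classes, model expects "
                f"{self.n_classes_}"
            )
        resc = nearest_rescale(mask_onehot, target_hw)
        out = self.cond_encoder_(nn.Tensor(resc.transpose(2, 0, 1)[None].astype(np.float32)))
        return out.data[0].transpose(1, 2, 0)

    def _cond_batch(self, onehots_nchw: np.ndarray) -> nn.Tensor:
        return self.cond_encoder_(nn.Tensor(onehots_nchw))

    # -- training ---------------------------------------------------------

    def fit(self, Z: np.ndarray, M: np.ndarray, scale_factor: float = 1.0):
        """Train on latents Z (N, h, w, c) and one-hot masks M (N, H, W, K).

        Z is multiplied by ``scale_factor`` (the autoencoder's latent
        standardization constant) before diffusion.
        """
        self._check_params()
        Z = np.asarray(Z, dtype=np.float32)
        M = np.asarray(M, dtype=np.float32)
        if Z.ndim != 4 or M.ndim != 4 or len(Z) != len(M):
            raise ValidationError("Z must be (N,h,w,c), M (N,H,W,K), equal N")
        n, h, w, c_lat = Z.shape
        self.latent_channels_ = c_lat
        self.n_classes_ = M.shape[-1]
        self.scale_factor_ = float(scale_factor)
        self.schedule_ = make_schedule(self.T, beta_start=self.beta_start,
                                       beta_end=self.beta_end)
        resume = self.warm_start and hasattr(self, "model_")
        rng = np.random.default_rng(self.seed + (len(getattr(self, "loss_history_", [])) if resume else 0))
        if not resume:
            self.cond_encoder_ = _CondEncoder(self.n_classes_, self.cond_channels, rng)
            self.model_ = _UNet(c_lat + self.cond_channels, c_lat, self.width,
                                self.n_down, self.temb_dim, rng)

        z_all = (Z * self.scale_factor_).transpose(0, 3, 1, 2)  # NCHW
        z_all, self.crop_box_ = self._pad_nchw(z_all)
        cond_in = np.stack([nearest_rescale(m, z_all.shape[2:]) for m in M])
        cond_in = cond_in.transpose(0, 3, 1, 2).astype(np.float32)

        params = self.model_.parameters() + self.cond_encoder_.parameters()
        opt = nn.Adam(params, lr=self.lr)
        ema = [p.data.copy() for p in params] if self.ema_decay else None
        if not resume:
            self.loss_history_ = []
        self.dropped_fraction_ = 0.0
        dropped = 0
        seen = 0
        for step in range(self.train_steps):
            # cosine decay to 10% of the base rate
            opt.lr = self.lr * (0.1 + 0.9 * 0.5 *
                                (1 + np.cos(np.pi * step / max(1, self.train_steps - 1))))
            idx = rng.integers(0, n, size=min(self.batch_size, n))
            z0 = z_all[idx]
            t = rng.integers(1, self.T + 1, size=len(idx))
            eps = rng.standard_normal(z0.shape).astype(np.float32)
            ab = self.schedule_.alpha_bar(t).reshape(-1, 1, 1, 1)
            zt = (np.sqrt(ab) * z0 + np.sqrt(1.0 - ab) * eps).astype(np.float32)
            cond = self._cond_batch(cond_in[idx])
            drop = rng.random(len(idx)) < self.p_drop
            dropped += int(drop.sum())
            seen += len(idx)
            if drop.any():
                keep = (~drop).astype(np.float32).reshape(-1, 1, 1, 1)
                cond = cond * keep
            x = nn.concat([nn.Tensor(zt), cond], axis=1)
            eps_hat = self.model_(x, t)
            diff = eps_hat - nn.Tensor(eps)
            loss = (diff * diff).mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(f"diffusion training diverged at step {step}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            if ema is not None:
                d = min(self.ema_decay, (1 + opt.t) / (10 + opt.t))
                for shadow, p in zip(ema, params):
                    shadow *= d
                    shadow += (1.0 - d) * p.data
            self.loss_history_.append(float(loss.data))
        if ema is not None:  # sample from the averaged weights
            for shadow, p in zip(ema, params):
                p.data = shadow.astype(np.float32)
        self.dropped_fraction_ = dropped / max(1, seen)
        return self

    def _pad_nchw(self, z_nchw: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
        hw = z_nchw.transpose(0, 2, 3, 1)
        padded, box = pad_latent(hw[0], self.n_down)
        out = np.stack([pad_latent(img, self.n_down)[0] for img in hw])
        return out.transpose(0, 3, 1, 2), box

    # -- inference --------------------------------------------------------

    def denoise_predict(self, z_t: np.ndarray, cond: np.ndarray | None,
                        t) -> np.ndarray:
        """eps_hat for a batch (N, c_lat, h, w); cond None means the null
        (all-zeros) condition tensor."""
        check_is_fitted(self, "model_")
        z_t = np.asarray(z_t, dtype=np.float32)
        if cond is None:
            cond = np.zeros((z_t.shape[0], self.cond_channels,
                             z_t.shape[2], z_t.shape[3]), np.float32)
        x = nn.concat([nn.Tensor(z_t), nn.Tensor(np.asarray(cond, np.float32))], axis=1)
        t = np.full(z_t.shape[0], t) if np.isscalar(t) else np.asarray(t)
        return self.model_(x, t).data

    def sample(self, mask, ae: KLAutoencoder, steps: int = 100,
               guidance_scale: float = 2.0, eta: float = 0.0,
               seed: int = 0) -> np.ndarray:
        """Synthesize one (H, W, C) cube array from a mask."""
        return self.sample_batch([mask], ae, steps=steps,
                                 guidance_scale=guidance_scale, eta=eta,
                                 seed=seed)[0]

    def sample_batch(self, masks, ae: KLAutoencoder, steps: int = 100,
                     guidance_scale: float = 2.0, eta: float = 0.0,
                     clip_x0: float | None = 2.0,
                     seed: int = 0) -> list[np.ndarray]:
        """Classifier-free-guided DDIM sampling for a batch of masks.

        Deterministic given the seed at eta = 0. At guidance scale 1 the
        unconditional pass is skipped (the combination reduces to the
        conditional prediction).
        """
        check_is_fitted(self, "model_")
        onehots = []
        for m in masks:
            oh = (one_hot(m, self.n_classes_) if isinstance(m, SemanticMask)
                  else np.asarray(m, np.float32))
            onehots.append(oh)
        n = len(onehots)
        # latent spatial dims from the AE factor, then padded for the U-Net
        H, W = onehots[0].shape[:2]
        f = ae.spatial_factor
        h, w = H // f, W // f
        hp = h + ((-h) % 2**self.n_down)
        wp = w + ((-w) % 2**self.n_down)
        cond_in = np.stack([nearest_rescale(oh, (hp, wp)) for oh in onehots])
        cond = self._cond_batch(cond_in.transpose(0, 3, 1, 2).astype(np.float32)).data

        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n, self.latent_channels_, hp, wp)).astype(np.float32)
        ts = ddim_timesteps(self.T, steps)
        for i, t in enumerate(ts):
            t_prev = int(ts[i + 1]) if i + 1 < len(ts) else 0
            eps_c = self.denoise_predict(z, cond, int(t))
            if guidance_scale == 1.0:
                eps_hat = eps_c
            else:
                eps_u = self.denoise_predict(z, None, int(t))
                eps_hat = cfg_combine(eps_c, eps_u, guidance_scale)
            z = ddim_step(z, eps_hat, int(t), t_prev, self.schedule_,
                          eta=eta, rng=rng, clip_x0=clip_x0).astype(np.float32)
        out = []
        for zi in z:
            lat = zi.transpose(1, 2, 0)[:h, :w] / self.scale_factor_
            out.append(np.clip(ae.decode(lat.astype(np.float32)), 0.0, None))
        return out

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        check_is_fitted(self, "model_")
        state = {f"unet.{k}": v for k, v in self.model_.state_dict().items()}
        state |= {f"cond.{k}": v for k, v in self.cond_encoder_.state_dict().items()}
        meta = json.dumps({
            "params": self.get_params(),
            "latent_channels": self.latent_channels_,
            "n_classes": self.n_classes_,
            "scale_factor": self.scale_factor_,
            "numpy_version": np.__version__,
        })
        np.savez(Path(path), __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **state)

    @classmethod
    def load(cls, path) -> "MaskDiffusion":
        with np.load(Path(path)) as f:
            meta = json.loads(bytes(f["__meta__"]).decode())
            state = {k: f[k] for k in f.files if k != "__meta__"}
        model = cls(**meta["params"])
        model.latent_channels_ = meta["latent_channels"]
        model.n_classes_ = meta["n_classes"]
        model.scale_factor_ = meta["scale_factor"]
        model.schedule_ = make_schedule(model.T, beta_start=model.beta_start,
                                        beta_end=model.beta_end)
        rng = np.random.default_rng(model.seed)
        model.cond_encoder_ = _CondEncoder(model.n_classes_, model.cond_channels, rng)
        model.model_ = _UNet(model.latent_channels_ + model.cond_channels,
                             model.latent_channels_, model.width, model.n_down,
                             model.temb_dim, rng)
        model.cond_encoder_.load_state_dict(
            {k[5:]: v for k, v in state.items() if k.startswith("cond.")})
        model.model_.load_state_dict(
            {k[5:]: v for k, v in state.items() if k.startswith("unet.")})
        model.loss_history_ = []
        return model
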