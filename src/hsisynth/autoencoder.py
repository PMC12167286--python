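"""KL-regularized variational autoencoder for hyperspectral cubes.

Compresses cubes both spatially (strided convolutions, factor ``f``) and
spectrally (C bands -> ``latent_channels``), trained with a pixelwise
reconstruction loss (L1 by default) plus a small KL term against a standard
normal prior. There is deliberately no perceptual and no adversarial loss
component: perceptual feature extractors do not transfer to hyperspectral
data, and an adversarial term adds no reconstruction benefit here.

After training, a global latent standardization constant (1 / std of sampled
training latents) is stored so the downstream variance-preserving diffusion
model operates on roughly unit-scale latents.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import nn
from .errors import ConfigError, ValidationError
from .hsi_io import HsiCube

__all__ = [
    "LatentPosterior", "Latent", "KLAutoencoder",
    "kl_term", "sample_latent", "ae_loss", "train_ae",
    "median_relative_error",
]

LOGVAR_MIN, LOGVAR_MAX = -30.0, 20.0


@dataclass
class LatentPosterior:
    """Diagonal-Gaussian posterior over a latent, h x w x c arrays."""

    mean: np.ndarray
    logvar: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float32)
        self.logvar = np.clip(np.asarray(self.logvar, dtype=np.float32),
                              LOGVAR_MIN, LOGVAR_MAX)
        if self.mean.shape != self.logvar.shape:
            raise ValidationError("posterior mean/logvar shape mismatch")


@dataclass
class Latent:
    """A latent sample plus the global standardization constant."""

    values: np.ndarray
    scale_factor: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if not self.scale_factor > 0:
            raise ValidationError("scale_factor must be positive")


# --------------------------------------------------------------------------
# loss pieces (pure numpy; the training loop uses autograd equivalents)
# --------------------------------------------------------------------------

def kl_term(posterior: LatentPosterior) -> float:
    """Mean over cells of KL(q || N(0,1)) = 0.5 (mu^2 + sigma^2 - 1 - log sigma^2)."""
    var = np.exp(posterior.logvar.astype(np.float64))
    kl = 0.5 * (posterior.mean.astype(np.float64) ** 2 + var - 1.0 - posterior.logvar)
    return float(kl.mean())


def sample_latent(posterior: LatentPosterior, seed: int,
                  scale_factor: float = 1.0) -> Latent:
    """Reparameterized draw mean + exp(logvar/2) * eps, eps ~ N(0,1)."""
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(posterior.mean.shape).astype(np.float32)
    values = posterior.mean + np.exp(0.5 * posterior.logvar) * eps
    return Latent(values=values, scale_factor=scale_factor)


def ae_loss(cube, reconstruction, posterior: LatentPosterior,
            lambda_kl: float, recon_loss: str = "l1") -> float:
    """Pixelwise reconstruction term plus lambda_KL * KL. Nothing else."""
    x = cube.data if isinstance(cube, HsiCube) else np.asarray(cube)
    r = np.asarray(reconstruction)
    if x.shape != r.shape:
        raise ValidationError("cube/reconstruction shape mismatch")
    diff = r.astype(np.float64) - x.astype(np.float64)
    if recon_loss == "l1":
        recon = float(np.abs(diff).mean())
    elif recon_loss == "l2":
        recon = float((diff**2).mean())
    else:
        raise ConfigError(f"unknown recon_loss: {recon_loss!r}")
    return recon + lambda_kl * kl_term(posterior)


def median_relative_error(cube, reconstruction, eps: float = 1e-6) -> float:
    """Median over all cells of |recon - x| / (|x| + eps)."""
    x = cube.data if isinstance(cube, HsiCube) else np.asarray(cube)
    r = np.asarray(reconstruction)
    return float(np.median(np.abs(r - x) / (np.abs(x) + eps)))


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------

class _Encoder(nn.Module):
    def __init__(self, c_in, width, n_down, c_lat, rng):
        # an extra full-resolution conv lets the latent encode sub-patch
        # boundary position, the main source of reconstruction blur
        layers = [nn.Conv2d(c_in, width, 3, rng=rng), nn.SiLU(),
                  nn.Conv2d(width, width, 3, rng=rng), nn.SiLU()]
        for _ in range(n_down):
            layers += [nn.Conv2d(width, width, 3, stride=2, rng=rng), nn.SiLU()]
        layers += [nn.Conv2d(width, width, 3, rng=rng), nn.SiLU(),
                   nn.Conv2d(width, 2 * c_lat, 3, rng=rng)]
        self.net = nn.Sequential(*layers)

    def forward(self, x):
        return self.net(x)


class _Decoder(nn.Module):
    def __init__(self, c_lat, width, n_up, c_out, rng):
        self.head = nn.Sequential(nn.Conv2d(c_lat, width, 3, rng=rng), nn.SiLU())
        self.ups = [nn.Sequential(nn.Conv2d(width, width, 3, rng=rng), nn.SiLU())
                    for _ in range(n_up)]
        self.tail = nn.Sequential(nn.Conv2d(width, width, 3, rng=rng), nn.SiLU(),
                                  nn.Conv2d(width, width, 3, rng=rng), nn.SiLU(),
                                  nn.Conv2d(width, c_out, 3, rng=rng))

    def forward(self, z):
        h = self.head(z)
        for block in self.ups:
            h = block(nn.upsample2x(h))
        return self.tail(h)


class KLAutoencoder(BaseEstimator):
    """Spatio-spectral KL-VAE as a scikit-learn style estimator.

    Parameters
    ----------
    spatial_factor : int
        Spatial downsampling factor f (power of 2). Latents are (H/f, W/f).
    latent_channels : int
        Spectral dimension of the latent (c_lat).
    lambda_kl : float
        Weight of the KL term. Kept deliberately small: a low weight
        benefits reconstruction quality, and reconstruction is what the
        downstream diffusion model depends on.
    recon_loss : {"l1", "l2"}
        Pixelwise reconstruction loss.
    """

    def __init__(self, spatial_factor: int = 2, latent_channels: int = 4,
                 lambda_kl: float = 1e-6, recon_loss: str = "l1",
                 width: int = 16, epochs: int = 25, batch_size: int = 8,
                 lr: float = 2e-3, ema_decay: float = 0.999,
                 val_fraction: float = 0.1, seed: int = 0):
        self.spatial_factor = spatial_factor
        self.latent_channels = latent_channels
        self.lambda_kl = lambda_kl
        self.recon_loss = recon_loss
        self.width = width
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.ema_decay = ema_decay
        self.val_fraction = val_fraction
        self.seed = seed

    # -- helpers ----------------------------------------------------------

    def _check_params(self):
        f = self.spatial_factor
        if f < 1 or (f & (f - 1)):
            raise ConfigError("spatial_factor must be a power of 2")
        if self.latent_channels < 1:
            raise ConfigError("latent_channels must be >= 1")
        if self.lambda_kl < 0:
            raise ConfigError("lambda_kl must be >= 0")
        if self.recon_loss not in ("l1", "l2"):
            raise ConfigError(f"unknown recon_loss: {self.recon_loss!r}")

    @staticmethod
    def _stack(X) -> np.ndarray:
        """Accept a list of HsiCube/arrays or an (N, H, W, C) array."""
        if isinstance(X, np.ndarray) and X.ndim == 4:
            return X.astype(np.float32)
        arrs = [x.data if isinstance(x, HsiCube) else np.asarray(x, np.float32)
                for x in X]
        return np.stack(arrs).astype(np.float32)

    def _check_dims(self, h, w):
        f = self.spatial_factor
        if h % f or w % f:
            raise ConfigError(f"spatial dims ({h}, {w}) not divisible by f={f}")

    # -- estimator API ----------------------------------------------------

    def fit(self, X, y=None):
        """Train on a set of cubes; X is a list of HsiCube or (N,H,W,C) array."""
        self._check_params()
        data = self._stack(X)
        if len(data) == 0:
            raise ValidationError("empty training set")
        n, h, w, c = data.shape
        self._check_dims(h, w)
        n_down = int(np.log2(self.spatial_factor))
        rng = np.random.default_rng(self.seed)
        self.n_bands_ = c
        self.encoder_ = _Encoder(c, self.width, n_down, self.latent_channels, rng)
        self.decoder_ = _Decoder(self.latent_channels, self.width, n_down, c, rng)

        n_val = max(1, int(round(self.val_fraction * n))) if n > 2 else 0
        perm = rng.permutation(n)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        if len(train_idx) == 0:
            train_idx, val_idx = perm, perm[:0]
        x_all = data.transpose(0, 3, 1, 2)  # NCHW

        params = self.encoder_.parameters() + self.decoder_.parameters()
        opt = nn.Adam(params, lr=self.lr)
        ema = [p.data.copy() for p in params] if self.ema_decay else None
        self.loss_history_ = []
        self.val_loss_history_ = []
        for epoch in range(self.epochs):
            # cosine decay to 5% of the base rate over the run
            opt.lr = self.lr * (0.05 + 0.95 * 0.5 *
                                (1 + np.cos(np.pi * epoch / max(1, self.epochs - 1))))
            order = rng.permutation(train_idx)
            epoch_losses = []
            for start in range(0, len(order), self.batch_size):
                batch = x_all[order[start : start + self.batch_size]]
                loss = self._loss_tensor(batch, rng)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"training diverged (non-finite loss) at epoch {epoch}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                if ema is not None:
                    # warm up the horizon so early weights do not dominate
                    d = min(self.ema_decay, (1 + opt.t) / (10 + opt.t))
                    for shadow, p in zip(ema, params):
                        shadow *= d
                        shadow += (1.0 - d) * p.data
                epoch_losses.append(float(loss.data))
            self.loss_history_.append(float(np.mean(epoch_losses)))
            if len(val_idx):
                self.val_loss_history_.append(self._eval_loss(x_all[val_idx]))
        if ema is not None:  # evaluate and serve the averaged weights
            for shadow, p in zip(ema, params):
                p.data = shadow.astype(np.float32)
        # global latent standardization for the diffusion stage
        stds = []
        sample_rng = np.random.default_rng(self.seed + 1)
        for i in range(0, n, self.batch_size):
            post = self._encode_batch(x_all[i : i + self.batch_size])
            eps = sample_rng.standard_normal(post.mean.shape).astype(np.float32)
            z = post.mean + np.exp(0.5 * post.logvar) * eps
            stds.append(z)
        self.scale_factor_ = float(1.0 / (np.concatenate([s.ravel() for s in stds]).std() + 1e-12))
        return self

    def _encode_batch(self, x_nchw: np.ndarray) -> LatentPosterior:
        out = self.encoder_(nn.Tensor(x_nchw)).data
        c = self.latent_channels
        return LatentPosterior(mean=out[:, :c], logvar=out[:, c:])

    def _loss_tensor(self, batch: np.ndarray, rng: np.random.Generator):
        c = self.latent_channels
        out = self.encoder_(nn.Tensor(batch))
        mean = out[:, :c]
        logvar = out[:, c:].clip(LOGVAR_MIN, LOGVAR_MAX)
        eps = rng.standard_normal(mean.shape).astype(np.float32)
        z = mean + (logvar * 0.5).exp() * eps
        recon = self.decoder_(z)
        diff = recon - nn.Tensor(batch)
        if self.recon_loss == "l1":
            recon_term = diff.abs().mean()
        else:
            recon_term = (diff * diff).mean()
        kl = ((mean * mean + logvar.exp() - 1.0 - logvar) * 0.5).mean()
        return recon_term + self.lambda_kl * kl

    def _eval_loss(self, x_nchw: np.ndarray) -> float:
        post = self._encode_batch(x_nchw)
        recon = self.decoder_(nn.Tensor(post.mean)).data
        x = x_nchw
        if self.recon_loss == "l1":
            r = float(np.abs(recon - x).mean())
        else:
            r = float(((recon - x) ** 2).mean())
        return r + self.lambda_kl * kl_term(post)

    # -- inference --------------------------------------------------------

    def encode(self, cube) -> LatentPosterior:
        """Posterior for one cube (H, W, C) -> (H/f, W/f, c_lat) fields."""
        check_is_fitted(self, "encoder_")
        x = cube.data if isinstance(cube, HsiCube) else np.asarray(cube, np.float32)
        if x.ndim != 3:
            raise ValidationError("encode expects one H x W x C cube")
        if x.shape[2] != self.n_bands_:
            raise ValidationError(
                f"cube has {x.shape[2]} bands, model expects {self.n_bands_}"
            )
        self._check_dims(x.shape[0], x.shape[1])
        post = self._encode_batch(x.transpose(2, 0, 1)[None])
        return LatentPosterior(mean=post.mean[0].transpose(1, 2, 0),
                               logvar=post.logvar[0].transpose(1, 2, 0))

    def decode(self, latent) -> np.ndarray:
        """Decode a Latent (or h x w x c array) back to an (H, W, C) array."""
        check_is_fitted(self, "decoder_")
        z = latent.values if isinstance(latent, Latent) else np.asarray(latent, np.float32)
        if z.ndim != 3 or z.shape[2] != self.latent_channels:
            raise ValidationError(
                f"latent must be h x w x {self.latent_channels}, got {z.shape}"
            )
        out = self.decoder_(nn.Tensor(z.transpose(2, 0, 1)[None])).data[0]
        return out.transpose(1, 2, 0)

    def transform(self, X) -> np.ndarray:
        """Posterior means for a batch, (N, H/f, W/f, c_lat)."""
        check_is_fitted(self, "encoder_")
        data = self._stack(X)
        post = self._encode_batch(data.transpose(0, 3, 1, 2))
        return post.mean.transpose(0, 2, 3, 1)

    def reconstruct(self, cube) -> np.ndarray:
        """Deterministic round trip decode(encode(cube).mean)."""
        return self.decode(self.encode(cube).mean.astype(np.float32))

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        check_is_fitted(self, "encoder_")
        path = Path(path)
        state = {f"enc.{k}": v for k, v in self.encoder_.state_dict().items()}
        state |= {f"dec.{k}": v for k, v in self.decoder_.state_dict().items()}
        meta = json.dumps({
            "params": self.get_params(),
            "scale_factor": self.scale_factor_,
            "n_bands": self.n_bands_,
            "loss_history": self.loss_history_,
            "val_loss_history": self.val_loss_history_,
            "numpy_version": np.__version__,
        })
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)

    @classmethod
    def load(cls, path) -> "KLAutoencoder":
        with np.load(Path(path)) as f:
            meta = json.loads(bytes(f["__meta__"]).decode())
            state = {k: f[k] for k in f.files if k != "__meta__"}
        model = cls(**meta["params"])
        n_down = int(np.log2(model.spatial_factor))
        rng = np.random.default_rng(model.seed)
        model.n_bands_ = meta["n_bands"]
        model.encoder_ = _Encoder(model.n_bands_, model.width, n_down,
                                  model.latent_channels, rng)
        model.decoder_ = _Decoder(model.latent_channels, model.width, n_down,
                                  model.n_bands_, rng)
        model.encoder_.load_state_dict(
            {k[4:]: v for k, v in state.items() if k.startswith("enc.")})
        model.decoder_.load_state_dict(
            {k[4:]: v for k, v in state.items() if k.startswith("dec.")})
        model.scale_factor_ = meta["scale_factor"]
        model.loss_history_ = meta["loss_history"]
        model.val_loss_history_ = meta["val_loss_history"]
        return model


def train_ae(dataset, config: dict | None = None) -> KLAutoencoder:
    """Functional wrapper: fit a KLAutoencoder on (cube, mask, ...) tuples."""
    cubes = [item[0] if isinstance(item, tuple) else item for item in dataset]
    return KLAutoencoder(**(config or {})).fit(cubes)
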