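"""Convolutional variational autoencoder and its denoising variant.

The model compresses a 64x64 grayscale patch to a 5-dimensional latent
Gaussian and decodes it back through transposed convolutions:

encoder:  (64,64,1) -> Conv(32,k3,s2,relu,same) -> Conv(64,k3,s2,relu,same)
          -> flatten (16,384) -> Dense(10,relu) -> [Dense(d) mu, Dense(d)
          log sigma^2] -> z = mu + exp(log sigma^2 / 2) * eps
decoder:  d -> Dense(16,384) -> reshape (16,16,64) -> ConvT(64,k3,s2,relu)
          -> ConvT(32,k3,s2,relu) -> ConvT(1,k3,s1,sigmoid) -> (64,64,1)

Training minimises reconstruction loss plus the KL divergence of the
approximate posterior N(mu, sigma^2) from the standard normal prior.  The
reconstruction term is pixelwise binary cross-entropy summed over the image
and averaged over the batch (a per-pixel mean is available via
``loss_scale="mean"``).  The denoising variant feeds the encoder Gaussian-
corrupted inputs (``noise_factor`` times standard normal, clipped to [0,1])
while the loss always compares the reconstruction with the *clean* image,
so with ``noise_factor=0`` it degenerates exactly to the plain VAE.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field

import numpy as np

from . import _nn

logger = logging.getLogger(__name__)

_EPS = 1e-7
FLAT_WIDTH = 16 * 16 * 64  # flattened feature width shared by encoder/decoder

__all__ = [
    "VaeConfig",
    "VaeModel",
    "reparameterize",
    "kl_divergence",
    "reconstruction_loss",
    "add_noise",
    "build_vae",
    "train_vae",
    "reconstruct",
    "save_vae",
    "load_vae",
]


@dataclass
class VaeConfig:
    """Hyperparameters of the (denoising) VAE.

    ``noise_factor`` 0 gives the plain convolutional VAE; 0.2 the denoising
    variant.  The learning rate is decayed by ``lr_decay_factor`` whenever
    the validation loss fails to improve for ``lr_patience`` epochs
    (reduce-on-plateau).
    """

    latent_dim: int = 5
    noise_factor: float = 0.0
    learning_rate: float = 1e-3
    lr_decay_factor: float = 0.5
    lr_patience: int = 2
    epochs: int = 30
    batch_size: int = 64
    seed: int = 0
    loss_scale: str = "sum"  # "sum": per-image pixel sum; "mean": per-pixel mean

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.noise_factor < 0:
            raise ValueError("noise_factor must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.loss_scale not in ("sum", "mean"):
            raise ValueError("loss_scale must be 'sum' or 'mean'")


@dataclass
class VaeModel:
    encoder_body: _nn.Sequential
    dense_mean: _nn.Dense
    dense_log_var: _nn.Dense
    decoder: _nn.Sequential
    config: VaeConfig
    trained: bool = False
    history: dict = field(default_factory=dict)

    @property
    def params(self):
        return (
            self.encoder_body.params
            + self.dense_mean.params
            + self.dense_log_var.params
            + self.decoder.params
        )

    @property
    def grads(self):
        return (
            self.encoder_body.grads
            + self.dense_mean.grads
            + self.dense_log_var.grads
            + self.decoder.grads
        )

    def encode(self, x, training=False):
        """Returns (z_mean, z_log_var) for a batch."""
        h = self.encoder_body.forward(x, training=training)
        return self.dense_mean.forward(h, training=training), self.dense_log_var.forward(
            h, training=training
        )


def reparameterize(z_mean, z_log_var, noise_draw):
    """z = mu + exp(log sigma^2 / 2) * eps, elementwise."""
    z_mean = np.asarray(z_mean)
    z_log_var = np.asarray(z_log_var)
    noise_draw = np.asarray(noise_draw)
    if not (z_mean.shape == z_log_var.shape == noise_draw.shape):
        raise ValueError(
            f"shape mismatch: mu {z_mean.shape}, log-var {z_log_var.shape}, "
            f"eps {noise_draw.shape}"
        )
    return z_mean + np.exp(0.5 * z_log_var) * noise_draw


def kl_divergence(z_mean, z_log_var):
    """KL( N(mu, sigma^2) || N(0, I) ) = -1/2 sum(1 + log s^2 - mu^2 - s^2).

    For a 1-D vector returns the scalar KL; for a 2-D (batch, dim) array
    returns per-sample KLs.  Always >= 0, and 0 exactly at mu=0, log s^2=0.
    """
    z_mean = np.asarray(z_mean, dtype=np.float64)
    z_log_var = np.asarray(z_log_var, dtype=np.float64)
    if z_mean.shape != z_log_var.shape:
        raise ValueError("z_mean and z_log_var must have equal shapes")
    if not (np.isfinite(z_mean).all() and np.isfinite(z_log_var).all()):
        raise ValueError("non-finite values in KL inputs")
    per = -0.5 * np.sum(1.0 + z_log_var - z_mean**2 - np.exp(z_log_var), axis=-1)
    return float(per) if per.ndim == 0 else per


def reconstruction_loss(x, x_hat, scale="sum"):
    """Pixelwise binary cross-entropy, summed per image, averaged over batch.

    ``scale="mean"`` averages over pixels as well, giving a per-pixel loss.
    """
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    p = np.clip(x_hat, _EPS, 1.0 - _EPS)
    bce = -(x * np.log(p) + (1.0 - x) * np.log1p(-p))
    per_image = bce.reshape(len(x), -1).sum(axis=1)
    if scale == "mean":
        per_image = per_image / bce.reshape(len(x), -1).shape[1]
    return float(per_image.mean())


def add_noise(batch, noise_factor, seed=0, rng=None):
    """x + noise_factor * eps with eps iid standard normal, clipped to [0, 1]."""
    if noise_factor < 0:
        raise ValueError("noise_factor must be >= 0")
    batch = np.asarray(batch)
    rng = rng if rng is not None else np.random.default_rng(seed)
    noisy = batch + noise_factor * rng.standard_normal(batch.shape)
    return np.clip(noisy, 0.0, 1.0).astype(np.float32)


def build_vae(config: VaeConfig = None) -> VaeModel:
    """Assemble the encoder/decoder with seeded Glorot-initialised weights."""
    config = config or VaeConfig()
    rng = np.random.default_rng(np.random.SeedSequence((int(config.seed), 0)))
    d = config.latent_dim
    encoder_body = _nn.Sequential(
        [
            _nn.InputLayer((64, 64, 1)),
            _nn.Conv2D(1, 32, kernel=3, stride=2, activation="relu", rng=rng),
            _nn.Conv2D(32, 64, kernel=3, stride=2, activation="relu", rng=rng),
            _nn.Flatten(),
            _nn.Dense(FLAT_WIDTH, 10, activation="relu", rng=rng),
        ]
    )
    dense_mean = _nn.Dense(10, d, activation=None, rng=rng)
    dense_log_var = _nn.Dense(10, d, activation=None, rng=rng)
    decoder = _nn.Sequential(
        [
            _nn.InputLayer((d,)),
            _nn.Dense(d, FLAT_WIDTH, activation=None, rng=rng),
            _nn.Reshape((16, 16, 64)),
            _nn.ConvTranspose2D(64, 64, kernel=3, stride=2, activation="relu", rng=rng),
            _nn.ConvTranspose2D(64, 32, kernel=3, stride=2, activation="relu", rng=rng),
            _nn.ConvTranspose2D(32, 1, kernel=3, stride=1, activation="sigmoid", rng=rng),
        ]
    )
    return VaeModel(encoder_body, dense_mean, dense_log_var, decoder, config)


def _vae_batch_loss(model, x_in, x_clean, eps, scale):
    """Forward pass + losses; caches everything needed for backward."""
    h = model.encoder_body.forward(x_in, training=True)
    mu = model.dense_mean.forward(h, training=True)
    lv = model.dense_log_var.forward(h, training=True)
    z = reparameterize(mu, lv, eps)
    x_hat = model.decoder.forward(z.astype(np.float32), training=True)
    rec = reconstruction_loss(x_clean, x_hat, scale=scale)
    kl = float(np.mean(kl_divergence(mu, lv)))
    return x_hat, mu, lv, rec, kl


def _vae_batch_backward(model, x_hat, x_clean, mu, lv, eps, scale):
    n = len(x_clean)
    p = np.clip(x_hat, _EPS, 1.0 - _EPS)
    # d(BCE)/d(p); the decoder's sigmoid backward turns this into (p - x)/n
    dp = ((p - x_clean) / (p * (1.0 - p)) / n).astype(np.float32)
    if scale == "mean":
        dp /= np.prod(x_clean.shape[1:])
    dz = model.decoder.backward(dp)
    sigma = np.exp(0.5 * lv)
    dmu = (dz + mu / n).astype(np.float32)
    dlv = (dz * eps * 0.5 * sigma + 0.5 * (np.exp(lv) - 1.0) / n).astype(np.float32)
    dh = model.dense_mean.backward(dmu) + model.dense_log_var.backward(dlv)
    model.encoder_body.backward(dh)


def _evaluate_vae(model, images, config, rng_val):
    """Validation losses with sampled latents drawn from ``rng_val``."""
    rec_t = kl_t = 0.0
    bs = config.batch_size
    for start in range(0, len(images), bs):
        xb = images[start : start + bs]
        mu, lv = model.encode(xb, training=False)
        eps = rng_val.standard_normal(mu.shape)
        x_hat = model.decoder.forward(reparameterize(mu, lv, eps).astype(np.float32))
        rec_t += reconstruction_loss(xb, x_hat, scale=config.loss_scale) * len(xb)
        kl_t += float(np.sum(kl_divergence(mu, lv)))
    n = len(images)
    return rec_t / n, kl_t / n


def train_vae(model: VaeModel, data, config: VaeConfig = None):
    """Train with Adam and reduce-on-plateau; returns (model, history).

    ``data`` is a :class:`~histovae.preprocess.DatasetBundle`; only its
    train and validation images are used (the VAE is unsupervised).  For
    ``noise_factor > 0`` the encoder sees freshly corrupted inputs each
    batch while the loss targets the clean images.  Corruption, latent
    sampling and shuffling use independent child RNG streams of the config
    seed, so the noise-free denoising path is trajectory-identical to the
    plain VAE.
    """
    config = config or model.config
    x_train = np.ascontiguousarray(data.train_images, dtype=np.float32)
    x_val = np.ascontiguousarray(data.val_images, dtype=np.float32)
    if len(x_train) == 0:
        raise ValueError("empty training set")

    ss = np.random.SeedSequence((int(config.seed), 1))
    rng_shuffle, rng_latent, rng_noise, rng_val = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    optimizer = _nn.Adam(model.params, config.learning_rate)
    history = {
        "loss": [], "reconstruction_loss": [], "kl_loss": [],
        "val_loss": [], "val_reconstruction_loss": [], "val_kl_loss": [],
        "learning_rate": [],
    }
    best_val = np.inf
    wait = 0
    bs = config.batch_size
    for epoch in range(config.epochs):
        order = rng_shuffle.permutation(len(x_train))
        rec_sum = kl_sum = 0.0
        for start in range(0, len(order), bs):
            idx = order[start : start + bs]
            x_clean = x_train[idx]
            x_in = (
                add_noise(x_clean, config.noise_factor, rng=rng_noise)
                if config.noise_factor > 0
                else x_clean
            )
            eps = rng_latent.standard_normal((len(idx), config.latent_dim))
            x_hat, mu, lv, rec, kl = _vae_batch_loss(
                model, x_in, x_clean, eps, config.loss_scale
            )
            _vae_batch_backward(model, x_hat, x_clean, mu, lv, eps, config.loss_scale)
            optimizer.step(model.grads)
            rec_sum += rec * len(idx)
            kl_sum += kl * len(idx)
        rec_ep = rec_sum / len(order)
        kl_ep = kl_sum / len(order)
        if len(x_val):
            val_rec, val_kl = _evaluate_vae(model, x_val, config, rng_val)
        else:
            val_rec, val_kl = rec_ep, kl_ep
        history["loss"].append(rec_ep + kl_ep)
        history["reconstruction_loss"].append(rec_ep)
        history["kl_loss"].append(kl_ep)
        history["val_loss"].append(val_rec + val_kl)
        history["val_reconstruction_loss"].append(val_rec)
        history["val_kl_loss"].append(val_kl)
        history["learning_rate"].append(optimizer.learning_rate)
        logger.info(
            "vae epoch %d/%d loss=%.2f (rec=%.2f kl=%.2f) val=%.2f lr=%.2g",
            epoch + 1, config.epochs, rec_ep + kl_ep, rec_ep, kl_ep,
            val_rec + val_kl, optimizer.learning_rate,
        )
        # reduce-on-plateau on the validation loss
        if history["val_loss"][-1] < best_val - 1e-9:
            best_val = history["val_loss"][-1]
            wait = 0
        else:
            wait += 1
            if wait >= config.lr_patience:
                optimizer.learning_rate *= config.lr_decay_factor
                wait = 0
    model.trained = True
    model.history = history
    return model, history


def reconstruct(model: VaeModel, batch, seed: int = 0, use_mean: bool = False):
    """Encode -> sample -> decode a batch; output in (0, 1), same shape.

    ``use_mean`` decodes the posterior mean mu instead of a sampled latent,
    giving a fully deterministic reconstruction independent of ``seed``.
    """
    if not model.trained:
        raise ValueError("model has not been trained; call train_vae first")
    batch = np.ascontiguousarray(batch, dtype=np.float32)
    rng = np.random.default_rng(seed)
    out = np.empty_like(batch)
    bs = model.config.batch_size
    for start in range(0, len(batch), bs):
        xb = batch[start : start + bs]
        mu, lv = model.encode(xb, training=False)
        z = mu if use_mean else reparameterize(mu, lv, rng.standard_normal(mu.shape))
        out[start : start + bs] = model.decoder.forward(z.astype(np.float32))
    return out


def save_vae(model: VaeModel, path) -> None:
    """Single-file checkpoint: weights plus config and training flag."""
    arrays = {f"param_{i}": p for i, p in enumerate(model.params)}
    np.savez_compressed(
        path,
        config_json=json.dumps(asdict(model.config)),
        trained=int(model.trained),
        **arrays,
    )


def load_vae(path) -> VaeModel:
    with np.load(path, allow_pickle=False) as data:
        config = VaeConfig(**json.loads(str(data["config_json"])))
        model = build_vae(config)
        for i, p in enumerate(model.params):
            p[...] = data[f"param_{i}"]
        model.trained = bool(int(data["trained"]))
    return model
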