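"""Variational-autoencoder anomaly detection for lung slices.

A small convolutional VAE is trained to reconstruct *healthy* lung slices.
Fibrotic or otherwise abnormal tissue is absent from training, so the model
reconstructs it poorly; the per-voxel absolute reconstruction error, stacked
over slices and lightly smoothed, is the anomaly heatmap handed to the
volumetric classifier as a second input channel.

Training objective: mean squared reconstruction error plus
``kl_weight * KL(q(z|x) || N(0, I))``.  The heatmap path uses the posterior
mean (no sampling), so heatmaps are deterministic given a trained model.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from .nn import Adam, ConvNd, Dense, GlobalAvgPool, ReLU, Upsample2x, sigmoid
from .volumes import Volume

__all__ = ["VAEConfig", "ConvVAE", "train_vae", "compute_heatmap", "save_vae", "load_vae"]


@dataclass(frozen=True)
class VAEConfig:
    """Architecture and optimisation settings for the slice VAE."""

    slice_shape: tuple[int, int] = (48, 48)
    latent_dim: int = 16
    enc_channels: tuple[int, int] = (8, 16)
    kl_weight: float = 1e-3
    epochs: int = 40
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.kl_weight < 0:
            raise ValueError("kl_weight must be nonnegative")
        if any(s % 4 != 0 for s in self.slice_shape):
            raise ValueError("slice_shape must be divisible by 4 (two stride-2 stages)")


class ConvVAE:
    """Two stride-2 conv layers down, two upsample+conv layers back up."""

    def __init__(self, config: VAEConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c1, c2 = config.enc_channels
        h, w = config.slice_shape
        self._bottleneck = (c2, h // 4, w // 4)
        flat = c2 * (h // 4) * (w // 4)

        self.enc1 = ConvNd(1, c1, (3, 3), stride=2, rng=rng)
        self.enc_relu1 = ReLU()
        self.enc2 = ConvNd(c1, c2, (3, 3), stride=2, rng=rng)
        self.enc_relu2 = ReLU()
        self.enc_fc = Dense(flat, 2 * config.latent_dim, rng=rng)

        self.dec_fc = Dense(config.latent_dim, flat, rng=rng)
        self.dec_relu0 = ReLU()
        self.up1 = Upsample2x()
        self.dec1 = ConvNd(c2, c1, (3, 3), stride=1, rng=rng)
        self.dec_relu1 = ReLU()
        self.up2 = Upsample2x()
        self.dec2 = ConvNd(c1, 1, (3, 3), stride=1, rng=rng)

        self._layers = [self.enc1, self.enc2, self.enc_fc, self.dec_fc, self.dec1, self.dec2]
        self.history: list[float] = []

    def parameters(self):
        return [p for layer in self._layers for p in layer.parameters()]

    # -- forward pieces ----------------------------------------------------
    def encode(self, x: np.ndarray):
        h = self.enc_relu1.forward(self.enc1.forward(x))
        h = self.enc_relu2.forward(self.enc2.forward(h))
        self._enc_spatial = h.shape
        stats = self.enc_fc.forward(h.reshape(h.shape[0], -1))
        ld = self.config.latent_dim
        return stats[:, :ld], stats[:, ld:]

    def decode(self, z: np.ndarray):
        h = self.dec_relu0.forward(self.dec_fc.forward(z))
        h = h.reshape(h.shape[0], *self._bottleneck)
        h = self.dec_relu1.forward(self.dec1.forward(self.up1.forward(h)))
        logits = self.dec2.forward(self.up2.forward(h))
        self._recon = sigmoid(logits)
        return self._recon

    def reconstruct(self, slices: np.ndarray) -> np.ndarray:
        """Deterministic reconstruction through the posterior mean."""
        x = np.asarray(slices, dtype=np.float64)[:, None]
        mu, _ = self.encode(x)
        return self.decode(mu)[:, 0]

    # -- one training step ---------------------------------------------------
    def _step(self, x: np.ndarray, rng: np.random.Generator) -> float:
        b = x.shape[0]
        mu, logvar = self.encode(x)
        eps = rng.standard_normal(mu.shape)
        std = np.exp(0.5 * logvar)
        z = mu + eps * std
        recon = self.decode(z)

        npix = math.prod(x.shape[1:])
        mse = float(np.mean((recon - x) ** 2))
        kl = float(-0.5 * np.sum(1 + logvar - mu**2 - np.exp(logvar)) / b)
        kw = self.config.kl_weight
        self.last_mse, self.last_kl = mse, kl  # exposed so the loss decomposition is inspectable

        # backward: reconstruction branch
        g = 2.0 * (recon - x) / (b * npix)
        g = g * recon * (1.0 - recon)  # through the output sigmoid
        g = self.dec2.backward(g)
        g = self.up2.backward(g)
        g = self.dec1.backward(self.dec_relu1.backward(g))
        g = self.up1.backward(g)
        g = self.dec_fc.backward(self.dec_relu0.backward(g.reshape(b, -1)))
        dz = g

        dmu = dz + kw * mu / b
        dlogvar = dz * eps * 0.5 * std + kw * 0.5 * (np.exp(logvar) - 1.0) / b
        gstats = np.concatenate([dmu, dlogvar], axis=1)
        g = self.enc_fc.backward(gstats).reshape(self._enc_spatial)
        g = self.enc2.backward(self.enc_relu2.backward(g))
        self.enc1.backward(self.enc_relu1.backward(g), need_input_grad=False)

        return mse + kw * kl

    # -- weights ------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.value.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.value[...] = state[f"p{i}"]


def train_vae(healthy_slices: np.ndarray, config: VAEConfig = VAEConfig()) -> ConvVAE:
    """Fit the VAE on a stack of healthy lung slices ``(n, H, W)`` in [0, 1].

    Deterministic under the config seed (initialisation, shuffling, and the
    reparameterisation draws all flow from it).  The per-epoch mean loss is
    recorded in ``model.history``.
    """
    x = np.asarray(healthy_slices, dtype=np.float64)
    if x.ndim != 3 or x.shape[0] == 0:
        raise ValueError("healthy_slices must be a nonempty (n, H, W) stack")
    if x.shape[1:] != tuple(config.slice_shape):
        raise ValueError(f"slices {x.shape[1:]} do not match config.slice_shape {config.slice_shape}")

    model = ConvVAE(config)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(1,)))
    opt = Adam(model.parameters(), lr=config.learning_rate)
    n = x.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            batch = x[order[start : start + config.batch_size], None]
            opt.zero_grad()
            losses.append(model._step(batch, rng))
            opt.step()
        model.history.append(float(np.mean(losses)))
    return model


def compute_heatmap(volume: Volume, reconstructor, smooth_sigma: float = 1.0) -> np.ndarray:
    """Anomaly heatmap from per-slice reconstruction error.

    ``reconstructor`` is a trained :class:`ConvVAE` or any callable mapping a
    slice stack ``(n, H, W)`` to reconstructions of the same shape.  The
    axial slices of the (preprocessed) volume are reconstructed, the absolute
    error is stacked back into a volume, optionally Gaussian-smoothed, and
    max-normalised to [0, 1] (an all-zero map stays zero).
    """
    values = np.asarray(volume.values, dtype=np.float64)
    slices = np.moveaxis(values, 2, 0)  # (axial, sag, cor)
    recon_fn = reconstructor.reconstruct if isinstance(reconstructor, ConvVAE) else reconstructor
    recon = np.asarray(recon_fn(slices))
    if recon.shape != slices.shape:
        raise ValueError(f"reconstructor returned shape {recon.shape}, expected {slices.shape}")
    err = np.abs(slices - recon)
    heat = np.moveaxis(err, 0, 2)
    if smooth_sigma > 0:
        heat = ndimage.gaussian_filter(heat, smooth_sigma)
    peak = heat.max()
    if peak > 0:
        heat = heat / peak
    return heat


def save_vae(model: ConvVAE, path) -> None:
    """Single-archive checkpoint: weights plus the JSON-encoded config."""
    np.savez(path, __config__=json.dumps(asdict(model.config)), **model.state_dict())


def load_vae(path) -> ConvVAE:
    with np.load(path, allow_pickle=False) as data:
        cfg = json.loads(str(data["__config__"]))
        cfg["slice_shape"] = tuple(cfg["slice_shape"])
        cfg["enc_channels"] = tuple(cfg["enc_channels"])
        model = ConvVAE(VAEConfig(**cfg))
        model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model
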