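"""Variational-autoencoder tile features.

A convolutional VAE learns a compact latent representation (default 16
dimensions) of H&E tiles: an encoder maps a tile to a diagonal-Gaussian
posterior q(z|x) = N(mu, diag(sigma^2)); a mirrored decoder reconstructs the
tile from z. Training minimizes the negative Gaussian log-likelihood of the
reconstruction (fixed unit variance, i.e. a squared-error term plus its
normalizing constant) plus the closed-form KL divergence of the posterior
from the standard-normal prior. Downstream, every tile is represented by its
posterior mean, giving the tiles x features table consumed by the
representative-sample selection stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import InvalidSpecError
from . import nn

_LN2PI = float(np.log(2.0 * np.pi))


@dataclass
class FeatureTable:
    """Tiles x latent-features table with sample membership per row."""

    features: np.ndarray
    sample_ids: np.ndarray
    tile_ids: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.features, dtype=float)
        if f.ndim != 2:
            raise InvalidSpecError("features must be 2-D (tiles x features)")
        if len(self.sample_ids) != f.shape[0] or len(self.tile_ids) != f.shape[0]:
            raise InvalidSpecError("sample_ids/tile_ids length mismatch")
        if not np.all(np.isfinite(f)):
            raise InvalidSpecError("features contain non-finite values")
        self.features = f
        self.sample_ids = np.asarray(self.sample_ids)
        self.tile_ids = np.asarray(self.tile_ids)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"L{i + 1}": self.features[:, i] for i in range(self.n_features)}
        return pd.DataFrame({"tile_id": self.tile_ids, "sample_id": self.sample_ids, **cols})

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path)
        lcols = [c for c in df.columns if c.startswith("L") and c[1:].isdigit()]
        lcols.sort(key=lambda c: int(c[1:]))
        return cls(features=df[lcols].to_numpy(float),
                   sample_ids=df["sample_id"].astype(str).to_numpy(),
                   tile_ids=df["tile_id"].astype(str).to_numpy())


@dataclass
class VaeConfig:
    latent_dim: int = 16
    filters: int = 8          # first-layer filter count
    epochs: int = 40
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0


def vae_loss(x: np.ndarray, reconstruction: np.ndarray, mu: np.ndarray,
             logvar: np.ndarray):
    """(total, recon_term, kl_term), averaged over the batch.

    recon_term is the negative Gaussian log-likelihood with fixed unit
    variance: 0.5 * ||x - x_hat||^2 + (D/2) * ln(2*pi). kl_term is the
    closed-form KL(q || N(0, I)) = 0.5 * sum(mu^2 + sigma^2 - 1 - ln sigma^2),
    which is always >= 0 and 0 iff the posterior equals the prior.
    """
    for a in (x, reconstruction, mu, logvar):
        if not np.all(np.isfinite(a)):
            raise InvalidSpecError("non-finite inputs to vae_loss")
    x = np.asarray(x, dtype=float)
    xr = np.asarray(reconstruction, dtype=float)
    if x.shape != xr.shape:
        raise InvalidSpecError("reconstruction shape mismatch")
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    logvar = np.atleast_2d(np.asarray(logvar, dtype=float))
    n = mu.shape[0]
    d = int(np.prod(x.shape)) // n
    recon = 0.5 * float(np.sum((x - xr) ** 2)) / n + 0.5 * d * _LN2PI
    kl = 0.5 * float(np.sum(mu**2 + np.exp(logvar) - 1.0 - logvar)) / n
    return recon + kl, recon, kl


class VaeModel:
    """Conv encoder (3 stride-2 blocks + dense head) and mirrored decoder."""

    def __init__(self, tile_size: int, config: VaeConfig):
        if tile_size % 8 != 0 or tile_size < 8:
            raise InvalidSpecError("tile size must be a positive multiple of 8")
        if config.latent_dim < 1:
            raise InvalidSpecError("latent_dim must be >= 1")
        self.config = config
        self.tile_size = tile_size
        f, z = config.filters, config.latent_dim
        rng = np.random.default_rng(config.seed)
        s = tile_size // 8
        self._bottleneck = (4 * f, s, s)
        d_flat = 4 * f * s * s
        self.enc = [
            nn.Conv2d(3, f, stride=2, rng=rng), nn.LeakyReLU(),
            nn.Conv2d(f, 2 * f, stride=2, rng=rng), nn.LeakyReLU(),
            nn.Conv2d(2 * f, 4 * f, stride=2, rng=rng), nn.LeakyReLU(),
        ]
        self.enc_head = nn.Dense(d_flat, 2 * z, rng=rng)
        self.dec_head = nn.Dense(z, d_flat, rng=rng)
        self.dec = [
            nn.LeakyReLU(),
            nn.Upsample2x(), nn.Conv2d(4 * f, 2 * f, rng=rng), nn.LeakyReLU(),
            nn.Upsample2x(), nn.Conv2d(2 * f, f, rng=rng), nn.LeakyReLU(),
            nn.Upsample2x(), nn.Conv2d(f, 3, rng=rng), nn.Sigmoid(),
        ]
        self.layers = self.enc + [self.enc_head, self.dec_head] + self.dec
        self.history: dict = {"loss": [], "recon": [], "kl": []}

    # --- forward pieces -------------------------------------------------
    def encode(self, x_nchw: np.ndarray):
        h = x_nchw
        for layer in self.enc:
            h = layer.forward(h)
        self._enc_shape = h.shape
        flat = h.reshape(h.shape[0], -1)
        out = self.enc_head.forward(flat)
        z = self.config.latent_dim
        return out[:, :z], out[:, z:]

    def decode(self, z: np.ndarray) -> np.ndarray:
        h = self.dec_head.forward(z)
        c, s, _ = self._bottleneck
        h = h.reshape(z.shape[0], c, s, s)
        for layer in self.dec:
            h = layer.forward(h)
        return h

    def _backward(self, d_recon, d_mu, d_logvar):
        g = d_recon
        for layer in reversed(self.dec):
            g = layer.backward(g)
        g = self.dec_head.backward(g.reshape(g.shape[0], -1))
        dz = g  # gradient wrt sampled z
        return dz

    def _backward_encoder(self, d_mu, d_logvar):
        g = self.enc_head.backward(np.concatenate([d_mu, d_logvar], axis=1))
        g = g.reshape(self._enc_shape)
        for layer in reversed(self.enc):
            g = layer.backward(g)


def _as_nchw(tiles) -> np.ndarray:
    x = np.asarray(tiles, dtype=float)
    if x.ndim == 3:
        x = x[None]
    if x.ndim != 4 or x.shape[3] != 3:
        raise InvalidSpecError("tiles must be (N, H, W, 3)")
    return np.transpose(x, (0, 3, 1, 2))


def train_vae(tiles, latent_dim: int = 16, config: Optional[VaeConfig] = None) -> VaeModel:
    """Train a VAE on H&E tiles; seeded and reproducible."""
    if config is None:
        config = VaeConfig(latent_dim=latent_dim)
    else:
        config.latent_dim = latent_dim
    x = _as_nchw(tiles)
    if x.shape[0] < 1:
        raise InvalidSpecError("empty tile list")
    if x.shape[2] != x.shape[3]:
        raise InvalidSpecError("tiles must be square")
    model = VaeModel(tile_size=x.shape[2], config=config)
    opt = nn.Adam(model.layers, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    n = x.shape[0]
    d = int(np.prod(x.shape[1:]))
    for _ in range(config.epochs):
        order = rng.permutation(n)
        ep = {"loss": 0.0, "recon": 0.0, "kl": 0.0}
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = x[idx]
            b = len(idx)
            mu, logvar = model.encode(xb)
            logvar = np.clip(logvar, -8.0, 8.0)
            eps = rng.standard_normal(mu.shape)
            sig = np.exp(0.5 * logvar)
            z = mu + sig * eps
            xr = model.decode(z)
            total, recon, kl = vae_loss(xb, xr, mu, logvar)
            # gradients (mean over batch)
            d_recon = (xr - xb) / b
            dz = model._backward(d_recon, None, None)
            d_mu = dz + mu / b
            d_logvar = dz * eps * 0.5 * sig + 0.5 * (np.exp(logvar) - 1.0) / b
            model._backward_encoder(d_mu, d_logvar)
            opt.step()
            opt.zero_grad()
            ep["loss"] += total * b
            ep["recon"] += recon * b
            ep["kl"] += kl * b
        for k in ep:
            model.history[k].append(ep[k] / n)
    return model


def reconstruction_error(model: VaeModel, tiles) -> float:
    """Mean per-pixel squared reconstruction error using the posterior mean."""
    x = _as_nchw(tiles)
    mu, _ = model.encode(x)
    xr = model.decode(mu)
    return float(np.mean((x - xr) ** 2))


def encode_tiles(model: VaeModel, tiles, sample_ids: Sequence[str],
                 tile_ids: Optional[Sequence[str]] = None) -> FeatureTable:
    """One feature row (the posterior mean) per tile; deterministic."""
    x = _as_nchw(tiles)
    if len(sample_ids) != x.shape[0]:
        raise InvalidSpecError("tiles and sample_ids length mismatch")
    if tile_ids is None:
        tile_ids = [f"t{i}" for i in range(x.shape[0])]
    feats = []
    for start in range(0, x.shape[0], 64):
        mu, _ = model.encode(x[start : start + 64])
        feats.append(mu)
    return FeatureTable(features=np.vstack(feats),
                        sample_ids=np.asarray(sample_ids),
                        tile_ids=np.asarray(tile_ids))
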