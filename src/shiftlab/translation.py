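"""H&E -> virtual IF translation.

The translator is a conditional adversarial image-to-image model in the
pix2pix mould: a U-net generator G maps an RGB H&E tile to a single-channel
IF tile in [0, 1]; a patch-based discriminator D scores (H&E, IF) pairs as
real or generated. The generator objective combines the adversarial term
with an L1 reconstruction term whose weight lambda is adapted per batch to
the IF stain prevalence: with base weight 100, a batch in which a fraction p
of pixels exceed the source-WSI mean intensity trains with lambda = 100 * p,
so sparse-stain batches are not dominated by the L1 term.

An ``l1_only`` mode removes the discriminator and adversarial term, leaving
the U-net generator trained on the (adaptively weighted) L1 loss alone —
the supervised, pixel-loss-only baseline. Ensembling averages member model
outputs pixel-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage.transform import AffineTransform, warp

from .datatypes import InvalidSpecError
from . import nn


@dataclass
class TranslatorConfig:
    """Training configuration; the defaults are the full-scale profile."""

    mode: str = "adversarial"            # or "l1_only"
    base_lambda: float = 100.0
    learning_rate: float = 0.002
    epochs: int = 500
    batch_size: int = 64
    first_layer_filters: int = 128
    tile_size: int = 256
    max_steps: Optional[int] = None      # cap on optimization steps (desk use)
    augment: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("adversarial", "l1_only"):
            raise InvalidSpecError(f"unknown mode {self.mode!r}")
        if self.base_lambda < 0:
            raise InvalidSpecError("base_lambda must be >= 0")
        if self.batch_size < 1:
            raise InvalidSpecError("batch_size must be >= 1")


def desk_config(mode: str = "l1_only", **overrides) -> TranslatorConfig:
    """Small-tile CPU preset used by the test suite and examples."""
    cfg = dict(mode=mode, learning_rate=2e-3, epochs=1000, batch_size=8,
               first_layer_filters=8, tile_size=64, max_steps=400)
    cfg.update(overrides)
    return TranslatorConfig(**cfg)


def adaptive_lambda(if_batch: np.ndarray, wsi_mean_intensity: float,
                    base_lambda: float = 100.0) -> float:
    """Stain-prevalence-adapted L1 weight: base_lambda times the fraction of
    batch pixels strictly above the source-WSI mean intensity."""
    b = np.asarray(if_batch, dtype=float)
    if b.size == 0:
        raise InvalidSpecError("empty IF batch")
    if not np.isfinite(wsi_mean_intensity):
        raise InvalidSpecError("wsi_mean_intensity must be finite")
    p = float(np.mean(b > wsi_mean_intensity))
    return base_lambda * p


def cgan_objective(d_real, d_fake, y: np.ndarray, g_x: np.ndarray, lam: float):
    """Loss components of the conditional adversarial objective.

    ``d_real``/``d_fake`` are discriminator probabilities in (0, 1).
    Returns (L_cGAN, L_L1, total_G, total_D): the printed minimax objective
    E[log D(x,y)] + E[log(1 - D(x,G(x)))], the mean absolute error, the
    generator total using the non-saturating adversarial form
    -E[log D(x,G(x))] + lambda * L1, and the discriminator binary
    cross-entropy.
    """
    dr = np.asarray(d_real, dtype=float)
    df = np.asarray(d_fake, dtype=float)
    if np.any(dr <= 0) or np.any(dr >= 1) or np.any(df <= 0) or np.any(df >= 1):
        raise InvalidSpecError("discriminator outputs must lie strictly in (0, 1)")
    y = np.asarray(y, dtype=float)
    g = np.asarray(g_x, dtype=float)
    if y.shape != g.shape:
        raise InvalidSpecError("y and G(x) shapes differ")
    l_cgan = float(np.mean(np.log(dr)) + np.mean(np.log(1.0 - df)))
    l_l1 = float(np.mean(np.abs(y - g)))
    total_g = float(-np.mean(np.log(df)) + lam * l_l1)
    total_d = float(-(np.mean(np.log(dr)) + np.mean(np.log(1.0 - df))))
    return l_cgan, l_l1, total_g, total_d


# ---------------------------------------------------------------------------
# networks


class _Block:
    """Sequential block helper with forward/backward."""

    def __init__(self, layers):
        self.layers = layers

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class Generator:
    """U-net generator: 3 stride-2 encoder levels, skip connections, linear
    output head. Bottleneck is tile_size / 8 on a side.

    The output head is linear rather than squashed: with an L1 objective and
    mostly-dark IF targets a sigmoid head saturates (the constant-magnitude
    sign gradient keeps pushing background logits toward -inf until the
    layer is dead). Inference clips into [0, 1]."""

    def __init__(self, f: int, rng: np.random.Generator):
        self.f = f
        self.e0 = _Block([nn.Conv2d(3, f, rng=rng), nn.LeakyReLU()])
        self.e1 = _Block([nn.Conv2d(f, 2 * f, stride=2, rng=rng), nn.LeakyReLU()])
        self.e2 = _Block([nn.Conv2d(2 * f, 4 * f, stride=2, rng=rng), nn.LeakyReLU()])
        self.bott = _Block([nn.Conv2d(4 * f, 8 * f, stride=2, rng=rng), nn.LeakyReLU()])
        self.u2, self.u1, self.u0 = nn.Upsample2x(), nn.Upsample2x(), nn.Upsample2x()
        self.d2 = _Block([nn.Conv2d(12 * f, 4 * f, rng=rng), nn.LeakyReLU()])
        self.d1 = _Block([nn.Conv2d(6 * f, 2 * f, rng=rng), nn.LeakyReLU()])
        self.d0 = _Block([nn.Conv2d(3 * f, f, rng=rng), nn.LeakyReLU()])
        self.out = _Block([nn.Conv2d(f, 1, rng=rng)])
        self.layers = []
        for blk in (self.e0, self.e1, self.e2, self.bott, self.d2, self.d1, self.d0, self.out):
            self.layers.extend(blk.layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._a0 = self.e0.forward(x)
        self._a1 = self.e1.forward(self._a0)
        self._a2 = self.e2.forward(self._a1)
        b = self.bott.forward(self._a2)
        h2 = self.d2.forward(np.concatenate([self.u2.forward(b), self._a2], axis=1))
        h1 = self.d1.forward(np.concatenate([self.u1.forward(h2), self._a1], axis=1))
        h0 = self.d0.forward(np.concatenate([self.u0.forward(h1), self._a0], axis=1))
        return self.out.forward(h0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        f = self.f
        g = self.d0.backward(self.out.backward(dy))
        g_h1, g_a0 = g[:, : 2 * f], g[:, 2 * f :]
        g = self.d1.backward(self.u0.backward(g_h1))
        g_h2, g_a1 = g[:, : 4 * f], g[:, 4 * f :]
        g = self.d2.backward(self.u1.backward(g_h2))
        g_b, g_a2 = g[:, : 8 * f], g[:, 8 * f :]
        g = self.bott.backward(self.u2.backward(g_b)) + g_a2
        g = self.e2.backward(g) + g_a1
        g = self.e1.backward(g) + g_a0
        return self.e0.backward(g)


class PatchDiscriminator:
    """Conditional patch classifier on concatenated (H&E, IF): three stride-2
    conv blocks then a 1-channel logit map (one logit per receptive patch)."""

    def __init__(self, f: int, rng: np.random.Generator):
        self.net = _Block([
            nn.Conv2d(4, f, stride=2, rng=rng), nn.LeakyReLU(),
            nn.Conv2d(f, 2 * f, stride=2, rng=rng), nn.LeakyReLU(),
            nn.Conv2d(2 * f, 4 * f, stride=2, rng=rng), nn.LeakyReLU(),
            nn.Conv2d(4 * f, 1, rng=rng),
        ])
        self.layers = self.net.layers

    def forward(self, he: np.ndarray, if_chan: np.ndarray) -> np.ndarray:
        return self.net.forward(np.concatenate([he, if_chan], axis=1))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        g = self.net.backward(dlogits)
        return g[:, 3:]  # gradient wrt the IF member only


@dataclass
class Translator:
    """Trained generator (+ optional discriminator) with its config/history."""

    generator: Generator
    config: TranslatorConfig
    discriminator: Optional[PatchDiscriminator] = None
    history: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.config.mode == "l1_only" and self.discriminator is not None:
            raise InvalidSpecError("l1_only mode must not allocate a discriminator")


# ---------------------------------------------------------------------------
# augmentation


def _geom_transform(rng: np.random.Generator, size: int) -> AffineTransform:
    ang = np.deg2rad(rng.uniform(-10, 10))
    scale = rng.uniform(0.95, 1.05)
    tx, ty = rng.uniform(-3, 3, size=2)
    c = size / 2.0
    center = AffineTransform(translation=(-c, -c))
    tf = AffineTransform(rotation=ang, scale=(scale, scale), translation=(tx, ty))
    back = AffineTransform(translation=(c, c))
    return center + tf + back


def augment_pair_batch(batch: Sequence[Tuple[np.ndarray, np.ndarray]], seed: int):
    """Paired augmentation: geometric ops (flip / rotation / affine) share
    parameters within a pair; photometric noise is per-image; hue/saturation
    jitter touches the H&E member only. Seeded and reproducible."""
    rng = np.random.default_rng(seed)
    out = []
    for he, if_chan in batch:
        he = np.asarray(he, dtype=float).copy()
        if_chan = np.asarray(if_chan, dtype=float).copy()
        if rng.random() < 0.5:
            he, if_chan = he[:, ::-1], if_chan[:, ::-1]
        if rng.random() < 0.5:
            he, if_chan = he[::-1], if_chan[::-1]
        tf = _geom_transform(rng, he.shape[0])
        he = warp(he, tf.inverse, order=1, mode="reflect")
        if_chan = warp(if_chan, tf.inverse, order=1, mode="reflect")
        # photometric, per image
        sig = rng.uniform(0.0, 0.8)
        if sig > 0.05:
            he = ndimage.gaussian_filter(he, (sig, sig, 0))
            if_chan = ndimage.gaussian_filter(if_chan, sig)
        he = he + rng.normal(0.0, 0.01, he.shape)
        lam = np.clip(if_chan, 0.0, 1.0) * 50.0
        if_chan = rng.poisson(lam) / 50.0 * 0.5 + if_chan * 0.5
        if_chan = if_chan + rng.normal(0.0, 0.01, if_chan.shape)
        # hue/saturation jitter on the H&E member only
        hsv = skcolor.rgb2hsv(np.clip(he, 0.0, 1.0))
        hsv[:, :, 0] = (hsv[:, :, 0] + rng.uniform(-0.02, 0.02)) % 1.0
        hsv[:, :, 1] = np.clip(hsv[:, :, 1] * rng.uniform(0.9, 1.1), 0.0, 1.0)
        he = skcolor.hsv2rgb(hsv)
        out.append((np.clip(he, 0.0, 1.0), np.clip(if_chan, 0.0, 1.0)))
    return out


# ---------------------------------------------------------------------------
# training


def _stack_pairs(tile_pairs):
    hes, ifs = [], []
    for he, if_chan in tile_pairs:
        hes.append(np.asarray(he, dtype=np.float32))
        ifs.append(np.asarray(if_chan, dtype=np.float32))
    x = np.ascontiguousarray(np.transpose(np.stack(hes), (0, 3, 1, 2)))
    y = np.stack(ifs)[:, None]
    return x, y


def _bce_with_logits_grad(logits: np.ndarray, target: float):
    """Mean BCE loss and gradient wrt logits for a constant 0/1 target."""
    p = nn.sigmoid(logits)
    eps = 1e-12
    if target == 1.0:
        loss = -np.mean(np.log(p + eps))
    else:
        loss = -np.mean(np.log(1.0 - p + eps))
    grad = (p - target) / logits.size
    return float(loss), grad, p


def train_translator(tile_pairs, config: TranslatorConfig,
                     wsi_means: Optional[Sequence[float]] = None) -> Translator:
    """Train a translator on registered (H&E, IF) tile pairs.

    ``wsi_means`` carries each tile's source-WSI mean IF intensity for the
    adaptive-lambda rule; by default the mean over the training IF tiles is
    used for every tile. Adversarial mode alternates one discriminator and
    one generator update per batch; l1_only updates the generator on the
    adaptively weighted L1 loss alone.
    """
    tile_pairs = list(tile_pairs)
    if not tile_pairs:
        raise InvalidSpecError("empty training set")
    x, y = _stack_pairs(tile_pairs)
    n = x.shape[0]
    if wsi_means is None:
        wsi_means = np.full(n, float(y.mean()))
    else:
        wsi_means = np.asarray(wsi_means, dtype=float)
        if wsi_means.shape != (n,):
            raise InvalidSpecError("wsi_means must have one entry per pair")

    rng = np.random.default_rng(config.seed)
    gen = Generator(config.first_layer_filters, rng)
    g_opt = nn.Adam(gen.layers, lr=config.learning_rate)
    disc = d_opt = None
    if config.mode == "adversarial":
        disc = PatchDiscriminator(config.first_layer_filters, rng)
        d_opt = nn.Adam(disc.layers, lr=config.learning_rate)

    history = {"l1": [], "lambda": [], "g_adv": [], "d_loss": [], "d_acc": [],
               "g_total": []}
    steps = 0
    max_steps = config.max_steps or config.epochs * max(1, n // config.batch_size)
    done = False
    for _ in range(config.epochs):
        if done:
            break
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x[idx], y[idx]
            if config.augment:
                aug_seed = int(rng.integers(0, 2**31))
                pairs = [(np.transpose(xb[i], (1, 2, 0)), yb[i, 0]) for i in range(len(idx))]
                pairs = augment_pair_batch(pairs, aug_seed)
                xb = np.transpose(np.stack([p[0] for p in pairs]), (0, 3, 1, 2))
                yb = np.stack([p[1] for p in pairs])[:, None]
            b = len(idx)
            lam = adaptive_lambda(yb, float(wsi_means[idx].mean()),
                                  config.base_lambda)

            if config.mode == "adversarial":
                fake = gen.forward(xb)
                # --- discriminator update: real and fake in one pass, since
                # layer backward() assigns rather than accumulates gradients
                logits = disc.forward(np.concatenate([xb, xb]),
                                      np.concatenate([yb, fake]))
                p = nn.sigmoid(logits)
                p_r, p_f = p[:b], p[b:]
                eps = 1e-12
                d_loss = 0.5 * float(-np.mean(np.log(p_r + eps))
                                     - np.mean(np.log(1.0 - p_f + eps)))
                targets = np.zeros_like(p)
                targets[:b] = 1.0
                disc.backward((p - targets) / logits.size)
                d_opt.step()
                d_opt.zero_grad()
                d_acc = 0.5 * (float(np.mean(p_r > 0.5)) + float(np.mean(p_f <= 0.5)))
                # --- generator update (non-saturating + lambda * L1)
                fake = gen.forward(xb)
                logit_f = disc.forward(xb, fake)
                g_adv, grad_adv, _ = _bce_with_logits_grad(logit_f, 1.0)
                d_fake = disc.backward(grad_adv)
                l1 = float(np.mean(np.abs(yb - fake)))
                d_l1 = lam * np.sign(fake - yb) / fake.size
                gen.backward(d_fake + d_l1)
                d_opt.zero_grad()  # discard D grads from the G pass
                g_opt.step()
                g_opt.zero_grad()
                history["g_adv"].append(g_adv)
                history["d_loss"].append(d_loss)
                history["d_acc"].append(d_acc)
                history["g_total"].append(g_adv + lam * l1)
            else:
                fake = gen.forward(xb)
                l1 = float(np.mean(np.abs(yb - fake)))
                d_l1 = lam * np.sign(fake - yb) / fake.size
                gen.backward(d_l1)
                g_opt.step()
                g_opt.zero_grad()
                history["g_total"].append(lam * l1)

            history["l1"].append(l1)
            history["lambda"].append(lam)
            steps += 1
            if steps >= max_steps:
                done = True
                break

    return Translator(generator=gen, config=config, discriminator=disc,
                      history=history)


def translate_tile(model: Translator, he_tile: np.ndarray) -> np.ndarray:
    """Generate the virtual IF tile for one H&E tile; deterministic."""
    he = np.asarray(he_tile, dtype=float)
    if he.ndim != 3 or he.shape[2] != 3:
        raise InvalidSpecError("H&E tile must be (H, W, 3)")
    if he.shape[0] % 8 or he.shape[1] % 8:
        raise InvalidSpecError("tile dims must be multiples of 8")
    x = np.transpose(he, (2, 0, 1))[None]
    out = model.generator.forward(x)
    return np.clip(out[0, 0].astype(float), 0.0, 1.0)


def ensemble_translate(models: Sequence[Translator], he_tile: np.ndarray) -> np.ndarray:
    """Pixel-wise mean of member model outputs."""
    models = list(models)
    if not models:
        raise InvalidSpecError("empty model list")
    outs = [translate_tile(m, he_tile) for m in models]
    return np.mean(outs, axis=0)


def stitch_tiles(tiles: Sequence[Tuple[int, int, np.ndarray]],
                 grid_shape: Tuple[int, int]) -> np.ndarray:
    """Assemble (row, col, tile) records into a full image.

    The grid must be complete and free of duplicates; offending positions are
    named in the error.
    """
    rows, cols = grid_shape
    seen = {}
    for r, c, t in tiles:
        if (r, c) in seen:
            raise InvalidSpecError(f"duplicate grid cell ({r}, {c})")
        seen[(r, c)] = np.asarray(t)
    missing = [(r, c) for r in range(rows) for c in range(cols) if (r, c) not in seen]
    if missing:
        raise InvalidSpecError(f"missing grid cells: {missing}")
    extra = [rc for rc in seen if not (0 <= rc[0] < rows and 0 <= rc[1] < cols)]
    if extra:
        raise InvalidSpecError(f"grid cells outside the grid: {extra}")
    s = next(iter(seen.values())).shape[0]
    sample = next(iter(seen.values()))
    shape = (rows * s, cols * s) + sample.shape[2:]
    out = np.zeros(shape, dtype=sample.dtype)
    for (r, c), t in seen.items():
        out[r * s : (r + 1) * s, c * s : (c + 1) * s] = t
    return out
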