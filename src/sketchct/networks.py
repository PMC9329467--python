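"""Conditional GAN architectures for sketch-to-CT translation.

Two generators share one U-Net topology (seven stride-2 down-convolutions,
seven up-convolutions, skip connections):

* the baseline pix2pix generator maps a sketch deterministically to one
  CT image (one-to-one);
* the style generator replaces every decoder up-convolution with a style
  block: a 3x3 convolution whose kernel is modulated per input channel by
  scales computed from a shared 512-dimensional style vector, itself the
  output of a 4-layer fully connected mapping network fed with a standard
  normal latent.  Varying the latent yields distinct images from one
  sketch (one-to-many), which is what makes the model usable for data
  augmentation.

The patch discriminator scores channel-concatenated (sketch, image) pairs
and is identical for both models.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import _nn
from ._nn import (Conv2d, InstanceNorm2d, Linear, ModulatedConv2d, Module,
                  Tensor, concat, leaky_relu, relu, sigmoid, tanh,
                  upsample_nearest2x)

__all__ = [
    "GeneratorConfig", "ModelBundle",
    "build_generator", "build_style_generator", "build_discriminator",
    "build_model_bundle", "map_latent", "draw_style_latents", "generate",
    "images_to_uint8", "save_bundle", "load_bundle", "summary",
]


@dataclass(frozen=True)
class GeneratorConfig:
    depth: int = 7
    base_channels: int = 64
    image_size: int = 128
    use_style: bool = False
    latent_dim: int = 512
    demodulate: bool = True

    def __post_init__(self):
        if self.image_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"image_size {self.image_size} not divisible by "
                f"2^depth = {2 ** self.depth}")
        if self.latent_dim <= 0:
            raise ValueError("latent_dim must be positive")

    def encoder_channels(self):
        b = self.base_channels
        return [min(b * 2 ** i, 8 * b) for i in range(self.depth)]


# ---------------------------------------------------------------------------
# Building blocks

class MappingNetwork(Module):
    """Four fully connected layers turning a normal latent into a style."""

    def __init__(self, latent_dim, rng):
        self.layers = [Linear(latent_dim, latent_dim, rng)
                       for _ in range(4)]

    def forward(self, z):
        h = z
        for layer in self.layers:
            h = leaky_relu(layer(h), 0.2)
        return h


class StyleHead(Module):
    """Per-block 4-layer fully connected head: style vector -> per-input-
    channel kernel scales, initialised near the identity (scales ~ 1)."""

    def __init__(self, latent_dim, c_in, rng):
        self.layers = [Linear(latent_dim, latent_dim, rng)
                       for _ in range(3)]
        self.out = Linear(latent_dim, c_in, rng,
                          w_std=0.1 / np.sqrt(latent_dim), bias_init=1.0)

    def forward(self, w):
        h = w
        for layer in self.layers:
            h = leaky_relu(layer(h), 0.2)
        return self.out(h)


class UNetGenerator(Module):
    """Shared U-Net; decoder blocks are plain or style-modulated."""

    def __init__(self, config: GeneratorConfig, rng):
        self.config = config
        enc = config.encoder_channels()
        d = config.depth
        self.enc_convs, self.enc_norms = [], []
        c_prev = 1
        for i in range(d):
            self.enc_convs.append(Conv2d(c_prev, enc[i], 4, 2, 1, rng))
            # no norm on the first layer nor the (1x1-spatial) bottleneck
            self.enc_norms.append(
                InstanceNorm2d(enc[i]) if 0 < i < d - 1 else None)
            c_prev = enc[i]

        self.dec_convs, self.dec_norms, self.style_heads = [], [], []
        self.dec_in, self.dec_out = [], []
        for j in range(d):
            c_in = enc[d - 1] if j == 0 else \
                self.dec_out[j - 1] + enc[d - 1 - j]
            c_out = 1 if j == d - 1 else enc[d - 2 - j]
            self.dec_in.append(c_in)
            self.dec_out.append(c_out)
            if config.use_style:
                self.dec_convs.append(ModulatedConv2d(
                    c_in, c_out, 3, rng, demodulate=config.demodulate))
                self.style_heads.append(
                    StyleHead(config.latent_dim, c_in, rng))
                self.dec_norms.append(None)
            else:
                self.dec_convs.append(Conv2d(c_in, c_out, 3, 1, 1, rng))
                self.dec_norms.append(
                    InstanceNorm2d(c_out) if j < d - 1 else None)

    def forward(self, sketch, style=None):
        """``sketch``: (N,1,H,W) in [0,1]; ``style``: (N, latent_dim) style
        vector (mapping-network output), required iff ``use_style``."""
        cfg = self.config
        if cfg.use_style:
            if style is None:
                raise ValueError("style generator requires a style vector")
            style = style if isinstance(style, Tensor) else Tensor(style)
            if style.shape[-1] != cfg.latent_dim:
                raise ValueError(
                    f"style length {style.shape[-1]} != latent_dim "
                    f"{cfg.latent_dim}")
        h = sketch if isinstance(sketch, Tensor) else Tensor(sketch)
        skips = []
        for conv, norm in zip(self.enc_convs, self.enc_norms):
            h = conv(h)
            if norm is not None:
                h = norm(h)
            h = leaky_relu(h, 0.2)
            skips.append(h)
        d = cfg.depth
        h = skips[-1]
        for j in range(d):
            if j > 0:
                h = concat([h, skips[d - 1 - j]], axis=1)
            h = upsample_nearest2x(h)
            if cfg.use_style:
                scales = self.style_heads[j](style)
                h = self.dec_convs[j](h, scales)
            else:
                h = self.dec_convs[j](h)
            if j < d - 1:
                if self.dec_norms[j] is not None:
                    h = self.dec_norms[j](h)
                h = relu(h)
        return tanh(h)


class PatchDiscriminator(Module):
    """Stride-2 CNN scoring (sketch, image) pairs as a sigmoid patch grid.

    Identical for the baseline and style models.
    """

    def __init__(self, config: GeneratorConfig, rng, n_layers=4):
        b = config.base_channels
        chans = [min(b * 2 ** i, 8 * b) for i in range(n_layers)]
        self.convs, self.norms = [], []
        c_prev = 2
        for i, c in enumerate(chans):
            self.convs.append(Conv2d(c_prev, c, 4, 2, 1, rng))
            self.norms.append(InstanceNorm2d(c) if i > 0 else None)
            c_prev = c
        self.head = Conv2d(c_prev, 1, 3, 1, 1, rng)

    def forward(self, sketch, image):
        sketch = sketch if isinstance(sketch, Tensor) else Tensor(sketch)
        image = image if isinstance(image, Tensor) else Tensor(image)
        if sketch.shape[2:] != image.shape[2:]:
            raise ValueError("sketch and image spatial shapes differ")
        h = concat([sketch, image], axis=1)
        for conv, norm in zip(self.convs, self.norms):
            h = conv(h)
            if norm is not None:
                h = norm(h)
            h = leaky_relu(h, 0.2)
        return sigmoid(self.head(h))


# ---------------------------------------------------------------------------
# Public constructors and bundle

@dataclass
class ModelBundle:
    """Generator (+ mapping network for the style model) and discriminator."""

    generator: UNetGenerator
    discriminator: PatchDiscriminator
    mapping: MappingNetwork | None
    config: GeneratorConfig

    @property
    def use_style(self):
        return self.config.use_style

    def generator_parameters(self):
        params = self.generator.parameters()
        if self.mapping is not None:
            params = params + self.mapping.parameters()
        return params


def build_generator(config: GeneratorConfig, seed: int = 0) -> UNetGenerator:
    """Baseline one-to-one U-Net generator."""
    cfg = config if not config.use_style else \
        GeneratorConfig(**{**asdict(config), "use_style": False})
    return UNetGenerator(cfg, np.random.default_rng(seed))


def build_style_generator(config: GeneratorConfig, seed: int = 0):
    """Style generator + mapping network (one-to-many)."""
    if not config.use_style:
        raise ValueError("config.use_style must be True")
    rng = np.random.default_rng(seed)
    return UNetGenerator(config, rng), MappingNetwork(config.latent_dim, rng)


def build_discriminator(config: GeneratorConfig,
                        seed: int = 0) -> PatchDiscriminator:
    return PatchDiscriminator(config, np.random.default_rng(seed))


def build_model_bundle(config: GeneratorConfig, seed: int = 0) -> ModelBundle:
    if config.use_style:
        gen, mapping = build_style_generator(config, seed)
    else:
        gen, mapping = build_generator(config, seed), None
    disc = build_discriminator(config, seed + 1)
    return ModelBundle(gen, disc, mapping, config)


def map_latent(z, mapping: MappingNetwork) -> np.ndarray:
    """Deterministic latent -> style vector map (R^512 -> R^512)."""
    z = np.asarray(z, dtype=np.float32)
    if not np.all(np.isfinite(z)):
        raise ValueError("latent must be finite")
    squeeze = z.ndim == 1
    z2 = z[None] if squeeze else z
    expected = mapping.layers[0].weight.shape[0]
    if z2.shape[-1] != expected:
        raise ValueError(f"latent length {z2.shape[-1]} != {expected}")
    w = mapping(Tensor(z2)).data
    return w[0] if squeeze else w


def draw_style_latents(n, latent_dim, rng) -> np.ndarray:
    """n i.i.d. standard-normal latents."""
    return rng.standard_normal((n, latent_dim)).astype(np.float32)


def _as_model_sketch(sketch):
    s = np.asarray(sketch, dtype=np.float32)
    if s.max() > 1.0:
        s = s / 255.0
    if s.ndim == 2:
        s = s[None, None]
    elif s.ndim == 3:
        s = s[:, None]
    return s


def generate(bundle: ModelBundle, sketch, n: int = 1, latents=None,
             seed: int = 0, batch_size: int = 32) -> list[np.ndarray]:
    """Generate ``n`` images from one sketch.

    The baseline generator is one-to-one: all ``n`` outputs are identical.
    The style generator draws ``n`` fresh standard-normal latents (or uses
    the supplied ones) and returns ``n`` distinct images.  Outputs are 2-D
    float arrays in [-1, 1].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    s = _as_model_sketch(sketch)
    with _nn.no_grad():
        if not bundle.use_style:
            img = bundle.generator(Tensor(s)).data[0, 0]
            return [img.copy() for _ in range(n)]
        if latents is None:
            latents = draw_style_latents(n, bundle.config.latent_dim,
                                         np.random.default_rng(seed))
        latents = np.asarray(latents, dtype=np.float32)
        if latents.shape != (n, bundle.config.latent_dim):
            raise ValueError("latents must have shape (n, latent_dim)")
        out = []
        for k in range(0, n, batch_size):
            z = latents[k:k + batch_size]
            w = map_latent(z, bundle.mapping)
            batch = np.repeat(s, z.shape[0], axis=0)
            imgs = bundle.generator(Tensor(batch), Tensor(w)).data
            out.extend(imgs[i, 0] for i in range(imgs.shape[0]))
        return out


def images_to_uint8(images):
    """[-1, 1] model output -> 8-bit display scale."""
    return [np.clip(np.floor((np.asarray(im) + 1.0) * 127.5 + 0.5), 0, 255)
            .astype(np.uint8) for im in images]


# ---------------------------------------------------------------------------
# Checkpoint archive (single zip: config JSON + npz weights)

def save_bundle(bundle: ModelBundle, path):
    buf = io.BytesIO()
    arrays = {}
    for tag, mod in (("gen", bundle.generator), ("disc", bundle.discriminator),
                     ("map", bundle.mapping)):
        if mod is None:
            continue
        for i, a in enumerate(mod.state_arrays()):
            arrays[f"{tag}_{i}"] = a
    np.savez(buf, **arrays)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.json", json.dumps(asdict(bundle.config)))
        zf.writestr("weights.npz", buf.getvalue())


def load_bundle(path) -> ModelBundle:
    with zipfile.ZipFile(path) as zf:
        config = GeneratorConfig(**json.loads(zf.read("config.json")))
        data = np.load(io.BytesIO(zf.read("weights.npz")))
    bundle = build_model_bundle(config)
    for tag, mod in (("gen", bundle.generator), ("disc", bundle.discriminator),
                     ("map", bundle.mapping)):
        if mod is None:
            continue
        keys = sorted((k for k in data.files if k.startswith(tag + "_")),
                      key=lambda k: int(k.split("_")[1]))
        mod.load_state_arrays([data[k] for k in keys])
    return bundle


def summary(config: GeneratorConfig) -> str:
    """Layer table with parameter counts for the configured models."""
    bundle = build_model_bundle(config)
    lines = [f"{'model':<16}{'parameters':>12}",
             f"{'generator':<16}{bundle.generator.n_parameters():>12}"]
    if bundle.mapping is not None:
        lines.append(f"{'mapping':<16}{bundle.mapping.n_parameters():>12}")
    lines.append(
        f"{'discriminator':<16}{bundle.discriminator.n_parameters():>12}")
    enc = config.encoder_channels()
    lines.append("encoder channels: " + "->".join(map(str, enc)))
    lines.append("decoder channels: "
                 + "->".join(map(str, bundle.generator.dec_out)))
    return "\n".join(lines)
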