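"""Adversarial objectives and the training loop.

The discriminator maximizes the conditional GAN value
E[log D(x|y)] + E[log(1 - D(G(z|y)))]; its loss here is the negation of
that sum.  The generator minimizes the non-saturating adversarial term
-E[log D(G(z|y))] plus an L1 reconstruction penalty lambda * E|x - G(z|y)|
(lambda = 100 by default, the canonical pix2pix weight).  Training
alternates one discriminator and one generator Adam step per batch; for
the style model a fresh standard-normal latent is drawn per sample per
step.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._nn import Adam, Tensor, abs_, clip_values, log, mean
from .networks import ModelBundle, draw_style_latents, map_latent, save_bundle

__all__ = ["TrainConfig", "TrainHistory", "EpochRecord",
           "d_loss", "g_loss", "train", "TrainingDivergedError",
           "pairs_to_arrays"]

_EPS = 1e-7  # probability clamp for log stability


class TrainingDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults follow the production recipe
    (Adam beta1=0.9 beta2=0.999, lr 1e-5, batch 5; 400 epochs for the
    baseline, 200 for the style model)."""

    learning_rate: float = 1e-5
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 400
    batch_size: int = 5
    lambda_l1: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lambda_l1 < 0:
            raise ValueError("lambda_l1 must be >= 0")


@dataclass
class EpochRecord:
    epoch: int
    d_loss: float
    g_adv: float
    g_l1: float
    wall_s: float
    checkpoint: str | None = None


@dataclass
class TrainHistory:
    records: list[EpochRecord] = field(default_factory=list)

    def to_jsonl(self, path):
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(json.dumps(vars(r)) + "\n")


# ---------------------------------------------------------------------------
# Losses

def _clamped(scores):
    t = scores if isinstance(scores, Tensor) else Tensor(np.asarray(scores))
    if t.data.size == 0:
        raise ValueError("empty score batch")
    return clip_values(t, _EPS, 1.0 - _EPS)


def d_loss(real_scores, fake_scores) -> Tensor:
    """Discriminator loss: -[mean log D(x|y) + mean log(1 - D(G(z|y)))].

    Equals 2 log 2 at the uniform D = 0.5 equilibrium.
    """
    real = _clamped(real_scores)
    fake = _clamped(fake_scores)
    return -(mean(log(real)) + mean(log(1.0 - fake)))


def g_loss(fake_scores, generated, real, lambda_l1=100.0) -> Tensor:
    """Generator loss: non-saturating adversarial part plus weighted L1.

    -mean log D(G(z|y)) + lambda * mean |x - G(z|y)|.
    """
    gen = generated if isinstance(generated, Tensor) \
        else Tensor(np.asarray(generated, dtype=float))
    tgt = real if isinstance(real, Tensor) \
        else Tensor(np.asarray(real, dtype=float))
    if gen.shape != tgt.shape:
        raise ValueError("generated/real shape mismatch")
    fake = _clamped(fake_scores)
    adv = -mean(log(fake))
    l1 = mean(abs_(gen - tgt))
    return adv + lambda_l1 * l1


# ---------------------------------------------------------------------------
# Training loop

def pairs_to_arrays(pairs):
    """SlicePair list -> (sketches in [0,1], targets in [-1,1]), NCHW."""
    sk, ct = [], []
    for p in pairs:
        sk.append(np.asarray(p.sketch_image, dtype=np.float32) / 255.0)
        ct_img = np.asarray(p.ct_image, dtype=np.float32)
        if ct_img.ndim == 3:
            ct_img = ct_img[..., 0]
        ct.append(ct_img / 127.5 - 1.0)
    return (np.stack(sk)[:, None], np.stack(ct)[:, None])


def train(pairs, bundle: ModelBundle, config: TrainConfig,
          out_dir=None, checkpoint_every=0):
    """Train the bundle on (sketch, CT) pairs; returns (bundle, history).

    ``pairs`` is a list of SlicePair (or any objects with ``sketch_image``
    / ``ct_image``).  One discriminator step and one generator step per
    batch; shuffling, latents and everything else derive from
    ``config.seed``, so runs are reproducible.
    """
    if len(pairs) == 0:
        raise ValueError("empty dataset")
    sketches, targets = pairs_to_arrays(pairs)
    n = sketches.shape[0]
    rng = np.random.default_rng(config.seed)
    opt_d = Adam(bundle.discriminator.parameters(), lr=config.learning_rate,
                 beta1=config.beta1, beta2=config.beta2)
    opt_g = Adam(bundle.generator_parameters(), lr=config.learning_rate,
                 beta1=config.beta1, beta2=config.beta2)
    history = TrainHistory()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    for epoch in range(1, config.epochs + 1):
        t0 = time.time()
        order = rng.permutation(n)
        ep_d, ep_adv, ep_l1, n_batches = 0.0, 0.0, 0.0, 0
        for k in range(0, n, config.batch_size):
            idx = order[k:k + config.batch_size]
            y = Tensor(sketches[idx])
            x = Tensor(targets[idx])
            if bundle.use_style:
                # fresh latent per sample per step; mapping stays in the
                # graph so it receives generator gradients
                z = draw_style_latents(len(idx), bundle.config.latent_dim,
                                       rng)
                fake = bundle.generator(y, bundle.mapping(Tensor(z)))
            else:
                fake = bundle.generator(y)

            # discriminator step on detached fakes
            opt_d.zero_grad()
            ld = d_loss(bundle.discriminator(y, x),
                        bundle.discriminator(y, fake.detach()))
            ld.backward()
            opt_d.step()

            # generator step through the live fake graph
            opt_g.zero_grad()
            fake_scores = bundle.discriminator(y, fake)
            adv = -mean(log(_clamped(fake_scores)))
            l1 = mean(abs_(fake - x))
            lg = adv + config.lambda_l1 * l1
            lg.backward()
            opt_g.step()

            vals = (ld.item(), adv.item(), l1.item())
            if not all(np.isfinite(v) for v in vals):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}: "
                    f"d={vals[0]}, g_adv={vals[1]}, l1={vals[2]}")
            ep_d += vals[0]
            ep_adv += vals[1]
            ep_l1 += vals[2]
            n_batches += 1

        ckpt = None
        if out_dir is not None and checkpoint_every \
                and epoch % checkpoint_every == 0:
            ckpt = str(out_dir / f"checkpoint_{epoch:04d}.zip")
            save_bundle(bundle, ckpt)
        history.records.append(EpochRecord(
            epoch=epoch, d_loss=ep_d / n_batches, g_adv=ep_adv / n_batches,
            g_l1=ep_l1 / n_batches, wall_s=time.time() - t0,
            checkpoint=ckpt))
    if out_dir is not None:
        history.to_jsonl(out_dir / "history.jsonl")
        save_bundle(bundle, out_dir / "final.zip")
    return bundle, history
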