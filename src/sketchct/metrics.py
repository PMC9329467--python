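"""Image-quality metrics for generated CT slices: PSNR, SSIM, FID, LPIPS.

PSNR and SSIM follow their closed-form definitions on 8-bit images; SSIM
uses image-wide statistics (not the sliding-window variant) with the
constants C1 = 0.01 * 255^2 and C2 = 0.03 * 255^2, a windowed mode being
available behind a flag.  FID fits a Gaussian to deep features of each
image group and reports ||mu_F - mu_G||^2 + Tr(S_F + S_G - 2 (S_F S_G)^1/2),
with the matrix square root computed by symmetric eigendecomposition.
LPIPS sums, over extractor layers, the spatial mean of the weighted squared
difference of channel-unit-normalized feature maps.

Feature extractors are pluggable.  The default is a small deterministic
randomly initialised CNN (fixed seed) suitable for desk-scale experiments;
an ImageNet-pretrained Inception-v3 or AlexNet backbone can be substituted
by implementing the same two-method interface, which restores the
conventional large-scale definitions of FID and LPIPS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from skimage.metrics import structural_similarity as _sk_ssim

from ._nn import _im2col

__all__ = [
    "MetricReport", "SmallFeatureExtractor",
    "mse", "psnr", "ssim", "fid", "lpips", "evaluate",
    "PSNR_SENTINEL_DB",
]

PSNR_SENTINEL_DB = 99.0   # reported instead of +inf for identical images
_C1 = 0.01 * 255 ** 2
_C2 = 0.03 * 255 ** 2


@dataclass
class MetricReport:
    """Per-pair metric means plus one group-level FID."""

    psnr_mean: float
    ssim_mean: float
    lpips_mean: float
    fid: float
    n_pairs: int

    def __post_init__(self):
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if not -1.0 <= self.ssim_mean <= 1.0:
            raise ValueError("ssim_mean out of [-1, 1]")

    def to_dict(self):
        return {k: (int(v) if k == "n_pairs" else float(v))
                for k, v in vars(self).items()}


def _pair(f, g):
    f = np.asarray(f, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if f.shape != g.shape:
        raise ValueError(f"shape mismatch: {f.shape} vs {g.shape}")
    return f, g


def mse(f, g) -> float:
    """Mean squared pixel difference."""
    f, g = _pair(f, g)
    return float(np.mean((f - g) ** 2))


def psnr(f, g) -> float:
    """Peak signal-to-noise ratio in dB for 8-bit-range images.

    10 log10(255^2 / MSE); identical images return the documented
    sentinel ``PSNR_SENTINEL_DB`` instead of +inf.
    """
    m = mse(f, g)
    if m == 0:
        return PSNR_SENTINEL_DB
    return float(10.0 * np.log10(255.0 ** 2 / m))


def ssim(f, g, windowed: bool = False) -> float:
    """Structural similarity from luminance, contrast and structure terms.

    Default: single global statistics (means, variances, covariance over
    the whole image).  ``windowed=True`` switches to the standard
    sliding-window mean implementation.
    """
    f, g = _pair(f, g)
    if windowed:
        return float(_sk_ssim(f, g, data_range=255.0))
    mu_f, mu_g = f.mean(), g.mean()
    var_f, var_g = f.var(), g.var()
    cov = ((f - mu_f) * (g - mu_g)).mean()
    return float(((2 * mu_f * mu_g + _C1) * (2 * cov + _C2))
                 / ((mu_f ** 2 + mu_g ** 2 + _C1)
                    * (var_f + var_g + _C2)))


def fid(features_f, features_g) -> float:
    """Frechet distance between Gaussian fits of two feature groups.

    ||mu_F - mu_G||^2 + Tr(S_F + S_G - 2 sqrt(S_F S_G)), the square root
    evaluated as the symmetric form sqrt(S_F^1/2 S_G S_F^1/2) by
    eigendecomposition with tiny negative eigenvalues clipped to zero.
    Symmetric in its arguments.
    """
    F = np.atleast_2d(np.asarray(features_f, dtype=np.float64))
    G = np.atleast_2d(np.asarray(features_g, dtype=np.float64))
    if F.shape[1] != G.shape[1]:
        raise ValueError("feature dimension mismatch")
    if F.shape[0] < 2 or G.shape[0] < 2:
        raise ValueError("each group needs at least 2 samples")
    mu_f, mu_g = F.mean(axis=0), G.mean(axis=0)
    cov_f = np.cov(F, rowvar=False)
    cov_g = np.cov(G, rowvar=False)

    vals_f, vecs_f = linalg.eigh(cov_f)
    vals_f = np.clip(vals_f, 0.0, None)
    root_f = (vecs_f * np.sqrt(vals_f)) @ vecs_f.T
    inner = root_f @ cov_g @ root_f
    vals = linalg.eigh(inner, eigvals_only=True)
    # numerically tiny negative eigenvalues of the (PSD in exact
    # arithmetic) product are clipped to zero
    tol = 1e-8 * max(1.0, float(np.abs(vals).max()))
    if np.any(vals < -tol):
        raise ValueError("covariance product has large negative eigenvalues")
    tr_sqrt = np.sqrt(np.clip(vals, 0.0, None)).sum()
    return float(np.sum((mu_f - mu_g) ** 2)
                 + np.trace(cov_f) + np.trace(cov_g) - 2.0 * tr_sqrt)


def lpips(f, g, extractor, weights=None) -> float:
    """Perceptual distance between two images under a feature extractor.

    sum_l (1 / (M_l N_l)) sum_{M,N} ||w_l * (fhat^l - ghat^l)||^2 with
    channel-unit-normalized feature maps.  ``weights`` maps layer index to
    a per-channel vector; default is all-ones.
    """
    maps_f = extractor.feature_maps(f)
    maps_g = extractor.feature_maps(g)
    if len(maps_f) != len(maps_g):
        raise ValueError("extractor returned mismatched layer counts")
    if weights is not None and len(weights) != len(maps_f):
        raise ValueError("one weight vector per extractor layer required")
    total = 0.0
    for layer, (mf, mg) in enumerate(zip(maps_f, maps_g)):
        if mf.shape != mg.shape:
            raise ValueError("feature map shape mismatch")
        fhat = mf / np.sqrt((mf ** 2).sum(axis=0, keepdims=True) + 1e-10)
        ghat = mg / np.sqrt((mg ** 2).sum(axis=0, keepdims=True) + 1e-10)
        diff = fhat - ghat
        if weights is not None:
            w = np.asarray(weights[layer], dtype=np.float64)
            if w.shape != (mf.shape[0],):
                raise ValueError("weight length != channel count")
            diff = diff * w[:, None, None]
        total += float((diff ** 2).sum(axis=0).mean())
    return total


# ---------------------------------------------------------------------------
# Desk-scale feature extractor

class SmallFeatureExtractor:
    """Deterministic randomly initialised CNN for FID/LPIPS features.

    Three stride-2 ReLU convolution stages; LPIPS uses all three feature
    maps, FID uses the global average pool of the last stage.  Weights are
    fixed by ``seed``, so the extractor is deterministic.
    """

    name = "small"

    def __init__(self, seed: int = 0, channels=(8, 16, 32)):
        rng = np.random.default_rng(seed)
        self.weights = []
        c_prev = 1
        for c in channels:
            w = rng.normal(0.0, 1.0 / np.sqrt(c_prev * 9),
                           size=(c, c_prev, 3, 3))
            self.weights.append(w)
            c_prev = c
        self.feature_dim = channels[-1]

    def _prep(self, image):
        img = np.asarray(image, dtype=np.float64)
        if img.ndim == 3:          # RGB with equal channels -> luminance
            img = img.mean(axis=-1)
        if img.max() > 1.5:        # 8-bit input
            img = img / 127.5 - 1.0
        return img[None, None]

    def feature_maps(self, image):
        """List of (C, H, W) float feature maps, one per stage."""
        h = self._prep(image)
        maps = []
        for w in self.weights:
            o, c, kh, kw = w.shape
            cols, oh, ow = _im2col(h, kh, kw, stride=2, pad=1)
            h = np.maximum(
                (w.reshape(o, -1) @ cols[0]).reshape(1, o, oh, ow), 0.0)
            maps.append(h[0].copy())
        return maps

    def features(self, image):
        """Global-average-pooled top-stage features (``feature_dim``,)."""
        return self.feature_maps(image)[-1].mean(axis=(1, 2))


def evaluate(real_set, generated_set, extractor) -> MetricReport:
    """Table-style report: pairwise PSNR/SSIM/LPIPS means, one group FID.

    The two sets must be index-aligned (real_i corresponds to
    generated_i) and contain at least two images each (FID needs
    two-sample groups).
    """
    real_set, generated_set = list(real_set), list(generated_set)
    if len(real_set) != len(generated_set):
        raise ValueError("real and generated sets must have equal length")
    if len(real_set) < 2:
        raise ValueError("need at least 2 pairs (FID requires 2 per group)")
    psnrs, ssims, lpipss = [], [], []
    for r, g in zip(real_set, generated_set):
        psnrs.append(psnr(r, g))
        ssims.append(ssim(r, g))
        lpipss.append(lpips(r, g, extractor))
    feats_r = np.stack([extractor.features(r) for r in real_set])
    feats_g = np.stack([extractor.features(g) for g in generated_set])
    return MetricReport(
        psnr_mean=float(np.mean(psnrs)),
        ssim_mean=float(np.mean(ssims)),
        lpips_mean=float(np.mean(lpipss)),
        fid=fid(feats_r, feats_g),
        n_pairs=len(real_set),
    )
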