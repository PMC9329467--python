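"""CT preprocessing: VOI cropping, resampling, oblique slices, windowing,
edge extraction, and sketch binarization.

The pipeline turns an annotated 3-D CT volume into paired 2-D training
images: a cubic volume of interest (VOI) twice the tumor's long diameter is
cropped around the tumor center, resampled to isotropic 0.625 mm voxels,
and sliced.  Test VOIs contribute a single central axial slice; training
VOIs additionally contribute oblique slices at 10-degree steps to +/-30
degrees in the left-right and head-tail directions — the full 7x7 angle
grid, each emitted unmirrored and left-right mirrored, i.e. 98 images per
VOI.  Slices are resized to 128x128, rendered through the lung window
(level -600 HU, width 1600 HU) into 8-bit images, and paired with Canny
edges (5x5 Gaussian, hysteresis thresholds 128/200) standing in for
hand-drawn sketches.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .phantoms import AnnotatedVolume, HU_PAD

__all__ = [
    "VOIVolume", "SlicePair", "ObliqueSlice", "WindowSpec", "CannySpec",
    "TRAIN_ANGLES_DEG", "SLICES_PER_TRAIN_VOI",
    "crop_voi", "resample_isotropic", "extract_slices", "apply_window",
    "resize_to_model", "canny_edges", "binarize_sketch",
    "preprocess_volume", "write_ct_png", "write_sketch_png", "read_png",
    "write_manifest", "read_manifest",
]

TRAIN_ANGLES_DEG = (-30, -20, -10, 0, 10, 20, 30)
SLICES_PER_TRAIN_VOI = len(TRAIN_ANGLES_DEG) ** 2 * 2  # 7x7 grid, mirrored
MODEL_SIZE = 128


@dataclass
class VOIVolume:
    """Cubic volume of interest around one tumor."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    tumor_long_diameter_mm: float

    def __post_init__(self):
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 3-D")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")

    @property
    def is_isotropic(self):
        s = self.spacing_mm
        return abs(s[0] - s[1]) < 1e-9 and abs(s[1] - s[2]) < 1e-9

    @property
    def is_cubic(self):
        n = self.voxels.shape
        return n[0] == n[1] == n[2]


@dataclass
class ObliqueSlice:
    """One extracted 2-D HU slice with its slicing geometry."""

    image: np.ndarray
    angle_lr_deg: int
    angle_ht_deg: int
    mirrored: bool


@dataclass
class SlicePair:
    """A co-registered (CT render, sketch/edge) training pair."""

    ct_image: np.ndarray        # 128x128x3 uint8, three equal channels
    sketch_image: np.ndarray    # 128x128 uint8, values in {0, 255}
    angle_lr_deg: int = 0
    angle_ht_deg: int = 0
    mirrored: bool = False

    def __post_init__(self):
        if self.ct_image.shape[:2] != self.sketch_image.shape:
            raise ValueError("ct and sketch images must share spatial shape")
        if not np.all(np.isin(np.unique(self.sketch_image), (0, 255))):
            raise ValueError("sketch values must lie in {0, 255}")


@dataclass(frozen=True)
class WindowSpec:
    """Display window (level/width in HU); default is the lung window."""

    level: float = -600.0
    width: float = 1600.0

    def __post_init__(self):
        if not self.width > 0:
            raise ValueError("window width must be positive")


@dataclass(frozen=True)
class CannySpec:
    gaussian_kernel: int = 5
    low_threshold: int = 128
    high_threshold: int = 200

    def __post_init__(self):
        if self.gaussian_kernel < 1 or self.gaussian_kernel % 2 == 0:
            raise ValueError("gaussian_kernel must be a positive odd integer")
        if not 0 <= self.low_threshold < self.high_threshold <= 255:
            raise ValueError("need 0 <= low < high <= 255")


# ---------------------------------------------------------------------------
# 3-D stages

def crop_voi(volume: AnnotatedVolume) -> VOIVolume:
    """Crop a cube of physical side twice the tumor long diameter.

    The cube is centered on the annotated tumor center; voxels falling
    outside the source volume are padded with air (-1000 HU).
    """
    if volume.tumor_long_diameter_mm is None:
        raise ValueError("missing tumor annotation")
    d = volume.tumor_long_diameter_mm
    if not d > 0:
        raise ValueError("tumor long diameter must be positive")
    side_mm = 2.0 * d
    n = [int(round(side_mm / s)) for s in volume.spacing_mm]
    out = np.full(n, HU_PAD, dtype=volume.voxels.dtype)
    src, dst = [], []
    for ax in range(3):
        lo = volume.tumor_center_voxel[ax] - n[ax] // 2
        hi = lo + n[ax]
        src_lo, src_hi = max(lo, 0), min(hi, volume.voxels.shape[ax])
        src.append(slice(src_lo, src_hi))
        dst.append(slice(src_lo - lo, src_hi - lo))
    out[tuple(dst)] = volume.voxels[tuple(src)]
    return VOIVolume(out, volume.spacing_mm, d)


def resample_isotropic(voi: VOIVolume, target_mm: float = 0.625) -> VOIVolume:
    """Trilinear resampling to an isotropic voxel grid."""
    if not target_mm > 0:
        raise ValueError("target spacing must be positive")
    factors = [s / target_mm for s in voi.spacing_mm]
    if all(abs(f - 1.0) < 1e-9 for f in factors):
        return VOIVolume(voi.voxels.copy(), (target_mm,) * 3,
                         voi.tumor_long_diameter_mm)
    # resample onto an exactly cubic grid spanning the VOI's physical
    # side (2 x long diameter), centered on the cube center
    n_out = int(round(2.0 * voi.tumor_long_diameter_mm / target_mm))
    axes = []
    for ax in range(3):
        n_in = voi.voxels.shape[ax]
        c = (np.arange(n_out) - (n_out - 1) / 2.0) \
            * (target_mm / voi.spacing_mm[ax]) + (n_in - 1) / 2.0
        axes.append(c)
    grid = np.meshgrid(*axes, indexing="ij")
    vox = ndimage.map_coordinates(
        voi.voxels, [g.ravel() for g in grid], order=1,
        mode="nearest").reshape(n_out, n_out, n_out)
    return VOIVolume(vox, (target_mm,) * 3, voi.tumor_long_diameter_mm)


def extract_slices(voi: VOIVolume, train_mode: bool) -> list[ObliqueSlice]:
    """Extract the representative axial slice, or the training slice set.

    ``train_mode=False``: the single central axial plane. ``train_mode=True``:
    oblique planes through the cube center for every angle pair in the 7x7
    grid of 10-degree steps up to +/-30 degrees (left-right and head-tail
    tilts), each emitted unmirrored and left-right mirrored: 98 slices.
    """
    if not voi.is_cubic:
        raise ValueError("VOI must be cubic before slicing")
    n = voi.voxels.shape[0]
    c = (n - 1) / 2.0
    u = np.arange(n) - c
    uu, vv = np.meshgrid(u, u, indexing="ij")
    base = np.stack([uu.ravel(), vv.ravel(), np.zeros(n * n)])

    def plane(theta_lr, theta_ht):
        if theta_lr == 0 and theta_ht == 0:
            return voi.voxels[:, :, int(round(c))].astype(float)
        a, b = np.deg2rad(theta_lr), np.deg2rad(theta_ht)
        ry = np.array([[np.cos(a), 0, np.sin(a)],
                       [0, 1, 0],
                       [-np.sin(a), 0, np.cos(a)]])
        rx = np.array([[1, 0, 0],
                       [0, np.cos(b), -np.sin(b)],
                       [0, np.sin(b), np.cos(b)]])
        pts = (rx @ ry) @ base + c
        return ndimage.map_coordinates(
            voi.voxels, pts, order=1, mode="nearest").reshape(n, n)

    if not train_mode:
        return [ObliqueSlice(plane(0, 0), 0, 0, False)]

    out = []
    for t_lr in TRAIN_ANGLES_DEG:
        for t_ht in TRAIN_ANGLES_DEG:
            img = plane(t_lr, t_ht)
            out.append(ObliqueSlice(img, t_lr, t_ht, False))
            out.append(ObliqueSlice(np.fliplr(img), t_lr, t_ht, True))
    return out


# ---------------------------------------------------------------------------
# 2-D stages

def apply_window(hu_image, spec: WindowSpec = WindowSpec()) -> np.ndarray:
    """Linear HU -> 8-bit display mapping, clipped, rounded half-up."""
    if not spec.width > 0:
        raise ValueError("window width must be positive")
    lo = spec.level - spec.width / 2.0
    scaled = (np.asarray(hu_image, dtype=float) - lo) / spec.width * 255.0
    return np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8)


def resize_to_model(image, size: int = MODEL_SIZE) -> np.ndarray:
    """Bilinear resize of a square image to the model input size."""
    img = np.asarray(image)
    if img.shape[0] != img.shape[1]:
        raise ValueError("input must be square")
    if img.shape[0] == size:
        return img.copy()
    out = _sk_resize(img.astype(float), (size, size), order=1,
                     preserve_range=True, anti_aliasing=False)
    if np.issubdtype(img.dtype, np.integer):
        return np.clip(np.floor(out + 0.5), 0, 255).astype(img.dtype)
    return out


_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)


def _gaussian_kernel1d(ksize):
    # sigma tied to kernel size by the usual smoothing convention
    sigma = 0.3 * ((ksize - 1) * 0.5 - 1) + 0.8
    x = np.arange(ksize) - (ksize - 1) / 2.0
    k = np.exp(-(x ** 2) / (2 * sigma ** 2))
    return k / k.sum()


def canny_edges(ct_image_8bit, spec: CannySpec = CannySpec()) -> np.ndarray:
    """Canny edge detection on an 8-bit grayscale image.

    Four stages: 5x5 Gaussian smoothing, Sobel gradients, non-maximum
    suppression along the gradient normal, and hysteresis thresholding on
    the raw Sobel magnitude (weak >= low, strong >= high, 8-connected
    linking).  Output is binary {0, 255}.
    """
    img = np.asarray(ct_image_8bit, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    k1 = _gaussian_kernel1d(spec.gaussian_kernel)
    sm = ndimage.correlate1d(img, k1, axis=0, mode="mirror")
    sm = ndimage.correlate1d(sm, k1, axis=1, mode="mirror")
    gx = ndimage.correlate(sm, _SOBEL_X, mode="mirror")
    gy = ndimage.correlate(sm, _SOBEL_X.T, mode="mirror")
    mag = np.hypot(gx, gy)

    # non-maximum suppression with direction quantized to 4 sectors
    angle = np.rad2deg(np.arctan2(gy, gx)) % 180.0
    nms = np.zeros_like(mag)
    padded = np.pad(mag, 1, mode="constant")
    offs = {0: ((0, 1), (0, -1)), 45: ((1, 1), (-1, -1)),
            90: ((1, 0), (-1, 0)), 135: ((1, -1), (-1, 1))}
    sector = (np.floor((angle + 22.5) / 45.0).astype(int) % 4) * 45
    for sec, ((di1, dj1), (di2, dj2)) in offs.items():
        m = sector == sec
        n1 = padded[1 + di1:padded.shape[0] - 1 + di1,
                    1 + dj1:padded.shape[1] - 1 + dj1]
        n2 = padded[1 + di2:padded.shape[0] - 1 + di2,
                    1 + dj2:padded.shape[1] - 1 + dj2]
        # strict on one side so a symmetric (tied) edge keeps one pixel
        keep = m & (mag > n1) & (mag >= n2)
        nms[keep] = mag[keep]

    weak = nms >= spec.low_threshold
    strong = nms >= spec.high_threshold
    labels, n = ndimage.label(weak, structure=np.ones((3, 3)))
    if n == 0:
        return np.zeros_like(img, dtype=np.uint8)
    has_strong = ndimage.maximum(strong, labels, index=np.arange(1, n + 1))
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = has_strong > 0
    return keep[labels].astype(np.uint8) * 255


def binarize_sketch(scanned_image, threshold: int) -> np.ndarray:
    """Binarize a scanned dark-on-light sketch: pixels < threshold become
    strokes (255), the rest background (0)."""
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    img = np.asarray(scanned_image)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    return np.where(img < threshold, 255, 0).astype(np.uint8)


# ---------------------------------------------------------------------------
# Full pipeline and I/O

def preprocess_volume(volume: AnnotatedVolume, train_mode: bool,
                      window: WindowSpec = WindowSpec(),
                      canny: CannySpec = CannySpec(),
                      target_mm: float = 0.625,
                      size: int = MODEL_SIZE) -> list[SlicePair]:
    """Annotated volume -> list of (CT render, edge) slice pairs.

    ``size`` is the model resolution (128 for the production pipeline);
    edges are always detected at that scale so strokes stay connected.
    """
    voi = resample_isotropic(crop_voi(volume), target_mm)
    pairs = []
    for sl in extract_slices(voi, train_mode):
        hu = resize_to_model(sl.image, size)
        ct8 = apply_window(hu, window)
        edges = canny_edges(ct8, canny)
        pairs.append(SlicePair(
            ct_image=np.stack([ct8] * 3, axis=-1),
            sketch_image=edges,
            angle_lr_deg=sl.angle_lr_deg,
            angle_ht_deg=sl.angle_ht_deg,
            mirrored=sl.mirrored,
        ))
    return pairs


def write_ct_png(ct_image, path):
    """Save a CT render as 24-bit RGB PNG (three equal channels)."""
    img = np.asarray(ct_image)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    Image.fromarray(img.astype(np.uint8), mode="RGB").save(path)


def write_sketch_png(sketch_image, path):
    """Save a sketch/edge image as 8-bit grayscale PNG."""
    Image.fromarray(np.asarray(sketch_image).astype(np.uint8),
                    mode="L").save(path)


def read_png(path):
    img = Image.open(path)
    return np.asarray(img)


def write_manifest(rows, path):
    """Write the pair manifest CSV: one row per slice pair."""
    cols = ["ct_path", "sketch_path", "voi_id", "angle_lr", "angle_ht",
            "mirrored", "class"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_manifest(path):
    return pd.read_csv(path)


def export_pairs(pairs, voi_id, label, out_dir):
    """Write a VOI's slice pairs as PNGs; returns manifest rows."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, p in enumerate(pairs):
        ct_path = out_dir / f"{voi_id}_{k:03d}_ct.png"
        sk_path = out_dir / f"{voi_id}_{k:03d}_edge.png"
        write_ct_png(p.ct_image, ct_path)
        write_sketch_png(p.sketch_image, sk_path)
        rows.append([str(ct_path), str(sk_path), voi_id, p.angle_lr_deg,
                     p.angle_ht_deg, p.mirrored, label])
    return rows
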