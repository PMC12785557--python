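"""Image preprocessing for RISH micrographs.

The canonical chain is min-max normalization to [0, 1], per-RGB-channel
CLAHE (clip limit 2.0 in 8-bit histogram units, 8x8-pixel tiles), and a
3x3 Gaussian blur with sigma 1.0, followed by tiling into non-overlapping
64x64 patches for the patch-based segmentation model. Stitching is the
exact inverse of patch extraction (reflect padding is cropped away), so
``stitch_patches(extract_patches(x)) == x`` bit-exactly.

``RishPreprocessor`` wraps the enhancement chain as a stateless
scikit-learn transformer so it can sit in a sklearn ``Pipeline``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "PreprocessConfig",
    "PatchGrid",
    "RishPreprocessor",
    "minmax_normalize",
    "enhance",
    "extract_patches",
    "stitch_patches",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters.

    clahe_clip_limit is expressed in the conventional 8-bit histogram
    units (2.0 means twice the uniform bin height); clahe_tile_grid is
    the contextual tile side in pixels.
    """

    clahe_clip_limit: float = 2.0
    clahe_tile_grid: int = 8
    gaussian_kernel: int = 3
    gaussian_sigma: float = 1.0
    patch_size: int = 64
    per_channel_norm: bool = False

    def __post_init__(self) -> None:
        if min(self.clahe_clip_limit, self.clahe_tile_grid, self.gaussian_sigma) <= 0:
            raise ValueError("CLAHE/Gaussian parameters must be positive")
        if self.patch_size < 8:
            raise ValueError("patch_size must be >= 8")
        if self.gaussian_kernel % 2 != 1 or self.gaussian_kernel < 1:
            raise ValueError("gaussian_kernel must be odd and positive")


def minmax_normalize(image: np.ndarray, per_channel: bool = False) -> np.ndarray:
    """Scale intensities to [0, 1] by the global (or per-channel) min/max.

    A constant image maps to all zeros (the degenerate denominator is
    treated as 1) and logs a warning.
    """
    x = np.asarray(image, dtype=np.float64)
    axes = (0, 1) if per_channel and x.ndim == 3 else None
    lo = x.min(axis=axes, keepdims=axes is not None)
    hi = x.max(axis=axes, keepdims=axes is not None)
    span = hi - lo
    if np.any(span == 0):
        logger.warning("constant image (or channel) in min-max normalization; "
                       "mapping to zeros")
    span = np.where(span == 0, 1.0, span)
    return (x - lo) / span


def enhance(image: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Per-channel CLAHE followed by Gaussian denoising.

    Accepts a raw [0, 255] or normalized [0, 1] image; CLAHE runs on an
    8-bit quantization of each color channel (256 histogram bins) and the
    result is returned in [0, 1]. The Gaussian kernel is truncated to the
    configured odd size.
    """
    cfg = cfg or PreprocessConfig()
    x = np.asarray(image, dtype=np.float64)
    if x.ndim == 2:
        x = x[..., None]
    h, w = x.shape[:2]
    if h < cfg.clahe_tile_grid or w < cfg.clahe_tile_grid:
        raise ValueError(
            f"image {h}x{w} smaller than one CLAHE tile "
            f"({cfg.clahe_tile_grid} px); use a smaller clahe_tile_grid"
        )
    if x.max() > 1.0:
        x = x / 255.0
    x = np.clip(x, 0.0, 1.0)
    out = np.empty_like(x)
    # skimage's normalized clip limit is the 8-bit clip over the bin count
    clip = cfg.clahe_clip_limit / 256.0
    for ch in range(x.shape[2]):
        chan8 = (x[..., ch] * 255.0).round().astype(np.uint8)
        out[..., ch] = exposure.equalize_adapthist(
            chan8, kernel_size=cfg.clahe_tile_grid, clip_limit=clip, nbins=256
        )
    radius = (cfg.gaussian_kernel - 1) // 2
    out = ndimage.gaussian_filter(
        out, sigma=(cfg.gaussian_sigma, cfg.gaussian_sigma, 0), radius=(radius, radius, 0)
    )
    return out[..., 0] if image.ndim == 2 else out


def preprocess_field(image: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Full chain: min-max normalize then enhance. Returns float64 in [0, 1]."""
    cfg = cfg or PreprocessConfig()
    return enhance(minmax_normalize(image, per_channel=cfg.per_channel_norm), cfg)


@dataclass
class PatchGrid:
    """Row-major tiling of a (reflect-padded) image into square patches."""

    patches: np.ndarray  # (n, ps, ps) or (n, ps, ps, C)
    origins: list[tuple[int, int]]  # top-left corner of each tile, padded frame
    padded_shape: tuple[int, int]
    original_shape: tuple[int, int]
    patch_size: int
    pad_mode: str = "reflect"


def extract_patches(image: np.ndarray, cfg: PreprocessConfig | None = None) -> PatchGrid:
    """Tile into non-overlapping patch_size squares, reflect-padding edges.

    The tile count is ceil(H/ps) * ceil(W/ps); padding is cropped away
    again by :func:`stitch_patches`.
    """
    cfg = cfg or PreprocessConfig()
    ps = cfg.patch_size
    x = np.asarray(image)
    if x.ndim not in (2, 3):
        raise ValueError("expected a 2-D mask or 3-D multichannel image")
    h, w = x.shape[:2]
    hp, wp = math.ceil(h / ps) * ps, math.ceil(w / ps) * ps
    pad = [(0, hp - h), (0, wp - w)] + [(0, 0)] * (x.ndim - 2)
    # reflect padding needs >= 2 pixels along the axis; fall back to edge
    mode = "reflect" if min(h, w) > 1 else "edge"
    xp = np.pad(x, pad, mode=mode)
    patches, origins = [], []
    for r in range(0, hp, ps):
        for c in range(0, wp, ps):
            patches.append(xp[r : r + ps, c : c + ps])
            origins.append((r, c))
    return PatchGrid(
        patches=np.stack(patches),
        origins=origins,
        padded_shape=(hp, wp),
        original_shape=(h, w),
        patch_size=ps,
        pad_mode=mode,
    )


def stitch_patches(grid: PatchGrid) -> np.ndarray:
    """Inverse of :func:`extract_patches`: place tiles, crop the padding."""
    ps = grid.patch_size
    hp, wp = grid.padded_shape
    expected = {
        (r, c) for r in range(0, hp, ps) for c in range(0, wp, ps)
    }
    if len(grid.origins) != len(grid.patches):
        raise ValueError("patch/origin count mismatch")
    if set(grid.origins) != expected or len(grid.origins) != len(expected):
        raise ValueError("patch grid incomplete or has duplicate origins")
    trailing = grid.patches.shape[3:]
    out = np.zeros((hp, wp) + trailing, dtype=grid.patches.dtype)
    for patch, (r, c) in zip(grid.patches, grid.origins):
        out[r : r + ps, c : c + ps] = patch
    h, w = grid.original_shape
    return out[:h, :w]


class RishPreprocessor(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer applying normalize + CLAHE + Gaussian.

    ``transform`` accepts a single (H, W, 3) image or a batch
    (N, H, W, 3) and returns float arrays in [0, 1] of the same shape.
    """

    def __init__(
        self,
        clahe_clip_limit: float = 2.0,
        clahe_tile_grid: int = 8,
        gaussian_kernel: int = 3,
        gaussian_sigma: float = 1.0,
        per_channel_norm: bool = False,
    ):
        self.clahe_clip_limit = clahe_clip_limit
        self.clahe_tile_grid = clahe_tile_grid
        self.gaussian_kernel = gaussian_kernel
        self.gaussian_sigma = gaussian_sigma
        self.per_channel_norm = per_channel_norm

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(
            clahe_clip_limit=self.clahe_clip_limit,
            clahe_tile_grid=self.clahe_tile_grid,
            gaussian_kernel=self.gaussian_kernel,
            gaussian_sigma=self.gaussian_sigma,
            per_channel_norm=self.per_channel_norm,
        )

    def fit(self, X=None, y=None):  # noqa: N803 - sklearn signature
        return self

    def transform(self, X) -> np.ndarray:  # noqa: N803
        X = np.asarray(X)
        cfg = self._config()
        if X.ndim == 3:
            return preprocess_field(X, cfg)
        if X.ndim == 4:
            return np.stack([preprocess_field(img, cfg) for img in X])
        raise ValueError("expected (H, W, 3) image or (N, H, W, 3) batch")
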