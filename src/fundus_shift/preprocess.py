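"""Fundus preprocessing: local-average-color subtraction, resizing, augmentation.

The contrast-enhancement step follows the widely used subtract-local-average
recipe for fundus photographs: per channel,

    x' = clip(alpha * (x - G_sigma * x) + offset, [0, 1])

with defaults alpha = 4 and offset = 0.5 - the [0,1]-scale analog of the
classical ``4*x - 4*blur(x) + 128`` formulation. The blur scale sigma is a
fraction of image width so the operation is invariant to resolution. All
convolutions use reflect padding to avoid dark-edge artifacts near the disc
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize
from skimage.transform import rotate as _sk_rotate

from .image import Image
from .kernels import blur_radius_for_sigma, gaussian_blur


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs for the preprocessing stage.

    graham_blur_sigma_frac : blur scale as a fraction of image width (default 1/30)
    graham_alpha : contrast gain on the local-average residual
    graham_offset : mid-gray level added back after subtraction
    target_size : output side length in pixels (square)
    hflip_prob / rotation_max_deg : training-time augmentation only
    norm_mean / norm_std : optional channel standardization at the scorer boundary
    """

    graham_blur_sigma_frac: float = 1.0 / 30.0
    graham_alpha: float = 4.0
    graham_offset: float = 0.5
    target_size: int = 224
    hflip_prob: float = 0.5
    rotation_max_deg: float = 15.0
    norm_mean: tuple[float, float, float] | None = None
    norm_std: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.target_size <= 0:
            raise ValueError("target_size must be positive")
        if not 0.0 <= self.hflip_prob <= 1.0:
            raise ValueError("hflip_prob must lie in [0, 1]")
        if not 0.0 <= self.graham_offset <= 1.0:
            raise ValueError("graham_offset must lie in [0, 1]")


def graham_preprocess(img: Image, cfg: PreprocessConfig) -> Image:
    """Subtract the local average color and recenter at ``graham_offset``.

    Applied per channel inside the fundus mask; pixels outside the mask are
    set to the offset so the background carries no signal.
    """
    sigma = cfg.graham_blur_sigma_frac * img.pixels.shape[1]
    if sigma <= 0:
        raise ValueError("blur sigma must be positive")
    radius = blur_radius_for_sigma(sigma)
    out = np.empty_like(img.pixels)
    for c in range(3):
        blurred = gaussian_blur(img.pixels[:, :, c], radius, sigma)
        out[:, :, c] = cfg.graham_alpha * (img.pixels[:, :, c] - blurred) + cfg.graham_offset
    np.clip(out, 0.0, 1.0, out=out)
    out[~img.mask] = cfg.graham_offset
    return Image(pixels=out, mask=img.mask.copy(), id=img.id, meta=dict(img.meta))


def resize_normalize(img: Image, target_size: int) -> Image:
    """Bilinear resize to a square raster; values stay in [0, 1]."""
    if target_size <= 0:
        raise ValueError("target_size must be positive")
    h, w = img.shape
    if (h, w) == (target_size, target_size):
        return Image(pixels=img.pixels.copy(), mask=img.mask.copy(),
                     id=img.id, meta=dict(img.meta))
    px = _sk_resize(img.pixels, (target_size, target_size), order=1,
                    mode="edge", anti_aliasing=False, preserve_range=True)
    mask = _sk_resize(img.mask.astype(np.float64), (target_size, target_size),
                      order=0, mode="edge", anti_aliasing=False,
                      preserve_range=True) > 0.5
    return Image(pixels=np.clip(px, 0.0, 1.0), mask=mask, id=img.id,
                 meta=dict(img.meta))


def standardize(pixels: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Optional channel-wise affine standardization at the scorer boundary."""
    if cfg.norm_mean is None or cfg.norm_std is None:
        return pixels
    mean = np.asarray(cfg.norm_mean, dtype=np.float64)
    std = np.asarray(cfg.norm_std, dtype=np.float64)
    return (pixels - mean[None, None, :]) / std[None, None, :]


def augment(img: Image, cfg: PreprocessConfig,
            rng: np.random.Generator) -> Image:
    """Training-time augmentation: random horizontal flip and small rotation.

    Rotation is bilinear about the image center; out-of-bounds pixels are
    filled with the mid-gray offset. Never applied on the evaluation path.
    """
    px = img.pixels
    mask = img.mask
    if cfg.hflip_prob > 0 and rng.random() < cfg.hflip_prob:
        px = px[:, ::-1, :]
        mask = mask[:, ::-1]
    angle = float(rng.uniform(-cfg.rotation_max_deg, cfg.rotation_max_deg)) \
        if cfg.rotation_max_deg > 0 else 0.0
    if angle != 0.0:
        px = _sk_rotate(px, angle, resize=False, order=1, mode="constant",
                        cval=cfg.graham_offset, preserve_range=True)
        mask = _sk_rotate(mask.astype(np.float64), angle, resize=False, order=0,
                          mode="constant", cval=0.0, preserve_range=True) > 0.5
    return Image(pixels=np.clip(np.ascontiguousarray(px), 0.0, 1.0),
                 mask=np.ascontiguousarray(mask), id=img.id, meta=dict(img.meta))
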