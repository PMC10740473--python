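"""Gaussian kernel machinery shared by the degradation operators and preprocessing.

All smoothing in the package goes through explicit, normalized, finite-support
Gaussian kernels with reflect (half-sample symmetric) boundary handling, so
every operator can be checked against a direct double-loop convolution.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage


def gaussian_kernel1d(radius: int, sigma: float) -> np.ndarray:
    """Normalized 1-D Gaussian kernel of length ``2*radius + 1``.

    Parameters
    ----------
    radius : int
        Half-width of the kernel support in pixels; ``radius=0`` yields ``[1.0]``.
    sigma : float
        Spatial constant of the Gaussian, in pixels. Must be positive.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if radius < 0:
        raise ValueError(f"radius must be non-negative, got {radius}")
    u = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-(u * u) / (2.0 * sigma * sigma))
    return k / k.sum()


def gaussian_kernel(radius: int, sigma: float) -> np.ndarray:
    """Normalized 2-D Gaussian kernel of shape ``(2*radius+1, 2*radius+1)``.

    Rotationally symmetric samples of ``exp(-(u^2+v^2) / (2 sigma^2))``,
    normalized to sum to one. Separable: equals the outer product of the
    normalized 1-D kernel with itself.
    """
    k1 = gaussian_kernel1d(radius, sigma)
    return np.outer(k1, k1)


def gaussian_blur(field: np.ndarray, radius: int, sigma: float) -> np.ndarray:
    """Convolve a 2-D field with the normalized Gaussian kernel, reflect padding.

    Implemented as two separable 1-D convolutions, mathematically identical to
    the full 2-D kernel because the normalized 2-D kernel factorizes exactly.
    """
    if field.ndim != 2:
        raise ValueError("gaussian_blur expects a 2-D field")
    if radius == 0:
        return field.astype(np.float64, copy=True)
    k1 = gaussian_kernel1d(radius, sigma)
    out = ndimage.convolve1d(field.astype(np.float64), k1, axis=0, mode="reflect")
    return ndimage.convolve1d(out, k1, axis=1, mode="reflect")


def blur_radius_for_sigma(sigma: float) -> int:
    """Default kernel half-width covering three standard deviations."""
    return max(1, int(math.ceil(3.0 * sigma)))
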