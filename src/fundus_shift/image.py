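"""Image container and PNG/CSV input-output.

The in-memory raster is always float RGB in [0, 1] with an optional boolean
mask marking the fundus disc (the circular imaged area of the retina); pixels
outside it are background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image as PILImage

_RANGE_TOL = 1e-9


@dataclass
class Image:
    """Float RGB raster in [0, 1] with a fundus-disc mask.

    Attributes
    ----------
    pixels : ndarray, shape (H, W, 3)
        Intensities in [0, 1].
    mask : ndarray of bool, shape (H, W)
        True inside the fundus disc. All-true when unknown.
    id : str
        Opaque identifier carried through the pipeline.
    meta : dict
        Free-form provenance (e.g. planted lesion centers for synthetic data).
    """

    pixels: np.ndarray
    mask: np.ndarray | None = None
    id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must have shape (H, W, 3), got {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image dimensions must be positive")
        if px.min() < -_RANGE_TOL or px.max() > 1.0 + _RANGE_TOL:
            raise ValueError("pixel values must lie in [0, 1]")
        self.pixels = np.clip(px, 0.0, 1.0)
        if self.mask is None:
            self.mask = np.ones(px.shape[:2], dtype=bool)
        else:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != px.shape[:2]:
                raise ValueError("mask shape must match pixel grid")
            self.mask = m

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


def disc_mask(height: int, width: int, radius: float,
              center: tuple[float, float] | None = None) -> np.ndarray:
    """Boolean mask of a filled disc; default center is the image center."""
    if center is None:
        center = ((height - 1) / 2.0, (width - 1) / 2.0)
    rr, cc = np.ogrid[:height, :width]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def save_png(img: Image, path: str | Path) -> None:
    """Write 8-bit RGB PNG; intensities scaled by 255 and rounded half-even."""
    arr = np.rint(img.pixels * 255.0).astype(np.uint8)
    PILImage.fromarray(arr, mode="RGB").save(Path(path))


def load_png(path: str | Path, id: str | None = None,
             estimate_mask: bool = True) -> Image:
    """Read an RGB PNG/JPEG into the float container.

    When ``estimate_mask`` is set, the fundus disc is estimated as the set of
    pixels noticeably brighter than the dark background (median intensity of
    the four 5x5 corner patches plus a small margin); otherwise the mask is
    all-true.
    """
    p = Path(path)
    arr = np.asarray(PILImage.open(p).convert("RGB"), dtype=np.float64) / 255.0
    mask = estimate_disc_mask(arr) if estimate_mask else None
    return Image(pixels=arr, mask=mask, id=id if id is not None else p.stem)


def estimate_disc_mask(pixels: np.ndarray) -> np.ndarray:
    """Heuristic fundus mask: pixels brighter than the corner background level."""
    lum = pixels.mean(axis=2)
    h, w = lum.shape
    k = max(1, min(5, h, w))
    corners = np.concatenate([
        lum[:k, :k].ravel(), lum[:k, -k:].ravel(),
        lum[-k:, :k].ravel(), lum[-k:, -k:].ravel(),
    ])
    background = float(np.median(corners))
    mask = lum > background + 0.02
    if not mask.any():  # flat image: treat everything as foreground
        return np.ones_like(mask)
    return mask


def write_labels_csv(path: str | Path, ids: list[str], labels: list[int]) -> None:
    pd.DataFrame({"id": ids, "label": labels}).to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str})
    if not {"id", "label"}.issubset(df.columns):
        raise ValueError("labels CSV must have columns id,label")
    return df
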