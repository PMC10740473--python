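"""Synthetic fundus-like images and prediction sets with known structure.

Real referable-DR screening data (fundus photographs plus a binary
referable/non-referable grade) is access-restricted, so the pipeline is
exercised on a geometric emulation: a dark background, a bright circular
retinal disc with mild radial shading and dark vessel arcs, and - for
positive cases - planted bright "lesion" blobs that play the role of the
exudates a grader would flag. The class signal is exactly the presence of
lesions, which gives the degradation operators a mechanistic way to destroy
it.

The second generator produces prediction sets (score, label pairs) with a
controlled calibration structure: scores are drawn from a named distribution
and labels from Bernoulli(g(score)) for a configurable link g. The identity
link is perfectly calibrated by construction; shift/temperature links give
controlled miscalibration whose true calibration error is known analytically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import LabeledDataset, LabeledItem
from .image import Image, disc_mask
from .metrics import PredictionSet

# ---------------------------------------------------------------------------
# fundus-like images


@dataclass(frozen=True)
class SyntheticImageParams:
    """Parameters of the geometric fundus emulation.

    Defaults give a 128x128 image with a disc filling 90% of the frame,
    reddish base color, six vessel arcs and, for positives, bright lesion
    bumps of Gaussian profile (sigma = lesion_radius_px / 2) and amplitude
    ``lesion_intensity``.
    """

    height: int = 128
    width: int = 128
    disc_radius_frac: float = 0.9
    background_level: float = 0.05
    disc_base_color: tuple[float, float, float] = (0.55, 0.30, 0.12)
    vessel_count: int = 6
    lesion_count_range: tuple[int, int] = (1, 4)
    lesion_intensity: float = 0.3
    lesion_radius_px: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("image dimensions must be positive")
        if not 0.0 < self.disc_radius_frac <= 1.0:
            raise ValueError("disc_radius_frac must lie in (0, 1]")
        for name in ("background_level", "lesion_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if any(not 0.0 <= c <= 1.0 for c in self.disc_base_color):
            raise ValueError("disc_base_color components must lie in [0, 1]")
        if self.vessel_count < 0:
            raise ValueError("vessel_count must be non-negative")
        lo, hi = self.lesion_count_range
        if lo < 0 or hi < lo:
            raise ValueError("lesion_count_range must be a non-negative interval")
        if self.lesion_radius_px <= 0:
            raise ValueError("lesion_radius_px must be positive")


# lesions are yellowish-white: strongest in red/green, weak in blue
_LESION_RGB = np.array([1.0, 0.9, 0.3])
_VESSEL_RGB = np.array([0.45, 0.35, 0.6])  # multiplicative darkening per channel


def synth_fundus_image(params: SyntheticImageParams,
                       rng: np.random.Generator | None = None
                       ) -> tuple[Image, int]:
    """Render one fundus-like image; label is 1 iff at least one lesion is planted.

    Deterministic given (params, rng state): calling with a freshly seeded
    generator reproduces the image bit for bit.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    radius = params.disc_radius_frac * min(h, w) / 2.0
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    mask = disc_mask(h, w, radius)

    yy, xx = np.mgrid[:h, :w]
    rho = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2) / max(radius, 1.0)

    gain = rng.uniform(0.85, 1.0)  # per-image illumination variation
    shading = 1.0 - 0.25 * np.clip(rho, 0.0, 1.0) ** 2
    pixels = np.full((h, w, 3), params.background_level, dtype=np.float64)
    base = np.asarray(params.disc_base_color)
    pixels[mask] = gain * shading[mask, None] * base[None, :]

    for _ in range(params.vessel_count):
        _draw_vessel(pixels, mask, (cy, cx), radius, rng)

    lo, hi = params.lesion_count_range
    n_lesions = int(rng.integers(lo, hi + 1))
    centers = []
    sigma = params.lesion_radius_px / 2.0
    for _ in range(n_lesions):
        theta = rng.uniform(0.0, 2.0 * math.pi)
        r = 0.75 * radius * math.sqrt(rng.uniform())
        ly, lx = cy + r * math.sin(theta), cx + r * math.cos(theta)
        bump = np.exp(-((yy - ly) ** 2 + (xx - lx) ** 2) / (2.0 * sigma**2))
        pixels += params.lesion_intensity * bump[:, :, None] * _LESION_RGB[None, None, :]
        centers.append((float(ly), float(lx)))

    np.clip(pixels, 0.0, 1.0, out=pixels)
    pixels[~mask] = params.background_level
    img = Image(pixels=pixels, mask=mask,
                meta={"lesion_centers": centers, "gain": gain})
    return img, int(n_lesions > 0)


def _draw_vessel(pixels: np.ndarray, mask: np.ndarray,
                 center: tuple[float, float], radius: float,
                 rng: np.random.Generator) -> None:
    """Darken a curved arc radiating from the disc center (a crude vessel)."""
    h, w = mask.shape
    cy, cx = center
    angle0 = rng.uniform(0.0, 2.0 * math.pi)
    curvature = rng.uniform(-1.5, 1.5)
    thickness = rng.uniform(0.8, 1.8)
    hit = np.zeros((h, w), dtype=bool)
    for t in np.linspace(0.02, 0.95, 120):
        theta = angle0 + curvature * t
        py = cy + t * radius * math.sin(theta)
        px = cx + t * radius * math.cos(theta)
        r = int(math.ceil(thickness))
        y0, y1 = max(0, int(py) - r), min(h, int(py) + r + 1)
        x0, x1 = max(0, int(px) - r), min(w, int(px) + r + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        sy, sx = np.ogrid[y0:y1, x0:x1]
        hit[y0:y1, x0:x1] |= (sy - py) ** 2 + (sx - px) ** 2 <= thickness**2
    hit &= mask
    pixels[hit] *= _VESSEL_RGB[None, :]


def synth_dataset(params: SyntheticImageParams, n: int, positive_frac: float,
                  rng: np.random.Generator | None = None) -> LabeledDataset:
    """Generate n images with exactly round(positive_frac * n) positives.

    Positives use the configured lesion count range clamped to at least one
    lesion; negatives carry no lesions. Each image gets its own child seed so
    datasets are reproducible item by item.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0.0 <= positive_frac <= 1.0:
        raise ValueError("positive_frac must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_pos = int(round(positive_frac * n))
    pos_idx = set(rng.permutation(n)[:n_pos].tolist())
    child_seeds = rng.integers(0, 2**31 - 1, size=n)

    lo, hi = params.lesion_count_range
    pos_params = replace(params, lesion_count_range=(max(1, lo), max(1, hi)))
    neg_params = replace(params, lesion_count_range=(0, 0))

    items = []
    for i in range(n):
        p = pos_params if i in pos_idx else neg_params
        img, label = synth_fundus_image(p, np.random.default_rng(int(child_seeds[i])))
        img.id = f"img_{i:05d}"
        items.append(LabeledItem(id=img.id, image=img, label=label))
    return LabeledDataset(items, metadata={"source": "synthetic",
                                           "n": n, "positive_frac": positive_frac})


# ---------------------------------------------------------------------------
# prediction sets with controlled calibration


@dataclass(frozen=True)
class CalibrationScenario:
    """Score distribution plus link g from score to true event probability.

    ``link='identity'`` is perfectly calibrated by construction:
    P(Y=1 | f=p) = p. A 'shift' link g(p) = clip(p - delta, 0, 1) models an
    overconfident model; 'temperature' applies g(p) = sigmoid(logit(p)/T);
    'constant' ignores the score entirely.
    """

    n: int
    score_dist: str = "uniform"
    score_params: dict = field(default_factory=dict)
    link: str = "identity"
    link_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if self.score_dist not in ("uniform", "beta", "constant"):
            raise ValueError(f"unknown score distribution {self.score_dist!r}")
        if self.link not in ("identity", "shift", "temperature", "constant"):
            raise ValueError(f"unknown link {self.link!r}")

    def draw_scores(self, rng: np.random.Generator) -> np.ndarray:
        p = self.score_params
        if self.score_dist == "uniform":
            lo, hi = p.get("low", 0.0), p.get("high", 1.0)
            if not 0.0 <= lo <= hi <= 1.0:
                raise ValueError("uniform score bounds must satisfy 0 <= low <= high <= 1")
            return rng.uniform(lo, hi, size=self.n)
        if self.score_dist == "beta":
            return rng.beta(p["a"], p["b"], size=self.n)
        return np.full(self.n, float(p["value"]))

    def apply_link(self, scores: np.ndarray) -> np.ndarray:
        p = self.link_params
        if self.link == "identity":
            probs = scores
        elif self.link == "shift":
            probs = np.clip(scores - p["delta"], 0.0, 1.0)
        elif self.link == "temperature":
            t = p["t"]
            eps = 1e-12
            logit = np.log(np.clip(scores, eps, 1 - eps) /
                           np.clip(1.0 - scores, eps, 1 - eps))
            probs = 1.0 / (1.0 + np.exp(-logit / t))
        else:
            probs = np.full_like(scores, float(p["value"]))
        if probs.min() < 0.0 or probs.max() > 1.0:
            raise ValueError("link must map scores into [0, 1]")
        return probs


def synth_predictions(scenario: CalibrationScenario,
                      rng: np.random.Generator | None = None) -> PredictionSet:
    """Draw scores from the scenario's distribution and labels ~ Bernoulli(g(score))."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    scores = scenario.draw_scores(rng)
    probs = scenario.apply_link(scores)
    labels = (rng.uniform(size=scenario.n) < probs).astype(np.int64)
    return PredictionSet(scores=scores, labels=labels)
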