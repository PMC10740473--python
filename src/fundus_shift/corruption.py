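"""Fundus-specific image degradations for distribution-shift evaluation.

Three acquisition-time degradation mechanisms are modeled, each applied to
the raw image before preprocessing:

* **Light transmission disturbance** - stray light and uneven sensitivity
  produce over-/under-exposure. An illumination bias panel J (a hard disc of
  signed amplitude ``bias_level`` centered at (a, b) with radius r_L) is
  smoothed by a Gaussian kernel G_L and combined with contrast/brightness
  factors: ``x' = clip(alpha * (G_L * J) + x + beta, [0, s])``.
* **Image blurring** - defocus, motion or media opacity (e.g. cataract):
  ``x' = clip(G_B * x + n, [0, 1])`` where n is i.i.d. additive Gaussian
  sensor noise.
* **Retinal artifact** - dust and grains on the imaging optics: a sum of K
  Gaussian-smoothed disc bumps of disc radius r_k/4, kernel spread sigma_k
  and signed luminance bias o_k, added to the image and clipped.

All operators are deterministic given their config and seed, preserve labels
by construction (only pixels change) and keep outputs in range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import LabeledDataset, LabeledItem
from .image import Image, disc_mask
from .kernels import blur_radius_for_sigma, gaussian_blur, gaussian_kernel

# re-exported: the kernel constructor is part of this module's public surface
__all__ = [
    "LightTransmissionConfig", "BlurConfig", "ArtifactConfig",
    "gaussian_kernel", "corrupt_light", "corrupt_blur", "corrupt_artifact",
    "apply_shift", "severity_config", "SHIFT_NAMES", "SEVERITY_NAMES",
]


@dataclass(frozen=True)
class LightTransmissionConfig:
    """alpha/beta/s are contrast, brightness and saturation (clip bound) factors;
    the panel J sits at ``center`` = (row, col) with radius r_L and is smoothed
    by a Gaussian of spatial constant sigma_L; ``bias_level`` > 0 over-illuminates,
    < 0 under-illuminates."""

    alpha: float = 1.0
    beta: float = 0.0
    s: float = 1.0
    center: tuple[float, float] = (0.0, 0.0)
    r_L: float = 32.0
    sigma_L: float = 12.0
    bias_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r_L <= 0:
            raise ValueError("r_L must be positive")
        if self.sigma_L <= 0:
            raise ValueError("sigma_L must be positive")
        if not 0.0 < self.s <= 1.0:
            raise ValueError("saturation bound s must lie in (0, 1]")


@dataclass(frozen=True)
class BlurConfig:
    """Gaussian blur of kernel radius r_B / spatial constant sigma_B plus
    additive Gaussian sensor noise of standard deviation noise_sigma."""

    r_B: int = 5
    sigma_B: float = 2.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r_B < 0:
            raise ValueError("r_B must be non-negative")
        if self.sigma_B <= 0:
            raise ValueError("sigma_B must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass(frozen=True)
class ArtifactConfig:
    """K dust/grain artifacts: disc bumps of radius r_k/4 smoothed with spread
    sigma_k and signed luminance bias o_k, centers uniform on the fundus mask."""

    K: int = 10
    radius_range: tuple[float, float] = (8.0, 24.0)
    sigma_range: tuple[float, float] = (1.5, 3.0)
    bias_range: tuple[float, float] = (-0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError("K must be non-negative")
        if not 0 < self.radius_range[0] <= self.radius_range[1]:
            raise ValueError("radius_range must be a positive interval")
        if not 0 < self.sigma_range[0] <= self.sigma_range[1]:
            raise ValueError("sigma_range must be a positive interval")
        if self.bias_range[0] > self.bias_range[1]:
            raise ValueError("bias_range must be a non-empty interval")


def corrupt_light(img: Image, cfg: LightTransmissionConfig,
                  rng: np.random.Generator | None = None) -> Image:
    """Apply the light-transmission disturbance.

    The kernel shares the panel radius: G_L has half-width round(r_L) and
    spatial constant sigma_L. ``rng`` is accepted for interface uniformity;
    the operator is fully determined by its config.
    """
    h, w = img.shape
    a, b = cfg.center
    if not (0 <= a < h and 0 <= b < w):
        raise ValueError(f"panel center {cfg.center} outside image bounds {(h, w)}")
    panel = np.where(disc_mask(h, w, cfg.r_L, center=(a, b)), cfg.bias_level, 0.0)
    radius = int(round(cfg.r_L))
    smoothed = gaussian_blur(panel, radius, cfg.sigma_L) if radius > 0 else panel
    out = np.clip(cfg.alpha * smoothed[:, :, None] + img.pixels + cfg.beta,
                  0.0, cfg.s)
    return Image(pixels=out, mask=img.mask.copy(), id=img.id, meta=dict(img.meta))


def corrupt_blur(img: Image, cfg: BlurConfig,
                 rng: np.random.Generator | None = None) -> Image:
    """Gaussian blur (reflect padding) followed by additive Gaussian noise."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    out = np.empty_like(img.pixels)
    for c in range(3):
        out[:, :, c] = gaussian_blur(img.pixels[:, :, c], cfg.r_B, cfg.sigma_B)
    if cfg.noise_sigma > 0:
        out += rng.normal(0.0, cfg.noise_sigma, size=out.shape)
    np.clip(out, 0.0, 1.0, out=out)
    return Image(pixels=out, mask=img.mask.copy(), id=img.id, meta=dict(img.meta))


def corrupt_artifact(img: Image, cfg: ArtifactConfig,
                     rng: np.random.Generator | None = None) -> Image:
    """Add K Gaussian-smoothed disc bumps at random positions on the fundus."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if cfg.K == 0:
        return Image(pixels=img.pixels.copy(), mask=img.mask.copy(),
                     id=img.id, meta=dict(img.meta))
    flat = np.flatnonzero(img.mask)
    if flat.size == 0:
        raise ValueError("cannot place artifacts: fundus mask is empty")
    h, w = img.shape
    centers = flat[rng.integers(0, flat.size, size=cfg.K)]
    radii = rng.uniform(*cfg.radius_range, size=cfg.K)
    sigmas = rng.uniform(*cfg.sigma_range, size=cfg.K)
    biases = rng.uniform(*cfg.bias_range, size=cfg.K)

    field = np.zeros((h, w), dtype=np.float64)
    for k in range(cfg.K):
        cy, cx = divmod(int(centers[k]), w)
        bump = disc_mask(h, w, radii[k] / 4.0, center=(cy, cx)).astype(np.float64)
        kr = blur_radius_for_sigma(float(sigmas[k]))
        field += biases[k] * gaussian_blur(bump, kr, float(sigmas[k]))
    out = np.clip(img.pixels + field[:, :, None], 0.0, 1.0)
    return Image(pixels=out, mask=img.mask.copy(), id=img.id, meta=dict(img.meta))


# ---------------------------------------------------------------------------
# severity presets and dataset-level application

SHIFT_NAMES = ("light", "blur", "artifact")
SEVERITY_NAMES = ("none", "low", "mid", "high")

# pixel quantities below are stated for a 128-px image side and scaled by
# min(H, W) / 128 at application time
_LIGHT_PRESETS = {
    "low": dict(alpha=1.0, beta=0.03, s=1.0, bias=0.08, r_frac=0.30),
    "mid": dict(alpha=1.0, beta=0.06, s=1.0, bias=0.18, r_frac=0.35),
    "high": dict(alpha=1.0, beta=0.12, s=0.95, bias=0.35, r_frac=0.40),
}
_BLUR_PRESETS = {
    "low": dict(sigma=1.0, noise=0.005),
    "mid": dict(sigma=3.0, noise=0.01),
    "high": dict(sigma=8.0, noise=0.02),
}
_ARTIFACT_PRESETS = {
    "low": dict(K=4, radius=(8.0, 16.0), sigma=(1.0, 2.0), bias=(-0.15, 0.15)),
    "mid": dict(K=12, radius=(10.0, 24.0), sigma=(1.5, 3.0), bias=(-0.25, 0.25)),
    "high": dict(K=30, radius=(12.0, 40.0), sigma=(2.0, 4.0), bias=(-0.4, 0.4)),
}


def severity_config(shift: str, severity: str, img: Image,
                    rng: np.random.Generator, seed: int = 0):
    """Materialize a per-image corruption config from a named severity preset.

    Random elements (panel center and illumination sign for the light shift)
    are drawn from ``rng``; pixel-scale parameters scale with image size.
    Returns None for severity 'none'.
    """
    if shift not in SHIFT_NAMES:
        raise ValueError(f"unknown shift {shift!r}; expected one of {SHIFT_NAMES}")
    if severity not in SEVERITY_NAMES:
        raise ValueError(f"unknown severity {severity!r}; expected one of {SEVERITY_NAMES}")
    if severity == "none":
        return None
    h, w = img.shape
    scale = min(h, w) / 128.0
    if shift == "light":
        p = _LIGHT_PRESETS[severity]
        # panel center uniform in the central half of the frame
        a = rng.uniform(0.25 * h, 0.75 * h)
        b = rng.uniform(0.25 * w, 0.75 * w)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        r_l = p["r_frac"] * min(h, w)
        return LightTransmissionConfig(
            alpha=p["alpha"], beta=sign * p["beta"], s=p["s"], center=(a, b),
            r_L=r_l, sigma_L=r_l / 3.0, bias_level=sign * p["bias"], seed=seed)
    if shift == "blur":
        p = _BLUR_PRESETS[severity]
        sigma = p["sigma"] * scale
        return BlurConfig(r_B=blur_radius_for_sigma(sigma), sigma_B=sigma,
                          noise_sigma=p["noise"], seed=seed)
    p = _ARTIFACT_PRESETS[severity]
    return ArtifactConfig(
        K=p["K"],
        radius_range=(p["radius"][0] * scale, p["radius"][1] * scale),
        sigma_range=(p["sigma"][0] * scale, p["sigma"][1] * scale),
        bias_range=p["bias"], seed=seed)


_OPERATORS = {"light": corrupt_light, "blur": corrupt_blur,
              "artifact": corrupt_artifact}


def apply_shift(dataset: LabeledDataset, shift: str, severity_preset: str,
                seed: int) -> LabeledDataset:
    """Corrupt every image in a dataset with per-image derived seeds.

    Image i uses seed ``seed + i`` so datasets are reproducible item by item
    and images can be regenerated independently. Labels are untouched;
    provenance (shift, severity, seed, per-image parameters) is recorded in
    the returned dataset's metadata.
    """
    if shift not in SHIFT_NAMES:
        raise ValueError(f"unknown shift {shift!r}; expected one of {SHIFT_NAMES}")
    if severity_preset not in SEVERITY_NAMES:
        raise ValueError(f"unknown severity {severity_preset!r}; "
                         f"expected one of {SEVERITY_NAMES}")
    if severity_preset == "none":
        meta = dict(dataset.metadata)
        meta.update({"shift": shift, "severity": "none", "seed": seed})
        return LabeledDataset(list(dataset.items), metadata=meta)
    op = _OPERATORS[shift]

    items = []
    manifest = []
    for i, item in enumerate(dataset.items):
        item_seed = seed + i
        rng = np.random.default_rng(item_seed)
        cfg = severity_config(shift, severity_preset, item.image, rng,
                              seed=item_seed)
        corrupted = op(item.image, cfg, rng)
        items.append(LabeledItem(id=item.id, image=corrupted, label=item.label))
        manifest.append({"id": item.id, "seed": item_seed,
                         "config": _config_record(cfg)})
    meta = dict(dataset.metadata)
    meta.update({"shift": shift, "severity": severity_preset, "seed": seed,
                 "per_image": manifest})
    return LabeledDataset(items, metadata=meta)


def _config_record(cfg) -> dict:
    rec = {}
    for name, value in vars(cfg).items():
        if isinstance(value, tuple):
            rec[name] = [float(v) for v in value]
        elif isinstance(value, (int, np.integer)):
            rec[name] = int(value)
        else:
            rec[name] = float(value)
    return rec
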