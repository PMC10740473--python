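"""Tests for the three fundus degradation operators and dataset-level shifts."""

import numpy as np
import pytest
from skimage import measure

from fundus_shift import (ArtifactConfig, BlurConfig, Image,
                          LightTransmissionConfig, apply_shift,
                          corrupt_artifact, corrupt_blur, corrupt_light,
                          gaussian_kernel, synth_dataset)
from fundus_shift.kernels import blur_radius_for_sigma
from fundus_shift.synthetic import SyntheticImageParams
from _oracles import conv2d_reflect, gaussian_kernel_direct


class TestGaussianKernel:
    def test_radius_zero(self):
        np.testing.assert_array_equal(gaussian_kernel(0, 1.0), [[1.0]])

    @pytest.mark.parametrize("radius,sigma", [(1, 1.0), (3, 0.7), (5, 4.2)])
    def test_normalized_and_symmetric(self, radius, sigma):
        k = gaussian_kernel(radius, sigma)
        assert k.shape == (2 * radius + 1, 2 * radius + 1)
        assert abs(k.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(k, k.T, atol=1e-15)
        np.testing.assert_allclose(k, k[::-1, ::-1], atol=1e-15)
        np.testing.assert_allclose(k, gaussian_kernel_direct(radius, sigma),
                                   atol=1e-15)

    def test_center_weight_closed_form(self):
        # 3x3, sigma=1: center = 1 / (1 + 4 e^-1/2 + 4 e^-1)
        expected = 1.0 / (1.0 + 4 * np.exp(-0.5) + 4 * np.exp(-1.0))
        assert gaussian_kernel(1, 1.0)[1, 1] == pytest.approx(expected, abs=1e-12)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            gaussian_kernel(1, 0.0)


class TestCorruptLight:
    def test_zero_bias_identity(self, random_image):
        cfg = LightTransmissionConfig(bias_level=0.0, beta=0.0, s=1.0,
                                      center=(4, 4), r_L=2.0, sigma_L=1.0)
        out = corrupt_light(random_image, cfg)
        np.testing.assert_array_equal(out.pixels, random_image.pixels)

    def test_brightness_saturation(self, random_image):
        cfg = LightTransmissionConfig(bias_level=0.0, beta=1.0, s=1.0,
                                      center=(4, 4), r_L=2.0, sigma_L=1.0)
        out = corrupt_light(random_image, cfg)
        assert (out.pixels == 1.0).all()

    def test_scalar_case(self):
        """1x1 image 0.4, panel bias 0.2 covering the pixel, radius-0 kernel,
        alpha=1, beta=0.1 -> 1*0.2 + 0.4 + 0.1 = 0.7."""
        img = Image(pixels=np.full((1, 1, 3), 0.4))
        cfg = LightTransmissionConfig(alpha=1.0, beta=0.1, s=1.0,
                                      center=(0, 0), r_L=0.4, sigma_L=1.0,
                                      bias_level=0.2)
        out = corrupt_light(img, cfg)
        np.testing.assert_allclose(out.pixels, 0.7, atol=1e-12)

    def test_center_outside_image(self, random_image):
        cfg = LightTransmissionConfig(center=(100, 0), r_L=2.0, sigma_L=1.0)
        with pytest.raises(ValueError):
            corrupt_light(random_image, cfg)

    def test_monotone_under_positive_bias(self, random_image):
        """Positive illumination bias and brightness never darken a pixel
        below its unclipped value."""
        cfg = LightTransmissionConfig(alpha=1.0, beta=0.05, s=1.0,
                                      center=(4, 4), r_L=3.0, sigma_L=1.5,
                                      bias_level=0.2)
        out = corrupt_light(random_image, cfg)
        assert (out.pixels >= np.minimum(random_image.pixels, 1.0) - 1e-12).all()

    def test_matches_direct_convolution(self, random_image):
        cfg = LightTransmissionConfig(alpha=1.3, beta=0.02, s=0.97,
                                      center=(3, 5), r_L=2.0, sigma_L=1.1,
                                      bias_level=-0.15)
        out = corrupt_light(random_image, cfg)
        h, w = 8, 8
        panel = np.zeros((h, w))
        for y in range(h):
            for x in range(w):
                if (y - 3) ** 2 + (x - 5) ** 2 <= cfg.r_L**2:
                    panel[y, x] = cfg.bias_level
        smoothed = conv2d_reflect(panel, gaussian_kernel(2, cfg.sigma_L))
        expected = np.clip(cfg.alpha * smoothed[:, :, None]
                           + random_image.pixels + cfg.beta, 0.0, cfg.s)
        np.testing.assert_allclose(out.pixels, expected, atol=1e-10)


class TestCorruptBlur:
    def test_identity(self, random_image):
        cfg = BlurConfig(r_B=0, sigma_B=1.0, noise_sigma=0.0)
        out = corrupt_blur(random_image, cfg)
        np.testing.assert_array_equal(out.pixels, random_image.pixels)

    def test_constant_eigenfunction(self, flat_image):
        cfg = BlurConfig(r_B=3, sigma_B=1.5, noise_sigma=0.0)
        out = corrupt_blur(flat_image, cfg)
        np.testing.assert_allclose(out.pixels, 0.5, atol=1e-12)

    def test_impulse_center_weight(self):
        px = np.zeros((3, 3, 3))
        px[1, 1, :] = 1.0
        out = corrupt_blur(Image(pixels=px), BlurConfig(r_B=1, sigma_B=1.0))
        expected = 1.0 / (1.0 + 4 * np.exp(-0.5) + 4 * np.exp(-1.0))
        assert out.pixels[1, 1, 0] == pytest.approx(expected, abs=1e-12)

    def test_matches_direct_convolution(self, random_image):
        cfg = BlurConfig(r_B=2, sigma_B=1.4, noise_sigma=0.0)
        out = corrupt_blur(random_image, cfg)
        kern = gaussian_kernel(2, 1.4)
        for c in range(3):
            expected = np.clip(conv2d_reflect(random_image.pixels[:, :, c], kern),
                               0.0, 1.0)
            np.testing.assert_allclose(out.pixels[:, :, c], expected, atol=1e-10)

    def test_reduces_total_variation(self, rng):
        """Noise-free blurring smooths: total variation never increases."""
        def tv(a):
            return np.abs(np.diff(a, axis=0)).sum() + np.abs(np.diff(a, axis=1)).sum()
        for _ in range(5):
            img = Image(pixels=rng.uniform(size=(12, 12, 3)))
            out = corrupt_blur(img, BlurConfig(r_B=2, sigma_B=1.0))
            assert tv(out.pixels) <= tv(img.pixels) + 1e-12

    def test_noise_is_seeded(self, random_image):
        cfg = BlurConfig(r_B=1, sigma_B=1.0, noise_sigma=0.05, seed=42)
        a = corrupt_blur(random_image, cfg)
        b = corrupt_blur(random_image, cfg)
        np.testing.assert_array_equal(a.pixels, b.pixels)


class TestCorruptArtifact:
    def test_zero_artifacts_identity(self, random_image):
        out = corrupt_artifact(random_image, ArtifactConfig(K=0))
        np.testing.assert_array_equal(out.pixels, random_image.pixels)

    def test_single_bump_topology(self):
        """One positive-bias artifact on a flat field raises exactly one
        connected region, bounded by disc area plus kernel support."""
        img = Image(pixels=np.full((24, 24, 3), 0.3))
        cfg = ArtifactConfig(K=1, radius_range=(8.0, 8.0),
                             sigma_range=(1.0, 1.0), bias_range=(0.2, 0.2),
                             seed=7)
        out = corrupt_artifact(img, cfg)
        raised = out.pixels[:, :, 0] > 0.3 + 1e-9
        assert measure.label(raised).max() == 1
        disc_r = 8.0 / 4.0 + blur_radius_for_sigma(1.0)
        assert raised.sum() <= np.pi * disc_r**2 + 4 * disc_r

    def test_two_plateaus_superposition(self):
        """Two non-overlapping near-delta-smoothed bumps of bias 0.1 on a flat
        0.2 field give two plateaus at 0.3."""
        img = Image(pixels=np.full((32, 32, 3), 0.2))
        cfg = ArtifactConfig(K=2, radius_range=(8.0, 8.0),
                             sigma_range=(0.05, 0.05), bias_range=(0.1, 0.1),
                             seed=3)
        out = corrupt_artifact(img, cfg)
        plateau = np.isclose(out.pixels[:, :, 0], 0.3, atol=1e-6)
        regions = measure.label(plateau).max()
        assert regions == 2  # seed chosen so the sampled centers do not overlap
        assert out.pixels.max() == pytest.approx(0.3, abs=1e-6)

    def test_empty_mask_error(self):
        img = Image(pixels=np.full((8, 8, 3), 0.5),
                    mask=np.zeros((8, 8), dtype=bool))
        with pytest.raises(ValueError):
            corrupt_artifact(img, ArtifactConfig(K=1))

    def test_matches_direct_superposition(self, random_image):
        """Replays the operator's own parameter draws and rebuilds the field
        with the double-loop convolution oracle."""
        cfg = ArtifactConfig(K=3, radius_range=(4.0, 10.0),
                             sigma_range=(0.8, 1.5), bias_range=(-0.2, 0.2),
                             seed=11)
        out = corrupt_artifact(random_image, cfg)

        rng = np.random.default_rng(11)
        flat = np.flatnonzero(random_image.mask)
        centers = flat[rng.integers(0, flat.size, size=3)]
        radii = rng.uniform(4.0, 10.0, size=3)
        sigmas = rng.uniform(0.8, 1.5, size=3)
        biases = rng.uniform(-0.2, 0.2, size=3)
        field = np.zeros((8, 8))
        for k in range(3):
            cy, cx = divmod(int(centers[k]), 8)
            bump = np.zeros((8, 8))
            for y in range(8):
                for x in range(8):
                    if (y - cy) ** 2 + (x - cx) ** 2 <= (radii[k] / 4.0) ** 2:
                        bump[y, x] = 1.0
            kr = blur_radius_for_sigma(float(sigmas[k]))
            field += biases[k] * conv2d_reflect(bump, gaussian_kernel(kr, float(sigmas[k])))
        expected = np.clip(random_image.pixels + field[:, :, None], 0.0, 1.0)
        np.testing.assert_allclose(out.pixels, expected, atol=1e-10)


@pytest.fixture(scope="module")
def tiny_dataset():
    params = SyntheticImageParams(height=48, width=48, seed=2,
                                  lesion_radius_px=3.0)
    return synth_dataset(params, 8, 0.5, np.random.default_rng(2))


class TestApplyShift:

    def test_none_severity_unchanged(self, tiny_dataset):
        out = apply_shift(tiny_dataset, "blur", "none", seed=0)
        for a, b in zip(out, tiny_dataset):
            np.testing.assert_array_equal(a.image.pixels, b.image.pixels)

    @pytest.mark.parametrize("shift", ["light", "blur", "artifact"])
    def test_deterministic_and_label_preserving(self, tiny_dataset, shift):
        a = apply_shift(tiny_dataset, shift, "mid", seed=5)
        b = apply_shift(tiny_dataset, shift, "mid", seed=5)
        assert list(a.labels) == list(tiny_dataset.labels)
        for ia, ib in zip(a, b):
            np.testing.assert_array_equal(ia.image.pixels, ib.image.pixels)
        for ia, ic in zip(a, tiny_dataset):
            assert ia.image.pixels.min() >= 0.0 and ia.image.pixels.max() <= 1.0
            assert not np.array_equal(ia.image.pixels, ic.image.pixels)

    def test_provenance_recorded(self, tiny_dataset):
        out = apply_shift(tiny_dataset, "artifact", "low", seed=9)
        assert out.metadata["shift"] == "artifact"
        assert out.metadata["severity"] == "low"
        assert out.metadata["seed"] == 9
        assert len(out.metadata["per_image"]) == len(tiny_dataset)

    def test_unknown_names(self, tiny_dataset):
        with pytest.raises(ValueError):
            apply_shift(tiny_dataset, "snow", "mid", seed=0)
        with pytest.raises(ValueError):
            apply_shift(tiny_dataset, "blur", "extreme", seed=0)
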