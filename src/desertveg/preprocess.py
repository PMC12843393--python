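"""Three-stage preprocessing applied before feature extraction.

The chain, in order:

1. **Gaussian denoising** of each RGB channel (default sigma = 1.0 px,
   kernel truncated at 4 sigma, reflective padding) to suppress sensor
   noise.
2. **Illumination normalization**: histogram equalization of the V channel
   in HSV space, ``V' = (L - 1) * CDF(V)`` with ``L = 256`` gray levels and
   the inclusive empirical CDF, so the top occupied level always maps
   to 1.0 and the induced intensity map is monotone non-decreasing.
3. **Bilateral smoothing** (defaults sigma_d = 9 px, sigma_r = 75 on the
   0-255 intensity axis), edge-preserving; all three RGB channels share a
   common range weight computed from the Euclidean RGB color distance, so
   the stage is a single standard color bilateral filter rather than three
   independent ones, and iso-luminant chroma edges are preserved.

Each RGB-domain stage re-quantizes to 8 bits by rounding half away from
zero, which makes the whole chain bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .color import hsv_to_rgb, quantize_u8, rgb_to_hsv
from .exceptions import InputError, ParameterError

__all__ = [
    "PreprocessParams",
    "gaussian_denoise",
    "equalize_value_channel",
    "bilateral_smooth",
    "preprocess",
]

#: bilateral window truncation, in units of sigma_d
BILATERAL_TRUNCATE = 2.0
#: Gaussian kernel truncation, in units of sigma
GAUSSIAN_TRUNCATE = 4.0


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters of the preprocessing chain (defaults are the method's)."""

    gaussian_sigma: float = 1.0
    bilateral_sigma_d: float = 9.0
    bilateral_sigma_r: float = 75.0
    gray_levels_L: int = 256

    def __post_init__(self):
        if self.gaussian_sigma <= 0:
            raise ParameterError("gaussian_sigma must be positive")
        if self.bilateral_sigma_d <= 0 or self.bilateral_sigma_r <= 0:
            raise ParameterError("bilateral sigmas must be positive")
        if self.gray_levels_L < 2:
            raise ParameterError("gray_levels_L must be >= 2")


def _check_rgb_u8(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3 or img.size == 0:
        raise InputError(f"expected a non-empty HxWx3 RGB image, got shape {img.shape}")
    return img


def gaussian_denoise(img: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Isotropic Gaussian smoothing of each channel, 8-bit in and out."""
    img = _check_rgb_u8(img)
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    out = np.empty(img.shape, dtype=np.float64)
    for c in range(3):
        ndimage.gaussian_filter(
            img[..., c].astype(np.float64),
            sigma=sigma,
            mode="reflect",
            truncate=GAUSSIAN_TRUNCATE,
            output=out[..., c],
        )
    return quantize_u8(out)


def equalize_value_channel(hsv: np.ndarray, L: int = 256) -> np.ndarray:
    """Histogram-equalize the V channel of an HSV image; H and S untouched.

    V is quantized to ``L`` levels; level ``v`` maps to
    ``floor((L - 1) * CDF(v)) / (L - 1)`` with the inclusive empirical CDF
    ``P(X <= v)``, computed in exact integer arithmetic.
    """
    hsv = np.asarray(hsv, dtype=np.float64)
    if hsv.ndim != 3 or hsv.shape[2] != 3:
        raise InputError(f"expected an HxWx3 HSV image, got shape {hsv.shape}")
    if L < 2:
        raise ParameterError(f"L must be >= 2, got {L}")
    v = hsv[..., 2]
    if np.any(v < 0) or np.any(v > 1):
        raise InputError("V channel must lie in [0, 1]")

    levels = np.minimum((v * L).astype(np.int64), L - 1)
    counts = np.bincount(levels.ravel(), minlength=L)
    cum = np.cumsum(counts)  # inclusive CDF numerator
    n = levels.size
    mapped_levels = (L - 1) * cum // n  # exact floor((L-1)*CDF)
    v_eq = mapped_levels[levels] / (L - 1)

    out = hsv.copy()
    out[..., 2] = v_eq
    return out


def bilateral_smooth(
    img: np.ndarray, sigma_d: float = 9.0, sigma_r: float = 75.0
) -> np.ndarray:
    """Edge-preserving color bilateral smoothing of an 8-bit RGB image.

    The spatial kernel is a Gaussian of scale ``sigma_d`` truncated at
    2 sigma_d; the range kernel is a Gaussian of scale ``sigma_r`` on the
    Euclidean RGB color distance (0-255 per axis), shared by the three
    channels — the standard color bilateral, which preserves iso-luminant
    chroma edges (vegetation against equally bright soil) as well as
    brightness edges. Reflective padding.
    """
    img = _check_rgb_u8(img)
    if sigma_d <= 0 or sigma_r <= 0:
        raise ParameterError("bilateral sigmas must be positive")

    radius = int(np.ceil(BILATERAL_TRUNCATE * sigma_d))
    rgb = img.astype(np.float64)
    # np.pad 'symmetric' == scipy.ndimage 'reflect' (half-sample symmetry)
    pad_rgb = np.pad(rgb, ((radius, radius), (radius, radius), (0, 0)), mode="symmetric")

    h, w = rgb.shape[:2]
    acc = np.zeros_like(rgb)
    norm = np.zeros((h, w))
    inv2sd2 = 1.0 / (2.0 * sigma_d**2)
    inv2sr2 = 1.0 / (2.0 * sigma_r**2)
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            sw = np.exp(-(dy * dy + dx * dx) * inv2sd2)
            shifted = pad_rgb[radius + dy : radius + dy + h, radius + dx : radius + dx + w]
            dist2 = np.sum((shifted - rgb) ** 2, axis=-1)
            wgt = sw * np.exp(-dist2 * inv2sr2)
            norm += wgt
            acc += wgt[..., None] * shifted
    return quantize_u8(acc / norm[..., None])


def preprocess(
    img: np.ndarray, params: PreprocessParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Run the full chain; return the preprocessed RGB image and its HSV form.

    Gaussian denoise -> HSV -> equalize V -> back to RGB -> bilateral. The
    returned HSV image is the representation of the final RGB image (hue in
    degrees, S and V in [0, 1]) ready for feature extraction.
    """
    params = params or PreprocessParams()
    img = _check_rgb_u8(img)
    smoothed = gaussian_denoise(img, params.gaussian_sigma)
    hsv = rgb_to_hsv(smoothed)
    hsv_eq = equalize_value_channel(hsv, params.gray_levels_L)
    rgb_eq = hsv_to_rgb(hsv_eq)
    rgb_out = bilateral_smooth(rgb_eq, params.bilateral_sigma_d, params.bilateral_sigma_r)
    return rgb_out, rgb_to_hsv(rgb_out)
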