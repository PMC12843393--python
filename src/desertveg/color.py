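"""Color-space conversion and spectral vegetation indices.

HSV convention used throughout the package: hue in degrees in ``[0, 360)``,
saturation and value dimensionless in ``[0, 1]``. The conversion follows the
classic hexcone model: with ``m = max(r, g, b)`` and ``n = min(r, g, b)``,

* ``H = 0`` when ``m = n``; otherwise 60° times the fractional sector offset
  of the dominant channel, wrapped into ``[0, 360)``,
* ``S = 0`` when ``m = 0``, else ``(m - n) / m``,
* ``V = m`` (channels normalized to ``[0, 1]``).

The two spectral baselines are the excess-green index ``ExG = 2G - R - B``
(high over vegetation) and the color index of vegetation extraction
``CIVE = 0.441 R - 0.811 G + 0.385 B + 18.78745`` (low over vegetation, the
green channel entering with a large negative weight). Both are evaluated on
raw 8-bit channel values. Each index is typically followed by Otsu
thresholding on the vegetation-bearing side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateInputError, InputError, ParameterError

__all__ = [
    "IndexImage",
    "rgb_to_hsv",
    "hsv_to_rgb",
    "excess_green",
    "cive_index",
    "otsu_threshold",
    "otsu_scalar",
]

#: additive constant of the CIVE linear combination
CIVE_OFFSET = 18.78745
CIVE_COEFFS = (0.441, -0.811, 0.385)

#: which side of an Otsu threshold is vegetation, per index
INDEX_POLARITY = {"ExG": "above", "CIVE": "below"}


@dataclass(frozen=True)
class IndexImage:
    """A real-valued spectral-index image plus the index it came from."""

    values: np.ndarray
    index_name: str

    def __post_init__(self):
        if self.index_name not in INDEX_POLARITY:
            raise ParameterError(f"unknown index {self.index_name!r}")

    @property
    def vegetation_side(self) -> str:
        return INDEX_POLARITY[self.index_name]


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3 or img.size == 0:
        raise InputError(f"expected a non-empty HxWx3 RGB image, got shape {img.shape}")
    return img


def rgb_to_hsv(img: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to HSV (hue in degrees, S and V in [0,1]).

    Hand-rolled rather than delegated so the hue-degree convention and the
    ``m = n -> H = 0``, ``m = 0 -> S = 0`` degenerate cases are exactly the
    documented ones.
    """
    img = _check_rgb(img)
    rgb = img.astype(np.float64) / 255.0
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    m = np.max(rgb, axis=-1)
    n = np.min(rgb, axis=-1)
    delta = m - n

    safe = np.where(delta > 0, delta, 1.0)
    h = np.zeros_like(m)
    # first-match channel ordering r, g, b for ties on the max
    is_r = (m == r) & (delta > 0)
    is_g = (m == g) & ~is_r & (delta > 0)
    is_b = (delta > 0) & ~is_r & ~is_g
    h = np.where(is_r, (60.0 * (g - b) / safe + 360.0) % 360.0, h)
    h = np.where(is_g, (60.0 * (b - r) / safe + 120.0) % 360.0, h)
    h = np.where(is_b, (60.0 * (r - g) / safe + 240.0) % 360.0, h)

    s = np.where(m > 0, delta / np.where(m > 0, m, 1.0), 0.0)
    return np.stack([h, s, m], axis=-1)


def hsv_to_rgb(hsv: np.ndarray) -> np.ndarray:
    """Invert :func:`rgb_to_hsv`, returning an 8-bit RGB image.

    Exact inverse up to 8-bit rounding (round half away from zero).
    """
    hsv = np.asarray(hsv, dtype=np.float64)
    if hsv.ndim != 3 or hsv.shape[2] != 3:
        raise InputError(f"expected an HxWx3 HSV image, got shape {hsv.shape}")
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    if np.any(h < 0) or np.any(h >= 360):
        raise InputError("hue must lie in [0, 360)")

    hp = h / 60.0
    c = v * s
    x = c * (1.0 - np.abs(hp % 2.0 - 1.0))
    base = v - c
    sector = np.floor(hp).astype(int) % 6
    zeros = np.zeros_like(c)
    # per-sector (R,G,B) offsets before adding the common base value
    r = np.choose(sector, [c, x, zeros, zeros, x, c])
    g = np.choose(sector, [x, c, c, x, zeros, zeros])
    b = np.choose(sector, [zeros, zeros, x, c, c, x])
    rgb = np.stack([r, g, b], axis=-1) + base[..., None]
    return quantize_u8(rgb * 255.0)


def quantize_u8(arr: np.ndarray) -> np.ndarray:
    """Clip to [0, 255] and round half away from zero to uint8."""
    return np.floor(np.clip(arr, 0.0, 255.0) + 0.5).astype(np.uint8)


def excess_green(img: np.ndarray) -> IndexImage:
    """ExG = 2G - R - B on raw 0-255 channel values."""
    img = _check_rgb(img).astype(np.float64)
    vals = 2.0 * img[..., 1] - img[..., 0] - img[..., 2]
    return IndexImage(vals, "ExG")


def cive_index(img: np.ndarray) -> IndexImage:
    """CIVE = 0.441 R - 0.811 G + 0.385 B + 18.78745 on raw 0-255 values."""
    img = _check_rgb(img).astype(np.float64)
    cr, cg, cb = CIVE_COEFFS
    vals = cr * img[..., 0] + cg * img[..., 1] + cb * img[..., 2] + CIVE_OFFSET
    return IndexImage(vals, "CIVE")


def otsu_scalar(values: np.ndarray, n_bins: int = 256) -> float:
    """Otsu threshold of a real-valued array over an ``n_bins`` histogram.

    The histogram spans the observed min-max range. Candidate thresholds are
    the interior bin edges; the returned threshold maximizes the
    between-class variance ``w0 * w1 * (mu0 - mu1)**2``, with the lowest
    maximizing edge chosen on ties. Values ``>= threshold`` fall in the
    upper class.
    """
    if n_bins < 2:
        raise ParameterError(f"n_bins must be >= 2, got {n_bins}")
    vals = np.asarray(values, dtype=np.float64).ravel()
    if vals.size == 0:
        raise InputError("empty index image")
    lo, hi = vals.min(), vals.max()
    if lo == hi:
        raise DegenerateInputError("constant index image has no Otsu threshold")

    counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
    counts = counts.astype(np.float64)
    total = counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])

    w0 = np.cumsum(counts)[:-1]  # mass strictly below edge k+1
    w1 = total - w0
    csum = np.cumsum(counts * centers)[:-1]
    tsum = (counts * centers).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = csum / w0
        mu1 = (tsum - csum) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    k = int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximum
    return float(edges[k + 1])


def otsu_threshold(
    index: IndexImage | np.ndarray, n_bins: int = 256
) -> tuple[float, np.ndarray]:
    """Otsu-threshold an index image on its vegetation-bearing side.

    Returns ``(threshold, mask)`` with ``mask`` boolean, True = vegetation:
    ``values >= threshold`` for ExG (vegetation is bright), ``values <
    threshold`` for CIVE (vegetation is dark). A plain array is treated as
    an above-threshold index.
    """
    if isinstance(index, IndexImage):
        values, side = index.values, index.vegetation_side
    else:
        values, side = np.asarray(index), "above"
    t = otsu_scalar(values, n_bins=n_bins)
    mask = values >= t if side == "above" else values < t
    return t, mask
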