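"""Dense per-pixel gray-level co-occurrence (GLCM) texture features.

For every pixel, a ``window x window`` neighborhood (default 7x7, reflective
padding) of the quantized gray image is summarized by four Haralick-style
statistics of its co-occurrence matrix at pixel distance ``d`` (default 1),
computed for the four orientations 0°, 45°, 90°, 135° and averaged over
orientations:

* contrast     ``sum (i - j)^2 P(i, j)``            (0 for a flat window)
* homogeneity  ``sum P(i, j) / (1 + |i - j|)``      (1 for a flat window)
* energy       ``sum P(i, j)^2``                    (1 for a flat window)
* correlation  ``sum (i - mu_i)(j - mu_j) P(i, j) / (sigma_i sigma_j)``

Pairs are counted symmetrically (each neighboring pair contributes in both
directions) and normalized to probabilities, so both marginals of ``P``
coincide. A window with zero marginal variance has undefined correlation;
it is defined as 1 here (a constant patch is perfectly self-correlated).

The dense extractor is vectorized: contrast, homogeneity and the correlation
moments are sliding-window sums of per-pair maps, and energy uses a
sort-and-run-length identity (``sum of c^2`` over run lengths ``c`` equals
``sum over elements of (2 r - 1)`` with ``r`` the rank within its run).
It is numerically identical (to float precision) to recomputing
:func:`glcm_window` + :func:`glcm_props` at every pixel.

The feature vector fed to the classifier stacks color and texture per pixel
in the fixed order (H, S, V, contrast, homogeneity, energy, correlation),
with hue rescaled from degrees to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import DegenerateInputError, InputError, ParameterError

__all__ = [
    "GLCMMatrix",
    "TextureFeatures",
    "quantize_gray",
    "glcm_window",
    "glcm_props",
    "dense_texture",
    "assemble_features",
    "ANGLES",
]

#: the four orientations, degrees -> (row, col) offset at distance 1
ANGLES = (0, 45, 90, 135)
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class GLCMMatrix:
    """A normalized, symmetric co-occurrence matrix with its provenance."""

    P: np.ndarray
    gray_levels: int
    distance: int
    angle: int


@dataclass(frozen=True)
class TextureFeatures:
    contrast: float
    homogeneity: float
    energy: float
    correlation: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.contrast, self.homogeneity, self.energy, self.correlation]
        )


def quantize_gray(gray: np.ndarray, G: int) -> np.ndarray:
    """Uniformly quantize a [0, 1] gray image into integer levels 0..G-1."""
    if G < 2:
        raise ParameterError(f"G must be >= 2, got {G}")
    gray = np.asarray(gray, dtype=np.float64)
    if np.any(gray < 0) or np.any(gray > 1):
        raise InputError("gray values must lie in [0, 1]")
    return np.minimum((gray * G).astype(np.int64), G - 1)


def glcm_window(
    window: np.ndarray, d: int = 1, angle: int = 0, G: int | None = None
) -> GLCMMatrix:
    """Symmetric, normalized GLCM of one quantized window at offset (d, angle).

    Every pair of pixels separated by the offset is counted in both
    directions, then the count matrix is normalized to sum 1.
    """
    window = np.asarray(window)
    if angle not in _OFFSETS:
        raise ParameterError(f"angle must be one of {ANGLES}, got {angle}")
    if d < 1:
        raise ParameterError(f"d must be >= 1, got {d}")
    dr, dc = (o * d for o in _OFFSETS[angle])
    h, w = window.shape
    if h <= abs(dr) or w <= abs(dc):
        raise DegenerateInputError(
            f"window {window.shape} too small for offset ({dr}, {dc})"
        )
    if G is None:
        G = int(window.max()) + 1

    ra = slice(max(0, -dr), h - max(0, dr))
    ca = slice(max(0, -dc), w - max(0, dc))
    rb = slice(max(0, dr), h + min(0, dr))
    cb = slice(max(0, dc), w + min(0, dc))
    a = window[ra, ca].ravel()
    b = window[rb, cb].ravel()

    P = np.zeros((G, G), dtype=np.float64)
    np.add.at(P, (a, b), 1.0)
    np.add.at(P, (b, a), 1.0)
    return GLCMMatrix(P / P.sum(), G, d, angle)


def glcm_props(P: np.ndarray | GLCMMatrix) -> TextureFeatures:
    """Contrast, homogeneity, energy and correlation of a normalized GLCM."""
    if isinstance(P, GLCMMatrix):
        P = P.P
    P = np.asarray(P, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise InputError(f"P must be square, got shape {P.shape}")
    if not np.isclose(P.sum(), 1.0):
        raise InputError("P must be normalized to sum 1")

    G = P.shape[0]
    i, j = np.meshgrid(np.arange(G), np.arange(G), indexing="ij")
    diff = i - j
    contrast = float(np.sum(diff**2 * P))
    homogeneity = float(np.sum(P / (1.0 + np.abs(diff))))
    energy = float(np.sum(P**2))

    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    lv = np.arange(G, dtype=np.float64)
    mu_i = float(pi @ lv)
    mu_j = float(pj @ lv)
    var_i = float(pi @ (lv - mu_i) ** 2)
    var_j = float(pj @ (lv - mu_j) ** 2)
    if var_i <= 0 or var_j <= 0:
        correlation = 1.0  # constant window: perfectly self-correlated
    else:
        correlation = float(
            np.sum((i - mu_i) * (j - mu_j) * P) / np.sqrt(var_i * var_j)
        )
    return TextureFeatures(contrast, homogeneity, energy, correlation)


def _window_sums(pair_map: np.ndarray, wr: int, wc: int) -> np.ndarray:
    """Sliding-window sums of shape-(wr, wc) windows of a 2-D map."""
    return sliding_window_view(pair_map, (wr, wc)).sum(axis=(-2, -1))


def dense_texture(
    gray: np.ndarray,
    window: int = 7,
    d: int = 1,
    G: int = 32,
    angles: tuple[int, ...] = ANGLES,
) -> np.ndarray:
    """Per-pixel orientation-averaged GLCM features of a [0, 1] gray image.

    Returns an ``H x W x 4`` float array ordered (contrast, homogeneity,
    energy, correlation). Borders use reflective padding so every pixel has
    a full centered window.
    """
    if window % 2 == 0 or window < 3:
        raise ParameterError(f"window must be odd and >= 3, got {window}")
    if d < 1:
        raise ParameterError(f"d must be >= 1, got {d}")
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise InputError(f"expected a 2-D gray image, got shape {gray.shape}")
    if gray.shape[0] < window or gray.shape[1] < window:
        raise InputError(f"image {gray.shape} smaller than the {window}x{window} window")
    if window <= d:
        raise ParameterError("window must exceed the pair distance d")

    levels = quantize_gray(gray, G)
    rad = window // 2
    # np.pad 'symmetric' == half-sample reflection, matches the oracle
    pad = np.pad(levels, rad, mode="symmetric")
    h, w = gray.shape

    feats = np.zeros((h, w, 4), dtype=np.float64)
    for angle in angles:
        # normalize offsets to dr >= 0; symmetric counting makes the sign
        # of the offset irrelevant, so (-1, 1) and (1, -1) give the same GLCM
        odr, odc = _OFFSETS[angle]
        dr, dc = odr * d, odc * d
        if dr < 0:
            dr, dc = -dr, -dc

        hp, wp = pad.shape
        a = pad[: hp - dr, max(0, -dc) : wp - max(0, dc)]
        b = pad[dr:, max(0, dc) : wp - max(0, -dc)]
        af = a.astype(np.float64)
        bf = b.astype(np.float64)

        wr, wc = window - dr, window - abs(dc)
        n_pairs = wr * wc  # directed pairs per window, one direction

        da = np.abs(a - b)
        s_contrast = _window_sums((da.astype(np.float64)) ** 2, wr, wc)
        s_homog = _window_sums(1.0 / (1.0 + da), wr, wc)
        s_ab = _window_sums(af * bf, wr, wc)
        s_sum = _window_sums(af + bf, wr, wc)
        s_sq = _window_sums(af**2 + bf**2, wr, wc)

        contrast = s_contrast / n_pairs
        homog = s_homog / n_pairs
        mu = s_sum / (2.0 * n_pairs)
        var = s_sq / (2.0 * n_pairs) - mu**2
        cov = s_ab / n_pairs - mu**2
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = cov / var
        corr = np.where(var > 1e-12, corr, 1.0)

        # energy via sorted pair codes: sum over runs of c^2 == sum (2r - 1)
        codes_a = (a * G + b).astype(np.int32)
        codes_b = (b * G + a).astype(np.int32)
        win_a = sliding_window_view(codes_a, (wr, wc)).reshape(h, w, n_pairs)
        win_b = sliding_window_view(codes_b, (wr, wc)).reshape(h, w, n_pairs)
        codes = np.sort(np.concatenate([win_a, win_b], axis=-1), axis=-1)
        m = codes.shape[-1]
        pos = np.arange(m)
        newflag = np.ones(codes.shape, dtype=bool)
        newflag[..., 1:] = codes[..., 1:] != codes[..., :-1]
        start = np.maximum.accumulate(np.where(newflag, pos, 0), axis=-1)
        rank = pos - start + 1
        sum_c2 = np.sum(2 * rank - 1, axis=-1)
        energy = sum_c2 / float(m) ** 2

        feats[..., 0] += contrast
        feats[..., 1] += homog
        feats[..., 2] += energy
        feats[..., 3] += corr

    feats /= len(angles)
    return feats


def assemble_features(hsv: np.ndarray, texture: np.ndarray) -> np.ndarray:
    """Stack per-pixel color and texture into the 7-channel feature array.

    Channel order (H/360, S, V, contrast, homogeneity, energy, correlation);
    hue is rescaled to [0, 1] so all channels are comparable before
    standardization. Hue circularity is not modeled.
    """
    hsv = np.asarray(hsv, dtype=np.float64)
    texture = np.asarray(texture, dtype=np.float64)
    if hsv.ndim != 3 or hsv.shape[2] != 3:
        raise InputError(f"expected HxWx3 HSV, got shape {hsv.shape}")
    if texture.ndim != 3 or texture.shape[2] != 4:
        raise InputError(f"expected HxWx4 texture, got shape {texture.shape}")
    if hsv.shape[:2] != texture.shape[:2]:
        raise InputError(
            f"spatial shapes differ: {hsv.shape[:2]} vs {texture.shape[:2]}"
        )
    scaled = hsv.copy()
    scaled[..., 0] /= 360.0
    return np.concatenate([scaled, texture], axis=-1)
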