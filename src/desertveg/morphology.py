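"""Morphological refinement of predicted vegetation masks.

The refinement chain is opening with a 3x3 circular element (removes
isolated false-positive pixels), closing with a 5x5 circular element (fills
small gaps inside vegetation), then a 3x3 median filter (smooths boundaries),
in that order.

Discrete "circular" footprints: the 3x3 element is the radius-1 diamond
(center + 4-neighbors, 5 pixels); the 5x5 element is the radius-2 disk
(13 pixels). Erosion pads with True and dilation with False outside the
image, which keeps opening anti-extensive, closing extensive, and the
duality ``closing(m) == ~opening(~m)`` exact including borders. The median
of a binary window is its strict majority vote (ties impossible with odd
windows); reflective padding.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .exceptions import InputError, ParameterError

__all__ = [
    "disk_footprint",
    "binary_opening",
    "binary_closing",
    "median_smooth",
    "postprocess_mask",
]


def disk_footprint(size: int) -> np.ndarray:
    """Discrete disk inscribed in a ``size x size`` box (size odd).

    size 3 -> radius-1 diamond (5 px); size 5 -> radius-2 disk (13 px).
    """
    if size % 2 == 0 or size < 1:
        raise ParameterError(f"footprint size must be odd and >= 1, got {size}")
    r = size // 2
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    # r=1: the 5-px diamond; r=2: the 13-px disk
    return (y * y + x * x) <= r * r


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.size == 0:
        raise InputError(f"expected a non-empty 2-D binary mask, got shape {mask.shape}")
    return mask.astype(bool)


def binary_opening(mask: np.ndarray, footprint: np.ndarray | None = None) -> np.ndarray:
    """Erosion then dilation; anti-extensive and idempotent."""
    mask = _check_mask(mask)
    fp = disk_footprint(3) if footprint is None else np.asarray(footprint, bool)
    eroded = ndimage.binary_erosion(mask, structure=fp, border_value=1)
    return ndimage.binary_dilation(eroded, structure=fp, border_value=0)


def binary_closing(mask: np.ndarray, footprint: np.ndarray | None = None) -> np.ndarray:
    """Dilation then erosion; extensive and idempotent."""
    mask = _check_mask(mask)
    fp = disk_footprint(5) if footprint is None else np.asarray(footprint, bool)
    dilated = ndimage.binary_dilation(mask, structure=fp, border_value=0)
    return ndimage.binary_erosion(dilated, structure=fp, border_value=1)


def median_smooth(mask: np.ndarray, window: int = 3) -> np.ndarray:
    """Majority vote in a ``window x window`` neighborhood, reflective pad."""
    mask = _check_mask(mask)
    if window % 2 == 0 or window < 1:
        raise ParameterError(f"window must be odd and >= 1, got {window}")
    counts = ndimage.uniform_filter(
        mask.astype(np.float64), size=window, mode="reflect"
    ) * (window * window)
    # strict majority; round to kill float fuzz from the uniform filter
    return np.round(counts).astype(np.int64) > (window * window) // 2


def postprocess_mask(
    mask: np.ndarray,
    *,
    opening: bool = True,
    closing: bool = True,
    median: bool = True,
) -> np.ndarray:
    """Full refinement: opening (3x3), closing (5x5), median (3x3), in order.

    Individual stages can be disabled for ablation.
    """
    out = _check_mask(mask)
    if opening:
        out = binary_opening(out)
    if closing:
        out = binary_closing(out)
    if median:
        out = median_smooth(out, 3)
    return out
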