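"""Reading and writing the package's on-disk image formats.

RGB images are 8-bit PNG/TIFF/JPEG; binary masks are single-channel PNG with
0 = non-vegetation and 255 = vegetation; real-valued index images and
feature stacks go to 32-bit float TIFF for inspection.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .exceptions import InputError

__all__ = [
    "read_rgb",
    "write_rgb",
    "read_mask",
    "write_mask",
    "write_float_tiff",
    "read_float_tiff",
]


def read_rgb(path: str | Path) -> np.ndarray:
    """Load an image as an HxWx3 uint8 array (alpha dropped, gray expanded)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"))
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InputError(f"{path} did not decode to an RGB image")
    return arr


def write_rgb(path: str | Path, img: np.ndarray) -> None:
    img = np.asarray(img)
    if img.dtype != np.uint8 or img.ndim != 3 or img.shape[2] != 3:
        raise InputError("expected an HxWx3 uint8 image")
    Image.fromarray(img, mode="RGB").save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Load a 0/255 single-channel PNG as a boolean mask (>=128 is True)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr >= 128


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise InputError("expected a 2-D binary mask")
    Image.fromarray(np.where(mask, 255, 0).astype(np.uint8), mode="L").save(path)


def write_float_tiff(path: str | Path, arr: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(arr, dtype=np.float32))


def read_float_tiff(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=np.float64)
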