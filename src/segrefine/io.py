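"""Image and mask file I/O.

TIFF is the preferred carrier (tifffile); PNG is accepted for intensity
images (imageio). Label masks are written as integer TIFF — 16-bit when the
labels fit, 32-bit otherwise — and validated on read.
"""

from __future__ import annotations

import os

import numpy as np
import tifffile
import imageio.v3 as iio

_TIFF_EXTS = {".tif", ".tiff"}


def _is_tiff(path: str) -> bool:
    return os.path.splitext(str(path))[1].lower() in _TIFF_EXTS


def read_image(path: str) -> np.ndarray:
    """Read a grayscale or 3-channel intensity image from TIFF or PNG."""
    if _is_tiff(path):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim not in (2, 3) or (arr.ndim == 3 and arr.shape[2] != 3):
        raise ValueError(
            f"{path}: expected H×W or H×W×3 image, got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr.astype(np.float64, copy=False))):
        raise ValueError(f"{path}: image contains non-finite values")
    return arr


def read_mask(path: str) -> np.ndarray:
    """Read an integer label mask (0 = background)."""
    if _is_tiff(path):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"{path}: label mask must be 2-D, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if np.any(arr != np.round(arr)):
            raise ValueError(f"{path}: mask has non-integer values")
        arr = arr.astype(np.int64)
    if arr.min() < 0:
        raise ValueError(f"{path}: mask has negative labels")
    return arr.astype(np.int32 if arr.max() < 2**31 else np.int64)


def write_image(path: str, image: np.ndarray) -> None:
    if _is_tiff(path):
        tifffile.imwrite(path, image)
    else:
        iio.imwrite(path, image)


def write_mask(path: str, mask: np.ndarray) -> None:
    mask = np.asarray(mask)
    dtype = np.uint16 if mask.max(initial=0) < 2**16 else np.int32
    if not _is_tiff(path):
        raise ValueError("label masks must be written as TIFF")
    tifffile.imwrite(path, mask.astype(dtype))
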