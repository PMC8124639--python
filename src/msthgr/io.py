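"""Reading and writing 8-bit grayscale images (JPEG/PNG/TIFF)."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .enhance import render_uint8

__all__ = ["read_image", "write_image", "LUMA_WEIGHTS"]

# ITU-R 601 luma coefficients for RGB inputs.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def read_image(path) -> np.ndarray:
    """Read an image as 8-bit grayscale (uint8).

    RGB(A) inputs are converted to luma with ITU-R 601 weights; inputs
    with bit depth other than 8 are rejected.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.dtype != np.uint8:
        raise ValueError(f"unsupported bit depth in {path}: {arr.dtype} (expected uint8)")
    if arr.ndim == 3:
        if arr.shape[2] not in (3, 4):
            raise ValueError(f"unsupported channel count in {path}: {arr.shape}")
        luma = arr[..., :3].astype(np.float64) @ LUMA_WEIGHTS
        arr = render_uint8(luma)
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image shape in {path}: {arr.shape}")
    return arr


def write_image(img, path) -> None:
    """Write an image as 8-bit grayscale, rendering floats by clip+round."""
    path = Path(path)
    arr = np.asarray(img)
    if arr.dtype != np.uint8:
        arr = render_uint8(arr)
    try:
        iio.imwrite(path, arr)
    except Exception as exc:
        raise IOError(f"cannot write image {path}: {exc}") from exc
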