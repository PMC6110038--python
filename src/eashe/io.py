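"""Reading and writing 8-bit raster images (PNG, TIFF, PGM/PPM)."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

SUPPORTED_SUFFIXES = {".png", ".tif", ".tiff", ".pgm", ".ppm"}


def read_image(path) -> np.ndarray:
    """Read an 8-bit grayscale or RGB image.

    Returns a ``(H, W)`` or ``(H, W, 3)`` uint8 array.  An RGBA image is
    reduced to RGB (alpha dropped); higher bit depths are rejected with a
    message naming the offending depth.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such image file: {p}")
    if p.suffix.lower() not in SUPPORTED_SUFFIXES:
        raise ValueError(
            f"unsupported format {p.suffix!r}; supported: PNG, TIFF, PGM, PPM"
        )
    arr = iio.imread(p)
    if arr.dtype != np.uint8:
        raise ValueError(
            f"{p.name}: only 8-bit images are supported, got dtype {arr.dtype} "
            f"({arr.dtype.itemsize * 8}-bit); convert to 8-bit first"
        )
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[..., 0]
    if arr.ndim not in (2, 3) or (arr.ndim == 3 and arr.shape[2] != 3):
        raise ValueError(f"{p.name}: unsupported image layout {arr.shape}")
    return arr


def write_image(path, image: np.ndarray) -> None:
    """Write a uint8 image; PGM is written as binary P5 with maxval 255."""
    p = Path(path)
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("image values outside [0, 255]")
        arr = arr.astype(np.uint8)
    if p.suffix.lower() == ".pgm" and arr.ndim != 2:
        raise ValueError("PGM supports grayscale images only")
    if p.suffix.lower() == ".ppm" and arr.ndim != 3:
        raise ValueError("PPM supports RGB images only")
    iio.imwrite(p, arr)
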