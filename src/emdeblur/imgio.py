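"""Grayscale 8/16-bit PNG/TIFF reading and writing on the unit range."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile


def write_gray(path: str | Path, img: np.ndarray, bitdepth: int = 16) -> None:
    """Write a [0,1] float image as 8- or 16-bit grayscale PNG/TIFF."""
    path = Path(path)
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if bitdepth == 8:
        arr = np.round(np.clip(img, 0, 1) * 255).astype(np.uint8)
    elif bitdepth == 16:
        arr = np.round(np.clip(img, 0, 1) * 65535).astype(np.uint16)
    else:
        raise ValueError("bitdepth must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def read_gray(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a grayscale image; returns ([0,1] float array, source bitdepth)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3:  # collapse an accidental RGB to luminance
        arr = arr.mean(axis=-1)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0, 8
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0, 16
    arr = arr.astype(np.float64)
    return np.clip(arr, 0.0, 1.0), 16
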