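"""Reading and writing the raster formats the pipeline touches.

Grayscale inputs are 8- or 16-bit single-channel PNG/TIFF, converted to
real-valued intensities on load.  Magnitude images are written as 16-bit
PNG after min-max rescaling; the rescaling is presentation-only — in-memory
processing always runs on the unscaled reals.  Binary masks travel as 8-bit
PNG with foreground 255.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_gray", "read_mask", "write_gray16", "write_mask"]


def read_gray(path: str | Path) -> np.ndarray:
    """Load a grayscale image as float64; RGB(A) inputs average the color channels."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2D image, got {arr.shape}")
    return arr.astype(np.float64)


def read_mask(path: str | Path) -> np.ndarray:
    """Load a binary mask: any nonzero pixel is foreground."""
    return (read_gray(path) > 0).astype(np.uint8)


def write_gray16(path: str | Path, image: np.ndarray) -> None:
    """Save a real-valued image as min-max rescaled 16-bit PNG."""
    arr = np.asarray(image, dtype=np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    scaled = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
    iio.imwrite(Path(path), (scaled * 65535.0).round().astype(np.uint16))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Save a {0,1} mask as an 8-bit PNG with foreground 255."""
    arr = np.asarray(mask)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("mask must contain only 0 and 1")
    iio.imwrite(Path(path), (arr.astype(np.uint8) * 255))
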