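"""Image and array I/O: 8-bit grayscale PNG/TIFF in, same out.

The coding transforms are defined on 8-bit intensities, so 16-bit inputs
are rejected rather than silently rescaled.  Color inputs are reduced to
luminance with the fixed ITU-R BT.601 weights (0.299, 0.587, 0.114),
rounded to the nearest integer — deterministic and documented so coded
outputs are reproducible byte for byte.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_gray", "write_gray", "read_mask", "write_mask", "to_luminance"]

_LUMA = np.array([0.299, 0.587, 0.114])


def to_luminance(rgb: np.ndarray) -> np.ndarray:
    """BT.601 luminance of an (..., 3) or (..., 4) uint8 array."""
    return np.floor(rgb[..., :3].astype(np.float64) @ _LUMA + 0.5).astype(np.uint8)


def read_gray(path: str | Path) -> np.ndarray:
    """Read an image as 8-bit grayscale; rejects 16-bit and float inputs."""
    arr = iio.imread(path)
    if arr.dtype != np.uint8:
        raise ValueError(
            f"{path}: expected 8-bit image data, got dtype {arr.dtype}; "
            "rescale explicitly before coding"
        )
    if arr.ndim == 3:
        arr = to_luminance(arr)
    if arr.ndim != 2:
        raise ValueError(f"{path}: unsupported image shape {arr.shape}")
    return arr


def write_gray(path: str | Path, image: np.ndarray) -> None:
    image = np.asarray(image)
    if image.size and (image.min() < 0 or image.max() > 255):
        raise ValueError("intensities outside [0, 255]; quantize before writing")
    iio.imwrite(path, image.astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask stored as a 0/255 (or 0/1) grayscale image."""
    arr = read_gray(path)
    return (arr > 0).astype(np.uint8)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)
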