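"""Deterministic synthetic inputs: the worked 3x3 patch, texture mosaics, disks.

Everything here is a pure function of its spec — a single integer seed
drives one ``numpy.random.default_rng`` generator per call, so outputs are
bit-identical across runs and platforms and no dataset download is ever
needed.  The mosaic and disk generators emulate, at desk scale, the two
evaluation regimes the coding transform targets: texture-boundary
extraction (known inter-tile boundary) and region segmentation (known
region mask).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FixtureSpec",
    "example1_patch",
    "constant_image",
    "ramp_image",
    "checkerboard",
    "texture_mosaic",
    "noisy_disk",
]

# 3x3 patch: center 183, ring clockwise from top-left
# (210, 106, 231, 233, 79, 142, 209, 188)
_EXAMPLE1 = np.array(
    [[210, 106, 231],
     [188, 183, 233],
     [209, 142, 79]],
    dtype=np.uint8,
)

KINDS = ("example1", "constant", "ramp", "checkerboard", "texture_mosaic", "noisy_disk")


@dataclass(frozen=True)
class FixtureSpec:
    """What to generate, how big, and with which seed / noise level."""

    kind: str = "texture_mosaic"
    size: int = 64
    seed: int = 0
    noise_level: float = 0.0
    value: int = 128  # constant / disk foreground intensity

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.size < 1:
            raise ValueError(f"size must be >= 1, got {self.size}")
        if self.noise_level < 0:
            raise ValueError(f"noise_level must be >= 0, got {self.noise_level}")


def example1_patch() -> np.ndarray:
    """The worked 3x3 neighborhood: center 183, ring 210,106,231,233,79,142,209,188."""
    return _EXAMPLE1.copy()


def constant_image(size: int = 16, value: int = 144) -> np.ndarray:
    if not 0 <= value <= 255:
        raise ValueError(f"value {value} outside [0, 255]")
    return np.full((size, size), value, dtype=np.uint8)


def ramp_image(size: int = 16) -> np.ndarray:
    """Row-major ramp of intensities wrapping at 256."""
    return (np.arange(size * size, dtype=np.int64) % 256).reshape(size, size).astype(np.uint8)


def checkerboard(size: int = 16, low: int = 0, high: int = 255) -> np.ndarray:
    j, k = np.indices((size, size))
    return np.where((j + k) % 2 == 0, low, high).astype(np.uint8)


def texture_mosaic(spec: FixtureSpec | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Two statistically distinct textures side by side, plus the boundary mask.

    The left tile is low-variance isotropic noise around a dark mean; the
    right tile is high-variance noise with a strong horizontal stripe
    orientation around a bright mean.  The boundary mask marks the first
    column of the right tile (one column: ``size`` pixels for a vertical
    split).
    """
    if spec is None:
        spec = FixtureSpec(kind="texture_mosaic")
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    split = size // 2

    left = 70 + rng.normal(0.0, 6.0 + spec.noise_level, (size, split))
    stripes = 40.0 * np.sin(np.arange(size) * np.pi / 2.0)[:, None]
    right = 170 + stripes + rng.normal(0.0, 18.0 + spec.noise_level, (size, size - split))
    image = np.clip(np.round(np.concatenate([left, right], axis=1)), 0, 255).astype(np.uint8)

    boundary = np.zeros((size, size), dtype=np.uint8)
    boundary[:, split] = 1
    return image, boundary


def noisy_disk(spec: FixtureSpec | None = None) -> tuple[np.ndarray, np.ndarray]:
    """A filled disk over background with additive discrete noise, plus its mask.

    ``spec.value`` is the disk intensity (background is 40); the noise is
    integer-rounded Gaussian with standard deviation ``noise_level``.  At
    ``noise_level=0`` exactly two intensities are present.
    """
    if spec is None:
        spec = FixtureSpec(kind="noisy_disk")
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    center = (size - 1) / 2.0
    radius = size / 4.0
    j, k = np.indices((size, size))
    mask = ((j - center) ** 2 + (k - center) ** 2 <= radius**2).astype(np.uint8)

    background = 40
    image = np.where(mask, spec.value, background).astype(np.int64)
    if spec.noise_level > 0:
        image = image + np.round(rng.normal(0.0, spec.noise_level, image.shape)).astype(np.int64)
    return np.clip(image, 0, 255).astype(np.uint8), mask


def generate(spec: FixtureSpec):
    """Dispatch on ``spec.kind``; returns an image or an (image, mask) pair."""
    if spec.kind == "example1":
        return example1_patch()
    if spec.kind == "constant":
        return constant_image(spec.size, spec.value)
    if spec.kind == "ramp":
        return ramp_image(spec.size)
    if spec.kind == "checkerboard":
        return checkerboard(spec.size)
    if spec.kind == "texture_mosaic":
        return texture_mosaic(spec)
    return noisy_disk(spec)
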