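"""Strided pooling over multichannel volumes: reference max pooling and Z pooling.

A volume is a dense array whose last axis is the channel axis; pooling
slides a window over the image axes only and never mixes channels.  With
stride ``s`` each image axis of size ``n`` shrinks to ``ceil(n / s)``
(anchors at 0, s, 2s, ...).  Windows overhanging the volume edge read
zeros, which decompose to the empty term set and therefore trigger the
center-fallback of the Z-coding rule.

``max_pool`` keeps the window maximum (the standard downsampling baseline).
``z_pool`` instead treats the anchor's value as the Z-coding center and the
window's other values as its neighbors, so the output is the Z-code of the
window — a parameterless, order-independent alternative that pools texels
rather than raw maxima.  Real-valued feature maps must first be quantized
onto the 8-bit range (``quantize``), since the Zeckendorf term sets are
defined for integers in [0, 255].

Window anchoring: an odd side length d = 2K+1 spans offsets -K..K; an even
d = 2K spans -(K-1)..K, i.e. the anchor sits at the top-left of the central
2x2 block.  This makes outputs bit-reproducible across implementations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np

from .zcoding import ZCodingConfig, _pair_table

__all__ = [
    "PoolingSpec",
    "MultiWindowSpec",
    "window_offsets",
    "max_pool",
    "z_pool",
    "quantize",
    "dequantize",
    "multi_window_spec",
]

QUANTIZATION_MODES = ("none", "affine_to_255")


@dataclass(frozen=True)
class PoolingSpec:
    """Window side length(s), stride and quantization policy.

    ``window`` is one side length applied to every image axis, or a tuple
    with one side length per image axis.  ``quantization`` controls how
    real-valued volumes are mapped to the 8-bit range before Z pooling.
    """

    window: int | tuple[int, ...] = 2
    stride: int = 2
    quantization: str = "none"

    def __post_init__(self):
        sizes = (self.window,) if isinstance(self.window, int) else tuple(self.window)
        if not sizes or any(d < 1 for d in sizes):
            raise ValueError(f"window side lengths must be >= 1, got {self.window!r}")
        if self.stride < 1:
            raise ValueError(f"stride must be >= 1, got {self.stride}")
        if self.quantization not in QUANTIZATION_MODES:
            raise ValueError(
                f"quantization must be one of {QUANTIZATION_MODES}, got {self.quantization!r}"
            )

    def sides(self, n_image_axes: int) -> tuple[int, ...]:
        if isinstance(self.window, int):
            return (self.window,) * n_image_axes
        sizes = tuple(self.window)
        if len(sizes) != n_image_axes:
            raise ValueError(
                f"window has {len(sizes)} side lengths for {n_image_axes} image axes"
            )
        return sizes


@dataclass(frozen=True)
class MultiWindowSpec:
    """Schedule of pooling window sizes with a per-scale multiplicity.

    ``window_sizes`` are strictly increasing; ``multiplicity`` is the number
    of features collected per scale; ``k`` is the scale count derived from
    the input size.
    """

    window_sizes: tuple[int, ...]
    multiplicity: int
    k: int

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.window_sizes, self.window_sizes[1:])):
            raise ValueError(f"window sizes must be strictly increasing: {self.window_sizes}")
        if self.multiplicity < 1:
            raise ValueError(f"multiplicity must be >= 1, got {self.multiplicity}")


def window_offsets(side: int) -> range:
    """1-D offsets spanned by a window side (odd: -K..K; even: -(K-1)..K)."""
    if side < 1:
        raise ValueError(f"window side must be >= 1, got {side}")
    k = side // 2
    return range(-(k - 1) if side % 2 == 0 else -k, k + 1)


def _strided_window_stack(volume: np.ndarray, spec: PoolingSpec, pad_value=0):
    """Gather window values at every strided anchor.

    Returns (stack, center_index) where ``stack`` has shape
    (n_offsets, *out_spatial, channels) and ``center_index`` is the stack
    row holding the anchor's own value (offset all-zero).
    """
    spatial = volume.shape[:-1]
    sides = spec.sides(len(spatial))
    for d, n in zip(sides, spatial):
        if d > n:
            raise ValueError(f"window side {d} larger than volume axis of size {n}")
    offs_per_axis = [list(window_offsets(d)) for d in sides]
    pad = [(-o[0], o[-1]) for o in offs_per_axis] + [(0, 0)]
    padded = np.pad(volume, pad, mode="constant", constant_values=pad_value)
    anchors = [np.arange(math.ceil(n / spec.stride)) * spec.stride + p[0]
               for n, p in zip(spatial, pad)]
    out_spatial = tuple(len(a) for a in anchors)

    combos = list(product(*offs_per_axis))
    center_index = combos.index(tuple(0 for _ in sides))
    stack = np.empty((len(combos),) + out_spatial + volume.shape[-1:], dtype=padded.dtype)
    for i, combo in enumerate(combos):
        idx = np.ix_(*[a + o for a, o in zip(anchors, combo)], np.arange(volume.shape[-1]))
        stack[i] = padded[idx]
    return stack, center_index


def max_pool(volume: np.ndarray, spec: PoolingSpec) -> np.ndarray:
    """Strided window maximum, per channel; image axes shrink to ceil(n/s).

    Overhanging window positions read zeros (the padding convention shared
    with ``z_pool``), which is neutral for the nonnegative feature maps
    this package targets.
    """
    volume = np.asarray(volume)
    if volume.ndim < 2:
        raise ValueError("volume must have at least one image axis plus a channel axis")
    stack, _ = _strided_window_stack(volume, spec, pad_value=0)
    return stack.max(axis=0)


def z_pool(
    volume: np.ndarray,
    spec: PoolingSpec,
    config: ZCodingConfig | None = None,
) -> np.ndarray:
    """Strided Z pooling: the window's Z-code replaces the window maximum.

    Per channel and strided anchor, the anchor's value is the Z-coding
    center and the window's other values are its neighbors; the output is
    the aggregated per-neighbor stack exactly as in the per-pixel coding
    rule.  A 1x1 window has no neighbors and is the identity (up to
    striding).  Like max pooling this is an operator without parameters.

    Real-valued volumes require ``spec.quantization == "affine_to_255"``;
    integer volumes must already lie in [0, 255].
    """
    if config is None:
        config = ZCodingConfig()
    volume = np.asarray(volume)
    if volume.ndim < 2:
        raise ValueError("volume must have at least one image axis plus a channel axis")
    if not np.issubdtype(volume.dtype, np.integer):
        if spec.quantization != "affine_to_255":
            raise ValueError(
                "real-valued volume requires quantization='affine_to_255'"
            )
        volume, _ = quantize(volume)
    if volume.size and (volume.min() < 0 or volume.max() > 255):
        raise ValueError("integer volume values outside [0, 255]")

    stack, center_index = _strided_window_stack(volume.astype(np.int64), spec, pad_value=0)
    centers = stack[center_index]
    neighbor_rows = [i for i in range(stack.shape[0]) if i != center_index]
    if not neighbor_rows:
        return centers
    table = _pair_table(
        config.set_op, config.integration_op, config.saturate, config.difference_reversed
    )
    pooled = table[centers, stack[neighbor_rows[0]]]
    for i in neighbor_rows[1:]:
        f = table[centers, stack[i]]
        pooled = np.maximum(pooled, f) if config.aggregation_op == "sup" else np.minimum(pooled, f)
    return pooled


def quantize(volume: np.ndarray, per_channel: bool = True):
    """Affine min-max map of a real volume onto integers 0..255.

    Per-channel by default (preserves channel-relative contrast); constant
    channels map to 0.  Rounding is half-up.  Integer input already in
    [0, 255] is returned unchanged with identity parameters.  Returns
    ``(quantized, params)`` where ``params`` supports :func:`dequantize`.
    """
    volume = np.asarray(volume)
    if np.issubdtype(volume.dtype, np.integer):
        if volume.size and (volume.min() < 0 or volume.max() > 255):
            raise ValueError("integer volume values outside [0, 255]")
        params = {"lo": np.zeros(volume.shape[-1]), "scale": np.ones(volume.shape[-1]),
                  "per_channel": True, "identity": True}
        return volume, params
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume contains non-finite values")
    axes = tuple(range(volume.ndim - 1)) if per_channel else tuple(range(volume.ndim))
    lo = volume.min(axis=axes, keepdims=True)
    hi = volume.max(axis=axes, keepdims=True)
    span = hi - lo
    scale = np.where(span > 0, 255.0 / np.where(span > 0, span, 1.0), 0.0)
    q = np.floor((volume - lo) * scale + 0.5).astype(np.int64)
    params = {"lo": lo, "scale": scale, "per_channel": per_channel, "identity": False}
    return q, params


def dequantize(volume: np.ndarray, params) -> np.ndarray:
    """Approximate inverse of :func:`quantize` (exact for identity params)."""
    if params.get("identity"):
        return np.asarray(volume)
    scale = params["scale"]
    inv = np.where(scale > 0, 1.0 / np.where(scale > 0, scale, 1.0), 0.0)
    return np.asarray(volume) * inv + params["lo"]


def multi_window_spec(
    input_size: int, multiplicity: int = 10, use_formula: bool = False
) -> MultiWindowSpec:
    """Multi-scale window schedule for an input of side ``input_size``.

    The default schedule is the fixed set {1, 3, 5, 9} capped at the input
    size, with scale count k = floor(log2(s) + 2).  ``use_formula``
    switches to the geometric rule d_i = 2^(i-1) + 1 (giving 2, 3, 5, 9,
    17, ...), an alternative that grows the receptive field with the
    input.
    """
    if input_size < 1:
        raise ValueError(f"input_size must be >= 1, got {input_size}")
    k = int(math.floor(math.log2(input_size) + 2)) if input_size > 1 else 2
    if use_formula:
        sizes = tuple(dict.fromkeys(2 ** (i - 1) + 1 for i in range(1, k + 1)))
    else:
        sizes = (1, 3, 5, 9)
    sizes = tuple(d for d in sizes if d <= input_size) or (1,)
    return MultiWindowSpec(window_sizes=sizes, multiplicity=multiplicity, k=k)
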