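"""Image Z coding: the Zeckendorf neighborhood transform, plus the LBP baseline.

Each pixel of an 8-bit grayscale image is replaced by an aggregate of
set-operation pooling between its Zeckendorf term set and those of its
neighbors.  For every neighbor p of center I0:

    S(p) = set_op(Zck(I0), Zck(neighbor_p))        # intersection or difference
    F(p) = I0                  if S(p) is empty
           integration_op(S)   otherwise           # sup, inf, or (saturated) sum

and the output pixel is ``aggregation_op`` over the stack F.  With
(intersection, sup, sup) and the worked 3x3 neighborhood
(center 183, ring 210,106,231,233,79,142,209,188) the stack is
(144, 183, 144, 183, 183, 34, 144, 144) and the Z-code is 183.

The transform is invariant to permutations of the neighbor list (the
reductions are symmetric), hence tolerant of rotated neighborhoods; the
whole-image transform commutes with 90-degree rotations and flips under
replicate or reflect borders.

The module works on plain integer numpy arrays in [0, 255].  Image-level
transforms are vectorized through a cached 256x256 lookup table of the
per-neighbor value F.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .codec import fibonacci_basis, zeckendorf

__all__ = [
    "ZCodingConfig",
    "neighbors",
    "ring_offsets",
    "z_code_pixel",
    "z_code_stack",
    "z_code_image",
    "lbp_pixel",
    "lbp_image",
]

SET_OPS = ("intersection", "set_difference")
INTEGRATION_OPS = ("sup", "inf", "sum")
AGGREGATION_OPS = ("sup", "inf")
BORDER_MODES = ("replicate", "reflect", "passthrough")


@dataclass(frozen=True)
class ZCodingConfig:
    """Operator pair, window and border policy for Z coding.

    Parameters
    ----------
    window_size : odd int >= 3
        Side length of the square neighborhood.
    set_op : {"intersection", "set_difference"}
        Set operation between the center's and each neighbor's term sets.
        Set difference is oriented Zck(center) \\ Zck(neighbor); flip with
        ``difference_reversed``.
    integration_op : {"sup", "inf", "sum"}
        Reduction over the term set produced for one neighbor.
    aggregation_op : {"sup", "inf"}
        Reduction over the stack of per-neighbor values.
    border_mode : {"replicate", "reflect", "passthrough"}
        Edge policy; ``passthrough`` copies original border pixels.
    saturate : bool
        Clamp the ``sum`` integration at 255 to preserve the 8-bit range.
    """

    window_size: int = 3
    set_op: str = "intersection"
    integration_op: str = "sup"
    aggregation_op: str = "sup"
    border_mode: str = "replicate"
    saturate: bool = True
    difference_reversed: bool = False

    def __post_init__(self):
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError(f"window_size must be odd and >= 3, got {self.window_size}")
        if self.set_op not in SET_OPS:
            raise ValueError(f"set_op must be one of {SET_OPS}, got {self.set_op!r}")
        if self.integration_op not in INTEGRATION_OPS:
            raise ValueError(
                f"integration_op must be one of {INTEGRATION_OPS}, got {self.integration_op!r}"
            )
        if self.aggregation_op not in AGGREGATION_OPS:
            raise ValueError(
                f"aggregation_op must be one of {AGGREGATION_OPS}, got {self.aggregation_op!r}"
            )
        if self.border_mode not in BORDER_MODES:
            raise ValueError(
                f"border_mode must be one of {BORDER_MODES}, got {self.border_mode!r}"
            )


def ring_offsets(window_size: int) -> list[tuple[int, int]]:
    """(row, col) offsets of a square window's non-center cells in ring order.

    Concentric rings from innermost outward, each traversed clockwise from
    its top-left corner; for ``window_size=3`` this is exactly the
    clockwise-from-top-left listing
    (-1,-1), (-1,0), (-1,+1), (0,+1), (+1,+1), (+1,0), (+1,-1), (0,-1).
    """
    if window_size < 3 or window_size % 2 == 0:
        raise ValueError(f"window_size must be odd and >= 3, got {window_size}")
    offsets: list[tuple[int, int]] = []
    for r in range(1, window_size // 2 + 1):
        offsets.extend((-r, c) for c in range(-r, r + 1))      # top row, left->right
        offsets.extend((j, r) for j in range(-r + 1, r + 1))   # right column, downward
        offsets.extend((r, c) for c in range(r - 1, -r - 1, -1))  # bottom, right->left
        offsets.extend((j, -r) for j in range(r - 1, -r, -1))  # left column, upward
    return offsets


def neighbors(image: np.ndarray, j: int, k: int, window_size: int = 3) -> tuple[int, ...]:
    """Intensities of the window ring around pixel (j, k), in ring order.

    Raises IndexError if (j, k) is outside the image, or if the window does
    not fit inside it (border expansion is the image transform's job, not
    this accessor's).
    """
    image = np.asarray(image)
    h, w = image.shape
    if not (0 <= j < h and 0 <= k < w):
        raise IndexError(f"pixel ({j}, {k}) outside {h}x{w} image")
    r = window_size // 2
    if j - r < 0 or k - r < 0 or j + r >= h or k + r >= w:
        raise IndexError(
            f"{window_size}x{window_size} window at ({j}, {k}) overhangs the image"
        )
    return tuple(int(image[j + dj, k + dk]) for dj, dk in ring_offsets(window_size))


# ---------------------------------------------------------------------------
# bitmask machinery: a term set over the 12-element basis packs into 12 bits

@lru_cache(maxsize=None)
def _decomposition_masks() -> np.ndarray:
    """12-bit term-set mask of every intensity 0..255 (bit i = basis[i])."""
    basis = fibonacci_basis(255)
    masks = np.zeros(256, dtype=np.int32)
    for n in range(256):
        mask = 0
        for t in zeckendorf(n, basis).terms:
            mask |= 1 << basis.index(t)
        masks[n] = mask
    return masks


@lru_cache(maxsize=None)
def _mask_reductions() -> dict[str, np.ndarray]:
    """sup / inf / sum of the term set encoded by each 12-bit mask."""
    basis = np.asarray(fibonacci_basis(255).values)
    nmask = 1 << len(basis)
    idx = np.arange(nmask)[:, None]
    member = (idx >> np.arange(len(basis))[None, :] & 1).astype(bool)
    sums = member @ basis
    # position of highest/lowest set bit -> largest/smallest term
    sup = np.where(member, basis[None, :], 0).max(axis=1)
    inf = np.where(member, basis[None, :], np.iinfo(np.int64).max).min(axis=1)
    inf[0] = 0
    return {"sup": sup, "inf": inf, "sum": sums}


@lru_cache(maxsize=None)
def _pair_table(
    set_op: str, integration_op: str, saturate: bool, difference_reversed: bool
) -> np.ndarray:
    """256x256 table of the per-neighbor value F(center, neighbor)."""
    masks = _decomposition_masks()
    c = masks[:, None]
    n = masks[None, :]
    if set_op == "intersection":
        s = c & n
    elif difference_reversed:
        s = n & ~c
    else:
        s = c & ~n
    values = _mask_reductions()[integration_op][s]
    if integration_op == "sum" and saturate:
        values = np.minimum(values, 255)
    centers = np.broadcast_to(np.arange(256)[:, None], (256, 256))
    return np.where(s == 0, centers, values).astype(np.int32)


# ---------------------------------------------------------------------------


def z_code_pixel(center: int, neighbor_values, config: ZCodingConfig | None = None) -> int:
    """Z-code of one pixel from its center intensity and neighbor list.

    Follows the per-neighbor set operation / integration / stack
    aggregation flow described in the module docstring.  An empty neighbor
    list returns the center unchanged.
    """
    if config is None:
        config = ZCodingConfig()
    neighbor_values = [int(v) for v in np.asarray(neighbor_values).ravel()]
    if not neighbor_values:
        return int(center)
    stack = z_code_stack(center, neighbor_values, config)
    return int(stack.max() if config.aggregation_op == "sup" else stack.min())


def z_code_stack(center: int, neighbor_values, config: ZCodingConfig | None = None) -> np.ndarray:
    """The per-neighbor value stack F, before aggregation (for inspection)."""
    if config is None:
        config = ZCodingConfig()
    center = int(center)
    if not 0 <= center <= 255:
        raise ValueError(f"intensity {center} outside [0, 255]")
    nb = np.asarray(neighbor_values, dtype=np.int64).ravel()
    if nb.size and (nb.min() < 0 or nb.max() > 255):
        raise ValueError("neighbor intensities outside [0, 255]")
    table = _pair_table(
        config.set_op, config.integration_op, config.saturate, config.difference_reversed
    )
    return table[center, nb]


def z_code_image(image: np.ndarray, config: ZCodingConfig | None = None) -> np.ndarray:
    """Apply the Z-coding transform to a whole grayscale image.

    Returns an array of the same shape.  Borders follow
    ``config.border_mode``; with ``passthrough``, border pixels (and the
    whole image, if smaller than the window) are copied unchanged and a
    UserWarning is raised in the too-small case.
    """
    if config is None:
        config = ZCodingConfig()
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {image.shape}")
    if image.size and (image.min() < 0 or image.max() > 255):
        raise ValueError("image intensities outside [0, 255]")
    img = image.astype(np.int64)
    r = config.window_size // 2
    h, w = img.shape

    if config.border_mode == "passthrough" and (h < config.window_size or w < config.window_size):
        warnings.warn(
            f"image {h}x{w} smaller than {config.window_size}x{config.window_size} "
            "window with passthrough borders; returned unchanged",
            UserWarning,
            stacklevel=2,
        )
        return image.copy()

    if config.border_mode == "replicate":
        padded = np.pad(img, r, mode="edge")
    elif config.border_mode == "reflect":
        padded = np.pad(img, r, mode="reflect")
    else:  # passthrough: compute interior only on the unpadded image
        padded = img

    table = _pair_table(
        config.set_op, config.integration_op, config.saturate, config.difference_reversed
    )
    ph, pw = padded.shape
    centers = padded[r : ph - r, r : pw - r]
    stack = np.empty((len(ring_offsets(config.window_size)),) + centers.shape, dtype=np.int32)
    for i, (dj, dk) in enumerate(ring_offsets(config.window_size)):
        nb = padded[r + dj : ph - r + dj, r + dk : pw - r + dk]
        stack[i] = table[centers, nb]
    coded = stack.max(axis=0) if config.aggregation_op == "sup" else stack.min(axis=0)

    if config.border_mode == "passthrough":
        out = img.copy()
        out[r : h - r, r : w - r] = coded
    else:
        out = coded
    return out.astype(image.dtype if np.issubdtype(image.dtype, np.integer) else np.int64)


# ---------------------------------------------------------------------------
# LBP baseline


def lbp_pixel(center: int, neighbor_values) -> int:
    """Local binary pattern code of one pixel (P=8, R=1).

    Bit p is set iff the p-th neighbor (ring order, clockwise from
    top-left) is >= the center; the code is sum of 2^p over set bits.
    """
    nb = np.asarray(neighbor_values).ravel()
    if nb.size != 8:
        raise ValueError(f"LBP requires exactly 8 neighbors, got {nb.size}")
    bits = (nb.astype(np.int64) - int(center)) >= 0
    return int((bits << np.arange(8)).sum())


def lbp_image(image: np.ndarray, border_mode: str = "replicate") -> np.ndarray:
    """LBP transform of a whole image with the 3x3 ring, P=8, R=1."""
    if border_mode not in ("replicate", "reflect"):
        raise ValueError(f"border_mode must be replicate or reflect, got {border_mode!r}")
    img = np.asarray(image).astype(np.int64)
    padded = np.pad(img, 1, mode="edge" if border_mode == "replicate" else "reflect")
    h, w = img.shape
    out = np.zeros((h, w), dtype=np.int64)
    for p, (dj, dk) in enumerate(ring_offsets(3)):
        nb = padded[1 + dj : 1 + h + dj, 1 + dk : 1 + w + dk]
        out += ((nb - img) >= 0).astype(np.int64) << p
    return out
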