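"""Downsample a feature volume with max pooling vs parameterless Z pooling.

Pools the same random 8x8 single-channel volume with both operators
(3x3 window, stride 2) and prints both outputs; also shows the
multi-window schedule used to grow the receptive field without adding
parameters.
"""

import numpy as np

from zeckpool import PoolingSpec, ZCodingConfig, max_pool, multi_window_spec, z_pool

rng = np.random.default_rng(0)
vol = rng.integers(0, 256, (8, 8, 1))
spec = PoolingSpec(window=3, stride=2)

print("input (channel 0):")
print(vol[..., 0])
print("\nmax pool, 3x3 window, stride 2:")
print(max_pool(vol, spec)[..., 0])
print("\nZ pool (intersection, sup, sup), same window and stride:")
print(z_pool(vol, spec, ZCodingConfig())[..., 0])
print("\nmax pooling keeps the loudest value per window; Z pooling keeps the")
print("largest Fibonacci structure the anchor shares with its window — a texel,")
print("not a peak — and falls back to the anchor when nothing is shared.")

mw = multi_window_spec(input_size=64, multiplicity=10)
print(f"\nmulti-window schedule for a 64x64 input: sizes {mw.window_sizes}, "
      f"multiplicity {mw.multiplicity}, k = {mw.k} scales")
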