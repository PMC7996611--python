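# Methods

## The model

Zeckendorf's theorem: every positive integer `N` is uniquely the sum of
distinct, pairwise non-consecutive Fibonacci numbers. The codec uses the
*distinct-value* basis — the mathematical sequence starts f(0) = f(1) = 1,
but the operational object is the set of distinct values, so 1 appears
once and the 8-bit basis is the 12 values {1, 2, 3, 5, 8, 13, 21, 34, 55,
89, 144, 233}. The greedy largest-first construction implemented here is
the classical proof device: it always selects non-adjacent terms, and the
resulting representation is also the one with the fewest terms among all
Fibonacci subset sums of the same integer. Both properties are verified
exhaustively over 0..255 in the test suite by brute-force subset
enumeration (2^12 subsets). `zeckendorf(0)` returns the empty term set:
the theorem covers positive integers only, but pixel value 0 must
compose correctly with set intersection, and the empty set does.

Z coding replaces a pixel `I0` by `aggregate_p F(p)` where, per neighbor
`p`, `S(p)` is the intersection (or difference) of the two term sets and
`F(p)` is `I0` when `S(p)` is empty, otherwise a reduction (sup, inf or
sum) of `S(p)`. The empty-set fallback is applied for both set
operations; the worked example fixes it for intersection and we
generalize the same rule to set difference, whose orientation is
`Zck(center) \ Zck(neighbor)` with a `difference_reversed` flag for the
other direction. The union operator is deliberately absent: it is not
discriminating between textures. Figure-caption notation of the form
`max(min)` is ambiguous about which reduction is the inner one, so the
configuration exposes `integration_op` (per-neighbor, inner) and
`aggregation_op` (over the stack, outer) as two explicit fields instead.

## Numerical and convention choices

- **Intensity domain.** All coding operates on integers in [0, 255];
  16-bit inputs are rejected rather than rescaled, color inputs are
  reduced to BT.601 luminance (0.299, 0.587, 0.114, rounded) so outputs
  are byte-reproducible.
- **Saturation.** With `saturate=True` (default) the `sum` integration
  is clamped at 255 so outputs always remain valid 8-bit images. For
  intersection and difference the reduced set is a subset of one
  operand's term set and therefore sums within [0, 255] anyway, so the
  clamp is a guard that keeps the 8-bit contract under any operator
  combination rather than a frequently active path.
- **Neighbor order.** The 3×3 ring is listed clockwise from the top-left
  corner. The reductions are symmetric, so Z coding is invariant to this
  order; it matters only for LBP, where bit `p` (weight `2^p`) is the
  p-th listed neighbor and the comparison is `t(g_p − g_c) = 1` iff the
  difference is ≥ 0. For windows larger than 3×3 the order is concentric
  rings, innermost first, each clockwise from its top-left corner — an
  arbitrary but fixed convention that reduces to the 3×3 listing.
- **Borders.** The per-image transform defaults to replicate padding;
  `reflect` and `passthrough` (copy original border pixels, warn and
  return unchanged if the image is smaller than the window) are
  available. Replicate and reflect preserve the transform's equivariance
  under 90° rotations and flips, which the property tests check.
- **Pooling geometry.** Strides anchor at 0, s, 2s, ..., so each image
  axis of size n yields ⌈n/s⌉ outputs. Odd windows (side 2K+1) span
  offsets −K..K; even windows (side 2K) span −(K−1)..K, i.e. the anchor
  is the top-left cell of the central 2×2 block. Windows overhanging the
  volume read zeros for both operators — zero decomposes to the empty
  term set, so in Z pooling padded cells trigger the center fallback and
  are effectively neutral. Channels are never mixed. A 1×1 window makes
  Z pooling the identity (up to striding).
- **Quantization.** Z pooling needs integers in [0, 255]; real feature
  maps are mapped by a per-channel affine min–max transform with
  half-up rounding (per-volume mode by flag). Per-channel is the default
  because it preserves channel-relative contrast; constant channels map
  to 0. The affine parameters are returned for approximate inversion.
- **Multi-window schedule.** The default schedule is the fixed window
  set {1, 3, 5, 9} (capped at the input size) with multiplicity m = 10
  and scale count k = ⌊log₂(s) + 2⌋. The geometric rule d_i = 2^(i−1)+1,
  which grows the receptive field with the input, is available via
  `use_formula=True`; the two disagree at the first scale (1 vs 2) and
  for large inputs, so the choice is explicit rather than silent.
- **Boundary matching.** A predicted boundary pixel is a true positive
  when a ground-truth boundary pixel lies within a Euclidean pixel
  radius (default tolerance 0 = exact overlap), computed with a distance
  transform; recall is the mirror image on the truth side. This is a
  transparent substitute for benchmark-specific bipartite matchers,
  whose behavior is not reproducible from their descriptions; at
  tolerance 0 swapping the two masks swaps P and R exactly.
- **Dice loss.** Implemented as printed: `1 − 2Σ P_i T_i / (Σ P_i + Σ T_i + ε)`
  with ε = 1 in the denominator only. This makes the loss 1.0 for two
  empty masks and nonzero even for a perfect match, which conflicts with
  the usual motivation for the smoothing term; the common variant that
  adds ε to the numerator as well (empty-vs-empty scores 0) is available
  via `symmetric_epsilon=True`, but the printed form stays the default.
- **F-measure degeneracy.** P = R = 0 is undefined by the formula and is
  reported as 0 with a `DegenerateMetricWarning`, as are metrics on
  empty masks.

## Synthetic data

The fixture generators make the package testable with no downloads.
`example1_patch` is the fixed 3×3 reference neighborhood. `texture_mosaic`
places a low-variance isotropic texture beside a high-variance,
horizontally striped one (means 70 vs 170, noise σ 6 vs 18, stripe
amplitude 40) with the exact one-column inter-tile boundary as ground
truth; `noisy_disk` is a filled disk (radius a quarter of the side) over
background 40 with integer Gaussian noise, for region-overlap metrics.
Every generator is a pure function of its spec — one integer seed drives
one `numpy.random.default_rng`, so outputs are bit-identical across runs.

These fixtures exercise the *mechanics* the package guarantees —
exactness of the codec, operator equivalences, metric arithmetic,
boundary scoring on a known edge. They are not natural images: passing
tests demonstrate correctness of the transforms and metrics, not
segmentation quality on photographs or MRI volumes, which depends on
data, post-processing and (for CNN use) training choices that are out of
scope here. The desk-scale end-to-end check — Z coding a 64×64 mosaic,
thresholding its horizontal gradient, and scoring the boundary at
tolerance 1 — asserts only a qualitative property: the coded image's
boundary F-measure must beat a size-matched random baseline.

## Problem sizes

Exhaustive codec checks run over the full 8-bit range (256 values × 4096
subsets). Pooling equivalence is verified on 100 random volumes up to
16×16×2 against a per-anchor brute-force oracle, and the invariance
properties on 50 seeded 9×9 images; these sizes make every path
(striding, padding, even/odd windows, multi-channel) exhaustive at the
scale where independent oracles are feasible.

## Limitations

- Gradients are not defined: Z pooling here is a forward array operator
  (pure array in → array out) that a deep-learning framework can wrap;
  training-time integration is the consumer's responsibility.
- Arbitrary-precision Zeckendorf arithmetic, negafibonacci coding, and
  ternary (three-level) local patterns are out of scope.
- The boundary matcher is radius-based, not bipartite: scores are
  comparable within this package, not directly against benchmark tables
  produced with other matchers.
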