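"""Score a texture-boundary prediction: precision, recall, F-measure, Dice.

Generates a two-texture mosaic with a known inter-tile boundary, Z-codes
it, predicts boundary pixels from the coded image's horizontal gradient,
and evaluates the prediction against the ground truth at match tolerance
1 pixel.
"""

import numpy as np
from scipy import ndimage

from zeckpool import (
    FixtureSpec,
    MatchPolicy,
    ZCodingConfig,
    boundary_precision_recall,
    dice_loss,
    f_measure,
    texture_mosaic,
    z_code_image,
)

img, truth = texture_mosaic(FixtureSpec(kind="texture_mosaic", size=64, seed=0))
coded = z_code_image(img, ZCodingConfig())

grad = np.abs(ndimage.sobel(coded.astype(float), axis=1))
n_positives = 2 * int(truth.sum())
threshold = np.partition(grad.ravel(), -n_positives)[-n_positives]
pred = (grad >= threshold).astype(int)

policy = MatchPolicy(tolerance=1)
precision, recall = boundary_precision_recall(pred, truth, policy)
f = f_measure(precision, recall, alpha=0.5)
loss = dice_loss(pred, truth, epsilon=1.0)

print(f"boundary precision: {precision:.4f}   (predicted pixels near a true boundary)")
print(f"boundary recall:    {recall:.4f}   (true boundary pixels that were found)")
print(f"F-measure (a=0.5):  {f:.4f}   (harmonic mean of the two)")
print(f"Dice loss (eps=1):  {loss:.4f}   (pixel-overlap loss; 0 would be perfect")
print("                             overlap up to the epsilon smoothing)")
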