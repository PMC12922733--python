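"""Moran's I anchor patterns: checkerboard, two-block, and random.

Moran's I measures spatial autocorrelation on a graph: -1 for perfect
alternation, near -1/(N-1) (about 0) for random placement, approaching +1
for a segregated half-and-half pattern.
"""

import numpy as np

from pdmap import MoransInputs, grid_weights, morans_I

n = 16
w = grid_weights((n, n))

yy, xx = np.indices((n, n))
checker = ((yy + xx) % 2).astype(float).ravel()
print(f"checkerboard {n}x{n}:      I = {morans_I(MoransInputs(checker, w)):+.4f}")

block = np.zeros((n, n))
block[:, n // 2:] = 1.0
print(f"two-block half/half:     I = {morans_I(MoransInputs(block.ravel(), w)):+.4f}"
      f"   (closed form 1 - 1/(n-1) = {1 - 1 / (n - 1):+.4f})")

rng = np.random.default_rng(0)
rand = rng.integers(0, 2, n * n).astype(float)
print(f"random values:           I = {morans_I(MoransInputs(rand, w)):+.4f}"
      f"   (expectation -1/(N-1) = {-1 / (n * n - 1):+.4f})")

for big in (64, 256):
    v = np.zeros((big, big))
    v[:, big // 2:] = 1.0
    I = morans_I(MoransInputs(v.ravel(), grid_weights((big, big))))
    print(f"two-block {big:>3}x{big:<3}:       I = {I:+.6f}  (toward +1)")
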