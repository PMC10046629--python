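"""The polynomial nodal operator and its decomposition into plain convolutions.

Builds one operational layer, shows that a single connection computes
psi(w, y) = sum_q w_q y^q, and that the whole layer equals the sum of Q
ordinary convolutions applied to the input's element-wise powers —
with Q = 1 collapsing to a conventional convolution.
"""

import numpy as np

from mwbrain.core_ops import (
    NodalWeights,
    OperationalLayerSpec,
    nodal_transform,
    operational_conv_forward,
)
from mwbrain.nn import functional as F

rng = np.random.default_rng(0)

# one connection: third-order polynomial of the input value
w = np.array([0.8, -0.3, 0.1])
y = 0.5
print(f"psi({w}, {y}) = {nodal_transform(w, y):.6f}")
print(f"  by hand: {0.8 * 0.5 - 0.3 * 0.25 + 0.1 * 0.125:.6f}")

# a full layer: Q = 3 banks over a 2-channel 8x8 map
spec = OperationalLayerSpec(in_channels=2, out_channels=1, kernel_size=3, q_order=3)
weights = NodalWeights(banks=rng.standard_normal((3, 1, 2, 3, 3)) * 0.3,
                       bias=np.zeros(1))
x = rng.standard_normal((8, 8, 2))

out = operational_conv_forward(x, weights, spec)
decomposed = sum(
    F.conv2d((x.transpose(2, 0, 1)[None]) ** (q + 1), weights.banks[q], pad=1)
    for q in range(3))[0, 0]
print(f"layer output vs sum of power-convolutions, max |diff|: "
      f"{np.abs(out[:, :, 0] - decomposed).max():.2e}")

# Q = 1 is an ordinary convolution
spec1 = OperationalLayerSpec(in_channels=2, out_channels=1, kernel_size=3, q_order=1)
w1 = NodalWeights(banks=weights.banks[:1], bias=np.zeros(1))
plain = F.conv2d(x.transpose(2, 0, 1)[None], weights.banks[0], pad=1)[0, 0]
out1 = operational_conv_forward(x, w1, spec1)
print(f"Q=1 vs plain convolution, max |diff|: "
      f"{np.abs(out1[:, :, 0] - plain).max():.2e}")
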