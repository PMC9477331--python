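"""Inspect the channel-gated encoder-decoder.

The network has no skip connections; a per-channel state S_l (product of two
sigmoid branches, so always inside (0,1)) is threaded between consecutive
levels instead, scaling each residual block's output per channel.
"""

import numpy as np

from nucseg.network import FGDCNet, NetworkConfig

config = NetworkConfig(depth=3, base_channels=8, label_size=48, seed=0)
net = FGDCNet(config)

print(net.summary().splitlines()[0])
print(f"total parameters: {net.num_params()}")

x = np.random.default_rng(0).random((1, 96, 96, 3))
y = net.forward(x)
print(f"input {x.shape[1:]} -> output {y.shape[1:]} (central crop only)")
for i, s in enumerate(net.last_states):
    print(f"  level {i}: channel state length {s.shape[1]}, "
          f"range ({s.min():.3g}, {s.max():.3g})")
print(
    "\nState lengths follow the channel ladder (2C while encoding, C/2 while "
    "decoding) and every entry stays strictly inside (0,1)."
)
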