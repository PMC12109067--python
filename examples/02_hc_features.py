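"""Horizontal-cell On-Off features: the binary motion cue.

For every interior pixel, a horizontal-cell unit compares the frame-t center
with each of its 8 neighbors in frame t+dt, per RGB channel; it outputs 1
when the difference is below theta_h = 3 (a perceptual match).  The neighbor
lying along the motion direction matches at object pixels, so match counts
per neighbor already hint at the direction.
"""

import numpy as np

from hcdm import build_group, feature_matrix, hc_response
from hcdm.hc_frontend import NEIGHBOR_OFFSETS

pair = build_group("random-random", 8, seed=3)[0]
field = hc_response(pair.frame_t, pair.frame_t1, theta_h=3)
X = feature_matrix(field)  # (900, 24): 8 neighbors x 3 channels per field

print(f"true direction: {pair.label.name}, offset {pair.label.offset}")
print(f"feature matrix: {X.shape}, active fraction {X.mean():.3f}\n")

print("matches per neighbor offset (summed over channels and fields):")
counts = X.reshape(-1, 3, 8).sum(axis=(0, 1))
for k, (dy, dx) in enumerate(NEIGHBOR_OFFSETS):
    marker = "  <-- motion direction" if (dy, dx) == pair.label.offset else ""
    print(f"  ({dy:+d},{dx:+d}): {counts[k]:4d}{marker}")

print("\nOn a random background, accidental matches are rare (~2% per"
      "\nchannel), so the moved object inflates exactly one neighbor's count.")
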