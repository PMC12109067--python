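"""Train a small dendritic model end-to-end and inspect what it learned.

A J=1 model (one dendritic branch per direction output) is trained on one
group with plain SGD on the exact chain-rule gradients.  After training,
most synapses sit in constant-1 (pass-through) or constant-0 (pruned)
states; the informative ones become excitatory or inhibitory -- the
synaptic-pruning picture of dendritic learning.
"""

from collections import Counter

import numpy as np

from hcdm import (ModelParams, TrainConfig, build_group,
                  classify_synapse_state, train)
from hcdm.evaluation import accuracy
from hcdm.training import precompute_features

train_pairs = build_group("random-random", 640, seed=11)
test_pairs = build_group("random-random", 160, seed=12)
X, y = precompute_features(train_pairs)

model = ModelParams.init_random(n_branches=1, rng=0)
config = TrainConfig(eta=30.0, batch_size=128, max_epochs=120, seed=1)
model, records = train(model, (X, y), config)

print(f"epochs run: {len(records)}")
print(f"final train accuracy: {records[-1].train_accuracy:.1f}%")
print(f"held-out accuracy:    {accuracy(model, test_pairs):.1f}%")

states = Counter(
    classify_synapse_state(model.w[i, j, m], model.q[i, j, m])
    for i in range(24) for j in range(model.n_branches) for m in range(8))
print("\nsynapse states after learning:")
for state, count in sorted(states.items()):
    print(f"  {state:12s} {count:4d}")
print("\nconstant_0 synapses are functionally pruned (they silence their"
      "\nbranch); constant_1 synapses pass through without effect.")
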