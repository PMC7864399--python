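"""Learn a dictionary from synthetic scenes and score recovery of the truth.

Trains a single sparse-coding layer on scenes sampled from a planted
4-atom Gabor bank and reports, per planted atom, the best normalized
cross-correlation with a learned atom (1 = perfectly recovered).
Runs in under a minute; the full benchmark in the test suite uses
8 atoms and 500 scenes.
"""

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.signal import correlate2d

from sdpc import (InferenceConfig, LayerSpec, SDPCNetwork, TrainConfig,
                  make_gabor_dictionary, sample_hierarchical, train)

d_true, orientations = make_gabor_dictionary(4, 9,
                                             orientations=np.radians([0, 45, 90, 135]))
scenes = sample_hierarchical(d_true, None, (8, 8), 150, n_active=3,
                             noise=(0.01, 0.0), seed=11)

network = SDPCNetwork([LayerSpec(8, 1, (9, 9), 1, 0.1)], rng_seed=5)
history = train([s.image for s in scenes], network,
                TrainConfig(epochs=10, learning_rates=(0.1,), rng_seed=7,
                            lr_decay=0.92, recycle_unused=True),
                InferenceConfig(feedback_strength=0.0, max_iterations=200))
print(history[["epoch", "loss_1", "sparsity_1"]].tail(3).to_string(index=False))

C = np.zeros((8, 4))
for i, a in enumerate(network.dictionaries[0].atoms):
    for j, b in enumerate(d_true.atoms):
        C[i, j] = np.max(np.abs(correlate2d(a[0], b[0], mode="full")))
rows, cols = linear_sum_assignment(-C)
for j, r in sorted(zip(cols, rows)):
    print(f"planted atom at {np.degrees(orientations[j]):5.1f} deg: "
          f"matched correlation {C[r, j]:.3f}")
print("Values near 1 mean the learner rediscovered the planted oriented atoms "
      "purely from the image statistics.")
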