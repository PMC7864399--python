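"""Interaction maps: how feedback reshapes the surround of active units.

Trains a small two-layer model on synthetic scenes (about a minute),
drives it with contour stimuli (chains of co-oriented Gabor patches),
and compares the interaction map around the most active units with and
without feedback. Prints the region-wise activity ratios, aggregated
over stimuli, and saves a quiver plot per condition.
"""

import numpy as np

from sdpc import (InferenceConfig, LayerSpec, SDPCNetwork, TrainConfig,
                  make_contour_images, make_gabor_dictionary,
                  sample_hierarchical, train)
from sdpc.interaction import (compute_interaction_map, feedback_ratios,
                              fit_orientation_bank, plot_interaction_map)
from sdpc.synthetic import make_colinear_dictionary

d1, orientations = make_gabor_dictionary(8, 9, seed=0)
d2 = make_colinear_dictionary(orientations, 9)
scenes = sample_hierarchical(d1, d2, (4, 4), 240, n_active=2,
                             noise=(0.01, 0.01), seed=21)
network = SDPCNetwork([LayerSpec(8, 1, (9, 9), 1, 0.3),
                       LayerSpec(8, 8, (9, 9), 1, 0.05)], rng_seed=9)
print("training a 2-layer model on 240 synthetic scenes ...")
train([s.image for s in scenes], network,
      TrainConfig(epochs=10, learning_rates=(0.1, 0.1), rng_seed=3,
                  lr_decay=0.92, recycle_unused=True),
      InferenceConfig(feedback_strength=1.0, max_iterations=200))

bank = fit_orientation_bank(network.dictionaries[0])
print(f"{bank.n_kept}/{len(bank.orientations)} features kept by the Gabor fit")

ratios = {"end": [], "side": [], "center": []}
for feature in bank.kept_indices[:4]:
    theta = bank.orientations[feature]
    images = np.concatenate([
        make_contour_images(theta=theta, seed=1000 * feature + s)
        for s in range(5)])
    maps = {}
    for k_fb in (0.0, 1.0):
        cfg = InferenceConfig(feedback_strength=k_fb, max_iterations=300)
        maps[k_fb] = compute_interaction_map(network, images, bank, feature, cfg)
    r = feedback_ratios(maps[1.0], maps[0.0])
    for region in ratios:
        ratios[region].append(r.r_a[region])
    if feature == bank.kept_indices[0]:
        for k_fb, m in maps.items():
            plot_interaction_map(m, f"interaction_map_kfb{k_fb:g}.png")

for region, values in ratios.items():
    print(f"median activity ratio r_a({region}-zone) = {np.median(values):.3f}")
print("r_a > 1: feedback amplifies that region; r_a < 1: feedback suppresses "
      "it. Amplification along the contour axis (end-zone) together with "
      "suppression at the classical receptive field (center) is the "
      "association-field signature of contour integration.")
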