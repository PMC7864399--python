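"""Shared fixtures: planted generative models and one trained toy network.

The two-layer toy network is expensive to train, so it is built once per
session and reused by every analysis-level test. Its study conditions
(scene statistics, architecture, penalties, training schedule) are the
package defaults documented in docs/methods.md.
"""

import numpy as np
import pytest

from sdpc import (InferenceConfig, LayerSpec, SDPCNetwork, TrainConfig,
                  make_gabor_dictionary, sample_hierarchical, train)
from sdpc.synthetic import make_colinear_dictionary

TOY_SEEDS = {"scenes": 21, "init": 9, "train": 3, "eval_scenes": 77}


@pytest.fixture(scope="session")
def planted_model():
    """Planted dictionaries: 8 oriented Gabors and their co-linear layer-2 atoms."""
    d1, orientations = make_gabor_dictionary(8, 9, seed=0)
    d2 = make_colinear_dictionary(orientations, 9)
    return d1, d2, orientations


@pytest.fixture(scope="session")
def toy_network(planted_model):
    """A 2-layer network trained (k_FB = 1) on scenes from the planted model."""
    d1, d2, _ = planted_model
    scenes = sample_hierarchical(d1, d2, (4, 4), 240, n_active=2,
                                 noise=(0.01, 0.01), seed=TOY_SEEDS["scenes"])
    specs = [LayerSpec(8, 1, (9, 9), 1, 0.3), LayerSpec(8, 8, (9, 9), 1, 0.05)]
    network = SDPCNetwork(specs, rng_seed=TOY_SEEDS["init"])
    config = TrainConfig(epochs=10, learning_rates=(0.1, 0.1), momentum=0.9,
                         batch_size=10, rng_seed=TOY_SEEDS["train"], lr_decay=0.92,
                         recycle_unused=True, recycle_threshold=0.05)
    train([s.image for s in scenes], network, config,
          InferenceConfig(feedback_strength=1.0, max_iterations=200))
    return network


@pytest.fixture(scope="session")
def eval_scenes(planted_model):
    """Held-out scenes from the same generative process as the training set."""
    d1, d2, _ = planted_model
    return sample_hierarchical(d1, d2, (4, 4), 60, n_active=2,
                               noise=(0.01, 0.01), seed=TOY_SEEDS["eval_scenes"])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
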