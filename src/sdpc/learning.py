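"""Dictionary learning: alternate converged inference with Hebbian-like updates.

After the activity maps of a batch have converged, each layer's atoms
move along the correlation between the layer's activity and its
prediction residual (the gradient of the layer loss with respect to the
atoms), with classical heavy-ball momentum, and are then l2-normalized
— without the renormalization, scaling an atom up and its coefficients
down leaves every loss unchanged, so the solution would be redundant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .inference import layer_loss, run_inference
from .network import Dictionary, InferenceConfig, SDPCNetwork
from .operators import synthesize

__all__ = ["TrainConfig", "dictionary_gradient", "dictionary_update",
           "normalize_atoms", "train"]


@dataclass
class TrainConfig:
    """Training-loop parameters.

    ``learning_rates`` has one entry per layer; the batch gradient is
    averaged (not summed) over the batch, so rates are batch-size
    independent. ``max_update_norm`` guards against exploding steps:
    if any atom moves by more than this factor of its norm in one
    update (before renormalization), the learning rate is too high.
    """

    epochs: int = 10
    learning_rates: tuple[float, ...] = (1e-4, 5e-3)
    momentum: float = 0.9
    batch_size: int = 10
    rng_seed: int = 0
    max_update_norm: float = 10.0
    lr_decay: float = 1.0  # per-epoch multiplicative decay of all learning rates
    recycle_unused: bool = False  # re-seed near-silent atoms from data patches
    recycle_threshold: float = 0.01  # min activation probability, fraction of uniform

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if any(lr < 0 for lr in self.learning_rates):
            raise ValueError("learning rates must be >= 0")


def dictionary_gradient(atoms: np.ndarray, activity: np.ndarray, target: np.ndarray,
                        stride: int = 1) -> np.ndarray:
    """Gradient of ``1/2 ||target - D^T activity||^2`` w.r.t. the atoms.

    Equals minus the correlation of the activity map with the residual
    at every kernel offset.
    """
    residual = target - synthesize(atoms, activity, stride)
    w, h = atoms.shape[2:]
    windows = sliding_window_view(residual, (w, h), axis=(1, 2))[:, ::stride, ::stride]
    # windows: [n_c, w_m, h_m, w, h]; activity: [n_f, w_m, h_m]
    return -np.einsum("jab,mabpq->jmpq", activity, windows, optimize=True)


def normalize_atoms(dictionary: Dictionary, rng: np.random.Generator | None = None) -> Dictionary:
    """Rescale every atom to unit l2 norm, in place.

    A numerically zero atom cannot be normalized; it is reinitialized
    from the standard normal (with a warning) and then normalized, which
    restarts a dead feature instead of propagating NaNs.
    """
    norms = dictionary.atom_norms()
    dead = norms < 1e-300
    if np.any(dead):
        warnings.warn(f"reinitializing {int(dead.sum())} zero atom(s)")
        rng = rng or np.random.default_rng(0)
        dictionary.atoms[dead] = rng.standard_normal(dictionary.atoms[dead].shape)
        norms = dictionary.atom_norms()
    dictionary.atoms /= norms[:, None, None, None]
    return dictionary


@dataclass
class MomentumState:
    """Heavy-ball velocity per layer."""

    velocities: list[np.ndarray] = field(default_factory=list)

    @classmethod
    def for_network(cls, network: SDPCNetwork) -> "MomentumState":
        return cls([np.zeros_like(d.atoms) for d in network.dictionaries])


def dictionary_update(dictionary: Dictionary, activity: np.ndarray, target: np.ndarray,
                      learning_rate: float, stride: int = 1,
                      momentum: float = 0.0, velocity: np.ndarray | None = None,
                      max_update_norm: float = 10.0,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """One learning step for a single layer; returns the new velocity.

    The dictionary is modified in place: heavy-ball step down the
    residual-correlation gradient, then atom renormalization.
    """
    grad = dictionary_gradient(dictionary.atoms, activity, target, stride)
    if velocity is None:
        velocity = np.zeros_like(grad)
    velocity = momentum * velocity - learning_rate * grad
    step_norms = np.linalg.norm(velocity.reshape(len(velocity), -1), axis=1)
    if np.any(step_norms > max_update_norm * np.maximum(dictionary.atom_norms(), 1e-12)):
        raise RuntimeError(
            "dictionary update explodes (step norm exceeds "
            f"{max_update_norm}x atom norm); lower the learning rate")
    dictionary.atoms += velocity
    normalize_atoms(dictionary, rng)
    return velocity


def _recycle_unused(network: SDPCNetwork, usage: list[np.ndarray],
                    images, momentum_state: "MomentumState",
                    rng: np.random.Generator, threshold: float) -> None:
    """Re-seed atoms that captured almost no activity during the epoch.

    A feature whose share of active units fell below ``threshold`` times
    the uniform share is re-initialized — first-layer atoms from a random
    (mean-subtracted, normalized) image patch, deeper atoms from the
    standard normal — and its momentum is cleared. This is the usual cure
    for dead or duplicated features in dictionary learning.
    """
    for i, counts in enumerate(usage):
        total = counts.sum()
        if total == 0:
            continue
        dead = counts < threshold * total / len(counts)
        if not np.any(dead):
            continue
        d = network.dictionaries[i]
        for j in np.flatnonzero(dead):
            if i == 0:
                img = np.atleast_3d(np.asarray(images[rng.integers(len(images))],
                                               dtype=float))
                img = img if img.ndim == 3 else img[None]
                w, h = network.specs[0].kernel_size
                x = rng.integers(0, max(img.shape[1] - w, 0) + 1)
                y = rng.integers(0, max(img.shape[2] - h, 0) + 1)
                patch = img[:, x:x + w, y:y + h].copy()
                patch -= patch.mean()
                d.atoms[j] = patch if np.linalg.norm(patch) > 0 else \
                    rng.standard_normal(d.atoms[j].shape)
            else:
                d.atoms[j] = rng.standard_normal(d.atoms[j].shape)
            momentum_state.velocities[i][j] = 0.0
        normalize_atoms(d, rng)


def train(images: list[np.ndarray] | np.ndarray, network: SDPCNetwork,
          train_config: TrainConfig, inference_config: InferenceConfig | None = None,
          checkpoint_every: int = 0, checkpoint_hook=None) -> pd.DataFrame:
    """Alternate converged inference and dictionary learning over a dataset.

    ``images`` are assumed preprocessed. The feedback strength during
    training defaults to 1 (it is varied only at evaluation time).
    Returns a per-epoch history (losses, sparsity fractions, convergence
    rate); the network's dictionaries are trained in place.
    Deterministic given ``train_config.rng_seed``.
    """
    if inference_config is None:
        inference_config = InferenceConfig(feedback_strength=1.0)
    if len(train_config.learning_rates) != network.n_layers:
        raise ValueError("need one learning rate per layer")
    rng = np.random.default_rng(train_config.rng_seed)
    momentum_state = MomentumState.for_network(network)
    n = len(images)
    rows = []
    for epoch in range(train_config.epochs):
        rates = [lr * train_config.lr_decay ** epoch
                 for lr in train_config.learning_rates]
        order = rng.permutation(n)
        epoch_losses = np.zeros(network.n_layers)
        epoch_sparsity = np.zeros(network.n_layers)
        usage = [np.zeros(d.n_features) for d in network.dictionaries]
        n_converged = 0
        for start in range(0, n, train_config.batch_size):
            batch = [images[i] for i in order[start:start + train_config.batch_size]]
            grads = [np.zeros_like(d.atoms) for d in network.dictionaries]
            for image in batch:
                state = run_inference(network, image, inference_config)
                n_converged += state.all_converged
                x = network.fit_input(image)
                acts = [a.values for a in state.activities]
                for i in range(network.n_layers):
                    target = x if i == 0 else acts[i - 1]
                    grads[i] += dictionary_gradient(
                        network.dictionaries[i].atoms, acts[i], target,
                        network.specs[i].stride)
                    epoch_losses[i] += layer_loss(
                        network, acts, x, i, k_fb=inference_config.feedback_strength)
                    epoch_sparsity[i] += state.activities[i].sparsity_fraction()
                    usage[i] += np.count_nonzero(acts[i] > 0, axis=(1, 2))
            for i in range(network.n_layers):
                if rates[i] == 0:
                    continue
                grad = grads[i] / len(batch)
                v = momentum_state.velocities[i]
                v = train_config.momentum * v - rates[i] * grad
                d = network.dictionaries[i]
                step_norms = np.linalg.norm(v.reshape(len(v), -1), axis=1)
                if np.any(step_norms > train_config.max_update_norm):
                    raise RuntimeError(
                        f"layer {i} dictionary update explodes; lower the learning rate")
                d.atoms += v
                normalize_atoms(d, rng)
                momentum_state.velocities[i] = v
        if train_config.recycle_unused:
            _recycle_unused(network, usage, images, momentum_state, rng,
                            train_config.recycle_threshold)
        if not np.all(np.isfinite(epoch_losses)):
            raise RuntimeError(f"non-finite loss at epoch {epoch}: {epoch_losses}")
        row = {"epoch": epoch, "converged_fraction": n_converged / n}
        for i in range(network.n_layers):
            row[f"loss_{i + 1}"] = epoch_losses[i] / n
            row[f"sparsity_{i + 1}"] = epoch_sparsity[i] / n
        rows.append(row)
        if checkpoint_every and checkpoint_hook and (epoch + 1) % checkpoint_every == 0:
            checkpoint_hook(epoch, network)
    return pd.DataFrame(rows)
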