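"""Activity inference: proximal-gradient descent of the per-layer losses.

Each layer ``i`` minimizes its local loss

    L_i = 1/2 ||g_{i-1} - D_i^T g_i||^2
        + k_FB/2 ||g_i - D_{i+1}^T g_{i+1}||^2   (absent for the top layer)
        + lambda_i ||g_i||_1,      subject to g_i >= 0,

where ``g_0`` is the preprocessed image. The update alternates a
gradient step on the smooth terms with a non-negative soft threshold
(ISTA), optionally accelerated with FISTA momentum. One outer iteration
sweeps layers bottom-up, each layer using the freshest neighbour
activities (Gauss-Seidel order). All activity maps start at zero; a
layer has reached a fixed point when its relative change falls below
the configured threshold (an all-zero map counts as converged: zero is
a valid fixed point for large penalties).
"""

from __future__ import annotations

import math

import numpy as np

from .network import ActivityMap, InferenceConfig, NetworkState, SDPCNetwork
from .operators import analyze, soft_threshold, synthesize

__all__ = ["layer_loss", "inference_step", "run_inference", "DivergenceError"]


class DivergenceError(RuntimeError):
    """Non-finite values appeared during inference."""


def _prediction(network: SDPCNetwork, activities: list[np.ndarray], i: int) -> np.ndarray:
    """Top-down prediction of layer ``i``'s representation by layer ``i + 1``."""
    return synthesize(network.dictionaries[i + 1].atoms, activities[i + 1],
                      network.specs[i + 1].stride)


def _smooth_gradient(network: SDPCNetwork, activities: list[np.ndarray],
                     image: np.ndarray, i: int, k_fb: float) -> np.ndarray:
    below = image if i == 0 else activities[i - 1]
    spec = network.specs[i]
    atoms = network.dictionaries[i].atoms
    residual = below - synthesize(atoms, activities[i], spec.stride)
    grad = -analyze(atoms, residual, spec.stride)
    if i + 1 < network.n_layers and k_fb > 0:
        grad = grad + k_fb * (activities[i] - _prediction(network, activities, i))
    return grad


def _step_size(network: SDPCNetwork, grid_shape: tuple[int, int], i: int,
               config: InferenceConfig) -> float:
    L = network.lipschitz(i, grid_shape)
    if config.step_size_mode == "coupled" and i + 1 < network.n_layers:
        L = L + config.feedback_strength
    return 1.0 / L


def layer_loss(network: SDPCNetwork, activities: list[np.ndarray], image: np.ndarray,
               layer_index: int, k_fb: float | None = None,
               lambda_sparsity: float | None = None) -> float:
    """Evaluate one layer's loss at the given activities.

    With ``k_fb = 0`` (or at the top layer) this is the convolutional
    LASSO objective of the layer.
    """
    network._check_index(layer_index)
    spec = network.specs[layer_index]
    lam = spec.lambda_sparsity if lambda_sparsity is None else lambda_sparsity
    k = 1.0 if k_fb is None else k_fb
    below = image if layer_index == 0 else activities[layer_index - 1]
    pred = synthesize(network.dictionaries[layer_index].atoms, activities[layer_index],
                      spec.stride)
    loss = 0.5 * float(np.sum((below - pred) ** 2))
    if layer_index + 1 < network.n_layers and k > 0:
        fb = activities[layer_index] - _prediction(network, activities, layer_index)
        loss += 0.5 * k * float(np.sum(fb ** 2))
    loss += lam * float(np.sum(np.abs(activities[layer_index])))
    return loss


def inference_step(network: SDPCNetwork, activities: list[np.ndarray], image: np.ndarray,
                   layer_index: int, config: InferenceConfig,
                   iteration: int = 0) -> np.ndarray:
    """One plain proximal-gradient (ISTA) update of a single layer.

    Returns the new non-negative activity array; neighbours are held
    fixed. Raises :class:`DivergenceError` if non-finite values appear.
    """
    spec = network.specs[layer_index]
    eta = _step_size(network, activities[layer_index].shape[1:], layer_index, config)
    k = config.feedback_strength
    grad = _smooth_gradient(network, activities, image, layer_index, k)
    new = soft_threshold(activities[layer_index] - eta * grad, eta * spec.lambda_sparsity)
    if not np.all(np.isfinite(new)):
        raise DivergenceError(
            f"non-finite activity in layer {layer_index} at iteration {iteration}")
    return new


def _relative_change(new: np.ndarray, old: np.ndarray) -> float:
    num = float(np.linalg.norm(new - old))
    den = float(np.linalg.norm(new))
    if den == 0.0:
        return 0.0 if num == 0.0 else math.inf
    return num / den


def run_inference(network: SDPCNetwork, image: np.ndarray,
                  config: InferenceConfig) -> NetworkState:
    """Infer all activity maps for one image.

    Runs Gauss-Seidel sweeps of per-layer proximal steps (FISTA momentum
    per layer unless ``config.acceleration == "ista"``) until every
    layer satisfies the fixed-point criterion or ``max_iterations`` is
    reached; in the latter case the state is returned with the
    unconverged layers flagged, never silently.
    """
    x = network.fit_input(image)
    shapes = network.activity_shapes(x.shape[1:])
    n = network.n_layers
    acts = [np.zeros((network.specs[i].n_features, *shapes[i])) for i in range(n)]
    mom = [a.copy() for a in acts]  # FISTA extrapolation points
    t_seq = [1.0] * n
    fista = config.acceleration == "fista"
    converged = [False] * n
    iteration = 0
    for iteration in range(1, config.max_iterations + 1):
        prev = [a.copy() for a in acts]
        for i in range(n):
            point = list(acts)
            if fista:
                point[i] = mom[i]
            grad = _smooth_gradient(network, point, x, i, config.feedback_strength)
            eta = _step_size(network, shapes[i], i, config)
            new = soft_threshold(point[i] - eta * grad,
                                 eta * network.specs[i].lambda_sparsity)
            if not np.all(np.isfinite(new)):
                raise DivergenceError(
                    f"non-finite activity in layer {i} at iteration {iteration}")
            if fista:
                restart = config.fista_restart and \
                    float(np.vdot(mom[i] - new, new - acts[i])) > 0.0
                if restart:
                    t_next, mom[i] = 1.0, new.copy()
                else:
                    t_next = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * t_seq[i] ** 2))
                    mom[i] = new + ((t_seq[i] - 1.0) / t_next) * (new - acts[i])
                t_seq[i] = t_next
            acts[i] = new
        converged = [
            _relative_change(acts[i], prev[i]) < config.fixed_point_threshold
            for i in range(n)
        ]
        if all(converged):
            break

    residuals = []
    losses = []
    for i in range(n):
        below = x if i == 0 else acts[i - 1]
        pred = synthesize(network.dictionaries[i].atoms, acts[i], network.specs[i].stride)
        residuals.append(below - pred)
        losses.append(layer_loss(network, acts, x, i, k_fb=config.feedback_strength))
    return NetworkState(
        activities=[ActivityMap(a, layer_index=i) for i, a in enumerate(acts)],
        residuals=residuals,
        losses=losses,
        n_iterations=iteration,
        converged=converged,
    )
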