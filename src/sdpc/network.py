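"""Layered network container: layer specs, dictionaries, and back-projection.

A network is an ordered stack of convolutional sparse-coding layers.
Layer ``i`` holds a dictionary ``D_i`` whose synthesis operator predicts
the representation of layer ``i - 1`` (layer 0 being the preprocessed
image). Feedforward and feedback connections share the same weights:
analysis uses ``D_i``, synthesis its transpose.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .operators import (DimensionError, activity_grid_shape, lipschitz_constant,
                        synthesize)

__all__ = [
    "LayerSpec",
    "Dictionary",
    "ActivityMap",
    "NetworkState",
    "InferenceConfig",
    "SDPCNetwork",
]


@dataclass(frozen=True)
class LayerSpec:
    """Static description of one layer.

    Parameters
    ----------
    n_features : int
        Number of atoms (feature maps) in the layer.
    n_channels : int
        Channel count of the representation the layer predicts.
    kernel_size : (int, int)
        Spatial extent ``(w, h)`` of each atom.
    stride : int
        Spatial subsampling factor; must not exceed the kernel side, so
        receptive fields tile or overlap the input without gaps.
    lambda_sparsity : float
        l1 penalty weight on the layer's activity.
    """

    n_features: int
    n_channels: int
    kernel_size: tuple[int, int]
    stride: int = 1
    lambda_sparsity: float = 0.0

    def __post_init__(self) -> None:
        if self.n_features < 1 or self.n_channels < 1:
            raise ValueError("n_features and n_channels must be >= 1")
        w, h = self.kernel_size
        if w < 1 or h < 1:
            raise ValueError("kernel sides must be >= 1")
        if not (1 <= self.stride <= min(w, h)):
            raise ValueError(
                f"stride must be in [1, min kernel side]; got {self.stride} for kernel {self.kernel_size}"
            )
        if self.lambda_sparsity < 0:
            raise ValueError("lambda_sparsity must be >= 0")


@dataclass
class Dictionary:
    """One layer's bank of convolutional atoms, shape ``[n_f, n_c, w, h]``."""

    atoms: np.ndarray
    layer_index: int = 0

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=float)
        if self.atoms.ndim != 4:
            raise DimensionError("atoms must be a 4-axis tensor [n_f, n_c, w, h]")
        if not np.all(np.isfinite(self.atoms)):
            raise ValueError("dictionary atoms must be finite")

    @property
    def n_features(self) -> int:
        return self.atoms.shape[0]

    def atom_norms(self) -> np.ndarray:
        return np.linalg.norm(self.atoms.reshape(self.n_features, -1), axis=1)


@dataclass
class ActivityMap:
    """Non-negative retinotopic tensor of latent activities, ``[n_f, w_m, h_m]``."""

    values: np.ndarray
    layer_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise DimensionError("activity must be a 3-axis tensor [n_f, x, y]")

    def active_count(self) -> int:
        """Number of strictly positive entries (soft thresholding makes exact zeros)."""
        return int(np.count_nonzero(self.values > 0))

    def sparsity_fraction(self) -> float:
        return self.active_count() / self.values.size


@dataclass
class NetworkState:
    """Full inference state for one input: activities, residuals, losses."""

    activities: list[ActivityMap]
    residuals: list[np.ndarray]
    losses: list[float]
    n_iterations: int = 0
    converged: list[bool] = field(default_factory=list)

    @property
    def all_converged(self) -> bool:
        return all(self.converged)


@dataclass(frozen=True)
class InferenceConfig:
    """Knobs of the activity inference loop.

    ``feedback_strength`` (k_FB) weights the top-down prediction error in
    every non-top layer's loss; 0 decouples the stack into independent
    convolutional LASSO problems. ``fixed_point_threshold`` is the
    relative activity change below which a layer counts as converged.
    ``step_size_mode`` selects the gradient step: ``"coupled"`` uses
    ``1 / (L + k_FB)`` (the smooth term's true Lipschitz constant once
    the feedback quadratic is included, stable for any k_FB),
    ``"literal"`` uses ``1 / L`` from the reconstruction term alone.
    """

    feedback_strength: float = 1.0
    fixed_point_threshold: float = 5e-3
    max_iterations: int = 500
    acceleration: str = "fista"  # "fista" | "ista"
    step_size_mode: str = "coupled"  # "coupled" | "literal"
    fista_restart: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.feedback_strength < 0:
            raise ValueError("feedback_strength must be >= 0")
        if self.fixed_point_threshold <= 0:
            raise ValueError("fixed_point_threshold must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.acceleration not in ("fista", "ista"):
            raise ValueError("acceleration must be 'fista' or 'ista'")
        if self.step_size_mode not in ("coupled", "literal"):
            raise ValueError("step_size_mode must be 'coupled' or 'literal'")

    def with_(self, **kwargs) -> "InferenceConfig":
        return replace(self, **kwargs)


class SDPCNetwork:
    """A stack of sparse-coding layers with shared feedforward/feedback weights."""

    def __init__(self, specs: list[LayerSpec], dictionaries: list[Dictionary] | None = None,
                 rng_seed: int = 0):
        if not specs:
            raise ValueError("network needs at least one layer")
        for i in range(1, len(specs)):
            if specs[i].n_channels != specs[i - 1].n_features:
                raise DimensionError(
                    f"layer {i} expects {specs[i].n_channels} channels but layer "
                    f"{i - 1} provides {specs[i - 1].n_features} features"
                )
        self.specs = list(specs)
        if dictionaries is None:
            rng = np.random.default_rng(rng_seed)
            dictionaries = []
            for i, s in enumerate(specs):
                atoms = rng.standard_normal((s.n_features, s.n_channels, *s.kernel_size))
                d = Dictionary(atoms, layer_index=i)
                d.atoms /= d.atom_norms()[:, None, None, None]
                dictionaries.append(d)
        if len(dictionaries) != len(specs):
            raise ValueError("one dictionary per layer required")
        self.dictionaries = list(dictionaries)

    @property
    def n_layers(self) -> int:
        return len(self.specs)

    # ----- geometry -----------------------------------------------------

    def fit_input(self, image: np.ndarray) -> np.ndarray:
        """Crop an image so every layer's stride tiles it exactly.

        The crop is symmetric: the excess ``e`` on an axis removes
        ``e // 2`` leading and ``e - e // 2`` trailing pixels. Working
        backwards from the top layer we find the largest admissible
        input size not exceeding the given one.
        """
        image = np.asarray(image, dtype=float)
        if image.ndim == 2:
            image = image[None]
        if image.shape[0] != self.specs[0].n_channels:
            raise DimensionError(
                f"image has {image.shape[0]} channels, layer 1 expects {self.specs[0].n_channels}"
            )
        target = [self._admissible_size(image.shape[1 + ax], ax) for ax in range(2)]
        for ax, size in enumerate(target):
            excess = image.shape[1 + ax] - size
            lo = excess // 2
            image = image[:, lo:lo + size, :] if ax == 0 else image[:, :, lo:lo + size]
        return image

    def _admissible_size(self, size: int, axis: int) -> int:
        def grid(n: int) -> int | None:
            for s in self.specs:
                k = s.kernel_size[axis]
                if n < k or (n - k) % s.stride:
                    return None
                n = (n - k) // s.stride + 1
            return n

        for n in range(size, 0, -1):
            if grid(n) is not None:
                return n
        raise DimensionError("image too small for the network's kernels")

    def activity_shapes(self, input_shape: tuple[int, int]) -> list[tuple[int, int]]:
        shapes = []
        cur = input_shape
        for s in self.specs:
            cur = activity_grid_shape(cur, s.kernel_size, s.stride)
            shapes.append(cur)
        return shapes

    # ----- back-projection ----------------------------------------------

    def effective_dictionary(self, layer_index: int) -> np.ndarray:
        """Back-project layer ``layer_index`` atoms into image space.

        Composes the synthesis operators of layers ``layer_index`` down
        to 1. The spatial support per axis grows as
        ``k_eff(i) = k_eff(i-1) + (k_i - 1) * prod(strides of layers < i)``.
        Returns an array ``[n_f_i, n_channels_1, k_eff, k_eff]``.
        """
        self._check_index(layer_index)
        eff = self.dictionaries[layer_index].atoms
        for i in range(layer_index - 1, -1, -1):
            lower = self.dictionaries[i]
            stride = self.specs[i].stride
            eff = np.stack([synthesize(lower.atoms, atom, stride) for atom in eff])
        return eff

    def effective_support(self, layer_index: int) -> tuple[int, int]:
        """Predicted spatial support of a layer's effective atoms (composition law)."""
        self._check_index(layer_index)
        k_eff = list(self.specs[0].kernel_size)
        jump = [self.specs[0].stride] * 2
        for i in range(1, layer_index + 1):
            for ax in range(2):
                k_eff[ax] += (self.specs[i].kernel_size[ax] - 1) * jump[ax]
                jump[ax] *= self.specs[i].stride
        return tuple(k_eff)

    def back_project(self, activity: ActivityMap | np.ndarray,
                     layer_index: int) -> np.ndarray:
        """Project a layer's activity into image space (its 'representation')."""
        self._check_index(layer_index)
        values = activity.values if isinstance(activity, ActivityMap) else np.asarray(activity)
        out = values
        for i in range(layer_index, -1, -1):
            out = synthesize(self.dictionaries[i].atoms, out, self.specs[i].stride)
        return out

    # ----- misc ----------------------------------------------------------

    def lipschitz(self, layer_index: int, grid_shape: tuple[int, int]) -> float:
        cached = getattr(self, "_lipschitz_cache", None)
        if cached is None:
            cached = self._lipschitz_cache = {}
        key = (grid_shape, hash(self.dictionaries[layer_index].atoms.tobytes()))
        entry = cached.get(layer_index)
        if entry is None or entry[0] != key:
            value = lipschitz_constant(
                self.dictionaries[layer_index].atoms, grid_shape,
                self.specs[layer_index].stride)
            cached[layer_index] = (key, value)
            entry = cached[layer_index]
        return entry[1]

    def _check_index(self, layer_index: int) -> None:
        if not (0 <= layer_index < self.n_layers):
            raise IndexError(f"layer index {layer_index} out of range [0, {self.n_layers})")
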