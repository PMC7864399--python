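"""Convolutional synthesis/analysis operators for sparse coding layers.

A layer's dictionary ``D`` is a bank of ``n_f`` atoms of shape
``[n_c, w, h]``. The *synthesis* operator maps an activity map
``gamma`` (shape ``[n_f, w_m, h_m]``) into the space below by placing a
copy of each atom, scaled by the local coefficient, at every activity
position (a strided, transposed 2-D convolution). The *analysis*
operator is its exact adjoint: a strided valid cross-correlation of the
input with each atom. All matrix-vector products in the model's
equations are these two operators.

Boundary handling is "valid": no zero padding, so a ``[w_m, h_m]``
activity grid synthesizes an image of side ``(w_m - 1) * stride + w``
and the operators are exact adjoints without any edge correction.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "synthesize",
    "analyze",
    "soft_threshold",
    "lipschitz_constant",
    "activity_grid_shape",
    "synthesized_shape",
]


class DimensionError(ValueError):
    """Shapes of a dictionary and a tensor are incompatible."""


def _check_atoms(atoms: np.ndarray) -> np.ndarray:
    atoms = np.asarray(atoms, dtype=float)
    if atoms.ndim != 4:
        raise DimensionError(
            f"dictionary must be a 4-axis tensor [n_f, n_c, w, h], got ndim={atoms.ndim}"
        )
    return atoms


def activity_grid_shape(input_shape: tuple[int, int], kernel_shape: tuple[int, int],
                        stride: int) -> tuple[int, int]:
    """Spatial shape ``(w_m, h_m)`` of the activity grid tiling an input.

    Requires the stride to divide ``input - kernel`` evenly; callers crop
    the input first if it does not (see ``network.fit_input``).
    """
    (W, H), (w, h) = input_shape, kernel_shape
    if W < w or H < h:
        raise DimensionError(f"input {input_shape} smaller than kernel {kernel_shape}")
    if (W - w) % stride or (H - h) % stride:
        raise DimensionError(
            f"stride {stride} does not tile input {input_shape} with kernel {kernel_shape}"
        )
    return ((W - w) // stride + 1, (H - h) // stride + 1)


def synthesized_shape(grid_shape: tuple[int, int], kernel_shape: tuple[int, int],
                      stride: int) -> tuple[int, int]:
    """Spatial shape of ``synthesize`` output: ``(w_m - 1) * stride + w`` per axis."""
    return ((grid_shape[0] - 1) * stride + kernel_shape[0],
            (grid_shape[1] - 1) * stride + kernel_shape[1])


from functools import lru_cache


@lru_cache(maxsize=64)
def _scatter_indices(w_m: int, h_m: int, w: int, h: int, stride: int, H: int) -> np.ndarray:
    """Flat output indices of every (activity position, kernel offset) pair."""
    ax = stride * np.arange(w_m)
    by = stride * np.arange(h_m)
    x = ax[:, None, None, None] + np.arange(w)[None, None, :, None]
    y = by[None, :, None, None] + np.arange(h)[None, None, None, :]
    return np.ravel(np.ascontiguousarray(x * H + y))


def synthesize(atoms: np.ndarray, activity: np.ndarray, stride: int = 1) -> np.ndarray:
    """Transposed (synthesis) convolution: predict the layer below.

    Parameters
    ----------
    atoms : ndarray, shape (n_f, n_c, w, h)
    activity : ndarray, shape (n_f, w_m, h_m)
    stride : int
        Spatial subsampling factor of the layer.

    Returns
    -------
    ndarray, shape (n_c, (w_m-1)*stride + w, (h_m-1)*stride + h)
    """
    atoms = _check_atoms(atoms)
    activity = np.asarray(activity, dtype=float)
    n_f, n_c, w, h = atoms.shape
    if activity.ndim != 3 or activity.shape[0] != n_f:
        raise DimensionError(
            f"activity shape {activity.shape} incompatible with dictionary {atoms.shape}"
        )
    w_m, h_m = activity.shape[1:]
    W, H = synthesized_shape((w_m, h_m), (w, h), stride)
    # contrib[m, a, b, p, q]: what activity (a, b) adds at pixel (a*s + p, b*s + q)
    contrib = np.einsum("jmpq,jab->mabpq", atoms, activity, optimize=True)
    flat_idx = _scatter_indices(w_m, h_m, w, h, stride, H)
    out = np.empty((n_c, W, H))
    for m in range(n_c):
        out[m] = np.bincount(flat_idx, weights=contrib[m].ravel(),
                             minlength=W * H).reshape(W, H)
    return out


def analyze(atoms: np.ndarray, tensor: np.ndarray, stride: int = 1) -> np.ndarray:
    """Adjoint of :func:`synthesize`: strided valid correlation with each atom.

    For all matching ``u, v``: ``<synthesize(D, u), v> == <u, analyze(D, v)>``.
    """
    atoms = _check_atoms(atoms)
    tensor = np.asarray(tensor, dtype=float)
    n_f, n_c, w, h = atoms.shape
    if tensor.ndim != 3 or tensor.shape[0] != n_c:
        raise DimensionError(
            f"tensor shape {tensor.shape} incompatible with dictionary {atoms.shape}"
        )
    grid = activity_grid_shape(tensor.shape[1:], (w, h), stride)
    windows = sliding_window_view(tensor, (w, h), axis=(1, 2))[:, ::stride, ::stride]
    # windows: [n_c, w_m, h_m, w, h]
    out = np.einsum("jmpq,mabpq->jab", atoms, windows, optimize=True)
    assert out.shape[1:] == grid
    return out


def soft_threshold(tensor: np.ndarray, alpha: float) -> np.ndarray:
    """Non-negative soft threshold ``max(x - alpha, 0)`` elementwise.

    This is the proximal operator of ``alpha * ||.||_1`` restricted to the
    non-negative orthant; it is what turns a gradient step into one
    inference step, and what makes exact zeros (inactive units) possible.
    """
    if alpha < 0:
        raise ValueError(f"threshold alpha must be >= 0, got {alpha}")
    return np.maximum(np.asarray(tensor, dtype=float) - alpha, 0.0)


def lipschitz_constant(atoms: np.ndarray, grid_shape: tuple[int, int], stride: int = 1,
                       n_iter: int = 100, tol: float = 1e-7,
                       seed: int = 0) -> float:
    """Largest eigenvalue of the composed analyze(synthesize(.)) operator.

    Power iteration on the activity space of spatial shape ``grid_shape``.
    The inference step size is ``1 / L`` (Lipschitz constant of the
    smooth reconstruction term).
    """
    atoms = _check_atoms(atoms)
    if not np.any(atoms):
        raise ValueError("zero dictionary: the reconstruction operator is degenerate")
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((atoms.shape[0], *grid_shape))
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(n_iter):
        Av = analyze(atoms, synthesize(atoms, v, stride), stride)
        lam_new = float(np.linalg.norm(Av))
        if lam_new == 0.0:
            raise ValueError("power iteration collapsed: degenerate operator")
        v = Av / lam_new
        if abs(lam_new - lam) <= tol * max(lam_new, 1.0):
            lam = lam_new
            break
        lam = lam_new
    return lam
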