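"""Synthetic data: planted dictionaries, generative-model scenes, contour stimuli.

Everything the analyses assume about real image ensembles — oriented
edge-like structure, sparse non-negative causes, additive Gaussian
degradation — is emulated here with known ground truth, so the whole
package is testable without any image download. Scenes are sampled from
the model's own hierarchical linear generative process:

    gamma_1 = max(D_2^T gamma_2 + eps_2, 0)     (two-layer scenes)
    x       = D_1^T gamma_1 + eps_1

with the latent maps, noise fields and dictionaries recorded, so the
algebra can be re-checked exactly and support recovery can be scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .network import Dictionary
from .operators import synthesize

__all__ = [
    "gabor_patch",
    "make_gabor_dictionary",
    "SyntheticScene",
    "sample_hierarchical",
    "make_contour_images",
]


def gabor_patch(size: int | tuple[int, int], theta: float, frequency: float,
                sigma: float | None = None, phase: float = 0.0,
                center: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """A 2-D Gabor patch with *stripe* orientation ``theta``.

    ``theta`` (radians) is the orientation of the iso-intensity stripes,
    measured from the first (row) axis towards the second; the carrier
    wave propagates perpendicular to it with spatial ``frequency``
    (cycles/pixel). The patch is zero-mean (DC removed) but not
    normalized.
    """
    if isinstance(size, int):
        size = (size, size)
    if frequency <= 0:
        raise ValueError("frequency must be > 0")
    if sigma is None:
        sigma = min(size) / 5.0
    xs = np.arange(size[0]) - (size[0] - 1) / 2.0 - center[0]
    ys = np.arange(size[1]) - (size[1] - 1) / 2.0 - center[1]
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    across = -X * np.sin(theta) + Y * np.cos(theta)  # perpendicular to the stripes
    envelope = np.exp(-(X ** 2 + Y ** 2) / (2.0 * sigma ** 2))
    patch = envelope * np.cos(2.0 * np.pi * frequency * across + phase)
    patch -= patch.mean()
    return patch


def make_gabor_dictionary(n_features: int, kernel_size: int | tuple[int, int],
                          orientations: np.ndarray | None = None,
                          frequency: float | None = None,
                          sigma: float | None = None,
                          phase: float = 0.0,
                          n_channels: int = 1,
                          seed: int = 0) -> tuple[Dictionary, np.ndarray]:
    """Bank of unit-norm oriented Gabor atoms with known orientations.

    Orientations default to ``n_features`` angles evenly spaced on
    [0, pi). Returns the dictionary and the planted orientation of each
    atom. Raises if the kernel cannot hold one carrier period.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if isinstance(kernel_size, int):
        kernel_size = (kernel_size, kernel_size)
    if frequency is None:
        frequency = 1.5 / min(kernel_size)
    if frequency * min(kernel_size) < 1.0:
        raise ValueError(
            f"kernel {kernel_size} too small for frequency {frequency} (needs one period)")
    if orientations is None:
        orientations = np.arange(n_features) * np.pi / n_features
    orientations = np.mod(np.asarray(orientations, dtype=float), np.pi)
    if orientations.shape != (n_features,):
        raise ValueError("need one orientation per feature")
    atoms = np.stack([
        np.repeat(gabor_patch(kernel_size, th, frequency, sigma, phase)[None],
                  n_channels, axis=0)
        for th in orientations
    ])
    norms = np.linalg.norm(atoms.reshape(n_features, -1), axis=1)
    atoms /= norms[:, None, None, None]
    del seed  # bank is deterministic; kept for interface symmetry
    return Dictionary(atoms, layer_index=0), orientations


def make_colinear_dictionary(orientations: np.ndarray, kernel_size: int | tuple[int, int],
                             ridge_sigma: float = 1.0, length_sigma: float | None = None,
                             ) -> Dictionary:
    """Second-layer atoms encoding short contours in an oriented feature space.

    Atom ``k`` lives in channel ``k`` only and is a non-negative ridge
    through the kernel centre along the direction of ``orientations[k]``
    (Gaussian cross-section ``ridge_sigma``, Gaussian length taper
    ``length_sigma``). Synthesizing such an atom produces co-linear,
    co-oriented first-layer activity — the planted association-field
    structure of the two-layer generative model.
    """
    orientations = np.asarray(orientations, dtype=float)
    n = len(orientations)
    if isinstance(kernel_size, int):
        kernel_size = (kernel_size, kernel_size)
    if length_sigma is None:
        length_sigma = min(kernel_size) / 2.5
    atoms = np.zeros((n, n, *kernel_size))
    xs = np.arange(kernel_size[0]) - (kernel_size[0] - 1) / 2.0
    ys = np.arange(kernel_size[1]) - (kernel_size[1] - 1) / 2.0
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    for k, th in enumerate(orientations):
        along = X * np.cos(th) + Y * np.sin(th)
        across = -X * np.sin(th) + Y * np.cos(th)
        ridge = np.exp(-across ** 2 / (2 * ridge_sigma ** 2)
                       - along ** 2 / (2 * length_sigma ** 2))
        atoms[k, k] = ridge
    atoms /= np.linalg.norm(atoms.reshape(n, -1), axis=1)[:, None, None, None]
    return Dictionary(atoms, layer_index=1)


@dataclass
class SyntheticScene:
    """One generated image with its ground-truth causes.

    The recorded fields satisfy the generative algebra exactly:
    ``image == synthesize(D1, gamma1) + eps1`` and, for two-layer scenes,
    ``gamma1 == synthesize(D2, gamma2) + eps2`` (``eps2`` absorbs the
    non-negativity clipping).
    """

    image: np.ndarray
    gamma1: np.ndarray
    eps1: np.ndarray
    gamma2: np.ndarray | None = None
    eps2: np.ndarray | None = None
    seed: int | None = None


def _sparse_map(rng: np.random.Generator, shape: tuple[int, int, int],
                n_active: int, amplitude: tuple[float, float]) -> np.ndarray:
    size = int(np.prod(shape))
    if not (0 <= n_active <= size):
        raise ValueError(f"requested {n_active} active units in a map of size {size}")
    gamma = np.zeros(size)
    idx = rng.choice(size, size=n_active, replace=False)
    gamma[idx] = rng.uniform(*amplitude, size=n_active)
    return gamma.reshape(shape)


def sample_hierarchical(d1: Dictionary, d2: Dictionary | None,
                        grid_shape: tuple[int, int], n_scenes: int,
                        n_active: int,
                        noise: tuple[float, float] = (0.0, 0.0),
                        stride1: int = 1, stride2: int = 1,
                        amplitude: tuple[float, float] = (0.5, 1.5),
                        seed: int = 0) -> list[SyntheticScene]:
    """Sample scenes from the hierarchical generative model.

    ``grid_shape`` is the spatial shape of the *top* latent map (gamma_2
    if ``d2`` is given, else gamma_1). The top map gets exactly
    ``n_active`` strictly positive entries at uniform positions with
    amplitudes uniform on ``amplitude``; lower maps follow the model's
    linear synthesis plus Gaussian noise and a non-negativity clip.
    """
    rng = np.random.default_rng(seed)
    sigma1, sigma2 = noise
    scenes = []
    for _ in range(n_scenes):
        if d2 is None:
            gamma1 = _sparse_map(rng, (d1.n_features, *grid_shape), n_active, amplitude)
            gamma2 = eps2 = None
        else:
            gamma2 = _sparse_map(rng, (d2.n_features, *grid_shape), n_active, amplitude)
            pred1 = synthesize(d2.atoms, gamma2, stride2)
            noisy1 = pred1 + (sigma2 * rng.standard_normal(pred1.shape) if sigma2 else 0.0)
            gamma1 = np.maximum(noisy1, 0.0)
            eps2 = gamma1 - pred1  # absorbs clipping, keeps the algebra exact
        clean = synthesize(d1.atoms, gamma1, stride1)
        eps1 = sigma1 * rng.standard_normal(clean.shape) if sigma1 else np.zeros_like(clean)
        scenes.append(SyntheticScene(image=clean + eps1, gamma1=gamma1, eps1=eps1,
                                     gamma2=gamma2, eps2=eps2, seed=seed))
    return scenes


def make_contour_images(theta: float, chain_length: int = 6, spacing: float = 3.0,
                        jitter: float = 0.3, size: int = 33,
                        n_images: int = 1, n_distractors: int = 8,
                        patch_size: int = 9, frequency: float | None = None,
                        amplitude: float = 1.0, seed: int = 0) -> np.ndarray:
    """Contour stimuli: a chain of co-oriented, co-linear Gabor patches.

    ``chain_length`` patches of stripe orientation ``theta`` are placed
    along the ``theta`` axis through the image centre, ``spacing``
    pixels apart, with optional i.i.d. Gaussian positional ``jitter``.
    ``n_distractors`` patches of random orientation and position are
    scattered on the background. Returns ``[n_images, 1, size, size]``.
    """
    rng = np.random.default_rng(seed)
    if frequency is None:
        frequency = 1.5 / patch_size
    half_span = spacing * (chain_length - 1) / 2.0
    if half_span + patch_size / 2.0 > size / 2.0:
        raise ValueError("chain does not fit in the image")
    direction = np.array([np.cos(theta), np.sin(theta)])
    centre = (size - 1) / 2.0
    images = np.zeros((n_images, 1, size, size))
    for n in range(n_images):
        canvas = images[n, 0]
        offsets = (np.arange(chain_length) - (chain_length - 1) / 2.0) * spacing
        for off in offsets:
            pos = centre + off * direction
            if jitter:
                pos = pos + jitter * rng.standard_normal(2)
            _stamp(canvas, gabor_patch(patch_size, theta, frequency) * amplitude, pos)
        for _ in range(n_distractors):
            pos = rng.uniform(patch_size / 2.0, size - patch_size / 2.0, size=2)
            if np.linalg.norm(pos - centre) < spacing:  # keep the centre clean
                continue
            th = rng.uniform(0.0, np.pi)
            _stamp(canvas, gabor_patch(patch_size, th, frequency) * amplitude, pos)
    return images


def _stamp(canvas: np.ndarray, patch: np.ndarray, pos: np.ndarray) -> None:
    """Add ``patch`` onto ``canvas`` centred at (fractional) ``pos``, clipped."""
    w, h = patch.shape
    x0 = int(round(pos[0] - (w - 1) / 2.0))
    y0 = int(round(pos[1] - (h - 1) / 2.0))
    xs = slice(max(x0, 0), min(x0 + w, canvas.shape[0]))
    ys = slice(max(y0, 0), min(y0 + h, canvas.shape[1]))
    if xs.start >= xs.stop or ys.start >= ys.stop:
        warnings.warn("patch entirely outside the canvas; skipped")
        return
    canvas[xs, ys] += patch[xs.start - x0:xs.stop - x0, ys.start - y0:ys.stop - y0]
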