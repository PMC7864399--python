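"""Image preprocessing: local contrast normalization and whitening.

LCN is a local subtractive then divisive normalization with a Gaussian
window (std 2 px, per channel, divisive floor 1e-4): it removes slow
luminance gradients and equalizes local contrast. Whitening decorrelates
nearby pixels; the default recipe fits a ZCA transform on small training
patches (9 x 9, eigenvalue floor 1e-2) and applies its central row as a
convolution kernel, which extends the patch-level transform to whole
images. A parameter-free frequency-domain 1/f ("retina-like") whitening
is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve

__all__ = ["local_contrast_normalize", "ZCAWhitener", "whiten_fourier", "preprocess"]


def local_contrast_normalize(image: np.ndarray, sigma: float = 2.0,
                             floor: float = 1e-4) -> np.ndarray:
    """Subtractive then divisive normalization with a Gaussian window.

    A constant image maps to zero everywhere (the divisive step is
    epsilon-regularized, never a division by zero).
    """
    image = _as_chw(image)
    out = np.empty_like(image)
    for c in range(image.shape[0]):
        local_mean = gaussian_filter(image[c], sigma, mode="reflect")
        centered = image[c] - local_mean
        local_sd = np.sqrt(gaussian_filter(centered ** 2, sigma, mode="reflect"))
        out[c] = centered / np.maximum(local_sd, floor)
    return out


def _as_chw(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        image = image[None]
    if image.ndim != 3:
        raise ValueError("image must be [x, y] or [channel, x, y]")
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    return image


@dataclass
class ZCAWhitener:
    """ZCA whitening fitted on image patches, applied as a convolution.

    The ZCA transform ``C^{-1/2}`` of the patch covariance ``C`` is
    symmetric and, for stationary statistics, approximately
    shift-invariant; its central row is then a whitening filter. The
    eigenvalue floor regularizes directions with almost no variance.
    """

    patch_size: int = 9
    eigen_floor: float = 1e-2
    kernel: np.ndarray | None = None
    zca_matrix: np.ndarray | None = None

    def fit(self, images: list[np.ndarray] | np.ndarray, n_patches: int = 20000,
            seed: int = 0) -> "ZCAWhitener":
        rng = np.random.default_rng(seed)
        k = self.patch_size
        patches = []
        images = [_as_chw(im) for im in images]
        per_image = max(1, n_patches // max(len(images), 1))
        for im in images:
            C, W, H = im.shape
            if W < k or H < k:
                raise ValueError("image smaller than the whitening patch")
            xs = rng.integers(0, W - k + 1, size=per_image)
            ys = rng.integers(0, H - k + 1, size=per_image)
            cs = rng.integers(0, C, size=per_image)
            for c, x, y in zip(cs, xs, ys):
                patches.append(im[c, x:x + k, y:y + k].ravel())
        X = np.asarray(patches)
        X = X - X.mean(axis=0)
        cov = X.T @ X / len(X)
        evals, evecs = np.linalg.eigh(cov)
        scale = 1.0 / np.sqrt(np.maximum(evals, self.eigen_floor * evals.max()))
        self.zca_matrix = (evecs * scale) @ evecs.T
        self.kernel = self.zca_matrix[(k * k) // 2].reshape(k, k)
        return self

    def transform_patches(self, patches: np.ndarray) -> np.ndarray:
        """Apply the exact ZCA transform to flattened patches (rows)."""
        if self.zca_matrix is None:
            raise RuntimeError("whitener not fitted")
        return patches @ self.zca_matrix.T

    def transform(self, image: np.ndarray) -> np.ndarray:
        if self.kernel is None:
            raise RuntimeError("whitener not fitted")
        image = _as_chw(image)
        return np.stack([
            fftconvolve(ch, self.kernel[::-1, ::-1], mode="same") for ch in image
        ])


def whiten_fourier(image: np.ndarray, cutoff: float = 0.8) -> np.ndarray:
    """Frequency-domain whitening: amplify amplitude proportionally to |f|.

    Compensates the ~1/f amplitude spectrum of natural images with the
    classic ``|f| * exp(-(|f|/f0)^4)`` filter, ``f0 = cutoff`` as a
    fraction of the Nyquist frequency, so the amplified corner
    frequencies are gently rolled off.
    """
    image = _as_chw(image)
    fx = np.fft.fftfreq(image.shape[1])
    fy = np.fft.fftfreq(image.shape[2])
    rho = np.hypot(*np.meshgrid(fx, fy, indexing="ij"))
    filt = rho * np.exp(-((rho / (cutoff * 0.5)) ** 4))
    out = np.stack([
        np.real(np.fft.ifft2(np.fft.fft2(ch) * filt)) for ch in image
    ])
    return out


def preprocess(image: np.ndarray, lcn: bool = True, whitener: ZCAWhitener | None = None,
               fourier_whitening: bool = False, lcn_sigma: float = 2.0) -> np.ndarray:
    """LCN followed by whitening (ZCA if a fitted whitener is given).

    Output is standardized to zero mean; with both steps off this is a
    plain mean subtraction.
    """
    image = _as_chw(image)
    if lcn:
        image = local_contrast_normalize(image, sigma=lcn_sigma)
    if whitener is not None:
        image = whitener.transform(image)
    elif fourier_whitening:
        image = whiten_fourier(image)
    return image - image.mean()
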