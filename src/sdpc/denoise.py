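"""Feedback denoising evaluation: corrupt, infer, back-project, compare.

Images are corrupted with additive i.i.d. Gaussian noise (in the
preprocessed/normalized intensity units, where the noise standard
deviations of the protocol are meaningful), activities are inferred at
each combination of noise level, feedback strength and first-layer
sparsity, and each layer's back-projected representation is compared to
the *original* (non-degraded) image with the structural similarity
index (SSIM). The baseline is the SSIM between original and noisy
images. No retraining happens across the sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from skimage.metrics import structural_similarity

from .inference import run_inference
from .network import InferenceConfig, SDPCNetwork

__all__ = ["SweepSpec", "corrupt", "ssim", "evaluate_denoising"]


@dataclass
class SweepSpec:
    """Grids of the denoising protocol.

    Defaults follow the study conditions: noise std 0..5, feedback
    strength 0..4, first-layer sparsity {0, 1.5, 3.0}.
    """

    sigmas: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)
    feedback_strengths: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0)
    lambda1_grid: tuple[float, ...] | None = None  # None: keep the network's lambda_1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.sigmas or not self.feedback_strengths:
            raise ValueError("grids must be non-empty")
        if any(s < 0 for s in self.sigmas):
            raise ValueError("noise std must be >= 0")


def corrupt(image: np.ndarray, sigma: float, seed: int = 0) -> np.ndarray:
    """Additive i.i.d. Gaussian noise of standard deviation ``sigma``.

    ``sigma=0`` returns the input unchanged; a fixed seed gives a
    reproducible noise field.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    image = np.asarray(image, dtype=float)
    if sigma == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    return image + sigma * rng.standard_normal(image.shape)


def ssim(image_a: np.ndarray, image_b: np.ndarray) -> float:
    """Structural similarity index between two images, clipped to [0, 1].

    Standard SSIM with an 11 x 11 Gaussian window (sigma 1.5) and the
    default stabilization constants; multi-channel images score the mean
    of the per-channel indices. The data range is taken from the joint
    span of both images so the index is symmetric.
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("images must be finite")
    if a.ndim == 2:
        a, b = a[None], b[None]
    span = float(max(a.max(), b.max()) - min(a.min(), b.min()))
    if span == 0:
        return 1.0
    vals = [
        structural_similarity(ca, cb, gaussian_weights=True, sigma=1.5,
                              use_sample_covariance=False, win_size=11,
                              data_range=span)
        for ca, cb in zip(a, b)
    ]
    return float(np.clip(np.mean(vals), 0.0, 1.0))


def _median_mad(values: np.ndarray) -> tuple[float, float]:
    med = float(np.median(values))
    return med, float(np.median(np.abs(values - med)))


def evaluate_denoising(network: SDPCNetwork, images: list[np.ndarray] | np.ndarray,
                       sweep: SweepSpec,
                       base_config: InferenceConfig | None = None) -> pd.DataFrame:
    """Run the full (sigma, k_FB, lambda_1) sweep and tabulate similarities.

    Returns one row per condition and layer with the median and median
    absolute deviation of SSIM(original, back-projected representation)
    over the image set, the baseline SSIM(original, noisy) summary, the
    number of images whose inference did not converge (recorded, never
    dropped), and the paired one-sided Wilcoxon p-value of the layer
    similarity against the baseline.
    """
    if base_config is None:
        base_config = InferenceConfig()
    lambda1_grid = sweep.lambda1_grid
    if lambda1_grid is None:
        lambda1_grid = (network.specs[0].lambda_sparsity,)
    originals = [network.fit_input(img) for img in images]
    rows = []
    for sigma in sweep.sigmas:
        noisy = [corrupt(img, sigma, seed=sweep.rng_seed + 7919 * i)
                 for i, img in enumerate(originals)]
        baseline = np.array([ssim(o, n) for o, n in zip(originals, noisy)])
        base_med, base_mad = _median_mad(baseline)
        for k_fb in sweep.feedback_strengths:
            for lam1 in lambda1_grid:
                config = base_config.with_(feedback_strength=k_fb)
                saved_spec = network.specs[0]
                network.specs[0] = _with_lambda(saved_spec, lam1)
                try:
                    sims = {i: [] for i in range(network.n_layers)}
                    n_unconverged = 0
                    for orig, noise_img in zip(originals, noisy):
                        state = run_inference(network, noise_img, config)
                        n_unconverged += not state.all_converged
                        for i in range(network.n_layers):
                            recon = network.back_project(state.activities[i], i)
                            sims[i].append(ssim(orig, recon))
                finally:
                    network.specs[0] = saved_spec
                for i in range(network.n_layers):
                    vals = np.array(sims[i])
                    med, mad = _median_mad(vals)
                    diff = vals - baseline
                    if np.allclose(diff, 0):
                        p = 1.0
                    else:
                        p = float(wilcoxon(vals, baseline, alternative="greater",
                                           zero_method="zsplit").pvalue)
                    rows.append({
                        "sigma": sigma, "k_fb": k_fb, "lambda1": lam1,
                        "layer": i + 1, "median": med, "mad": mad,
                        "n": len(vals), "baseline_median": base_med,
                        "baseline_mad": base_mad,
                        "n_unconverged": n_unconverged,
                        "p_vs_baseline": p,
                    })
    return pd.DataFrame(rows)


def _with_lambda(spec, lam):
    from dataclasses import replace
    return replace(spec, lambda_sparsity=lam)
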