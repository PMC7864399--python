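"""Interaction maps: association-field analogues around top-activated units.

The first layer's code assigns each feature a preferred orientation
(obtained by fitting its atom with a Gabor). For a chosen central
orientation, small neighborhoods are cropped around the most strongly
activated units of that feature, the activity of every oriented feature
inside the crop is normalized by its marginal (map-wide) activity, and
the normalized activities are combined across orientations as complex
numbers ``a * exp(j * theta)``. The argument and modulus of the complex
mean give, at every position of the neighborhood, a resulting
orientation and magnitude — the interaction map. Comparing maps with
and without feedback quantifies how top-down signals reshape the
extra-classical surround (co-linearity, co-circularity, activity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .inference import run_inference
from .network import Dictionary, InferenceConfig, SDPCNetwork
from .synthetic import gabor_patch

__all__ = [
    "OrientationBank", "InteractionMap", "fit_gabor", "fit_orientation_bank",
    "extract_top_neighborhoods", "marginal_activity", "normalized_activity",
    "circular_average", "compute_interaction_map", "colinearity_deviation",
    "cocircularity_deviation", "cocircular_reference", "region_masks",
    "feedback_ratios",
]


# --------------------------------------------------------------------------
# Orientation extraction
# --------------------------------------------------------------------------

def _gabor_quality(patch: np.ndarray, theta: float, frequency: float,
                   sigma: float) -> float:
    """Fraction of the patch's energy captured by the Gabor pair (theta, f, sigma).

    Projects onto the two-dimensional subspace spanned by the even and
    odd Gabor of the given parameters (orthonormalized), which makes the
    score phase-invariant and confined to [0, 1].
    """
    even = gabor_patch(patch.shape, theta, frequency, sigma, phase=0.0).ravel()
    odd = gabor_patch(patch.shape, theta, frequency, sigma, phase=np.pi / 2).ravel()
    basis = np.stack([even, odd], axis=1)
    q, _ = np.linalg.qr(basis)
    flat = patch.ravel()
    norm = np.linalg.norm(flat)
    if norm == 0:
        return 0.0
    return float(np.linalg.norm(q.T @ flat) / norm)


def fit_gabor(atom: np.ndarray, n_theta: int = 24,
              frequencies: tuple[float, ...] | None = None,
              sigmas: tuple[float, ...] | None = None) -> tuple[float, float]:
    """Fit one atom with a Gabor; return (orientation in [0, pi), quality in [0, 1]).

    Grid search over orientation, carrier frequency and envelope width,
    then a bounded 1-D refinement of the orientation. Quality is the
    *orientation-selective* explained energy ``(q* - q_orth) / (1 -
    q_orth)``, where ``q*`` is the energy fraction captured by the best
    phase-invariant Gabor pair and ``q_orth`` what the same pair
    captures at the orthogonal orientation (energy a fit explains
    regardless of orientation does not count). A clean oriented atom
    scores near 1; isotropic blobs and textures score near 0 no matter
    how well a degenerate Gabor happens to fit them, and are meant to
    be rejected by the caller's threshold.
    """
    atom = np.asarray(atom, dtype=float)
    if atom.ndim == 3:
        atom = atom.mean(axis=0)
    if atom.ndim != 2:
        raise ValueError("atom must be a 2-D patch or [channel, w, h]")
    side = min(atom.shape)
    if frequencies is None:
        frequencies = (1.0 / side, 1.5 / side, 2.0 / side, 3.0 / side)
    if sigmas is None:
        sigmas = (side / 6.0, side / 4.0, side / 2.5)
    best = (0.0, 0.0, frequencies[0], sigmas[0])
    for theta in np.arange(n_theta) * np.pi / n_theta:
        for f in frequencies:
            for s in sigmas:
                q = _gabor_quality(atom, theta, f, s)
                if q > best[0]:
                    best = (q, theta, f, s)
    quality, theta0, f0, s0 = best
    if quality == 0.0:
        return 0.0, 0.0
    res = minimize_scalar(
        lambda t: -_gabor_quality(atom, t, f0, s0),
        bounds=(theta0 - np.pi / n_theta, theta0 + np.pi / n_theta),
        method="bounded", options={"xatol": 1e-4})
    theta = float(np.mod(res.x, np.pi))
    q_best = float(-res.fun)
    q_orth = _gabor_quality(atom, theta + np.pi / 2.0, f0, s0)
    if q_orth >= 1.0 - 1e-12:
        return theta, 0.0
    return theta, float(np.clip((q_best - q_orth) / (1.0 - q_orth), 0.0, 1.0))


@dataclass
class OrientationBank:
    """Fitted preferred orientation per feature, with a keep/reject flag."""

    orientations: np.ndarray  # radians in [0, pi)
    qualities: np.ndarray
    keep: np.ndarray  # bool mask; rejected features never enter the circular stats
    threshold: float = 0.5

    @property
    def kept_indices(self) -> np.ndarray:
        return np.flatnonzero(self.keep)

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())


def fit_orientation_bank(dictionary: Dictionary | np.ndarray,
                         quality_threshold: float = 0.5) -> OrientationBank:
    """Fit every atom of a layer-1 dictionary; reject poorly oriented ones."""
    atoms = dictionary.atoms if isinstance(dictionary, Dictionary) else np.asarray(dictionary)
    fits = [fit_gabor(a) for a in atoms]
    orientations = np.array([f[0] for f in fits])
    qualities = np.array([f[1] for f in fits])
    return OrientationBank(orientations, qualities, qualities >= quality_threshold,
                           quality_threshold)


# --------------------------------------------------------------------------
# Map construction
# --------------------------------------------------------------------------

def extract_top_neighborhoods(activity: np.ndarray, feature_index: int, k: int = 10,
                              window: int = 9) -> tuple[list[np.ndarray],
                                                        list[tuple[int, int]]]:
    """Crop ``window x window`` neighborhoods around the strongest units.

    Centers are the ``k`` largest entries of the chosen feature plane;
    positions closer than half a window to the border are skipped and
    replaced by the next-ranked ones. Ties resolve deterministically in
    (x, then y) scan order. Returns possibly fewer than ``k`` crops if
    the map has too few valid centers.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    half = window // 2
    plane = activity[feature_index]
    order = np.argsort(-plane, axis=None, kind="stable")
    crops, centers = [], []
    for flat in order:
        if len(crops) == k:
            break
        x, y = np.unravel_index(flat, plane.shape)
        if not (half <= x < plane.shape[0] - half and half <= y < plane.shape[1] - half):
            continue
        crops.append(activity[:, x - half:x + half + 1, y - half:y + half + 1].copy())
        centers.append((int(x), int(y)))
    return crops, centers


def marginal_activity(activity: np.ndarray, feature_index: int,
                      center: tuple[int, int], window: int) -> float:
    """Mean of one feature plane outside an excluded window.

    The marginal is the expected activity of that orientation anywhere
    in the retinotopic map, i.e. the spatial average excluding the
    neighborhood under study.
    """
    half = window // 2
    x, y = center
    plane = activity[feature_index]
    mask = np.ones(plane.shape, dtype=bool)
    mask[max(x - half, 0):x + half + 1, max(y - half, 0):y + half + 1] = False
    if not mask.any():
        raise ValueError("excluded window covers the whole map; marginal undefined")
    return float(plane[mask].mean())


def normalized_activity(crop: np.ndarray, marginals: np.ndarray,
                        floor: float | None = None) -> np.ndarray:
    """Relative deviation of a crop from the marginal activity, per feature.

    ``a = (crop - marginal) / marginal``: positive where the local
    activity exceeds what that orientation does on average, negative
    below. ``floor`` (default ``1e-6 *`` the largest marginal) guards
    against zero marginals; pass ``floor=0`` to get a hard error
    instead.
    """
    marginals = np.asarray(marginals, dtype=float)
    if floor is None:
        floor = 1e-6 * float(marginals.max()) if marginals.max() > 0 else 1e-12
    if floor == 0 and np.any(marginals <= 0):
        raise ZeroDivisionError("zero marginal activity and no floor")
    denom = np.maximum(marginals, floor)
    return (crop - marginals[:, None, None]) / denom[:, None, None]


def circular_average(normalized_crops: list[np.ndarray] | np.ndarray,
                     orientations: np.ndarray,
                     doubled_angle: bool = False) -> np.ndarray:
    """Complex mean over orientations (and crops) of the normalized activity.

    Each crop contributes ``(1/n) sum_theta a[theta] * exp(j*theta)``
    per position; crops are averaged arithmetically in the complex
    domain before any argument/modulus is taken. With
    ``doubled_angle=True`` the phasor is ``exp(j*2*theta)``, the
    standard way to put axial (period-pi) data on the full circle; the
    default follows the single-angle form.
    """
    orientations = np.asarray(orientations, dtype=float)
    if orientations.size == 0:
        raise ValueError("empty feature set")
    crops = np.asarray(normalized_crops, dtype=float)
    if crops.ndim == 3:
        crops = crops[None]
    if crops.shape[1] != orientations.size:
        raise ValueError("one orientation per feature plane required")
    phase = 2.0 * orientations if doubled_angle else orientations
    phasors = np.exp(1j * phase)
    fields = np.einsum("cfxy,f->cxy", crops, phasors) / orientations.size
    return fields.mean(axis=0)


@dataclass
class InteractionMap:
    """Per-position resulting orientation and magnitude around strong units."""

    complex_field: np.ndarray
    theta_c: float
    feedback_strength: float = 0.0
    n_images: int = 0
    n_crops: int = 0
    doubled_angle: bool = False
    marginal_field: np.ndarray | None = None

    @property
    def window(self) -> int:
        return self.complex_field.shape[0]

    @property
    def orientation(self) -> np.ndarray:
        """Resulting orientation (radians); atan2 of the complex mean."""
        ang = np.angle(self.complex_field)
        return ang / 2.0 if self.doubled_angle else ang

    @property
    def magnitude(self) -> np.ndarray:
        """Resulting activity: modulus of the complex mean (>= 0)."""
        return np.abs(self.complex_field)


def compute_interaction_map(network: SDPCNetwork, images: np.ndarray,
                            bank: OrientationBank, central_feature: int,
                            config: InferenceConfig, k: int = 10,
                            window: int = 9, doubled_angle: bool = False,
                            activities: list[np.ndarray] | None = None) -> InteractionMap:
    """Aggregate an interaction map for one central feature over many images.

    For each image, layer-1 activities are inferred (or taken from
    ``activities`` if provided), neighborhoods are cropped around the
    ``k`` strongest units of the central feature, normalized by the
    marginal activity of each kept feature, and accumulated as complex
    fields. The per-crop and per-image aggregation is an arithmetic mean
    of the complex fields. A companion field built from the marginal
    activity itself (all-zero normalized activity) is not needed — the
    marginal enters through the normalization.
    """
    if not bank.keep[central_feature]:
        raise ValueError(f"central feature {central_feature} was rejected by the Gabor fit")
    kept = bank.kept_indices
    orientations = bank.orientations[kept]
    fields, n_crops, n_used = [], 0, 0
    if activities is None:
        activities = [
            run_inference(network, img, config).activities[0].values for img in images
        ]
    for gamma1 in activities:
        crops, centers = extract_top_neighborhoods(gamma1, central_feature, k, window)
        if not crops:
            continue
        normed = []
        for crop, center in zip(crops, centers):
            marginals = np.array([
                marginal_activity(gamma1, f, center, window) for f in kept
            ])
            normed.append(normalized_activity(crop[kept], marginals))
        fields.append(circular_average(normed, orientations, doubled_angle))
        n_crops += len(crops)
        n_used += 1
    if not fields:
        raise ValueError("no valid neighborhoods found in any image")
    return InteractionMap(
        complex_field=np.mean(fields, axis=0),
        theta_c=float(bank.orientations[central_feature]),
        feedback_strength=config.feedback_strength,
        n_images=n_used, n_crops=n_crops, doubled_angle=doubled_angle)


# --------------------------------------------------------------------------
# Circular statistics of the map
# --------------------------------------------------------------------------

def _circ_dist_pi(a: np.ndarray, b: np.ndarray | float) -> np.ndarray:
    """Circular distance between orientations (period pi), in [0, pi/2]."""
    d = np.mod(np.asarray(a) - b, np.pi)
    return np.minimum(d, np.pi - d)


def colinearity_deviation(theta_bar: np.ndarray | InteractionMap,
                          theta_c: float | None = None) -> np.ndarray:
    """Deviation of the map's orientations from the central orientation.

    Circular difference on period pi, so values lie in [0, pi/2]; a
    shift by pi (same orientation, opposite direction) gives zero.
    """
    if isinstance(theta_bar, InteractionMap):
        theta_c = theta_bar.theta_c if theta_c is None else theta_c
        theta_bar = theta_bar.orientation
    return _circ_dist_pi(theta_bar, theta_c)


def cocircular_reference(window: int, theta_c: float) -> np.ndarray:
    """Reference orientation field of perfect co-circularity.

    At each position (coordinates centred on the map middle) this is the
    tangent, at that position, of the circle through the centre whose
    tangent at the centre is ``theta_c``. On the ``theta_c`` axis (and
    at the centre) the circle degenerates to a line and the reference
    equals ``theta_c`` — the co-linear limit.
    """
    half = window // 2
    xs = np.arange(window) - half
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    denom = np.sin(theta_c) * X - np.cos(theta_c) * Y
    ref = np.full((window, window), theta_c, dtype=float)
    off_axis = np.abs(denom) > 1e-12
    r2 = (X ** 2 + Y ** 2).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        x_co = np.where(off_axis, np.sin(theta_c) * r2 / (2.0 * denom), 0.0)
        y_co = np.where(off_axis, -np.cos(theta_c) * r2 / (2.0 * denom), 0.0)
        dx = X - x_co
        dy = Y - y_co
        tangent = np.arctan(np.where(dx != 0, dy / np.where(dx != 0, dx, 1.0), np.inf)) \
            + np.pi / 2.0
    ref[off_axis] = np.mod(tangent[off_axis], np.pi)
    return ref


def cocircularity_deviation(theta_bar: np.ndarray | InteractionMap,
                            theta_c: float | None = None) -> np.ndarray:
    """Deviation of the map's orientations from perfect co-circularity."""
    if isinstance(theta_bar, InteractionMap):
        theta_c = theta_bar.theta_c if theta_c is None else theta_c
        theta_bar = theta_bar.orientation
    ref = cocircular_reference(theta_bar.shape[0], theta_c)
    return _circ_dist_pi(theta_bar, ref)


def region_masks(window: int, theta_c: float, sector_half_angle: float = np.pi / 4,
                 center_block: int = 1) -> dict[str, np.ndarray]:
    """End-zone, side-zone and centre masks of an interaction-map window.

    The end-zone is the +/- ``sector_half_angle`` angular sector around
    the ``theta_c`` axis, the side-zone the same sector around its
    orthogonal; the centre is the middle ``center_block x center_block``
    cells (the classical receptive field) and is excluded from both
    sectors. The masks are disjoint; cells exactly on a sector boundary
    belong to neither.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    half = window // 2
    xs = np.arange(window) - half
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    angle = np.arctan2(Y, X)
    d_end = _circ_dist_pi(angle, theta_c)
    d_side = _circ_dist_pi(angle, theta_c + np.pi / 2.0)
    cb = center_block // 2
    center = (np.abs(X) <= cb) & (np.abs(Y) <= cb)
    end = (d_end < sector_half_angle) & (d_end < d_side) & ~center
    side = (d_side < sector_half_angle) & (d_side < d_end) & ~center
    return {"end": end, "side": side, "center": center}


@dataclass
class FeedbackRatios:
    """Region-wise feedback modulation ratios (values > 1 mean 'more with feedback')."""

    r_colin: dict[str, float] = field(default_factory=dict)
    r_cocir: dict[str, float] = field(default_factory=dict)
    r_a: dict[str, float] = field(default_factory=dict)
    n_excluded: int = 0


def _region_median(values: np.ndarray, mask: np.ndarray) -> float:
    return float(np.median(values[mask]))


def _scaled_deviation(dev: np.ndarray, mask: np.ndarray, center: np.ndarray) -> float:
    """Marginal-over-region deviation ratio (a precision-like score).

    The marginal deviation is the median outside the region (and outside
    the classical RF); dividing by the region's median makes the score
    > 1 when the region is more aligned than the surround.
    """
    outside = ~mask & ~center
    region = _region_median(dev, mask)
    marginal = _region_median(dev, outside)
    if region == 0:
        region = np.finfo(float).tiny
    return marginal / region


def feedback_ratios(map_fb: InteractionMap, map_nofb: InteractionMap,
                    sector_half_angle: float = np.pi / 4,
                    center_block: int = 1) -> FeedbackRatios:
    """Compare interaction maps with and without feedback, per region.

    Both maps must come from the same images and central orientation.
    ``r_colin`` / ``r_cocir`` are ratios of the precision-like scaled
    deviations (with-feedback over without); ``r_a`` is the median over
    the region of the per-position magnitude ratio. Positions with zero
    no-feedback magnitude are excluded and counted.
    """
    if map_fb.window != map_nofb.window:
        raise ValueError("maps have different windows")
    if not np.isclose(map_fb.theta_c, map_nofb.theta_c):
        raise ValueError("maps have different central orientations")
    theta_c = map_fb.theta_c
    masks = region_masks(map_fb.window, theta_c, sector_half_angle, center_block)
    out = FeedbackRatios()
    dev_lin_fb = colinearity_deviation(map_fb)
    dev_lin_0 = colinearity_deviation(map_nofb)
    dev_cir_fb = cocircularity_deviation(map_fb)
    dev_cir_0 = cocircularity_deviation(map_nofb)
    mag_fb, mag_0 = map_fb.magnitude, map_nofb.magnitude
    valid = mag_0 > 0
    out.n_excluded = int((~valid).sum())
    center = masks["center"]
    for name, mask in masks.items():
        if name != "center":
            out.r_colin[name] = (_scaled_deviation(dev_lin_fb, mask, center)
                                 / _scaled_deviation(dev_lin_0, mask, center))
            out.r_cocir[name] = (_scaled_deviation(dev_cir_fb, mask, center)
                                 / _scaled_deviation(dev_cir_0, mask, center))
        m = mask & valid
        ratio = mag_fb[m] / mag_0[m]
        # mean, not median: on sparse synthetic backgrounds most surround
        # cells sit at a common baseline magnitude whose ratio is exactly 1,
        # and a median would see only that baseline
        out.r_a[name] = float(ratio.mean()) if ratio.size else np.nan
    return out


def plot_interaction_map(imap: InteractionMap, path=None, saturate=(0.3, 0.8),
                         ax=None):
    """Quiver-style rendering: one oriented segment per position, colored by magnitude."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    theta = imap.orientation
    mag = np.clip(imap.magnitude, *saturate)
    half = imap.window // 2
    for x in range(imap.window):
        for y in range(imap.window):
            c = plt.cm.viridis((mag[x, y] - saturate[0]) / (saturate[1] - saturate[0]))
            dx, dy = 0.4 * np.cos(theta[x, y]), 0.4 * np.sin(theta[x, y])
            ax.plot([y - half - dy, y - half + dy], [-(x - half) + dx, -(x - half) - dx],
                    color=c, lw=2)
    ax.set_aspect("equal")
    ax.set_title(f"theta_c = {np.degrees(imap.theta_c):.0f} deg, "
                 f"k_FB = {imap.feedback_strength:g}")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
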