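# Methods

## Model

A stack of `L` convolutional sparse-coding layers. Layer `i` holds a
dictionary `D_i` of `n_f` atoms of shape `[n_c, w, h]`; its synthesis
operator (a strided transposed convolution) predicts the representation
below, with `γ_0` the preprocessed image. Activities are non-negative
(firing-rate reading) and sparse under an ℓ1 penalty — the convex
relaxation of a sparse-support constraint on the generative causes.
Feedforward and feedback connections share weights: the analysis
operator is the exact adjoint of synthesis.

Boundary handling is "valid": no zero padding anywhere. An activity
grid of side `w_m` synthesizes an image of side `(w_m − 1)·stride + w`,
so the adjoint pair needs no edge corrections and the dense
(Toeplitz-matrix) formulation agrees with the convolutional one
elementwise — the test suite checks this on small instances. If a
stride does not tile an input exactly, the input is cropped
symmetrically (excess `e` removes `e // 2` leading and the rest
trailing pixels); the crop is computed jointly over all layers.

## Inference

Each layer descends its own local loss

    L_i = ½‖γ_{i−1} − D_iᵀγ_i‖² + (k_FB/2)‖γ_i − D_{i+1}ᵀγ_{i+1}‖² + λ_i‖γ_i‖₁

by a gradient step on the smooth terms followed by a non-negative soft
threshold `max(x − ηλ, 0)`. Choices that the loss alone does not fix:

- **Step size.** `η = 1/L` with `L` the largest eigenvalue of the
  composed analysis∘synthesis operator, computed by power iteration on
  the layer's own activity space (cached; recomputed when the atoms
  change). In the default *coupled* mode the feedback quadratic's
  curvature is included, `η = 1/(L + k_FB)`, which keeps the iteration
  a contraction for any feedback strength; a *literal* mode with
  `η = 1/L` is available as a config switch.
- **Acceleration.** FISTA with the standard momentum sequence
  `t_{k+1} = (1 + √(1 + 4t_k²))/2`, no restarts by default (a
  gradient-scheme restart is behind a flag). Plain ISTA is available
  and is the mode under which the per-step loss decrease is guaranteed
  and tested.
- **Layer order.** One outer iteration updates layers bottom-up, each
  using the freshest neighbour activities (Gauss–Seidel), matching a
  `for i = 1..L` sweep.
- **Convergence.** A layer has reached a fixed point when
  `‖γ^t − γ^{t−1}‖ / ‖γ^t‖ < T_fp` with `T_fp = 5e−3` by default. An
  all-zero map is defined as converged (0/0 → 0): zero is a valid fixed
  point under a large penalty. Non-convergence within the iteration
  budget is flagged on the returned state, never silent.

With `k_FB = 0` the stack decouples into independent convolutional
LASSO problems; the converged activities attain the dense-formulation
optimum within 1e−6 relative gap (tested against an independent
proximal solver on the materialized matrix).

## Learning

After inference has converged on a batch (10 images by default, k_FB=1
during training), each dictionary moves along the correlation between
its layer's activity and its prediction residual — the exact gradient
of the reconstruction term, verified against finite differences —
averaged over the batch, with heavy-ball momentum (0.9) and optional
per-epoch learning-rate decay. Atoms are ℓ2-renormalized after every
step; without this, atom/coefficient rescalings make solutions
redundant. A zero atom is reinitialized from the standard normal with a
warning.

Two standard dictionary-learning aids are available and used by the
recovery benchmark: an *overcomplete* learner (more learned atoms than
planted ones), and *recycling* of near-silent atoms (a feature whose
share of active units falls below 5% of the uniform share is re-seeded
from a random image patch and its momentum cleared). Both address the
classic failure mode where one learned atom straddles two correlated
ground-truth atoms.

## Preprocessing

Local contrast normalization: Gaussian-window (σ = 2 px) subtractive
then divisive normalization per channel, divisive floor 1e−4 (a
constant image maps to zero, never a division error). Whitening: ZCA
fitted on 9×9 training patches with an eigenvalue floor of 1e−2 of the
largest eigenvalue; the exact transform is exposed for patches, and
whole images are filtered with the ZCA matrix's central row as a
convolution kernel (valid for stationary statistics). A parameter-free
frequency-domain alternative (`|f|·exp(−(|f|/f₀)⁴)`, f₀ = 0.8 Nyquist)
is behind a flag.

## Synthetic data

The generator emulates exactly the structure the analyses assume:

- **Planted dictionaries.** Unit-norm oriented Gabor atoms with known
  angles (default: evenly spaced on [0, π)); second-layer atoms are
  non-negative co-linear ridges, one per orientation channel, so deeper
  causes correspond to short contours.
- **Scenes.** The top latent map gets an exact number of strictly
  positive entries at uniform positions, amplitudes uniform on
  [0.5, 1.5]; lower maps follow the linear synthesis plus i.i.d.
  Gaussian noise and a non-negativity clip (the clip is absorbed into
  the recorded noise term so the generative algebra is exact to 1e−10).
- **Contour stimuli.** Chains of co-oriented Gabor patches along the
  orientation axis (default: 6 patches, 3 px apart, positional jitter
  0.3 px, 33×33 px canvas, 8 random distractor patches). The spacing is
  deliberately smaller than the 9×9 analysis window so that co-linear
  neighbours of an active unit fall inside the surround being measured.

What the generator does **not** emulate: the full second-order and
phase statistics of natural images, occlusions, textures, and the
scale/content diversity of real databases. Passing tests therefore
establish that the implementation produces the claimed feedback effects
under the model's own generative assumptions — not that the effect
sizes transfer to natural images, which require full-scale training.

## Interaction maps

Per central feature (preferred orientation θ_c, obtained by fitting
each first-layer atom with a Gabor):

1. crop 9×9 neighbourhoods around the 10 most active units of that
   feature (border-adjacent peaks are replaced by next-ranked ones;
   ties resolve in scan order);
2. normalize every kept feature's activity by its marginal — the plane
   mean outside the neighbourhood — as `a = (γ − marg)/marg`, with an
   epsilon floor of 1e−6 of the largest marginal;
3. combine orientations as phasors: the per-position complex mean
   `(1/n)Σ_θ a[θ]e^{jθ}`, averaged over crops and then over images
   before taking argument (resulting orientation) and modulus
   (resulting activity). The single-angle phasor follows the printed
   convention of the underlying statistics; a doubled-angle variant
   (`e^{j2θ}`, the usual treatment of axial data) is behind a flag.

The Gabor-fit quality is the orientation-selective explained energy
`(q* − q_orth)/(1 − q_orth)`: energy a fit explains regardless of
orientation (isotropic blobs) does not count. Features below quality
0.5 are rejected and excluded from `n` in the circular statistics.

Deviations: co-linearity is the circular (period-π) difference to θ_c;
co-circularity is the difference to the tangent field of circles
through the window centre with tangent θ_c there (on the θ_c axis and
at the centre the circle degenerates and the reference equals θ_c).
Regions: end-zone and side-zone are ±45° angular sectors around the
θ_c axis and its orthogonal; boundary cells belong to neither. The
classical-RF "centre" is the single central cell: at this window scale
the immediately adjacent cells already show the opposite (facilitatory)
modulation along the contour axis, so a 3×3 centre block would average
two antagonistic effects into one number.

Feedback ratios compare maps from the same images at `k_FB` vs 0. The
region activity ratio `r_a` is the *mean* over region cells of the
per-position magnitude ratio (zero-denominator cells excluded and
counted): on sparse synthetic backgrounds most surround cells sit at a
common baseline magnitude whose ratio is exactly 1, so a median would
see only the baseline while the mean weights the cells that carry
signal. Co-linearity/co-circularity ratios scale each region's median
deviation by the median outside the region (a precision-like score)
before forming the with/without-feedback ratio.

## Denoising protocol

Noise is added after preprocessing, in normalized intensity units
(evaluation images are standardized to unit variance, so σ is in signal
units). For every (σ, k_FB, λ₁) cell the activities are inferred on the
noisy image, each layer's representation is back-projected to image
space, and compared with the *clean* image by SSIM (11×11 Gaussian
window, σ = 1.5, standard stabilization constants, per-channel mean;
the index is clipped to [0, 1] for reporting). The baseline is
SSIM(clean, noisy). Medians ± median absolute deviations over the image
set are reported with paired one-sided Wilcoxon p-values against the
baseline. The network is never retrained across the sweep.

## Study conditions of the scaled-down experiments

The full-scale configurations (64/128 features, 96×96 or 170×120
images, 250 epochs) are summarized by the analytic receptive-field
check only. The trainable experiments run at desk scale, chosen once:

- **Recovery benchmark:** 8 planted Gabors (9×9), 500 one-layer scenes
  on an 8×8 latent grid, 3 active units each, noise std 0.01; learner
  with 16 atoms, λ₁ = 0.1, 25 epochs, learning rate 0.1 with decay
  0.92, recycling on. Scored by max-weight bipartite matching of
  absolute normalized cross-correlations (shift-invariant).
- **Two-layer toy study:** scenes from the planted Gabor + co-linear
  ridge model (4×4 top grid, 2 causes, noise 0.01), 240 training
  images, architecture 8/8 features with 9×9 kernels, λ₁ = 0.3 (the
  face-configuration value), λ₂ = 0.05 — scaled to the toy's signal
  level so the second layer is active with randomly initialized
  weights — trained 10 epochs at k_FB = 1. Feedback effects are then
  measured at inference only: unit counts over 60 held-out scenes at
  k_FB ∈ {0, 1, 2, 4}; interaction-map ratios over 56 contour stimuli
  (8 orientations × 7 seeds) at k_FB = 1 vs 0; denoising over 40
  unit-variance scenes at σ ∈ {0, 5}, k_FB ∈ {0, 1, 4},
  λ₁ ∈ {0, 0.3, 3}.

## Known limitations

- The effective-support composition law `k_eff(i) = k_eff(i−1) +
  (k_i − 1)·Π strides` is exact for the implemented valid-boundary
  operators; printed RF sizes elsewhere that disagree with it for
  strided configurations are not reproduced.
- Interaction-map statistics on single sparse stimuli are dominated by
  a uniform background term; conclusions rest on the region means and
  on aggregation across stimuli, as described above.
- FISTA iterates may transiently increase the loss (only ISTA is
  monotone); fixed points can differ between step-size modes by amounts
  within the fixed-point tolerance.
- The learning loop is plain Python over images; it is sized for the
  desk-scale studies above, not for full image databases.
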