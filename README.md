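# sdpc — sparse deep predictive coding

`sdpc` models the early visual cortex (V1/V2) as a hierarchy of
convolutional sparse-coding layers coupled by predictive feedback, and
ships the analyses that make such a model scientifically useful:
effective receptive fields, interaction maps (association-field
analogues around strongly active units), and a noise/feedback denoising
evaluation. It is written for computational neuroscientists who want a
small, fully testable implementation of predictive-coding dynamics that
runs on synthetic data with known ground truth — no image database
required.

## The model

The stimulus is assumed to be generated hierarchically,

```
x       = D1ᵀ γ1 + ε1        γ1 ≥ 0 sparse
γ1      = D2ᵀ γ2 + ε2        γ2 ≥ 0 sparse
```

where each `Dᵢ` is a bank of convolutional atoms (shared feedforward /
feedback weights) and each `γᵢ` a non-negative retinotopic activity
map. Inference minimizes the per-layer losses

```
Lᵢ = ½‖γᵢ₋₁ − Dᵢᵀγᵢ‖² + (k_FB/2)‖γᵢ − Dᵢ₊₁ᵀγᵢ₊₁‖² + λᵢ‖γᵢ‖₁
```

(the feedback term is absent at the top layer) by proximal-gradient
steps with a non-negative soft threshold — ISTA, accelerated by FISTA —
sweeping the layers in Gauss–Seidel order until every activity map
reaches a relative fixed point. The feedback strength `k_FB` weights
the top-down prediction error: `k_FB = 0` decouples the stack into
independent convolutional LASSO problems; `k_FB > 0` lets deeper causes
reshape lower-layer activity. Learning alternates converged inference
with Hebbian-like dictionary updates (activity–residual correlations,
heavy-ball momentum, atom renormalization).

## A worked example

`examples/04_denoising_sweep.py` corrupts unit-variance synthetic
scenes with Gaussian noise, infers codes at several feedback strengths
with planted ground-truth weights, and compares each layer-1
reconstruction to the clean image with SSIM:

```
 sigma  k_fb   median      mad  baseline_median  p_vs_baseline
   0.0   0.0 0.889798 0.027902         1.000000   1.000000e+00
   2.0   0.0 0.535829 0.040959         0.390287   9.536743e-07
   2.0   1.0 0.621035 0.048006         0.390287   9.536743e-07
   2.0   4.0 0.678350 0.053018         0.390287   9.536743e-07
   5.0   0.0 0.183714 0.039609         0.106878   9.536743e-06
   5.0   1.0 0.242007 0.052534         0.106878   9.536743e-07
   5.0   4.0 0.299586 0.067850         0.106878   9.536743e-07
```

At noise σ = 2 the noisy image itself has median SSIM 0.39 with the
original; the sparse code's reconstruction reaches 0.54 with the
feedback off and 0.68 at `k_FB = 4` (paired Wilcoxon p < 1e-6 against
the baseline). Denoising is emergent — nothing here was trained on
noisy images — and grows with the feedback strength.

The other examples follow the same pattern: `01_sparse_inference.py`
(feedback recruits first-layer units: 23 active without feedback, 58
with it, on the same scene), `02_dictionary_learning.py` (planted
oriented atoms rediscovered with matched correlations ≥ 0.99),
`03_interaction_maps.py` (end-zone amplification and classical-RF
suppression around contour elements).

A thin CLI wraps the same library calls for shell use:
`sdpc train|infer|interaction-map|denoise-eval|synth --help`.

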