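# Methods

## The model

`residiff` implements diffusion-based super-resolution for paired MRI slices
in which the forward process shifts the high-resolution (HR) image toward its
low-resolution (LR) counterpart instead of toward pure noise.  With the
residual e0 = x_lr − x_hr, the forward Markov kernel is

    q(x_t | x_{t−1}) = N(x_{t−1} + α_t e0, γ² α_t I),      t = 1..T,

where α_t = β_t − β_{t−1} are first differences of a monotone sequence
β_1 → 0, β_T → 1.  Because the increments are independent, the marginal at
any step is available in closed form,

    q(x_t | x_0) = N(x_0 + β_t e0, γ² β_t I),

so training never has to iterate the chain.  The terminal state is
(almost) the LR image plus γ-scaled noise, which is why the reverse process
can start from the LR input rather than from white noise — the key to
few-step sampling for restoration tasks.

The reverse process uses the product-of-Gaussians posterior

    q(x_{t−1} | x_t, x_0) = N( (β_{t−1}/β_t) x_t + (α_t/β_t) x_0 ,
                               γ² α_t β_{t−1}/β_t I ),

with the clean image replaced by the network estimate
x̂_0 = g(x_t, x_lr, t).  A network that predicts x̂_0 (rather than the noise)
keeps every reverse step interpretable and makes the final step collapse to
x̂_0 exactly (β_0 = 0).

### Skip-step sampling

The generalized posterior between any two steps t_hi > t_lo is

    mean = (β_lo/β_hi) x_t + ((β_hi−β_lo)/β_hi) x̂_0,
    var  = γ² (β_hi−β_lo) β_lo / β_hi,

which reduces to the adjacent-step posterior when t_lo = t_hi − 1.  The
residual cancels algebraically between the two marginals, so skipping steps
needs nothing beyond x_t and x̂_0.  The default sampler visits
[T, 11, 7, 3, 0] for T = 15 — four denoiser calls.  Under a perfect denoiser
with noise suppressed, any valid grid returns x_hr exactly (an identity the
test suite checks to 1e−5); this is the formal sense in which subsampling
the grid is consistent.  Rebuilding the schedule with a smaller T is also
supported (`build_schedule(T=4, ...)`) as an alternative few-step mode.

Two textual conventions are resolved in the schedule itself: β_0 = 0 is
prepended (making the final reverse step deterministic, consistent with the
ε = 0 rule at t = 1), and the sampler initializes at x_lr + γ√β_T ε, i.e.
with variance γ²β_T rather than γ²; at β_T = 0.9999 the difference is
negligible.  The per-step forward variance is taken as γ²α_t so that
independent increments sum to the marginal variance γ²β_t; the Monte-Carlo
moment tests pin this down.

### Noise schedule

√β_t interpolates log-linearly in ((t−1)/(T−1))^p between √β_1 and √β_T:
a geometric schedule whose exponent p controls the growth rate (smaller p
front-loads the shift; the schedule tests assert this ordering).  Defaults:

| parameter | default | meaning |
|---|---|---|
| T | 15 | training steps |
| p | 0.3 | growth-rate exponent |
| γ (gamma) | 2.0 | noise scale of the forward kernel |
| κ (kappa) | 0.04 | bound on γ√β_1; β_1 = (κ/γ)² = 4e−4 |
| β_T | 0.9999 | terminal shift fraction |

Schedules are computed in double precision; image arithmetic is single
precision.

## Denoiser

A U-shaped encoder–decoder over NCHW float32 maps.  x_t and x_lr are
concatenated at the stem; a sinusoidal timestep embedding passes through a
two-layer MLP and conditions every residual block via scale-and-shift of the
normalized activations.  Window-attention blocks (layer-norm → windowed
multi-head self-attention → layer-norm → MLP, with residual additions)
replace conventional attention at the two coarsest resolutions; the
`use_swin=False` ablation removes them.  Shifted-window masking is not
implemented: windows are non-overlapping and fixed, which is sufficient at
the window counts used here.  Convolutions use reflection padding to avoid
ringing at masked backgrounds.  A global skip adds x_lr to the head output,
so the network learns the HR correction; block-output weights are
initialized at a 0.1 gain so the map starts near that skip while every
parameter stays on the gradient path.

Presets: `TINY` (16 base channels, 2 levels, window 4 — trains on one CPU in
minutes) and `PAPER_SCALE` (64 base channels, 4 levels — sized for GPU-class
runs; the published network's exact layer counts are not public, so this is
a convention, not a reproduction).  Ablation comparisons in-repo hold
everything but `use_swin` fixed.

The network and its training run on a small in-repo reverse-mode autodiff
over numpy (`residiff.nn.autodiff`); every primitive's gradient is verified
against central finite differences in the test suite.

## Training

Algorithm: per step, draw an independent uniform t ∈ {1..T} per sample,
corrupt with the closed-form marginal, predict x̂_0, and minimize

    L = λ · mean((x̂_0 − x_hr)²) + ℓ_p(x̂_0, x_hr),      λ = 10.

λ sits on the fidelity term.  The ℓ2 norm is reduced by the mean over pixels
and batch so λ stays comparable across image sizes.  ℓ_p is pluggable: the
default is the null function; `GradMagPerceptual` is a differentiable
multi-scale gradient-magnitude distance needing no pretrained weights (its
value at identical inputs sits at the smooth-L1 floor ≈ 1e−4 rather than
exactly 0); an external feature-network distance can be slotted in where
pretrained weights are available.

Optimizers: RAdam (default) or Adam.  Learning rate: linear warm-up then
half-cosine decay to zero.  The full-scale settings (batch 16, lr 5e−5 from
the published 2e−5–5e−5 range, 5000-step warm-up) are the config defaults at
paper scale; the tiny CPU preset uses batch 8, lr 1e−3, 100-step warm-up —
a deliberate test-scale departure, since hundred-thousand-step schedules are
meaningless over a few thousand steps.  Gradient clipping and weight EMA are
available but off by default.

All randomness is drawn from substreams keyed by (seed, step), so loss
traces are bit-reproducible and a checkpoint resume continues exactly where
the uninterrupted run would have been.

## Degradation protocol and phantoms

LR counterparts are made by per-axis downsampling (linear interpolation, no
anti-alias prefilter — the default of the common resampling tools; an
optional Gaussian pre-smooth is exposed for study) followed by
nearest-neighbor pre-upsampling back to the exact original grid.  Presets:
brain 4×4×4 (0.8 mm → 3.2 mm isotropic) and prostate spacing-driven
0.66×0.66×1.5 mm → 2×2×3 mm (the non-integer in-plane factor ≈ 3.03 is why
the spacing-driven path exists; integer factors remain the convenience path
for phantoms).  Volumes are degraded in 3-D, then sliced along the last
axis; the model itself is 2-D.

The phantom generator emulates skull-stripped, background-masked
single-channel slices: nested ellipses (piecewise-smooth anatomy), thin
curvilinear features (1–2 px), small high-contrast lesions, a smooth
multiplicative bias field, and additive Gaussian noise (σ = 0.01), clipped
to [0, 1] with exact-zero background.  Default conditions for the
desk-scale experiments: 200 training + 20 held-out phantoms at 32×32 with
factor-4 in-plane degradation, mirroring the brain protocol at a size a CPU
can train in minutes.  What phantoms do **not** emulate: real anatomical
statistics and texture, scanner noise correlations (Rician noise,
bias-field structure of receive coils), partial-volume effects at tissue
interfaces, or inter-subject variability.  Passing the desk-scale tests
therefore demonstrates that the machinery (schedule, sampler, training
loop, metrics) is correct and that the model class can learn a non-trivial
restoration operator — not that clinical-grade quality is reached, which the
published full-scale results address with private/external data and GPU
training.

## Metrics

PSNR, SSIM and GMSD are computed from their defining formulas (see the
module docstring for constants).  SSIM uses the original 11×11 Gaussian
window (σ = 1.5), K1 = 0.01, K2 = 0.03, Gaussian-weighted covariance, and
averages the local map over the interior where the window fits entirely.
GMSD uses 1/3-scaled 3×3 Prewitt gradients after 2× average-pooling, with
c = 170/255² on the unit range, and returns the population standard
deviation of the similarity map.  Identical inputs give PSNR = the finite dB
value at machine-epsilon MSE (a documented sentinel, so aggregates remain
finite), SSIM = 1, GMSD = 0.  The perceptual column is pluggable and
optional; tests never require a pretrained network.

## Numerical and design notes

- Degenerate inputs: constant volumes are fixed points of the degradation;
  constant masked regions normalize to zeros with a warning; an LR slice
  identical to HR makes the forward process the identity.
- Tie-breaks: nearest-neighbor resampling uses cell-center alignment with
  the lower index on exact ties.
- The written per-step noise coefficient of the iterated forward expansion
  does not square to the marginal variance; the closed-form marginal
  (variance γ²β_t) is treated as authoritative because independent
  increment variances add, and the Monte-Carlo tests confirm it.
- Desk-scale problem sizes (32×32 phantoms, ≤2000 steps, tiny preset) were
  chosen so the whole pipeline runs in minutes on one CPU; they are the
  package's own sizing of the study conditions.

## Known limitations

- At desk scale the 15-step sampler scores ~0.6–0.9 dB *below* the 4-step
  sampler, and the effect does not shrink with more training or a wider
  network.  Two mechanisms, both verified numerically: (i) the final
  per-step transition (t = 2 → 1) injects posterior noise
  σ = γ√(α₂β₁/β₂) ≈ 0.04, and at t = 1 the training distribution has
  x₁ ≈ x₀ + 0.04ε, so a (near-)optimal x̂₀ predictor essentially copies x₁
  — the output retains that noise, an MSE floor of ≈0.0016 that pins
  15-step PSNR near 19.3 dB at this problem scale; (ii) with noise
  suppressed a comparable gap remains because the low-t copy behavior also
  propagates error accumulated along the long chain (exposure bias).  The
  4-step grid stops at t = 3, outside the copy regime, and avoids both.
  Few-step sampling therefore loses nothing here — it is strictly the
  better operating point — but the two samplers do not agree to within
  0.5 dB at desk-scale fidelity.  Under the perfect denoiser both grids
  are exact, so this is a property of finite models at ~20 dB operating
  points, not of the schedule algebra.
- No shifted-window attention masking; no EMA by default; no distillation
  mode.
- The LPIPS-style pretrained perceptual metric is an adapter slot, not a
  bundled dependency.
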