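# Methods

## Image-formation model

A raw SIM frame is simulated as `D = (S·I) ⊗ H + N` on a square pixel grid.

* **Optics.** The OTF is the ideal incoherent diffraction-limited transfer
  function — the autocorrelation of a circular pupil, radially
  `(2/π)(arccos ρ − ρ√(1−ρ²))` with `ρ = k/k_c` and cutoff
  `k_c = 2·NA/λ`, converted to cycles/pixel through the sample-plane pixel
  size. Defaults (NA 1.2, λ 520 nm, 60 nm/px) give `k_c ≈ 0.277`
  cycles/pixel, comfortably below the grid Nyquist of 0.5; a configuration
  whose cutoff exceeds Nyquist still simulates but warns that the grid, not
  the optics, is the band limit. The PSF is stored as the exact inverse DFT
  of the OTF normalised to unit sum; the tiny negative discretisation
  ringing (≲1e−10) is retained so OTF and PSF remain an exact transform
  pair.
* **Blur** is circular (FFT) convolution — multiplication by the OTF in
  frequency space. Boundary wrap-around is physically wrong at the frame
  edge but irrelevant in practice: training crops and the tiled-inference
  blending keep edges out of the loss, and the alternative (padded linear
  convolution) would break the exact frequency-support invariants the tests
  rely on.
* **Illumination.** `I = I₀[1 − (m/2)cos(2π(kₓx + k_y y) + φ)]` with `x` the
  column and `y` the row index, 0-based. The three canonical phases
  {0, 2π/3, 4π/3} average to `I₀` at every pixel (machine precision), which
  is what makes the stack mean a faithful widefield image.
* **Noise.** Gaussian with standard deviation `η·σ`, where `σ` is the
  standard deviation of the *noiseless blurred* frame — the frame is the
  input to the detector, so its σ is the natural reference. A Poisson
  variant (`level` = photons per unit intensity) is provided; Gaussian is
  the default. Frames stay floating-point and unclipped through the whole
  pipeline; clipping and 16-bit quantisation happen only at TIFF export.

## Training-data generation

Each training pair is one ground-truth image plus one simulated stack.
Per stack: a single `k₀ ~ U(0.7, 0.95)·k_c` and `m ~ U(0.5, 1)`;
per orientation: angle = base + N(0, 0.05 rad) with the base grid (spacing
π/n_orientations) given a global offset drawn uniformly per stack so no
absolute stripe direction can be memorised; per frame: phase = base +
N(0, 0.05 rad); noise `η ~ U(0, 4)`. `k₀` near the cutoff is where the SIM
resolution gain is largest, and the jitter/noise ranges span the conditions
the robustness experiments probe. All ranges are config fields. Frames are
ordered orientation-major — the conventional 9-frame acquisition order and
part of the model contract, since the network consumes frames as input
channels.

Ground truths come either from a user-supplied image folder (centre-crop,
luminance grayscale, resize, [0,1]) or from the bundled procedural
generator, which composites smooth gradients, filled polygons, discs,
curved filaments, line gratings of 2–8 px spacing and single-pixel points
with randomised intensities. The generator is a stand-in for a photographic
corpus: it matches two properties that matter here — photographic fill
(background level 0.15–0.45, contrast normalised by the 99th percentile;
near-black images would both inflate PSNR and starve the spectral peaks the
parameter-recovery diagnostic needs) and guaranteed spectral content beyond
half the OTF cutoff (gratings, points) so there is super-resolution
information to learn. It does **not** reproduce natural-image statistics
(occlusions, perspective, texture spectra), so desk-scale results
demonstrate that the pipeline learns and generalises within its simulated
domain, not that a desk model transfers to photographs or real microscopy
data — the full-scale protocol exists for that.

## Networks and optimisation

All architectures map `(in_frames, H, W)` to `(1, H, W)` with no spatial
resampling. The default is a residual channel-attention network: head
convolution to `n_features` (64 full scale), 10 residual groups × 3
residual channel-attention blocks (conv-ReLU-conv followed by a channel
gate: global average pool → bottleneck with reduction 16 → sigmoid →
rescale), a group skip, a long skip over the body, and a 1-channel tail.
The attention-free variant uses the same backbone as a flat block sequence
with 0.1 residual scaling; the encoder–decoder baseline is a standard
4-level U-shaped network. 3×3 kernels, stride 1, same-padding, ReLU inside
blocks, linear output.

The engine is pure numpy (im2col convolution → BLAS GEMM, explicit
backward passes, Adam with the published default moment decays). Every
layer's gradient is checked against central finite differences in float64;
training runs in float32. Networks initialise with He-scaled weights plus
two conventions chosen for small step budgets: every residual branch's
closing convolution starts at zero (each block is initially the identity)
and the head/tail get a mean-of-frames centre tap on top of 0.3×-scaled
random weights, so the untrained network already emits approximately the
widefield projection and optimisation starts from the baseline rather than
from noise. Both are initialisation conventions only; the converged
architecture is unchanged.

Training minimises MSE (L1 optional) against the clean target with the
stepped schedule `lr(e) = lr₀ · 0.5^⌊e/20⌋`. The full-scale protocol
(`PAPER_TRAIN`) is 200 epochs at `lr₀ = 1e−4` on 512² pairs with 256²
random crops taken at load time. The desk preset (`DESK_TRAIN`, used by the
test suite) is 10 epochs, batch size 1 and `lr₀ = 1e−3`: it has ~300× fewer
optimiser steps than the full protocol, so the initial rate is raised one
decade while the halving rule stays identical. A seeded fraction of pairs
is held out; validation PSNR/SSIM are logged per epoch and the
best-validation weights are kept. Divergence (non-finite loss) aborts with
the offending epoch named.

Checkpoints are single `.npz` files holding the weights plus the full
estimator configuration and an optional simulation fingerprint, so a
checkpoint is self-describing.

## Evaluation conventions

PSNR is `10·log₁₀(range²/MSE)` with `data_range = 1` and a declared 100 dB
cap for identical images. SSIM is the standard 11-pixel Gaussian-window
formulation (σ 1.5, k₁ = 0.01, k₂ = 0.03). Both metrics compare images
normalised to [0,1]: the network output and the widefield projection are
min–max normalised before scoring, which puts the learned reconstruction
and the baseline on the same footing (neither is rewarded for contrast
scale alone).

**Noise sweep.** For one fixed test target, illumination parameters are
drawn once per replicate and a single unit-variance noise field per frame
is scaled across the η grid {0…9} (common random numbers), so each
replicate traces one acquisition degrading as noise grows and the η = 0 row
is exactly the noise-free score. The sweep target is part of the protocol
(a fixed procedural image), for a reason worth recording: at very small
image sizes the SSIM contrast term can make a clean-but-blurred widefield
image score *lower* than a mildly noisy one for some targets — a metric
artefact of blur domination, not a noise-robustness property.

**Pattern-parameter recovery.** Frames of one orientation are combined
with the canonical phase factors `Σⱼ e^{−iφⱼ} Dⱼ`, which cancels the
widefield component exactly and concentrates the separated first order at
`+k₀`; the dominant off-centre spectral peak gives `(k₀, θ)` (θ modulo π).
When the transfer functions are known — always, for simulated stacks — the
spectrum is Wiener-whitened by `1/(OTF + 0.1)` over the OTF support so the
peak is not handicapped by optical attenuation, and significance is judged
against the median of the peak's own radial shell; weak peaks (zero
modulation, overwhelming noise) are flagged rather than guessed. Because
detector noise is added *after* the OTF, stripes very close to the cutoff
are irrecoverable at high η regardless of whitening: at η = 2 the
diagnostic is reliable for mid-passband stripes (≈0.75·k_c) at the standard
512² frame size, and the flagged estimates mark the cases beyond reach.

## Desk scale vs full scale

The acceptance-style experiments in the test suite run at desk scale so the
whole suite finishes in minutes on one CPU: 32 pairs at 64² (10 epochs) for
the learning-signal check, 24 pairs at 48² (10 epochs, 3 seeds) for the
frame-count ablation, 5 replicates for the noise sweep. Two findings from
that scale are worth stating plainly:

* A tiny model reliably beats the widefield baseline by ~0.3–0.8 dB, and
  its SSIM advantage persists across the whole η ∈ [0, 9] sweep even though
  training only saw η ≤ 4.
* The frame-count ablation (9 vs 6 vs 3 vs widefield-input) is **flat at
  desk scale**: final-PSNR differences of ±0.1–0.7 dB are dominated by seed
  noise, with no reproducible ordering. The mechanism that separates the
  configurations at full scale — the network learning to demodulate
  super-resolution content from the stripe phases — requires far more
  capacity and training than a desk run affords; a convolution cannot shift
  spectra, so the separation is intrinsically a deep-nonlinear,
  data-hungry effect. The ablation harness reports the measured medians and
  treats sub-noise differences as ties.

## Numerical and degenerate-input conventions

Per-stack min–max normalisation to [0,1] before the network (reconstruction
is therefore exactly invariant to global affine intensity rescaling of a
stack); constant stacks normalise to zero. Timelapse TIFFs are grouped into
consecutive blocks of `in_frames` pages. Frames larger than the tile size
(default 512, overlap 32) are reconstructed in overlapping tiles blended
with a linear ramp; the channel-attention gates then see per-tile rather
than global statistics, which perturbs tile interiors slightly — tiling is
for memory, not a bit-exact equivalence. Layouts with fewer than three
phases per orientation are simulated but tagged underdetermined, mirroring
the analytical unmixing requirement. The widefield-input ablation
(`in_frames = 1`) feeds the network the stack mean; frame subsets take the
first `in_frames` frames in acquisition order.
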