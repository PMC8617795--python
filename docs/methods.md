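# Methods

## Problem and model

The package targets binary semantic segmentation of nerve structures in 2-D
grayscale ultrasound, where the training signal is a set of image/mask
pairs {Iₙ ∈ ℝ^{R×C}, Mₙ ∈ {0,1}^{R×C}}. A segmentation network is a
composition M̂ = φ_L ∘ … ∘ φ₁(I) of convolutional layers with ReLU
activations, a linear 1×1 "logit" layer G as the penultimate stage, and a
sigmoid head (only the bi-class case is implemented; a softmax head for
more classes is out of scope). Parameters are estimated by mini-batch Adam
on the Dice-based loss 1 − (2·Σ(M⊙M̂) + ε)/(ΣM + ΣM̂ + ε) with ε = 1. The
regularizer makes the empty-vs-empty case a perfect score rather than 0/0,
and the 1 − s orientation keeps the loss non-negative with minimum 0 at
perfect overlap.

Three builders share this contract:

* **FCN** — a VGG-style encoder (two 3×3 convolutions then 2×2 max pooling
  per stage), a 1×1 score convolution, and a single stride-2^depth
  transposed convolution back to input resolution.
* **U-net** — symmetric encoder/decoder with skip concatenations; each
  decoder stage is a stride-2 transposed convolution, concatenation with
  the same-depth encoder features, and two 3×3 convolutions.
* **ResUnet** — identical topology with each two-convolution block replaced
  by a residual block F ↦ ReLU(conv(ReLU(conv(F))) + P(F)), where P is a
  1×1 projection when the channel counts differ and the identity otherwise.

Exact filter counts and kernel sizes are not dictated by the method; the
defaults (base_filters doubling per stage, 3×3 kernels, transposed-
convolution upsampling) are conventional and fully configurable.

## The random-Fourier-feature layer

The Gaussian kernel κ(x−x′) = exp(−‖x−x′‖²/2σ²) is shift-invariant, so by
Bochner's theorem it is the expectation of cosine features under its
spectral measure. For this κ the spectral measure is the isotropic normal
with **per-coordinate standard deviation 1/σ** — note the inversion: a wide
kernel has a narrow spectrum. The layer draws ω_q ~ N(0, σ⁻²I) and
b_q ~ U[0, 2π) once, then maps each bottleneck feature vector x ∈ ℝ^D to
√(2/Q)·cos(ω_qᵀx + b_q), q = 1…Q̆. Properties relied on by the tests:
E[φ̂(x)ᵀφ̂(x′)] = κ(x−x′) (unbiasedness), Monte-Carlo variance ∝ 1/Q, and
boundedness of every coordinate by √(2/Q).

Design choices:

* **Placement.** The map is applied independently per spatial position
  (1×1-convolution pattern), preserving the "image-shaped" bottleneck grid:
  8×8×D → 8×8×Q̆ for a 128×128 input with four poolings. Flattening the
  whole grid into one vector would destroy the spatial layout the decoder
  needs and was rejected. It sits where the grid is smallest — after the
  last pooling in FCN, at the bottleneck end in U-net/ResUnet — because the
  mapping costs O(Q·P) per position.
* **ω, b fixed at initialization** (classical RFF). A `trainable` flag
  exposes the deep-kernel-learning variant where they become ordinary
  weights; it defaults to off.
* **Bandwidth σ.** Defaults to the median pairwise Euclidean distance of
  bottleneck feature vectors on one warm-up batch (the median heuristic),
  computed at the start of training; any positive value can be fixed
  instead. Q̆ is searched over {8, 16, 32, 64, 128} by the calling
  experiment, not tuned internally.

## Grad-CAM++ for segmentation

Classification CAM needs a scalar score; here the logit grid is collapsed
to the class-conditional score y(λ) = mean{G_ij : M_ij = λ}, λ ∈ {0,1}
(background/nerve). The ground-truth mask conditions the score when
available; the binarized prediction is the fallback. Saliency weights are

γ_d = Σ_ij α_ij ReLU(g_ij), α_ij = g_ij²/(2 g_ij² + (Σ_ab F_ab) g_ij³),

with g = ∂y/∂F^d the first-order gradient w.r.t. the tapped feature map.
This closed form is the standard substitution for the printed second/third
derivative expression and is exact — up to the overall positive factor
exp(S), which normalization removes — when the score is exponentiated
before differentiation. `gradcampp_weights_from_derivatives` evaluates the
derivative form directly from explicit derivative grids; the test suite
feeds it the analytically known derivatives (∂^k y/∂A^k = w^k·y for an
exponential-linear toy head) and checks agreement with the closed form to
10⁻⁵. 0/0 cells in α are set to 0: positions with no gradient get no
credit. The saliency map is the ReLU of the γ-weighted channel sum,
bilinearly upsampled to image size; the default tap is the convolutional
layer immediately before the RFF insertion (the bottleneck output when no
RFF layer is present). Normalization divides by the maximum, with the
all-zero map defined to stay all-zero.

## Explanation-map measures

Ĩ(λ) = S̃(λ) ⊙ I is pushed through the network to the linear logits and
rescored; with N test images, Increase Confidence = 100·#{ỹ > y}/N and
Win(r, r′) = 100·#{ỹ_r > ỹ_{r′}}/N, both with strict inequality, so ties
count toward neither side and Win(r,r′) + Win(r′,r) = 100 only holds
tie-free. Win pairs scores by image id. The region-averaged heatmap crops
each normalized map to its mask's bounding box, rescales to a common
64×64 canvas (bilinear; both configurable), and takes the pixel-wise
median across samples — the median rather than the mean to resist outlier
images — returning the median rescaled mask alongside for contour overlay.
Defaults report the nerve class (λ = 1); a flag selects λ = 0.

## Synthetic data: what it emulates and what it does not

The generator renders, per seed: a filled rotated ellipse (the nerve mask;
semi-major axis 10–20% of the canvas, axis ratio 0.55–0.95, any
orientation, placed fully inside the frame), a scene with background
brightness 0.35, nerve interior 0.60 and a 2-pixel hyperechoic rim at 0.90
just inside the boundary, a linear top-to-bottom attenuation ramp of
strength 0.35, and unit-mean gamma multiplicative speckle with shape 10
(≈32% intensity CV — strong but realistic granularity), clipped to [0,1].
Gamma speckle is a common surrogate for fully developed ultrasound
speckle; the rim-plus-darker-core rendering mimics the honeycomb
appearance segmenters must localize. Brightness and geometry defaults were
fixed once when the generator was written.

Not emulated: acoustic shadowing, anisotropy, out-of-plane artifacts,
multiple or touching nerves, annotation noise, scanner-dependent
post-processing. Passing tests therefore demonstrate that the pipeline's
machinery is correct and that the networks can learn this class of
appearance; they say nothing about clinical-grade performance on real
ultrasound, which requires the real datasets through the same PNG/TIFF
reader.

Datasets split 70/10/20 into train/validation/test (floor/floor/remainder,
disjoint, derived deterministically from the dataset seed), matching the
hold-out protocol the training loop expects.

## Numerical and implementation choices

* The networks run on a minimal in-repo reverse-mode autodiff engine over
  numpy (`_autodiff.py`): stride-1 'same' convolution as shifted-slice
  matmuls, 2×2 max pooling routing gradients to the first maximum in each
  window, block transposed convolutions (kernel = stride, no overlap),
  float32 training. Gradient correctness is pinned by finite-difference
  tests; everything is sized for CPUs (small images, thin filter banks).
* Adam uses the standard (β₁, β₂, ε̂) = (0.9, 0.999, 10⁻⁸); learning rate
  defaults to 10⁻³ (10⁻⁴ selectable), batch size 32. The best-validation
  parameter state is restored after training. Weight init is He-scaled
  normal; all rngs derive from the config seeds, so identical configs give
  identical weights and batches.
* Binarization threshold for the counting metrics is 0.5 (configurable);
  AUC uses the raw probabilities. GM is the geometric mean √(Sen·Spe).
  Per-image metrics whose denominator vanishes (empty mask, single-class
  AUC) are excluded from aggregates and counted, never zero-filled.
* The standard study size used by the end-to-end checks — 200 images at
  64×64, depth-3 U-net with 8 base filters, Q̆ = 8, 30 epochs — was chosen
  as the smallest configuration at which segmentation quality is clearly
  established (test Dice well above 80%) while the whole study trains in a
  few minutes on one CPU; the acceptance script runs it for an RFF-U-net
  and a plain U-net baseline.

## Known limitations

* Bi-class only; one nerve per synthetic scene.
* The FCN connects the RFF output directly to its score/upsampling head;
  no additional convolutions are interposed.
* The engine has no GPU path and no stride/dilation generality beyond what
  the three builders need.
* Increase Confidence and Win are reported for λ = 1 by default and are
  sensitive to ties only insofar as strict inequality discards them; on an
  easy synthetic task explained scores can saturate, making the Win
  direction between two strong models unstable across seeds.
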