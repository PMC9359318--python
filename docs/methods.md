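# Methods

## Model and assumptions

The classifier's weights carry a fully factorized Gaussian variational
posterior: every convolution kernel, dense weight and bias has a mean
tensor and an elementwise variance (stored as log-variance so positivity
needs no clipping). A forward pass propagates the first two moments of the
signal through each layer. Three kinds of step occur:

1. **Exact steps.** Linear maps of a constant input by random weights
   (first convolution), products of two independent Gaussian vectors
   (dense layers, inner convolutions), affine normalizations, flattening.
   For a product d_i = w_iᵀ b with w_i ~ N(m_i, Σ_i) independent of
   b ~ N(μ_b, Σ_b):

   E d_i = m_iᵀ μ_b,
   Cov(d_i, d_i) = tr(Σ_i Σ_b) + m_iᵀ Σ_b m_i + μ_bᵀ Σ_i μ_b,
   Cov(d_i, d_j) = m_iᵀ Σ_b m_j (i ≠ j).

   These are exact second moments even though the product itself is not
   Gaussian; the framework assumes the first two moments remain an adequate
   summary after each layer.

2. **Linearized steps.** Elementwise nonlinearities use a first-order
   Taylor expansion about the mean (Σ ← Σ ⊙ ∇f(μ)∇f(μ)ᵀ), and the softmax
   maps covariance through its Jacobian J = diag(g) − ggᵀ. The expansion is
   near-exact when pre-activation means sit several standard deviations
   from the ReLU kink and when pre-softmax variances are small; the error
   grows roughly with the output standard deviation. Empirically the full
   chain matches a sampling oracle to ~1% at parameter variance 2e-5 but
   degrades to tens of percent (covariance, softmax stage) by 1e-3.

3. **Selection steps.** Max-pooling pools the mean and gathers covariance
   rows/columns at the argmax indices of the mean ("co-pool"). Argmax ties
   break to the first index in row-major order, fixed, so results are
   bit-reproducible. This treats the argmax as deterministic, an
   approximation that is exact in the small-variance limit.

**Covariance representation.** Full covariance over the flattened
activation is the reference implementation: every operation supports it,
and it is the representation compared against the Monte-Carlo oracle. It
is O(n²) per feature map and infeasible at training scale, so the trained
classifier uses diagonal (elementwise-variance) propagation. For
transforms that do not mix off-diagonal mass into the diagonal
(nonlinearities, batch norm, pooling, flattening), the diagonal path
reproduces the diagonal of the full path bit for bit; for dense, inner
convolution, softmax and residual steps it is a documented approximation
that drops cross-covariances.

**Flattening order** is channel-major then row-major spatial (C-order
ravel of `(C, H, W)`), recorded in each activation's layout descriptor.
Convolutions use cross-correlation with zero padding and unit dilation;
output side is `floor((n + 2p − k)/s) + 1`.

**Residual blocks.** The reference operation follows the Jacobian form:
mean through y = x + F(x), covariance J Σ Jᵀ with J obtained by central
finite differences of the mean map (step 1e-5 · max(1, |μ_i|)) when no
analytic Jacobian is supplied. Inside the trained diagonal-mode network a
per-sample Jacobian is not affordable, so the skip and branch variances
add as if uncorrelated. This underestimates covariance when branch and
skip are strongly correlated; it is the standard scalable reduction and is
flagged here because the reference and training paths intentionally differ.

## Training objective

The loss is the negative evidence lower bound. The expected log-likelihood
places a Gaussian over the one-hot targets:

−NH/2·log 2π − Σ_i [ ½ log|Σ_ỹ,i| + ½ (y_i − μ_ỹ,i)ᵀ Σ_ỹ,i⁻¹ (y_i − μ_ỹ,i) ],

with the data sum scaled by N/B on a mini-batch. Because propagation is
analytic, the posterior expectation needs no Monte-Carlo draws (the M-draw
average degenerates to a single evaluation). The KL term is the closed
form between factorized Gaussians, scaled by 1/N per mini-batch. A
Gaussian likelihood over simplex-valued means has no intrinsic variance
floor, so the implementation adds jitter to the predictive covariance:
unconditionally (`jitter`, default 1e-3 during training) in the diagonal
path, and only on Cholesky failure in the full-covariance path, so exact
closed-form evaluations (e.g. Σ = I) are not perturbed. If a covariance is
still not factorizable after jitter, the diagonal is used with a warning.

**Optimization.** Plain SGD with a fixed learning rate, preceded by
global-norm gradient clipping (default 5.0). The clipping matters: the
quadratic term's 1/σ² gradients occasionally spike by two orders of
magnitude early in training and un-clipped SGD diverges at any useful
learning rate. Defaults (lr 0.05, batch 64, log-variance init −6, He
means) were set by a short stability scan on the synthetic benchmark.
Both objectives are internally divided by N so the learning rate is a
per-sample quantity and transfers between dataset sizes. Training aborts
with a diagnostic on a non-finite loss. Gradients come from a small
reverse-mode autodiff engine over numpy arrays written for this package;
the engine is finite-difference-checked in the test suite.

## Architecture

The default classifier is a scaled-down residual CNN for 28×28 inputs:
3×3 stem convolution (8 maps), 2×2 max-pool, a two-convolution residual
block at 8 maps, pool, a 3×3 transition to 16 maps, a second residual
block, pool, dense head, softmax. Width, depth and input shape are
configurable (`NetworkSpec`); the deterministic twin shares the
architecture and initial means, runs only the mean path, and trains with
cross-entropy. With all weight variances at zero the variational mean
forward and the twin forward are the same arithmetic, bit for bit — the
degenerate limit the tests pin down.

The scalar predictive variance attached to a decision is the
output-covariance diagonal entry at the predicted class (configurable to
trace or max-diagonal). The diagonal entry ties the uncertainty to the
decision actually made.

## Failure detection

A sample abstains when its predictive variance is *strictly greater* than
the threshold; a sample exactly at the threshold is retained (the
calibration sample that defines a median threshold is therefore kept).
Post-threshold accuracy over zero retained samples is reported as
undefined, never 100%. The fixed threshold defaults to the correct-decision
median at the minimum-noise bin; the combined median and a manual value are
the alternatives (further selection rules would be guesswork and are not
implemented).

The learned threshold is a regression network (raw pixels in; presets:
dense-only, or one convolution plus dense) fit with MSE or MAE to targets
equal to the trained model's predictive variance on *clean* images; each
clean image contributes itself plus one noisy copy per configured SNR, all
sharing the clean target. Its output is squared to keep cutoffs
non-negative. At test time each sample's variance is compared directly to
its own predicted cutoff (no margin).

## Perturbations

SNR is the energy ratio 10·log₁₀(Σx²/Σn²) in dB. Gaussian noise is scaled
per image so the pre-clip SNR hits the target exactly (the scale solves
the SNR equation in closed form; clipping to [0,1] happens afterwards and
the achieved value is reported pre-clip). Speckle is multiplicative,
x(1 + intensity·n). FGSM and PGD follow the sign of the input gradient of
cross-entropy on the predictive mean — the decision the detector protects —
with PGD projecting onto the ε-ball each step; sign vectors are upcast to
float64 so the ball bound |x′ − x|∞ ≤ ε holds to the last ulp, and
single-step PGD without random start reproduces FGSM exactly.

## Synthetic data

The generator emulates small biomedical benchmarks structurally: K
balanced classes (default 4) of 28×28 images in [0,1], one or three
channels, serialized in the common npz dialect
(`{train,val,test}_{images,labels}`, uint8, channels-last) so real
archives load through the same reader. Each class is a geometric shape
(disk, square, cross, ring, …) at a class-specific position over a
class-specific intensity gradient, jittered per sample in position (±2 px)
and scale (±15%), plus i.i.d. texture noise of standard deviation
1/separability (default 1/3). Shape-plus-gradient prototypes were chosen
over Gaussian blobs so that additive pixel noise degrades accuracy
gradually rather than cliff-like — the regime the variance-vs-noise
analysis requires. Images are quantized to the 8-bit grid at generation so
the archive round trip is exact.

What the generator does *not* emulate: the texture statistics, class
imbalance, label noise and inter-class similarity structure of real
histology/dermatoscopy/CT images. Passing the trend tests here shows the
*mechanism* works (variance tracks corruption, separates errors,
supports abstention); it does not certify accuracy numbers on any real
dataset.

**Noise bins.** The default evaluation bins are clean / −2 / −6 / −10 dB.
Published SNR tables for natural-image benchmarks sit higher (≈56 down to
≈3 dB) because those images carry more structure per pixel; on the
synthetic shapes the comparable accuracy-degradation profile (≈97% falling
to ≈45%) occurs at these lower SNRs, so the bins were placed by matching
the degradation profile rather than copying dB values. Attack defaults:
FGSM ε = 0.1; PGD ε = 0.1, α = 0.01, 20 steps, seeded random start.

## Problem sizes and determinism

The multi-seed trend analyses (tests and the acceptance script) use
n = 1200/300/600 train/val/test, five epochs, five seeds — about 30 s per
seed on one CPU; the single full-size benchmark run uses n = 2000 and ten
epochs. The Monte-Carlo oracle uses 100,000 draws on an 8×8 input at
parameter variance 2e-5, where the linearization error is far below the
sampling error. A global experiment seed fans out to named per-stage
streams (training shuffle, per-image noise, attack sample selection, PGD
start), so any stage can be re-run independently and bit-reproducibly;
CSV outputs carry a manifest with the config hash.

## Known limitations

* Diagonal-mode dense/conv/softmax/residual steps drop cross-covariances;
  full mode exists for verification, not training.
* The Gaussian likelihood on one-hot targets is a modeling convenience;
  its variance floor is the jitter constant, and reported predictive
  variances can underflow to 0 in float32 for very confident samples
  (medians and thresholds remain well-defined).
* The linearized softmax covariance becomes inaccurate at large
  pre-softmax variance (documented above); predictive variances in that
  regime are useful as a ranking signal rather than as exact moments.
* Batch normalization is implemented as a propagation operation with
  externally supplied statistics; the default trained architecture does
  not use it (biases provide the shift).
* The Carlini–Wagner attack and full-depth Resnet18 training are out of
  scope; the detection mechanisms are attack-agnostic and are exercised
  with FGSM/PGD at desk scale.
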