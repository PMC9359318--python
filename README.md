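# vdpnet

Bayesian convolutional classifiers that propagate uncertainty analytically,
with variance-thresholded failure detection for image-classification
models of the kind deployed on small biomedical images.

## The problem

A deployed classifier has no ground-truth labels, so it cannot monitor its
own accuracy. Softmax scores are a poor substitute: they are systematically
overconfident, and the gap between mean confidence and true accuracy widens
exactly when monitoring matters most — under sensor noise, distribution
shift, or adversarial manipulation. A model that carries a *calibrated*
per-decision uncertainty can instead abstain ("no decision") whenever that
uncertainty crosses a threshold, holding the sample for manual review.

`vdpnet` implements variational density propagation (VDP): the weights of a
convolutional network carry a factorized Gaussian variational posterior
q(θ) = N(M, V), and the first two moments of the signal are propagated in
closed form through every layer, so a single forward pass yields both the
decision and its predictive covariance — no test-time sampling.

## The model

Writing X̃ for the im2col matrix of the input and m, Σ for a kernel's mean
and (diagonal) covariance, the layer algebra is:

* **first convolution** (input constant): μ_z = X̃ m,  Σ_z = X̃ Σ X̃ᵀ — exact;
* **nonlinearity f** (first-order Taylor): μ ← f(μ),  Σ ← Σ ⊙ ∇f(μ)∇f(μ)ᵀ;
* **max-pool / co-pool**: pool the mean; keep covariance rows and columns at
  the argmax indices of the mean;
* **flatten**: concatenate; covariance is block-diagonal across kernels;
* **dense / inner convolution** (both factors random, independent):
  μ_d = mᵀμ_b,  Σ_d,ii = tr(Σ_i Σ_b) + m_iᵀΣ_b m_i + μ_bᵀΣ_i μ_b,
  Σ_d,ij = m_iᵀΣ_b m_j — exact second moments of a product of Gaussians;
* **softmax** (linearized): μ_ỹ = g(μ_d),  Σ_ỹ = J Σ_d Jᵀ with J the softmax
  Jacobian;
* **batch norm**: an affine map with diagonal scale γ/√(σ_B² + ε);
* **residual block** y = x + F(x): mean through the sum, covariance through
  the Jacobian of the summed map.

Training minimizes the negative evidence lower bound
ℒ = −E_q[log p(D | θ)] + KL(q(θ) ‖ p(θ)), with a Gaussian expected
log-likelihood over one-hot targets evaluated at the propagated (μ_ỹ, Σ_ỹ)
and a closed-form KL to a factorized Gaussian prior.

Two failure-detection mechanisms consume the scalar predictive variance
(the output-covariance diagonal at the predicted class):

* **fixed threshold** — the median variance of correct decisions at the
  minimum tested noise level;
* **learned threshold** — a small regression network trained to map an
  image (clean or noise-corrupted) to the predictive variance of its clean
  counterpart; each sample is compared against its own predicted cutoff.

A full covariance implementation (`CovarianceMode.FULL`) is the checkable
reference — it is validated against a Monte-Carlo sampling oracle — while
the diagonal mode scales to training and is what the classifier uses.

## Worked example

Synthetic 4-class 28×28 images (geometric prototypes plus texture noise,
MedMNIST-like npz layout) stand in for real data so the whole pipeline runs
in about half a minute on one CPU:

```python
from vdpnet.data import SyntheticSpec
from vdpnet.experiment import ExperimentConfig, run_experiment
from vdpnet.network import NetworkSpec

config = ExperimentConfig(
    dataset=SyntheticSpec(n_train=1200, n_val=300, n_test=600, seed=0),
    network=NetworkSpec(seed=0),
    epochs=5,
    seed=0,
)
result = run_experiment(config)
cols = ["bin", "vdp_accuracy_pct", "median_var_correct", "median_var_incorrect",
        "twin_gap_pct"]
noise = result.curves.query("bin in ['none', 'low', 'medium', 'high']")
print(noise[cols].round(4).to_string(index=False))
print(f"fixed threshold = {result.fixed_threshold:.3e}")
fixed = result.thresholds.query(
    "threshold_type == 'fixed-correct' and bin in ['none', 'low', 'medium', 'high']")
print(fixed[["bin", "pre_accuracy_pct", "abstained_pct", "post_accuracy_pct"]]
      .round(2).to_string(index=False))
```

prints

```
   bin  vdp_accuracy_pct  median_var_correct  median_var_incorrect  twin_gap_pct
  none           97.5000              0.0000                0.9273       -0.8224
   low           87.3333              0.0000                0.1438       -1.5334
medium           69.3333              0.0005                0.3616       20.1058
  high           50.3333              0.0079                0.2322       44.2639
fixed threshold = 0.000e+00
   bin  pre_accuracy_pct  abstained_pct  post_accuracy_pct
  none             97.50          38.33             100.00
   low             87.33          78.83              99.21
medium             69.33          90.67              96.43
  high             50.33          94.17              77.14
```

Reading the table: as Gaussian noise grows (bins none → high, target SNRs
of −2/−6/−10 dB), accuracy falls from 97.5% to 50.3% while the median
predictive variance of wrong decisions stays one to four orders of
magnitude above that of correct decisions — the signal the thresholds
exploit. The deterministic twin (same architecture, point weights) becomes
badly miscalibrated: its mean softmax confidence exceeds its accuracy by 44
points at high noise. Thresholding at the clean correct-median abstains on
more samples as noise rises (38% → 94%) and lifts the accuracy of the
retained decisions in every bin (e.g. 50.3% → 77.1% at high noise).

The same pipeline is available from the shell:

```bash
vdpnet init-config config.yaml
vdpnet report --config config.yaml --out runs/demo
```

which writes `curves.csv`, `attacks.csv`, `thresholds.csv`, model
checkpoints, and a manifest with the config hash and seeds.

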