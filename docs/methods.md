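# Methods

This note records the models, numerical choices, and deliberate design
decisions behind the package, and what the test suite does and does not
demonstrate.

## Problem setting

A classifier h_θ maps a 1-D physiological signal x (one beat, or a
multi-lead record) to one of M rhythm classes. An ℓ∞ adversary may replace
x by any x_adv with ‖x_adv − x‖∞ ≤ ε. We want h_θ to keep its accuracy both
on clean inputs and under the strongest white-box attacks, and we want part
of that robustness to be *certifiable* rather than empirical.

## Architecture

The network has three parts.

**Residual trunk.** Stem: 1-D convolution, kernel 11, stride 2, 64
channels, "same"-style padding (pad 5) — this padding choice is forced by
the published width arithmetic (187 → 94). Three residual layers of two
blocks each; each block is conv(k3, stride)–GN–LeakyReLU–conv(k3,1)–GN plus
a 1×1 projected skip, with both blocks of a layer at stride 2 (so each layer
divides the width by 4: 94 → 24 → 6 → 2). Group normalization uses 32
groups (4 in the narrow desk-scale profile) and the leaky slope is 0.01;
neither value is dictated by anything, both are conventional.

**CAS layer.** A final residual layer (stride 1 in the beats profile; the
multilead profile halves the width once, 264 → 132) whose blocks end in a
plain ReLU — CAS needs non-negative features. Each of the K = 2 blocks
carries a CAS module: global (or mask-restricted) average pooling gives the
channel activation vector f̂ᵏ ∈ R^C, an auxiliary linear classifier produces
p̂ᵏ = softmax(f̂ᵏHᵏ), and the column of Hᵏ ∈ R^{C×M} for the true class
(training) or the argmax of p̂ᵏ (inference; ties broken toward the lowest
index) multiplies the channels. At inference the reweighting is a
deterministic function of the input alone — no label information leaks.

**ℓ∞-distance head.** Layers of distance neurons u(x) = ‖x − w‖∞ + b; with
5 hidden layers of 512 units in the full profile (2 × 64 in the desk-scale
profile) and M output neurons. Every layer, hence the composition, is
1-Lipschitz under ℓ∞, giving the certified-margin property checked in the
test suite: if the top-two logit margin exceeds 2ε, no perturbation of the
head input within ε can change the argmax. For the 9-class profile the
output layer has 9 neurons.

**Masking (multilead profile).** Variable-length records are zero-padded
symmetrically to a common length (odd remainder to the right) and carry a
validity mask. The mask is downsampled alongside the features (position w
of a stride-s conv output is valid iff input position s·w is valid — with
"same" padding the receptive-field centre of output w is exactly s·w),
group-norm statistics are computed over valid positions only, features are
multiplied by the mask after the stem and after every block, and the final
reduction is a mask-weighted channel average. Together these make the
features exactly independent of the amount of padding whenever the padding
offset is a multiple of the total stride (2⁸ for the multilead profile);
the padding-invariance test verifies equality to ~1e-15. Sub-stride offsets
shift the convolution phase and change features slightly, as in any strided
CNN.

## Training

- Objectives: plain cross-entropy (`ce`), adversarial training (`at`),
  TRADES (`trades`, KL regularizer with weight β, default 6), and MART
  (`mart`) — boosted cross-entropy on adversarial outputs plus
  λ·KL(p_nat‖p_adv)·(1 − p_nat[y]), λ = 5 (the value standard for this
  objective; the trade-off is not otherwise pinned down). The CAS auxiliary
  heads receive the same outer objective, averaged over heads and scaled by
  α (default 2, the value found optimal in the hyperparameter sweep the
  package mirrors). An optional MSE term between the one-hot label and the
  natural-input probabilities (sum over classes, mean over the batch) aids
  convergence on the multilead profile; the printed form of that term is
  dimensionally ambiguous and this is the reading implemented.
- Inner maximisation: 10-step PGD maximising plain cross-entropy, ε = 0.1,
  step ε/10, uniform random start, adversarial examples regenerated at
  every parameter update. The outer minimisation targets the full
  objective. (Both choices are configurable; maximising the full objective
  is also supported.)
- Optimiser: Adamax with plateau-driven learning-rate decay. The full-size
  profile records the reference hyperparameters (batch 512, lr 1e-3); the
  desk-scale profile uses batch 64 and lr 2e-3, chosen once so that five
  epochs suffice for convergence on the synthetic task at ~1000 training
  beats.
- p-ramp: the distance head trains with the smooth p-norm surrogate, p
  ramped geometrically 8 → 1000 across epochs; all evaluation and attack
  generation on trained models use the exact p = ∞ (subgradient at the
  first maximal coordinate).
- Probability flooring: all logs of probabilities are clamped at 1e-12.

## Attacks

All ℓ∞ attacks clamp iterates to [x−ε, x+ε] and then to the data range
(default [−1, 1] for normalized signals; configurable to none, since ECG
amplitude is not intrinsically bounded). Random starts are uniform over the
ε-ball. Evaluation sweeps use step size ε/10; the reference protocol is 100
iterations (tests and the acceptance script use 20 to keep runs short — the
sweeps here are far past convergence at desk scale).

- FGSM ≡ PGD with one full-ε step and no random start.
- MI-FGSM accumulates g ← μ·g + ∇/‖∇‖₁ (μ = 1 by default; normalisation
  skipped when ‖∇‖₁ = 0) and steps by δ·sign(g).
- SAP convolves each step's sign-gradient update (not the cumulative
  perturbation) with a normalized 1-D Gaussian kernel, per lead,
  same-length with symmetric (reflect) boundary handling; s = 1 reduces
  exactly to PGD. Published kernel grids: s ∈ {5,7,11,15,19},
  σ ∈ {1,3,5,7,10}.
- C&W (ℓ₂): tanh change of variables within the clip box, Adam descent on
  ‖x_adv − x‖₂² + c·max(z_y − max_{k≠y} z_k + κ, 0); the returned sample is
  the successful iterate (margin beaten by κ) of least distortion, else the
  final iterate. Defaults c = 1, κ = 0, lr = 0.01, 100 iterations, no
  binary search over c.

On affine models the attack suite is validated against closed forms:
corner enumeration of the ε-ball for FGSM/PGD loss maxima, and the
point-to-hyperplane distance for the minimal C&W distortion (matched within
5%; within ~1% at small learning rates).

## Robustness metrics

ACC_robust = ACC_clean × AUC and F1_robust = F1_clean × AUC, with AUC the
trapezoidal area under the metric-vs-ε curve over [0, ε_max] divided by
ε_max, the ε = 0 clean point included in the grid. Both factors are
fractions in [0, 1]; results are conventionally reported ×100. The
integration rule is the standard reading — the source material does not
define it precisely, and its printed summary values cannot be reproduced
from its printed curves under any standard rule, so they are context, not
targets. F1 is macro-averaged. For SAP sweeps the abscissa is the
normalised rank index of the (s, σ) grid, since the sweep axis is not a
scalar ε.

Channel statistics: activations at the final feature-extraction layer,
pooled over the valid extent. A channel is "active" on a sample when its
pooled activation strictly exceeds threshold_frac × that sample's maximum
across channels (defaults 0.20 for beats, 0.70 for multilead; a
batch-global reference is available behind a flag — the per-sample reading
was chosen because the batch-global one makes the statistic depend on batch
composition). Channels are reported in descending order of natural
activation frequency.

## Synthetic data

Each class is a sum of Gaussian bumps (defaults: three per class, standing
in for P/QRS/T waves) with class-specific centres, widths, and amplitudes
drawn once per call from a seeded RNG and spread apart so classes are
separable; records add white noise (default sd 0.05 relative to unit QRS
amplitude) and slow sinusoidal baseline wander (default amplitude 0.05,
emulating respiration drift). The multilead generator repeats the beat
template at 1.2 Hz, applies fixed per-class per-lead gains, and draws
durations uniformly from the requested range. Presets mirror the two study
settings: 5-class single-lead 187-sample beats and 9-class 12-lead records
at 500 Hz.

What this does *not* emulate: physiological beat-to-beat variability, QRS
morphology changes within a class, electrode noise spectra, class overlap,
or inter-patient variation. Passing tests therefore demonstrate correctness
of the algorithms and the *direction* of the robustness effects on the
pinned fixture (MART > natural training; full model ≥ plain baseline), not
clinical-scale performance numbers: the synthetic task is far easier than
real arrhythmia classification and absolute accuracies are correspondingly
high. Because class templates are redrawn per seed and the desk-scale
schedule is short (~80 parameter updates), the size — occasionally even the
sign — of the MART-versus-natural gap varies across seeds: the 1-Lipschitz
head already makes a naturally trained model substantially robust on easy
template draws, echoing the finding that this architecture carries
robustness without adversarial training. `scripts/acceptance.py` reports
whatever its seed produces.

## Numerical and engineering choices

- All computation is float64 on a small reverse-mode autodiff engine
  (`caslcnet.nn`): broadcasting arithmetic, strided 1-D convolution
  (implemented as a short loop over kernel taps), group norm composed from
  primitives, stabilised log-sum-exp, and chunked p-norm/ℓ∞ distance
  layers with a first-argmax subgradient at p = ∞.
- Ties in any argmax resolve to the lowest index.
- Zero gradients make sign-updates no-ops; MI-FGSM guards ℓ₁-normalisation
  against zero gradients.
- An all-zero lead cannot be max-abs normalized; it is passed through with
  a warning. An all-invalid mask is an error.
- Checkpoints are single-file .npz archives with a versioned JSON header
  (schema 1) holding the config and training metadata.
- Single-threaded runs are bit-reproducible given the config seeds; the
  pipeline's report JSON excludes wall-clock timings for that reason.

## Known limitations

- The desk-scale profiles are narrow (16–64 channels); the full-width
  profiles build and evaluate correctly (the width arithmetic reproduces
  the reference table exactly) but adversarial training at full width and
  100 epochs is out of scope here.
- The ℓ∞ head certifies margins of the *head input*; the convolutional
  trunk is not Lipschitz-constrained, so end-to-end certification is not
  claimed — matching the design being reproduced.
- The multilead profile's exact padding invariance holds for stride-aligned
  padding offsets (see Masking above).
- C&W uses a fixed penalty constant; the classic binary-search refinement
  is not implemented.
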