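# Methods

## Model family

All seven architectures share one five-convolution backbone:

| layer | tiny profile (64×64 input) | full profile (227×227 input) |
|---|---|---|
| conv1 | 5×5, stride 2, 16 ch | 11×11, stride 4, 96 ch |
| LRN + maxpool | 2×2 / 2 | 3×3 / 2 |
| conv2 | 5×5, pad 2, 32 ch | 5×5, pad 2, 256 ch |
| LRN + maxpool | 2×2 / 2 | 3×3 / 2 |
| conv3–conv5 | 3×3, pad 1, 48/48/32 ch | 3×3, pad 1, 384/384/256 ch |
| merged width D | 128 | 1024 |
| dense | 64, 64 | 4096, 4096 |

conv3–conv5 share spatial dimensions by construction (3×3, stride 1,
pad 1), which is what makes channel concatenation between them legal; the
builder verifies spatial equality and raises a wiring error rather than
resampling. The variants differ only in connectivity:

* **base** — plain chain, classifier fed by flatten(pool(conv5)).
* **A** — conv5 input = concat(conv4, conv3); merged layer fed by conv5.
* **B** — merged layer fed by concat(conv5, conv3).
* **C** — merged layer fed by concat(conv4, conv5).
* **D** — same merge wiring as C. The description of D's "additional
  input" to conv4 is conv3's output, which is already conv4's input, so
  duplicating it would be degenerate; the distinguishing feature retained
  is the conv4+conv5 merge.
* **E** — merged layer fed by concat(conv3, conv4, conv5).
* **FMC** — conv5 input = concat(conv3, conv4); merged layer fed by
  concat(conv3, conv4, conv5).

Every non-base variant gets a merged layer (A's is fed by conv5 alone) so
the family differs in wiring only. The "+" in the multi-connection
formula is implemented as channel concatenation, not elementwise addition:
addition is ill-defined across unequal channel counts (384 vs 256), and
concatenation is the operation the merge-layer pseudo-code specifies.

**Merged layer.** concat → global Lp pooling per channel → linear
projection to width D → ReLU → dense head. The reduction exponent
defaults to p = 2 (spatial L2 norm per channel, the standard
generalized-mean pooling); |·| keeps the root real if an odd p is
configured. p is otherwise unconstrained in the method's description. The
searched "dimension" of the merged layer is interpreted as the projection
width D (the pooled channel count is fixed at 1024 by the full-profile
wiring).

**LRN** (k = 2, n = 5, α = 4·10⁻⁴, β = 0.75) is placed after conv1 and
conv2, the convention of the backbone this family modifies; the method
description supplies the hyperparameters but not the placement.

**Skip-widened kernels.** Where a skip connection widens a conv layer's
input (variant A and FMC conv5), checkpoint loading copies stored kernels
into the input-channel slice they match and leaves only the extra slice
scheme-initialized (He-scaled Gaussian), preserving transferred weights.

## Training

Mean binary cross-entropy with probabilities clipped at 1e-7 before the
log. The optimizer is the explicit momentum-SGD recurrence
v ← μv − λεw − εg, w ← w + v, implemented directly (not via a framework)
so the update itself is testable against a hand-unrolled recurrence.
Defaults follow the transfer recipe: ε = 1e-4, μ = 0.95, λ = 1e-6,
200 epochs, batch 32, first three conv layers frozen. Where the printed
recurrence carries the constants 0.9/0.0005, the stated experimental
settings (0.95, 1e-6) take precedence as defaults; both are configurable.
"Decay" is implemented as per-step weight decay, which is where the λ
term sits in the recurrence. Batch size is not specified by the method;
32 is a common default at this input scale.

The training loop retains the epoch with the best validation accuracy
(earliest epoch on ties). Gradients come from the package's reverse-mode
autodiff; the backward pass of every operation is verified against
central finite differences in the test suite.

**Saturation-safe loss gradient.** The loss *value* is computed from
clipped probabilities, but the gradient is taken through the fused
logit-space form dL/dz = (σ(z) − y)/n. With the gradient of the clipped
composition, a model initialized in the saturated regime (predicted
probability exactly 0/1 in float32) receives zero gradient and never
recovers; the fused form is identical wherever predictions are unclipped
and restoring where they are not.

**From-scratch protocol** (`from_scratch_config`): when no pretrained
weights exist, freezing the early layers would fix random filters, so
nothing is frozen, and the learning rate is raised to 1e-3 (momentum 0.9).
1e-3 was chosen by observing stable, monotone training-loss convergence
on the synthetic benchmark; 2e-2 visibly diverged (loss saturating within
one epoch) and 1e-4 converges but needlessly slowly for a randomly
initialized network.

## Synthetic data

Each patch contains one elliptical node on a noisy background. The three
class-separating knobs mirror the radiological criteria for a suspicious
node:

* **border_irregularity** — radial boundary perturbation
  r(θ) = r₀(1 + Σ_k a_k sin(kθ + φ_k)), harmonics k = 3…8 with random
  phases, amplitudes scaled so the RMS perturbation equals the knob value.
* **heterogeneity** — multiplicative Gaussian speckle smoothed with a
  σ = 1.5 px kernel and rescaled so the interior std/mean equals the knob.
* **roundness** — minor/major axis ratio, random orientation.

Per class the knobs are drawn from truncated normals. Defaults (positive
0.14/0.30/0.92 vs negative 0.03/0.06/0.62, sds 0.02/0.04/0.06) make the
classes well separated but overlapping — a converged classifier can
approach AUC 1.0 on a small test split while single-feature thresholds
cannot. Node diameters are uniform on [16, 40] px inside 64 px patches,
respecting a minimum-diameter inclusion threshold (the analogue of the
clinical >3 mm rule); interior/background base intensities are 0.75/0.25
with additive background noise sd 0.05 on the [0,1] scale. Intensities
are free parameters of the generator: the source imaging protocol does
not constrain patch statistics.

`zero_signal_config` sets both classes to one intermediate phenotype;
any classifier's expected AUC on such data is 0.5, which is used as the
negative control.

What the generator does **not** emulate: MRI physics (coil artifacts,
bias fields, T2 contrast), 3-D context, anatomical surroundings,
segmentation error, or patient-level correlation between patches. Passing
tests on this benchmark demonstrate that the architecture, optimizer and
evaluation machinery are correct and that the pipeline can recover a
known signal — not that the method reaches any particular accuracy on
clinical images.

## Splits and preprocessing

80/10/10 stratified splits: global per-split counts come from
largest-remainder rounding over all records (ties toward train, then
validation); each label's records are then apportioned by their own
quotas within those totals, keeping every split's class balance within
one sample of the global prevalence. Images are bilinearly resized,
standardized with mean/sd computed **on the training split only**, and
replicated to three channels (the backbone convention for grayscale
input).

## Evaluation

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP),
NPV TN/(TN+FN), accuracy (TP+TN)/n at threshold 0.5 with the ≥
convention; zero-denominator metrics are reported as undefined, never 0.
ROC from a full threshold sweep, AUC by trapezoid; an independent
Mann-Whitney midrank AUC serves as a cross-check in tests (the two agree
to 1e-10 under ties). For any single confusion matrix, accuracy is the
prevalence-weighted mean of sensitivity and specificity and therefore
lies between them; the panel asserts this identity. A reported
operating-point panel whose accuracy falls outside
[min, max](sensitivity, specificity) cannot come from one confusion
matrix — the package enforces the identity rather than reproducing such
panels.

The width search trains one model per candidate width
{32, 64, …, 4096} with a fixed seed, scores on the validation split,
and selects the argmax with the smallest-width tie-break; only the final
selected model should touch the test split. The ablation harness trains
each variant under identical data/seed and reports the test panel per
variant.

## Heat-maps

CAM M_c = Σ_k w_{c,k} f_k over the merged concatenation (or conv5 block
only, as an option), with w_{c,k} the composition of the merged
projection, dense and classifier weight matrices — the linear path,
ignoring ReLUs, the standard CAM approximation; the Lp-pooled channel
response is treated as each channel's scalar summary. Maps are min-max
normalized (constant maps become zeros with a warning), bilinearly
upsampled, pushed through a jet colormap (red = high evidence) and
alpha-blended (default 0.4) over the input.

## Problem sizes

The test suite and the acceptance script run the tiny profile: 64×64
patches, conv widths 16/32/48/48/32, merged width 128, 240–400 samples,
20–30 epochs, seeds fixed throughout. These sizes are the package's
desk-scale defaults for a from-scratch numpy implementation; the full
profile (227×227, widths 96/256/384/384/256, D = 1024) is built and
structurally verified in tests, and trains through the identical code
path.

## Known limitations

* No GPU path; the numpy engine is practical only at the tiny profile.
* No data augmentation, learning-rate schedules or early stopping beyond
  best-epoch selection — none are part of the training recipe modeled.
* Records are split independently; patient-level grouping is out of scope
  (one node per patient is the assumed structure).
* float32 is the default dtype; bit-exact determinism holds on a given
  BLAS/platform, not across platforms.
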