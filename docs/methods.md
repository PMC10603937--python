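# Methods

## Problem and model

The package segments layered tissue in grayscale OCT B-scans: each pixel is
assigned to one of C classes (background plus ordered retinal strata, and
optionally an optic-disc and a fluid class). The segmenter is a composition
of one or more encoder–decoder *stacks*.

**Encoder.** A five-stage pyramid at strides 2, 4, 8, 16, 32. Each stage is
two Conv–Norm–ReLU blocks (the first with stride 2), optionally followed by
a spatial-attention gate. Published backbone names (EfficientNet-B0…B5,
ResNet34D/50D, SEResNeXt50-32x4D) are accepted as registry keys; without an
external pretrained-backbone plug-in they resolve to built-in `TinyEncoder`
presets with graded widths and the same pyramid contract, so the
architecture is exercisable from scratch on a CPU. Pretrained weights are
never required.

**Spatial attention.** The gate is
`sigmoid(conv7x7([channel-mean; channel-max]))`, multiplied pixel-wise onto
the feature map. The pooled maps are replicate-padded before the 7×7
convolution so a constant feature map receives a constant gate. Clamping
every gate to 1 makes the attention decoder compute exactly the same
function as the plain decoder — the attention variant strictly generalizes
a plain U-Net decoder, and the test suite verifies this reduction.

**Decoder.** Five levels walk the pyramid deepest-first. Per level:
concatenation fusion with the skip map through a 1×1 projection back to the
primary map's channel count (`x' = Conv1x1(Cx+Cskip→Cx)([x, skip])`, the
skip resized bilinearly to x when spatial dims differ), spatial attention
*before* the ×2 upsampling, then a two-convolution refinement block. A 1×1
head yields C logits at input resolution. Upsampling defaults to bilinear
interpolation (artifact-free); a transposed-convolution variant
(zero-insertion + 3×3 convolution) is selectable.

**Stacking.** Stack k+1's input is the original image channel-concatenated
with stack k's softmax output (coupling `image+probs`; `probs_only` and
`logits` are provided). This implements the reading of the second stack as
a denoiser that sees both the raw evidence and the previous segmentation.
Feature-map-level coupling between stacks is not implemented.

Two refinement-specific defaults, both configurable on the model spec, make
the stacked composition train reliably from scratch:

- *stop-gradient coupling* (`detach_coupling=True`): the probabilities fed
  to the next stack are detached, so each stack trains on its own
  (auxiliary or final) loss and the refiner treats incoming probabilities
  as data — the intermediate-supervision regime of stacked-hourglass
  networks. With full end-to-end backpropagation the final-stack loss
  destabilised the first stack on high-noise phantoms and some seeds
  collapsed.
- *residual refinement* (`residual_refine=True`): stack k+1 predicts a
  logit-space correction added to stack k's logits, and its 1×1 head is
  zero-initialised, so at initialisation the refiner reproduces the
  previous stack's segmentation exactly and learns only the correction
  (residual learning). Without this, the refiner occasionally got stuck in
  a poor basin below its own input's quality; with it, the two-stack model
  consistently improves on the single stack under heavy noise. One
  consequence: gradients reach the refiner's body only after its head's
  first update.

## Losses

All losses are defined on class-probability maps with soft set sizes
(|X∩Y| = Σ g·p, |X−Y| = Σ g·(1−p), |Y−X| = Σ (1−g)·p) and are
differentiable end to end; hard (argmax) sets appear only in evaluation.

- **Dice**: mean over classes of 1 − (2|X∩Y|+s)/(|X|+|Y|+s). Smoothing
  s = 1e-6 by default; with s = 0 an empty-vs-empty class scores a perfect
  1 (loss 0). This 0/0 convention is the only place the loss and the
  evaluation metric can differ: the metric *excludes* classes absent from
  both masks from an image's mean rather than scoring them 1.
- **Lovász-Softmax**: per class, pixel errors |g − p| sorted in decreasing
  order (stable sort) and weighted by the first differences of the Jaccard
  errors of growing mispredicted prefixes; averaged over the classes
  present in the ground truth by default (`all` selectable). The printed
  symbolic form of this loss in the literature is ambiguous about the
  weights; this implementation is the standard sorted-error
  Jaccard-extension algorithm and is verified in tests against two
  independent oracles: 1 − IoU at every hard one-hot prediction, and the
  level-set (Choquet) integral of the Jaccard set loss on ≤8-pixel
  instances.
- **Tversky**: 1 − (|X∩Y|+s)/(|X∩Y| + α|X−Y| + β|Y−X| + s), mean over
  classes. α = β = 0.5 (the default) reduces exactly to Dice at s = 0.
  The α/β orientation follows the formula with X as ground truth, under
  which |X−Y| is the false-negative mass; prose descriptions that attach
  α to "false positives" assume the reverse orientation of the same
  expression.
- **Combined**: 0.5·Dice + 0.3·Lovász + 0.2·Tversky, weights configurable.

## Training protocol

Adam (β = 0.9/0.999), initial learning rate 0.001, cosine annealing to
0.01 × the initial rate over the epoch budget (optional linear warmup
prefix), batch size 32, at most 75 epochs with early stopping on validation
combined loss (patience 10). These are the protocol defaults; desk-scale
runs override epoch and batch counts. The schedule phrase "decaying by a
factor of 0.01 × learning rate" is read as *final* lr = 0.01 × initial; a
per-step decay reading would leave the printed initial rate meaningless by
epoch 2.

Gradient updates are clipped to a global L2 norm of 5 before the Adam step.
Small-batch training of randomly initialised segmentation networks under
set-overlap losses occasionally diverges early (one bad batch can saturate
the softmax); clipping removes these collapses without affecting converged
behavior.

Two stack-training regimes exist: **joint** (default) minimises
`0.4 · L(stack-1 output) + L(final output)` in one optimisation loop, so
the second stack trains against realistic, evolving first-stack errors
(with the default stop-gradient coupling each loss term updates its own
stack); **sequential** trains stack 1 to early stop, freezes it, then
trains stack 2. The published description does not state the regime; joint
matches the end-to-end architecture figure.

Augmentation (horizontal flip applied to image and mask together, additive
Gaussian noise σ = 0.02, contrast factor in [0.8, 1.2] — image only)
expands the training set by a factor of 2. Magnitudes are unstated in the
protocol this mirrors and were fixed once at values that visibly perturb
but never destroy layer structure. Expansion before splitting (the
bookkeeping that turns 122 images into 244 and then 148/48/48 at 60/20/20)
is reproduced by the documented call order; note that this order can place
augmented twins across splits, so the leak-free order (split, then expand
the training split) is the recommended one.

Splits use floor rounding on the validation and test fractions with the
remainder to train — the only rule consistent with 148/48/48 from 244.
k-fold cross-validation delegates to scikit-learn's shuffled `KFold` and
aggregates fold Dice as mean ± sample standard deviation (ddof = 1); the ±
convention is not defined in the source material and is documented here as
sample std across folds.

## Phantoms

The generator emulates exactly the statistics a layer segmenter exploits:

- boundaries: equally spaced base depths plus seeded vertical jitter and
  three low-frequency sinusoids, scaled by `boundary_smoothness` (pixels),
  column-sorted and clipped so curves never cross; zero smoothness gives
  flat, equally spaced layers;
- intensities: one mean reflectivity per layer in [0,1], alternating
  bright/dark by default like plexiform/nuclear strata;
- noise: multiplicative unit-mean Gamma speckle with `speckle_looks`
  controlling variance (the standard surrogate for coherent-imaging
  speckle; `None` disables it) plus additive Gaussian noise, clipped to
  [0,1];
- pathology: optionally a parabolic optic-disc cup re-labeling all layers
  it crosses, and an elliptical dark "fluid" blob confined to one layer.

Per-sample generators are spawned from a counter-keyed `SeedSequence`, so
datasets are bit-reproducible and order-independent. With noise disabled a
nearest-mean-intensity oracle attains Dice 1.0 — the phantom is learnable
by construction, which is what makes the training smoke tests meaningful.

What phantoms do **not** model: A-scan point-spread functions, shadowing,
vessel artifacts, curvature of real peripapillary anatomy, annotation
noise. Passing the phantom benchmarks therefore demonstrates that the
architecture, losses, and training loop function correctly and that the
two-stack composition does not hurt under heavy noise; it says nothing
quantitative about clinical OCT performance.

## Desk-scale benchmark conditions

CPU budgets dictate the problem sizes, chosen once:

- *learnability smoke*: single stack, 64 train / 16 validation phantoms at
  64×64 with 5 classes, default noise, batch 8, 20 epochs, three training
  seeds; claim: validation overall Dice ≥ 0.80 on every seed.
- *refinement comparison*: one vs two stacks on high-noise phantoms
  (speckle_looks = 1, σ = 0.1) at 32×32, 64 train / 24 validation, batch 8,
  24 epochs, three seeds each; claim: two-stack mean ≥ single-stack mean
  − 0.02 (non-inferiority). The published +0.83 pp two-stack improvement
  was measured on clinical data at full scale and is reported, not
  asserted, here.

## Numerical core

The network runs on a reverse-mode autodiff engine over numpy arrays
written for this package: broadcasting elementwise ops, reductions,
im2col-based 2-D convolution, exact bilinear resampling expressed as cached
1-D interpolation matrices, replicate padding as 0/1 selection matrices,
gather (for the sorted-error loss), and concatenation. Convolution layers
are He-initialised from an explicit `numpy.random.Generator`; batch
normalisation uses batch statistics in training and running averages at
evaluation (safe down to one sample because spatial positions enter the
statistics). Single-threaded runs are bit-deterministic given a seed;
multi-threaded BLAS runs are reproducible in practice but only the
single-threaded contract is tested.

## Known limitations

- No pretrained backbones ship with the package; the published-name
  registry entries are TinyEncoder stand-ins with matching contracts.
- Checkpoints store the flat parameter dict plus a JSON spec in `.npz`;
  there is no cross-version migration.
- The Lovász term's class averaging (`present` mode) makes batch loss a
  mean over pooled batch pixels, not a mean of per-image losses.
- CPU-only: full-resolution (1024×992) clinical B-scans forward fine, but
  training at that scale is impractical here.
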