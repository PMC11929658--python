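# Methods

This note documents the models and procedures the package implements, the
defaults it ships, and what its synthetic fixtures do and do not show.

## The network

The classifier is a lightweight ConvNeXt-style CNN for 224×224×3 inputs:

* **Stem** — 4×4 convolution, stride 4, width 96, batch normalisation (BN),
  leaky ReLU (slope 0.1, the DarkNet convention). Output 56×56.
* **Four stages** of inverted-bottleneck blocks with depths [2, 2, 6, 2]
  and widths [96, 192, 384, 768]. Each block applies a depthwise 7×7
  convolution (same padding), a 1×1 expansion by factor 4, and a 1×1
  projection back; BN follows each convolution and the single activation
  sits after the expansion.
* **Compression units** between stages 1–2, 2–3 and 3–4: a 3×3/stride-2 max
  pool depth-concatenated with a parallel 1×1 stride-2 convolution branch,
  halving the spatial size and doubling the channel width. Stage 4 keeps
  the 7×7 resolution.
* **Head** — global average pooling (GAP) over the 7×7×768 map, a fully
  connected layer, softmax.

### Block variants and the parameter budget

Two block designs are provided behind `ArchSpec.block_variant`:

* `split` (default): the input of width C is split into channel halves; one
  half passes through untouched, the other goes through the bottleneck at
  width C/2, and the halves are depth-concatenated. Channel count is
  conserved and the default four-class network has **4.66 M** trainable
  parameters.
* `literal`: the full-width inverted bottleneck with an additive skip,
  roughly four times heavier (~19 M parameters at the default widths).

The half-width split design is the default because the architecture is
meant to be lightweight (under ten million parameters) and because the
depth-concatenation compression units already signal a concatenative,
channel-economical design language. The traced shape plan of the default
build is 56 → 28 → 14 → 7 → 7.

Parameter accounting is verified two ways: the framework count (sum over
parameter arrays) and an analytic closed form (k·k·Cin·Cout/groups + bias
per convolution, 2 trainable values per BN channel) agree exactly on every
spec tested.

### Numerical engine

The layer framework is plain NumPy with explicit forward/backward passes:
convolution via im2col with stride-tricks views, max pooling with cached
argmax routing, standard BN backward in train mode and running statistics
in eval mode. Activations and parameters are float32. Because everything
is single-threaded NumPy, a fixed seed gives bit-reproducible training and
inference. Weight init is Kaiming fan-in for convolutions; BN starts at
scale 1, shift 0. Gradients were validated against central finite
differences layer by layer.

## Training recipe

Momentum SGD: constant learning rate 0.01, momentum 0.1, L2 weight decay
1e-4, mini-batch 32, cross-entropy, 70/30 stratified train/validation
split, validation every 50 iterations, best-validation checkpoint kept,
no augmentation, pixels scaled to [0, 1]. Momentum 0.1 is unusually low
for SGDM; it is kept as the package's printed default and is overridable
(`TrainConfig.momentum`). A non-finite loss aborts with the iteration and
learning rate in the message.

## Exemplar (fixed-size patch) feature engineering

1. Resize the image to 224×224.
2. Tile into 49 non-overlapping 32×32 patches, row-major; patch h sits at
   1-based origin (i, j) ∈ {1, 33, …, 193}².
3. Extract the GAP activation (length 768 by default) for the raw image and
   each patch — 50 vectors per image. Patches are bilinearly resized to
   the network input size before extraction; the fixed-input extractor
   convention. This choice is prominent because it changes the effective
   receptive field of patch features.
4. Merge into one vector of width 50·768 = 38,400 with the law
   F[q + 768·(t−1)] = fv_t[q]; t = 1 is the raw image. Column provenance
   (t, q) is preserved in CSV headers (`t{t}_q{q}`).

## NCA feature selection

The feature-selection variant of neighborhood component analysis: each
feature r has a non-negative weight v_r, distances are weighted Manhattan
d_ij = Σ_r v_r |x_ir − x_jr| / σ, stochastic-neighbour probabilities
p_ij ∝ exp(−d_ij) define the leave-one-out objective
f(v) = Σ_i Σ_{j: y_j=y_i} p_ij − λ Σ_r v_r, maximised by projected
gradient ascent (weights clipped at zero after each step) with a
backtracking step control that keeps the objective non-decreasing.
Features are ranked by decreasing weight; ties break by ascending index.

Design notes:

* **Length-scale σ** is the mean pairwise L1 distance at unit weights.
  Without it, high-dimensional distances are so large that the softmax
  collapses onto the single nearest neighbour and gradients die at the
  uniform initialisation.
* **Projected gradient on v (not ascent on w with v = w²).** A squared
  parametrisation has stationary traps at w_r = 0 (the gradient is
  proportional to w_r), which in planted-feature benchmarks reproducibly
  killed informative features that transiently crossed zero. Projection
  keeps the boundary gradient alive, and non-negativity is guaranteed by
  construction.
* λ defaults to 1/n; weights start at 1; features are z-scored (training
  statistics only) when `standardize` is on, which makes the ranking
  invariant to per-feature affine rescaling.
* Full-batch mode is deterministic and is the default; a seeded stochastic
  (per-sample) mode is available. Exact O(n²d) objective, accumulated in
  feature chunks; above `max_samples` (default 2000) rows a seeded
  subsample is used.
* Caveat: the leave-one-out softmax objective is *not* invariant to
  duplicating samples — a duplicate sits at distance zero and dominates
  its row. Deduplicate before fitting if duplicates are possible.

`select_top_k` returns the k highest-ranked columns in rank order.
`iterative_sweep` evaluates cross-validated accuracy for every subset size
in a range (the conventional range 100–1000 yields 901 entries) and
reports the first k attaining the maximum. The pipeline fits the ranking
on training-split rows only, to keep selection out of the evaluation data.

## Classifier harness and metrics

Default classifier: one-vs-all SVM with a cubic polynomial kernel
(1 + ⟨x, x′⟩/d)³, box constraint C = 1, on per-fold standardised features,
decided by maximal decision value (ties to the lowest class index).
Comparators (decision tree, linear discriminant, logistic regression,
Gaussian naive Bayes, 5-NN, one-hidden-layer MLP, 100-tree random forest)
use conventional defaults and the same protocol. Ten-fold stratified CV
pools out-of-fold predictions into one confusion matrix (rows = truth);
per-class precision = TP/column-sum, recall = TP/row-sum, F1 the harmonic
mean; overall values are macro (unweighted) averages. Empty denominators
yield 0 with a warning flag rather than NaN.

## Grad-CAM

Channel weights are the spatial means of the class-logit gradient at the
final stage output (the last convolutional map before GAP); the map is the
rectified weighted channel sum, bilinearly upsampled to the input size and
max-normalised (all-zero maps are preserved). For a GAP + linear head this
reduces to the classical class-activation map; the implementation
backpropagates through the head generically, so it remains correct for any
head shape. The tap layer is the final stage by default and is the tested
object; overlay rendering (jet colormap, alpha 0.4) is a CLI artifact only.

## Synthetic phantoms

Real FLAIR MRI of the four target conditions cannot be redistributed, so
fixtures are procedurally generated 224×224 head phantoms with
class-specific signatures: control (smooth ellipse, bright rim, small dark
ventricles), MS-like (3–9 bright periventricular foci, radius 3.5–7 px,
contrast +0.45), AD-like (ventricles enlarged ×1.6–2.0, rim thinned and
dimmed), CI-like (2–5 diffuse low-contrast deep patches, radius 9–16 px,
contrast +0.16), plus Gaussian smoothing and additive noise (sd 0.03).
The lesion contrasts were chosen once so that the classes are separable by
design — a z-scored intensity-histogram nearest-centroid probe clears 70%
on default settings — because every downstream statistical claim needs
separable inputs to be testable. Intensities are quantised to the 8-bit
grid at generation time so the PNG round trip is lossless. Each image is
drawn from its own (seed, class, index) RNG stream, so growing a dataset
never reshuffles existing images; the train/test split uses a dedicated
sub-seed. An optional flag reproduces a clinically realistic class
imbalance (ratios 900 : 302 : 897 : 1027).

What the phantoms do **not** emulate: anatomy (gyri, tissue interfaces,
partial-volume effects), scanner artifacts, inter-subject variability, or
the actual radiological appearance of any disease. Passing tests therefore
demonstrate that the pipeline's machinery is correct and that it can
recover designed class structure — not that it classifies clinical MRI.

## Desk-scale evaluation sizes

The end-to-end statistical check trains a reduced-width variant (depths
[1, 1, 1, 1], widths [8, 16, 32, 64], input 64, 15 epochs) on 40 phantoms
per class and requires ten-fold CV accuracy of the selected-100-feature
SVM to exceed twice the 25% four-class chance level. Input 64 rather than
32 is a structural requirement, not a tuning choice: at input 32 the final
stage map collapses to 1×1, GAP degenerates to the identity and patch
features lose all spatial pooling (observed CV accuracy 52% vs 86% at
input 64). Any reduced variant should keep the final map at 2×2 or larger.

## Known limitations

* The NumPy engine is CPU-only and practical at reduced widths; training
  the full-width default network is supported but slow.
* NCA cost is quadratic in sample count; the subsample threshold bounds it.
* The sweep re-fits the classifier for every k; for wide ranges prefer a
  cheap classifier configuration.
* BN statistics make extracted features depend (slightly) on the training
  history; extraction itself is deterministic in eval mode.
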