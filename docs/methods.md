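# Methods

## Network

The segmentation network is a 2D encoder/decoder U-Net applied per axial
slice, with two attention operators. All convolutions use zero same-padding
and stride 1, so the printed shape schedule holds exactly; no normalization
layers are used in the reference configuration. Input sizes must be
divisible by 2^(depth−1) = 16.

**Encoder.** Five levels; level k applies two 3×3 convolutions + ReLU at
width `base_channels · 2^k` and (for the first four levels) 2×2 max
pooling. With the default 256×256×1 input and base width 32 the pre-pool
outputs are 256×256×32, 128×128×64, 64×64×128, 32×32×256, and the fifth
level yields the 16×16×512 bottleneck.

**Spatial attention.** Channel-wise max- and average-pooling of the
bottleneck give two H×W descriptors; concatenated (H×W×2) they pass
through a single k×k convolution and sigmoid to a gate in (0,1)^{H×W},
which multiplies the bottleneck features. The kernel is configurable over
{1,3,5,7} with default 3 — a single kernel, not a parallel multi-kernel
bank; the parameter accounting below supports this reading.

**Decoder.** Four levels of 2×2 stride-2 transposed convolution (halving
width), concatenation with the matching encoder skip, then dual 3×3
convolutions + ReLU, recovering 256×256×32. An alternative
nearest-neighbour-upsample + 3×3 convolution path is selectable
(`upsample_mode="interp_plus_conv"`). Upsample→concatenate→convolve is the
canonical ordering and the one whose shape accounting is consistent; it is
the one implemented.

**Inter-slice attention.** The decoder features of slices i−1 and i+1 pass
through the same pooling/conv(3×3)/sigmoid operator as SA (its own weights,
shared between the two neighbours — symmetric by construction), producing
masks M₋, M₊; the fused map is curr ⊙ M₋ + curr ⊙ M₊ and feeds the 1×1
convolution + sigmoid head. The head is shared with the ISA-disabled path,
so ISA adds exactly the 19 parameters of its attention convolution. At
volume boundaries the missing neighbour is the current slice
(`replicate`, default) or a zero feature map (`zero`).

**Parameter accounting.** Conv layer = k·k·C_in·C_out + C_out. Totals:
encoder 4,711,648; decoder 3,047,840; head 33; SA 19; ISA 19 — 7,759,559
(7.76 M) for the reference configuration. The ablation variants order as
U-Net < U-Net+SA ≤ full and U-Net < U-Net+ISA ≤ full, and disabling both
modules reproduces the plain U-Net bit-for-bit under a shared seed because
shared layers are initialized first from the seeded generator.

**Initialization and determinism.** He-uniform conv weights
(bound √(6/fan_in)), zero biases, from `numpy.random.default_rng(seed)`.
All forward/backward computation is plain numpy, so runs are deterministic
for a given seed, input, and configuration. Emitted probabilities are
clipped to [1e−7, 1−1e−7] so the open-interval contract survives float32
sigmoid saturation.

**Autodiff.** A minimal tape-based reverse-mode engine over numpy arrays
(`hippseg.nn.autodiff`): im2col convolution, einsum transposed convolution,
argmax-routed max-pool gradients, broadcast-aware multiply/add, channel
max/mean reductions, and logit-space binary cross-entropy
(softplus form) for numerical stability. Gradients are verified against
central differences to 1e−7 in the test suite. Max-pool ties route the
gradient to the first argmax.

## Preprocessing

Per-slice min–max normalization to [0,1] (constant slices map to zero);
centred zero-padding onto the model canvas with recorded offsets so
crop-back is an exact inverse; CLAHE (scikit-image implementation;
`clip_limit` keeps the conventional OpenCV scale, default 2.0 with 8×8
tiles, converted internally to the normalized clip fraction); Gaussian
denoising (σ = 1 px default, `mode="nearest"`); random horizontal/vertical
flips, each with probability 0.5, applied identically to image, mask, and
— during inter-slice training — the neighbouring slices. Masks pass only
through geometric operations and stay exactly binary end-to-end. CLAHE and
denoising are off by default in training and independently switchable,
since which enhancement stages belong to the protocol is ambiguous;
augmentation applies at training time only.

## Metrics and statistics

Accuracy, precision, recall, F1, Dice, and IoU all derive from pixel-wise
TP/FP/TN/FN counts. From a single count table F1 and Dice are the same
formula; they diverge only under different aggregation, so both `micro`
(pool counts, then compute) and `per_slice_mean` (compute per slice, then
average) are provided. The primary aggregation is per-subject micro counts
with subject-level averaging, matching the paired-by-subject statistics.
Degenerate slices (empty truth and empty prediction) score 1.0 by default
(configurable). The Dice–Jaccard identity dice = 2·iou/(1+iou) holds to
1e−12 on every micro report.

Paired two-sided t-tests (scipy `ttest_rel`) compare per-subject Dice/IoU
between models at α = 0.05; identical lists return (t=0, p=1) and
zero-variance nonzero differences raise an explicit degenerate-test error.
Confidence intervals use the t distribution. k-fold splits (default k=5)
partition subjects — never slices — with a seeded shuffle and fold sizes
differing by at most one. No multiple-testing correction is applied; the
harness reports raw p-values.

## Training protocol

Adam (lr 0.001, framework-default moments), batch size 4, binary
cross-entropy on logits, up to 200 epochs. Early stopping monitors
validation loss with patience 20 (default); the returned weights are the
best-validation-loss checkpoint, never a later epoch.
Learning-rate scheduling is reduce-on-plateau (factor 0.5, patience 10,
floor 1e−5). When only a train/test split exists, a seeded 10% of training
subjects (at least one) is held out for early stopping. Per-subject slice
sampling takes every labelled slice plus an equal number of empty-mask
slices (seeded, configurable) to counter the extreme class imbalance.
When ISA is enabled, each training sample forwards its two neighbouring
slices through the shared encoder/decoder so gradients flow through the
attention masks; this triples the per-sample cost.

## Phantom generator

Each subject: a smooth tissue texture (Gaussian-filtered noise, σ = 6 px,
around intensity 0.35), a bright crescent (+0.35) present only in a
central labelled band, a fixed low-frequency multiplicative bias field
(amplitude 0.10, random orientation/phase per subject — a generic stand-in
for coil inhomogeneity, not a scanner model), and additive Gaussian noise
(σ = 0.03) clipped to [0,1]. The crescent is the set difference of two
equal discs offset by the thickness; centre and orientation drift per
slice with step norm ≤ `drift_per_slice` (default 1 px), keeping adjacent
masks at Dice ≥ 0.7 so inter-slice attention sees real signal. Masks are
the exact analytic supports — noise never touches labels. Defaults mirror
a cross-sectional cohort layout (189 slices/subject, 30-slice labelled
band, 192×160 slices, foreground a few percent of each labelled slice).

The standard desk-scale benchmark is 20 subjects × 12 slices at 64×64
(band 6, radius 10–13 px, seed 7) with a 15/5 subject split and a width-8
model — sizes chosen so the full train/evaluate cycle runs in minutes on
one CPU core. What passing shows: the complete pipeline learns a small,
drifting, concave bright structure under noise and bias to Dice ≥ 0.85 on
held-out subjects. What it does not show: performance on real MRI — the
phantom lacks anatomy, partial-volume boundaries, scanner variability, and
ambiguous neighbouring structures, and its contrast is far cleaner than
hippocampal grey matter.

## Design choices where the design was open

- Decoder ordering: upsample → concatenate skip → dual conv (the standard
  scheme; the alternative conv-before-concat breaks shape accounting).
- Skip fusion by concatenation, not addition.
- ISA placed after the decoder, before the (shared) segmentation head.
- Binarization threshold 0.5 with strict inequality (p > t).
- Boundary slices replicate their single neighbour by default.
- Degenerate empty/empty slices count as perfect (1.0), configurable.

## Known limitations

- CPU-only numpy execution: full-resolution 256×256 training at width 32
  is impractical here; the reference configuration is exercised at full
  size for shape/parameter contracts and trained at reduced size/width.
- Single-structure binary segmentation only; no subfield labels, no 3D
  convolutions, no Hausdorff/surface-distance metrics.
- The PNG writer quantizes images to 16 bits (masks are exact); NIfTI
  round-trips are bit-exact at float32.
- CLAHE differs in implementation detail from OpenCV's (tile interpolation
  and histogram handling), though both are contrast-limited adaptive
  equalization.
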