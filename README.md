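# hippseg

Dual-attention U-Net for hippocampus segmentation in axial brain MRI.

The hippocampus is a small, crescent-shaped medial-temporal-lobe structure
whose atrophy is an early Alzheimer's biomarker; delineating it on
T1-weighted MRI is hard because it occupies only a few percent of each
slice and its boundaries are ambiguous. `hippseg` implements a 2.5D
segmentation network for this task, together with the preprocessing
pipeline, confusion-matrix evaluation metrics, a statistical validation
harness, and a synthetic phantom generator so the whole system is testable
end-to-end with no external data.

## The model

The backbone is a five-level U-Net on 256×256×1 slices: each encoder level
applies dual 3×3 convolutions (ReLU) followed by 2×2 max pooling, with
widths 32, 64, 128, 256, 512 (feature maps 256×256×32 down to the 16×16×512
bottleneck); the decoder mirrors it with 2×2 transposed convolutions, skip
concatenation, and dual 3×3 convolutions back to 256×256×32, ending in a
1×1 convolution + sigmoid head. Two attention operators extend it:

- **Spatial attention (SA)** at the bottleneck. Channel-wise max- and
  average-pooling give two 16×16 descriptors; their concatenation passes
  through one k×k convolution (k ∈ {1,3,5,7}, default 3) and a sigmoid,
  producing a gate A ∈ (0,1)^{16×16} that multiplies the bottleneck
  features: F′ = F ⊙ A.
- **Inter-slice attention (ISA)** at the decoder output. For slice *i* the
  same pooling/conv/sigmoid operator (separate weights, shared between the
  two neighbours) turns the decoder features of slices *i−1* and *i+1* into
  masks M₋ and M₊, and the head consumes
  F′ᵢ = Fᵢ ⊙ M₋ + Fᵢ ⊙ M₊.

Disabling both flags gives the plain U-Net, so the four ablation variants
(U-Net, +SA, +ISA, full model) are one configuration apart and share
identical weights for the common layers under a shared seed. The reference
configuration totals 7,759,559 ≈ 7.76 M trainable parameters.

Training follows the protocol the evaluation targets: Adam at learning rate
0.001, batch size 4, binary cross-entropy, up to 200 epochs with early
stopping on validation loss and reduce-on-plateau scheduling. Evaluation
uses pixel-wise TP/FP/TN/FN counts (accuracy, precision, recall, F1, Dice,
IoU), paired t-tests at α = 0.05 on per-subject scores, 95% confidence
intervals, and subject-level 5-fold cross-validation splits.

The network and its backpropagation are implemented directly over numpy
(`hippseg.nn`): im2col convolutions, 2×2 transposed convolutions, max
pooling, and a tape-based reverse-mode autodiff, gradient-checked against
numerical differentiation in the test suite.

## Worked example

Per-layer parameter accounting of the reference model:

```text
$ hippseg params
enc0_conv1_w  (32, 1, 3, 3)                   288
enc0_conv1_b  (32,)                            32
enc0_conv2_w  (32, 32, 3, 3)                9,216
...
sa_b          (1,)                              1
isa_w         (1, 2, 3, 3)                     18
isa_b         (1,)                              1
total                                   7,759,559  (7.76 M)
```

Training the full model on the built-in phantom benchmark (20 subjects ×
12 slices at 64×64, drifting crescent foregrounds, narrow model width 8
for CPU speed), evaluating on 5 held-out subjects:

```python
import numpy as np
from hippseg import (CSDAUNet, ModelConfig, TrainConfig, evaluate,
                     fixture_volumes, split_train_val, train)

vols = fixture_volumes()
cfg = ModelConfig(input_height=64, input_width=64, base_channels=8, seed=0)
tc = TrainConfig(seed=0, max_epochs=30, early_stop_patience=30)
tr, val = split_train_val(vols[:15], tc)
weights, log = train(cfg, tr, val, tc)
model = CSDAUNet(cfg); model.load_state_dict(weights)
report, per_subject = evaluate(model, vols[15:], tc)
print("val dice by epoch:", [round(d, 3) for d in log.val_dice[9:13]])
print("held-out dice %.4f  iou %.4f" % (report.dice, report.iou))
```

which prints (about four minutes on one CPU core):

```text
val dice by epoch: [0.571, 0.857, 0.966, 0.993]
held-out dice 0.9995  iou 0.9990
```

The validation Dice climbs from zero (the network first learns the
background prior, then the structure) and the held-out-subject Dice ends
near 1.0 — the phantom task is intentionally learnable, so the number
demonstrates that the full pipeline (generation, conditioning, attention
forward/backward, early stopping, subject-level evaluation) works; it says
nothing about performance on real MRI. The same run via the CLI:
`hippseg simulate … && hippseg train … && hippseg evaluate …`, and
`hippseg ablate` trains all four attention variants and writes the metric
and paired-test tables.

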