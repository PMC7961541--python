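# Methods

## Problem and model

`coralseg` performs binary semantic segmentation — coral vs. background —
on single-channel grayscale images, the form in which both spectral-imager
bands and individual R/G/B channels of underwater photographs arrive. The
network is an encoder-decoder:

* **Backbone.** ResNet34 with its last residual stage pruned: a 7×7
  stride-2 convolution with batch normalisation and ReLU, a 3×3 stride-2
  max pool (the *low-level* feature tap at stride 4), then three stages of
  [3, 4, 6] basic residual blocks (`y = F(x) + x`, with a 1×1 projection
  shortcut when shape changes) at widths [64, 128, 256]. The residual
  branches contain 2·(3+4+6) = 26 convolutions — this census counts the
  two 3×3 convolutions per basic block and excludes the stem and the
  projection shortcuts, the only convention that yields 26 for a pruned
  ResNet34. The high-level output sits at stride 16 with 256 channels.
* **ASPP.** Four parallel dilated 3×3 convolutions at rates {1, 6, 12, 18}
  (rate 1 realised as a 1×1), each with batch norm + ReLU, plus a
  global-average-pooling branch (1×1 convolution + ReLU, broadcast back to
  the grid by bilinear interpolation, which is an exact constant fill from
  a 1×1 source). Branches are concatenated and reduced to 256 channels by
  a 1×1 convolution. The pooled branch intentionally skips batch
  normalisation: batch statistics over a 1×1 spatial extent are degenerate
  at the small batch sizes this package trains with.
* **Low-level path.** 1×1 reduction of the stride-4 stem features to 32
  channels, then space-to-depth with block size 4, aligning them with the
  stride-16 ASPP output at 512 channels.
* **Decoder.** Channel concatenation, two 7×7 "large-kernel" fusion
  convolutions at 256 channels (batch norm + ReLU), a 1×1 prediction
  convolution to 2·4² = 32 channels, depth-to-space back to stride 4, and
  bilinear ×4 interpolation to input resolution: 2×H×W class scores.
  Predicted masks are the per-pixel argmax with ties broken toward
  background.

Space-to-depth/depth-to-space use one fixed convention — the r×r offsets
of each block read row-major and fill the channel axis fastest, i.e.
input channel c, offset (i, j) → output channel c·r² + i·r + j — so the
two ops are exact mutual inverses (tested as a bijection preserving the
value multiset).

The dilation rates, the 32-channel low-level reduction, and the 7×7
fusion kernel are configurable: they follow the DeepLab/DeeperLab family
conventions rather than being uniquely determined by the architecture
description, which leaves them open.

All widths scale by a single `width` multiplier. `ModelConfig.desk()`
(width ¼, low-level reduction 8) is the configuration used throughout the
test suite; the architecture is size-agnostic for any side divisible
by 16, so the same code runs 512×512 at full width.

## Numerical core

No deep-learning framework is used: the package carries a small
reverse-mode automatic-differentiation engine on numpy arrays
(`coralseg.nn`). Convolution is im2col + GEMM with a cached
scatter-index/`bincount` adjoint; bilinear resampling is expressed as a
pair of per-axis interpolation matrices (half-pixel-centre convention)
so its adjoint is exact; max pooling records argmax positions; batch
normalisation implements the standard training-mode backward pass and
running statistics (momentum 0.1) for evaluation. Every op is validated
against scalar-loop oracles and central finite differences in the test
suite. Parameters are float32; Adam moments are float64.

## Training procedure

Two phases:

1. **Backbone pre-training** (`CoralPresenceClassifier`): backbone +
   global average pooling + linear 2-class head, trained on image-level
   coral-present labels.
2. **Segmentation training** (`CoralSegmenter`): the full network with
   per-pixel softmax cross-entropy `H(y_gt, y_p) = −Σ y_gt · log y_p`,
   optionally warm-started from the pre-trained backbone.

Shared settings (full-scale defaults): Adam (β₁ = 0.9, β₂ = 0.999,
ε = 1e-8) at initial rate v₀ = 1e-4 with exponential per-epoch decay
v(j) = α^j · v₀, α = 0.99, j starting at 0 so epoch 0 uses exactly v₀;
pre-training 200 epochs at batch 32, segmentation 150 epochs at batch 16;
90/10 train/validation split; training-split-only augmentation in which
rotation (angle uniform on [0°, 180°], counter-clockwise about the
centre, zero fill), horizontal flip and vertical flip each fire
independently with probability 0.5 (draw order: rotate?, angle — drawn
only when rotation fires —, hflip?, vflip?, one seeded stream per run,
so augmentation is replayable). Masks are resampled nearest-neighbour
and stay binary.

The loss sum is normalised (mean over pixels, then batch) so values are
comparable across image sizes; a `reduction="sum"` switch exposes the
unnormalised form. No weight decay, no early stopping, no class
weighting. Batches are reshuffled each epoch from the run seed and the
last partial batch is kept. With a fixed seed two runs produce
bit-identical loss curves and parameters.

Desk-scale runs in the tests use v₀ = 1e-3: with quarter-width models
and tens of images the full-scale 1e-4 converges needlessly slowly;
the schedule form and α are unchanged.

## Metrics

Per image: precision TP/(TP+FP), recall TP/(TP+FN), F1 the harmonic
mean, and mean IoU averaged over the two actual classes (background and
coral), skipping a class absent from both masks. The printed formula in
the source material normalises by 1/(c+1) with c = 2, which would
average over three classes for a binary task; averaging over the two
actual classes is the convention consistent with the reported score
scale, and is what this package implements. Degenerate denominators
yield `nan` — an explicit undefined marker excluded from dataset
aggregates, so negative images with empty predictions do not distort
means. Dataset aggregation is macro (per-image mean and population
standard deviation); a pixel-pooled micro aggregate can be assembled
from the exposed confusion counts if needed.

## Class-activation mapping

The CAM head taps the fused 256-channel decoder features before the
prediction head — the highest-resolution semantically rich map; the tap
is a configuration choice. A 1×1 convolution produces the non-coral and
coral response maps N0, N1; global average pooling gives
G_j = (1/(h·w))·Σ N_j; a 2×2 linear map of (G0, G1) gives the image-level
class scores, trained with cross-entropy against the image-level labels
while the segmenter stays frozen. The coral row of that linear map
supplies the scalar weights (w0, w1) of the activation map
CAM = w0·N0 + w1·N1, which is exactly the spatial decomposition of the
coral score (GAP commutes with the weighted combination). A
scalar-per-class variant (diagonal weights) was considered and rejected:
under a 2-way softmax only score differences matter, so its learned
signs are indeterminate and the combined map does not reliably highlight
coral. The raw map is bilinearly upsampled to input resolution and
min-max normalised to [0, 100] %; a constant raw map maps to all zeros
by convention. Normalisation is invariant to positive affine transforms
of the raw map and attains exactly 0 and 100 on any non-constant map.

## Synthetic scenes

The generator stands in for the real coral dataset so everything trains
and tests at desk scale without downloads. Positives place 1–4 random
rotated ellipses (semi-axes 0.4–1.0 × 0.22 × side, ≥ 2 px) whose union
is the mask, with intensity offset +0.4 over a Gaussian background
(level 0.25, σ = 0.08) and a low-frequency sinusoidal texture
(amplitude 0.06) inside the coral; negatives are background only. An
optional vertical illumination ramp mimics the unevenly lit spectral
frames. The positive fraction defaults to 2672/4131 ≈ 0.647, the coral
share of the emulated dataset. Sample i draws from
`default_rng([seed, i])`, so datasets rebuild bit-identically from
their JSON descriptor. The default contrast-to-noise ratio
(0.4/0.08 = 5, guaranteed ≥ 2 by construction) makes the foreground
separable by intensity — deliberately easy so that short CPU runs can
learn it.

What passing desk-scale tests shows: the architecture, gradients,
training loop, metrics and CAM machinery are correct end-to-end.
What it does not show: performance on real coral imagery, whose
foreground is not intensity-separable and whose textures, occlusions,
lighting and species variability the generator does not model. Full-dataset scores on real imagery are not reproducible at desk scale
and are not claimed.

## Problem sizes in the tests

The suite exercises: one full-width 512×512 forward pass (architecture
census); an 8-image overfit run (100 steps, training mean IoU ≥ 0.95);
a 64-train/16-validation run (20 epochs, held-out mean IoU ≥ 0.80); a
48-image CAM training run; and the CLI chain on 12 images. These sizes
keep the whole suite to a few minutes on one CPU while still executing
every phase of the pipeline.

## Known limitations

* Single-node, single-thread CPU training only; no GPU path.
* Binary segmentation only (`num_classes = 2` is assumed by the mask
  types and metrics).
* The preprocessing canonicalisation pads-then-scales; a centre-crop
  rule is not implemented (a crop rule would be a new,
  unconstrained choice).
* Batch-normalisation running statistics make evaluation-mode outputs
  depend on training history; very short runs can leave them noisy.
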