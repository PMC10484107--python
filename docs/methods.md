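# Methods

## Problem setting

A tray image contains many seeds on a dark, roughly uniform background.
The task has two stages: locate every seed (segmentation) and grade each
one as *good* or *defective* by visual appearance (classification).
Defective here means broken-kernel appearance — a missing piece of the
body or a blemished surface — the binary distinction a sorting machine
must act on.

## Segmentation model

The pipeline is the classic marker-controlled watershed recipe for
touching bright objects:

1. **Grayscale** via Rec. 601 luminance (0.299 R + 0.587 G + 0.114 B).
2. **Threshold** — Otsu's global threshold by default (the synthetic and
   tray images are strongly bimodal); an adaptive-Gaussian local
   threshold (block 51, offset +10 grey levels) is available for uneven
   illumination. Polarity is auto-corrected by taking the minority class
   as foreground. If the split is not genuinely bimodal (d′ between the
   two classes below 4) the image is treated as background-only and
   flagged rather than segmented into speckle.
3. **Hole filling** precedes any erosion: dark surface blemishes
   threshold out as interior holes and must be filled while the bright
   rim around them is still intact.
4. **Opening** (3×3, 2 iterations) removes white noise. Closing is
   available but disabled by default: closing fills the concave waist
   where two seeds touch and prevents the watershed from splitting them.
5. **Sure background** is the complement of the mask dilated 3×.
6. **Markers** are connected components of pixels whose Euclidean
   distance transform reaches 0.5× the maximum *of their own component*.
   Normalising per component rather than globally keeps small seeds from
   losing their marker next to large ones. The band between markers and
   sure background is the unknown region.
7. **Watershed** floods the negated distance transform from the markers,
   restricted to the cleaned foreground mask, with single-pixel watershed
   lines between adjacent regions. Restricting the flood makes the seed
   regions an exact partition of the binary body, so region areas are
   comparable to ground-truth mask areas.
8. **Crops** — one per surviving label (≥ 50 px by default), tight
   0-based half-open bounding boxes, sorted by (y0, x0).

All steps are scipy.ndimage / scikit-image primitives; every knob
(kernel, iterations, distance fraction, minimum area, threshold method)
sits in `SegmentationConfig`.

Touching seeds are split reliably when a distance-transform saddle
exists below the marker threshold — the case for roundish seeds
overlapping up to ~30% of a radius. Elongated ellipses meeting at a flat
side can merge into one basin; heavily adhering clusters are out of
scope.

## Classifier

`SeedClassifier` is a three-stage network of Inception-ResNet blocks in
which every 3×3 (and stacked-3×3-for-5×5) convolution is
depthwise-separable:

- **Stem**: ordinary 3×3 convolution, stride 2 (configurable), batch
  norm, ReLU.
- **Stage** = `modules_per_stage` blocks at constant width. Each block
  runs four parallel branches — 1×1; 1×1→3×3; 1×1→3×3→3×3 (a 5×5
  receptive field as two stacked 3×3); 3×3 average-pool→1×1 — concatenated
  on channels, added to the skip path (identity, or a 1×1 projection when
  widths differ), then ReLU. Every convolution is bias-free and followed
  by batch norm; there is no nonlinearity between the depthwise and
  pointwise halves of a separable convolution, so its trainable weight
  count is exactly `H·W·C + C·N`.
- **ECA gate** after each stage: global average pooling to one
  descriptor per channel, a shared 1-D convolution across channels of
  adaptive odd size `k` = nearest odd to `|log2(C)/γ + b/γ|` (γ=2, b=1,
  ties resolved downward, floor 1), sigmoid, and channel-wise
  multiplication. No dimensionality reduction; `k` weights per gate. The
  1-D kernel starts as a centred delta, so the initial gate of each
  channel depends on that channel alone.
- **Feature fusion**: the gated output of each stage is globally
  average-pooled; the three pooled vectors are concatenated (length =
  sum of stage widths) and fed to a single dense softmax head. With
  fusion disabled only the last stage's vector is used.
- Stride-2 separable convolutions sit between stages.

Defaults: input 128×128 RGB in [0,1], stages (2×32, 2×64, 2×128), branch
widths equal quarters of the stage width, He-uniform initialisation,
zero head bias, all weights drawn from a generator seeded by the model
config.

`param_report` walks the built network and tabulates, per layer, the
actual trainable weights against the `H·W·C·N` standard-convolution
equivalent, with batch-norm running statistics as the non-trainable
column; the totals are cross-checked against the engine's own weight
enumeration in the tests.

### The NumPy engine

The layers live in `seedqc.nn`: im2col convolutions (rectangular kernels
supported), depthwise convolution, batch norm with running statistics,
ReLU, average/global pooling, dense, ECA, softmax cross-entropy, Adam and
SGD. Every backward pass is hand-derived and verified against central
differences in the test suite. Arrays are float32 NCHW; forward passes
reduce to BLAS matmuls, so the desk-scale models train in tens of
seconds on one CPU.

## Training and evaluation

Training follows a fixed-epoch regime: Adam (β₁=0.9, β₂=0.999), batch
size 32, learning rate 0.001, 100 epochs by default, cross-entropy loss,
no augmentation (optional horizontal/vertical flips exist behind a
flag), no early stopping by default. An optional `stop_accuracy` ends
training at the first epoch whose held-out accuracy reaches a level —
the epoch budget is always the upper bound — which the tests use to
avoid paying full budgets after convergence. History records per-epoch
mean loss and test accuracy. Data order, flips and initialisation all
derive from explicit integer seeds, so runs are bit-reproducible on a
fixed software stack.

Evaluation computes the confusion counts with *defective* as positive
(the operationally costly class to miss) and reports accuracy,
precision, recall and F1 as percentages. Zero-denominator ratios are
reported as 0 with a logged warning rather than NaN. The arithmetic is
checked against scikit-learn on random confusion tuples to 1e-9.

## Detection

`detect` segments a scene, classifies every crop (expanded by the same
4 px margin the training crops carry, padded to square, bilinear-resized
to the model input), and emits one detection per crop — tight bbox,
class, softmax confidence — sorted by position, plus an annotated
overlay. `batch_detect` scores a directory against ground-truth JSON by
greedy IoU matching (threshold 0.5): matched pairs contribute their
(true, predicted) outcome; a missed defective seed counts as FN, a
missed good seed as FP, a spurious detection as FP. Per-image timing is
logged but is not a claim — it is hardware-dependent.

## Synthetic scenes

The generator emulates a seed-tray imaging rig: uniform dark background
(grey 30), additive Gaussian sensor noise (σ=4), and elliptical kernels
(semi-axes 10–22 px in 512×512 scenes, aspect ≤ 2:1) with a yellowish
tint, centre-to-edge shading and speckle texture. Placement is rejection
sampling with a 1000-attempt cap (failure raises `PlacementError`);
centre separation enforces a boundary clearance of `min_separation`
pixels, negative values permitting touching pairs. Per-scene RNG streams
derive from (seed, scene index), so scenes are independently
reproducible.

Defects (exactly `round(n_seeds × defect_fraction)` seeds per scene):

- **Fracture bite**: a circular bite at a kernel tip (within ~30° of the
  major axis) removing ≥ 12% of the body, with the exposed face painted
  pale and desaturated — broken maize kernels expose starchy endosperm,
  and the bright fracture face plus the truncated silhouette is what
  separates broken from intact kernels visually. Tip placement keeps the
  distance-transform ridge of the body in one piece, so a bitten seed
  does not masquerade as a touching pair.
- **Dark blemish**: a surface patch at 0.35–0.5× body intensity covering
  ≥ 10% of the body, restricted to pixels ≥ 6 px inside the (post-bite)
  body so an unbroken bright rim always encloses it and thresholding
  sees an interior hole, never a split seed.
- Or both.

What the generator does **not** model: photorealistic kernel texture,
illumination gradients, shadows, camera optics, multispectral channels,
or heavy adhesion of many seeds. Tests passing on these fixtures
demonstrate that the pipeline's geometry, bookkeeping and learning
behave as specified — not that the classifier's accuracy transfers to
any particular camera or cultivar.

The touching-pair fixture draws near-circular bodies (axis ratio
≥ 0.85): round seeds overlapping by 20% of a radius always leave a clear
distance saddle, which is the configuration the watershed stage is meant
to split (arbitrary-orientation ellipse pairs may genuinely share one
basin).

## Problem sizes in the tests and acceptance script

Chosen so the full suite and the acceptance run each complete in a few
minutes on one CPU: 512×512 scenes with 1–20 seeds; 50 scenes for
segmentation recovery and 20 touching pairs; classifier checks on a
reduced model (1 module per stage, widths 16/32/64, 64×64 crops) trained
on 800 balanced crops over three seeds with a 15-epoch cap; the
end-to-end run trains on crops from 40 scenes (4:1 split) and validates
on 10 held-out 10-seed scenes. The full-size default model (2 modules
per stage, widths 32/64/128, 128×128 input) uses the same code paths.

## Numerical and design notes

- Coordinates are 0-based, half-open everywhere; bounding boxes clip to
  image bounds.
- Marker labels: 0 unknown/watershed line, 1 background, ≥ 2 seeds.
- `round(n × f)` for defect counts is round-half-up.
- Otsu on inverted images can differ by 1–2 boundary pixels from the
  non-inverted result (256-bin histogram edges are not exactly mirrored);
  the polarity-correction test asserts ≥ 99.9% pixel agreement.
- Batch-norm running statistics use momentum 0.9; evaluation always uses
  running statistics, training always uses batch statistics.
- The F1 percentage is computed from P and R as fractions
  (`2PR/(P+R)·100`), equal to the harmonic mean of the printed
  percentages.
- The ECA rule yields k=3 for C=64 (|3.5| → 3) and k=5 for C=256
  (|4.5| → 5); the tie at integer odd midpoints resolves downward.
- Checkpoints are a `.npz` of weights in parameter order plus a JSON
  sidecar with the model config and class names and a CSV parameter
  report; loading rebuilds the architecture from the sidecar and
  restores weights by position.

## Known limitations

- Heavily adhering seed clusters (three or more seeds sharing one blob,
  or flat-side contact of elongated seeds) may not be split.
- The classifier is trained and validated on synthetic appearances; real
  deployments need retraining on camera data.
- Softmax confidences are uncalibrated; values near 1.0 reflect
  saturation, not calibrated probability.
- Wall-clock timings are logged for orientation only.
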