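# Methods

## Problem and model

`sowfast` classifies short single-animal video clips into five pig
behaviors — feeding, lying, motoring (walking/running/jumping),
scratching (rubbing against pen fixtures) and mounting — from the
spatiotemporal content of the clip alone, with no reliance on where in
the pen the animal is. The classifier is a dual-pathway 3-D
convolutional network in the SlowFast family with a two-layer
(basic-block) residual backbone:

* The **slow pathway** samples 8 frames from a 64-frame window
  (temporal stride 8) and carries the bulk of the channel capacity
  (64 stem channels; 128/256/512/1024 per residual stage at depth 34).
* The **fast pathway** samples 32 frames (stride 2) at 1/8 of the slow
  channel width at every stage (β = 1/8); its stem uses a 5-frame
  temporal kernel so high-frequency motion such as scratching is
  visible to the first layer.
* Neither pathway downsamples time; all temporal extents survive to the
  classifier. Spatial downsampling (stride 1×2×2) sits in the stem, the
  pool, and the entry block of res3–res5, giving
  224 → 112 → 56 → 56 → 28 → 14 → 7.
* In every residual block the second convolution is spatial-only
  (1×3×3). The first convolution is spatial-only in the slow res2/res3
  stages and 3×3×3 elsewhere (both pathways' res4/res5, all fast
  stages): temporal mixing in the wide pathway is reserved for the
  deepest, most abstract stages.
* **Lateral connections** after res2, res3 and res4 transform fast
  features with a 5×1×1 convolution, temporal stride 4, and 2× the fast
  channel count, which aligns the fast temporal length (32) to the slow
  one (8), then fuse them into the slow pathway.
* Both pathways are globally average-pooled, concatenated
  (1024 + 128 features at depth 34), passed through dropout 0.5 and a
  single fully connected softmax classifier.

Variants: depth 34 (blocks 3,4,6,3) at full or half channel width, and
depth 18 (blocks 2,2,2,2) at full width. Halving the widths quarters
the parameter count because the fast pathway scales with the fixed 1/8
ratio.

## Design choices where the design was open

* **Lateral fusion is concatenation by default.** The prose description
  of the fusion step says "addition", but the stated transform (2× the
  fast channel count) cannot match the slow width, so addition is not
  dimensionally possible as stated. Concatenation — the original
  SlowFast convention — reproduces the published parameter totals of
  all three variants to within 0.05% (165.44/41.40/86.00 M vs
  165.46/41.41/86.03 M), so concatenation is what the reference
  implementation must have used and is our default. A `project_sum`
  mode (project to the slow width with a 1×1×1 convolution, then add)
  is available on `ArchSpec.fusion` for the literal reading; it lands
  about 3% below the published totals.
* **Residual convention.** Post-activation blocks (conv→BN→ReLU),
  projection shortcut (1×1×1 conv + BN) exactly when the block changes
  channels or stride. Convolutions carry no bias (BN supplies the
  shift); the classifier carries one. These choices move the parameter
  count by well under 0.1%.
* **Parameter totals** include BN scale/shift and the classifier bias.
  Under this accounting the three variants match the published totals
  to 0.03%, which is how the "Mb" column was read as millions of
  parameters.
* **Training resize.** Only the crop size (224) is prescribed for
  training; we scale the shorter side to 240 first, matching the test
  protocol's scale, so train and test operate at the same object scale.
  A frame that already equals the crop size is used as-is.
* **Short clips are loop-padded** (window indices wrap modulo the clip
  length) rather than zero-padded, preserving the motion statistics of
  periodic behaviors; the same rule applies to the 10 test windows.
* **Warm-up.** The recipe says only that warm-up "was utilized"; we use
  a linear ramp from 0.1·η over the first 34 epochs' worth of
  iterations (≈11% of a 300-epoch schedule). Desk-scale runs keep the
  same proportion (3 of 30 epochs). An "iteration" in the cosine
  schedule is one mini-batch step.
* **Input scaling:** pixels to [0,1], then (x − 0.45)/0.225 per
  channel, the SlowFast convention; constants live in `TrainConfig`.
* **Ties** in any argmax resolve toward the lowest class index in the
  fixed vocabulary (feeding, lying, motoring, scratching, mounting).
* **Views accuracy** counts each of the 30 views' own argmax against
  the ground truth; per-sample top-1 uses the mean of the 30 softmax
  vectors. The per-class rate is the row-normalized confusion diagonal
  (a recall, although the source table labels it "precision"); rows
  with no samples report NaN.

## NumPy compute engine

The network, including backpropagation, runs on a small NumPy layer
library (`sowfast.nn`): im2col convolutions lowered to BLAS matrix
products, batch normalization with running statistics, spatial max
pooling, inverted dropout, momentum SGD. Every backward pass is tested
against central finite differences in float64, and the convolution
forward against a `scipy.ndimage` correlation oracle. First-layer
convolutions skip the input-gradient scatter (`input_grad=False`),
which roughly halves step time. Batch statistics are per-batch on a
single device (the degenerate case of synchronized BN). Forward passes
in evaluation mode are bitwise deterministic; training runs are exactly
reproducible given `TrainConfig.seed`, which seeds initialization, data
order, window/crop draws and dropout through independent
`SeedSequence` streams.

## Synthetic behavior clips

The behavior footage this model was designed for is not publicly
deposited, so the package ships a procedural generator whose five
classes carry the same kind of spatiotemporal signatures that
distinguish the behaviors, over the same clip geometry (25 fps, 64
frames by default; 64×64 px fixtures, configurable up to the source's
320×240):

| class      | motion kind       | default kinematics (64-px scale)         |
|------------|-------------------|------------------------------------------|
| feeding    | local oscillation | head region bobbing, 0.0625 cyc/frame, 1.5 px amplitude |
| lying      | static            | nothing moves                            |
| motoring   | translation       | whole body, 0.55 px/frame                |
| scratching | local oscillation | region beside a static fixture bar, 0.25 cyc/frame, 4 px |
| mounting   | overlap event     | second animal approaches at 0.45 px/frame and rests overlapping the first |

Objects are soft-edged ellipses on a fixed hatch-textured background;
per-clip intensities and geometry jitter are drawn from a seeded RNG so
no class is separable by brightness alone, and additive Gaussian pixel
noise (σ = 1.5 intensity units) is clipped to the 8-bit range.
Scratching oscillates strictly faster and wider than feeding — the
discriminative premise for the fast pathway — and mounting is the only
two-object class. The kinematic defaults were chosen so that two
hand-crafted features (log frame-difference energy and dominant
temporal frequency over motion pixels) separate the five classes with a
nearest-centroid rule, which the test suite verifies at ≥95% on 20
clips per class: the generator carries class signal independent of any
network.

What the generator does **not** emulate: photorealism, camera noise
structure, illumination changes, occlusion, multiple interacting
animals (beyond the mounting pair), background clutter, or intra-class
pose diversity. Results on synthetic clips therefore demonstrate that
the architecture, sampling protocol and optimization recipe can extract
spatiotemporal class signal end-to-end; they say nothing quantitative
about accuracy on real pig footage.

## Desk-scale problem sizes

Unit and acceptance tests run the full-fidelity architecture code at
reduced sizes chosen so the whole suite runs on one CPU: a reduced
variant with channel widths divided by 8, one block per stage,
16-frame windows (slow 2 / fast 8 frames) and 64-px crops. The
learnability check trains that variant for 30 epochs on 50 synthetic
clips per class (plus 10 validation and 20 held-out test clips per
class) with the published optimizer settings (η = 0.0125, batch 8,
momentum 0.9, weight decay 1e-4, dropout 0.5) and requires ≥90% top-1
on the held-out set under the full 30-view protocol. The published
same-pigsty accuracies themselves require the unpublished footage and
GPU-scale training; the package covers them only through the printed
confusion-matrix recomputation and the synthetic learnability check.

## Numerical details

* Convolution padding is (k−1)//2 per axis; output extents follow
  `floor((L + 2p − k)/s) + 1`. The shape table refuses inputs under
  32 px (the stride pyramid's total spatial factor).
* BN: eps 1e-5, momentum 0.1, unbiased running variance.
* Cross-entropy adds the dtype's tiny constant inside the log; a
  non-finite loss aborts training with a diagnostic.
* AVI I/O is an uncompressed RGB RIFF codec (bottom-up BGR DIB frames),
  lossless by construction; frame directories are PNG via imageio.
  Frame directories carry no rate metadata, so the reader takes a
  caller-supplied fps (default 25, the capture rate).
* Stratified splits allocate `floor(fraction·n)` rows per class per
  subset and hand remainders to subsets in declaration order; under a
  4:1:1 split this reproduces the published 789 → 529/130/130 sizes.
  The published 1000 → 211/789 first split has no stated ratio and is
  exposed as an arbitrary-size `random_split`.

## Known limitations

* No GPU path; full-size (224 px, 64-frame) training is impractical in
  this implementation — it exists for correctness, protocol fidelity
  and desk-scale experiments.
* The comparison backbones (C3D, MC4, rMC4, R(2+1)D, plain R3D,
  SlowFast-50) and Kinetics pretraining are out of scope.
* `read_clip` decodes only the package's own uncompressed AVI layout
  (plus image directories); compressed AVI streams require external
  transcoding.
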