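# sowfast

Dual-pathway spatiotemporal convolutional network for recognizing five
pig behaviors — **feeding, lying, motoring, scratching, mounting** —
from short single-animal video clips.

Daily behavior statistics reflect pig health: reduced feeding and
activity, longer lying times, or reduced grooming (scratching) flag
problems early, and mounting signals sexual maturity and injury risk.
Region-based detectors miss behaviors that do not move the animal, so
this package classifies the *motion itself*: a SlowFast-style network
whose **slow pathway** (8 sparse frames, wide channels) captures
spatial appearance while its **fast pathway** (32 dense frames, 1/8 of
the channels at every stage) captures fine temporal structure such as
the high-frequency rubbing of scratching. Time-strided lateral
connections after res2–res4 fuse fast features into the slow pathway;
both pathways are average-pooled, concatenated, and classified through
a single softmax layer. The backbone is a two-layer-block 3-D residual
network (depth 34: blocks 3,4,6,3; depth 18: 2,2,2,2) that never
downsamples time.

Training follows the published recipe: He fan-in initialization
(Var(w) = 2/n_l, zero biases), synchronized SGD with momentum 0.9,
weight decay 1e-4, dropout 0.5, batch 8, and a half-period cosine
schedule lr(n) = η·0.5·(cos(πn/n_max)+1) with η = 0.0125 and linear
warm-up. Inference averages softmax scores over 30 views per clip
(10 uniform temporal windows × 3 spatial 240-px crops).

Everything — including backpropagation through both pathways — runs on
a small, finite-difference-tested NumPy layer engine, so the package
has no deep-learning-framework dependency. Because the original
footage is not publicly deposited, a seeded synthetic-clip generator
provides five classes with the matching spatiotemporal signatures
(static scene; slow local oscillation; whole-body translation; fast
local oscillation against a fixture; two-body overlap event) so the
entire pipeline is testable end to end.

## Worked example

Generate a synthetic dataset, train the desk-scale reduced variant
(channel widths ÷8, one block per stage, 16-frame windows, 64-px
crops), and evaluate with the 30-view protocol:

```python
import sowfast as sf

scene = sf.SceneSpec()                      # 64x64 px, 64 frames, 25 fps
train_m = sf.generate_dataset(None, scene, 50, "data/train", seed=1)
val_m   = sf.generate_dataset(None, scene, 10, "data/val",   seed=1001)
test_m  = sf.generate_dataset(None, scene, 20, "data/test",  seed=2001)

sampling = sf.SamplingConfig(window_len=16, train_crop=64,
                             train_scale=64, test_scale=64)
net = sf.build_network(sf.reduced_arch_spec())
cfg = sf.TrainConfig(epochs=30, warmup_epochs=3.0, seed=1)
net, history = sf.train(net, train_m, val_m, cfg, sampling)
print(f"best val top-1 {history.best_val_top1:.2f} at epoch {history.best_epoch}")
print(sf.evaluate(net, test_m, sampling))
```

Output from this exact run (seed 1, about 7 minutes on one CPU):

```
best val top-1 1.00 at epoch 16
top-1 accuracy : 100.00%
views accuracy : 100.00%
confusion (rows = ground truth):
            feedin  lying motori scratc mounti
   feeding      20      0      0      0      0  100.00%
     lying       0     20      0      0      0  100.00%
  motoring       0      0     20      0      0  100.00%
scratching       0      0      0     20      0  100.00%
  mounting       0      0      0      0     20  100.00%
```

Top-1 accuracy scores each clip's view-averaged prediction; views
accuracy scores all 30×N individual views; the right-hand column is
the per-class rate (row-normalized confusion diagonal).

The full-size variants are available for accounting and inference
experiments:

```bash
sowfast count-params --variant pmb-scn-34    # 165.44 M parameters
sowfast shapes --variant pmb-scn-34          # per-stage output sizes
sowfast make-synth --n-per-class 10 --seed 0 --out data/demo
sowfast stats data/demo/manifest.csv
sowfast split data/demo/manifest.csv --fractions 4:1:1 --seed 0
```

## Layout

| module                | contents                                            |
|-----------------------|-----------------------------------------------------|
| `sowfast.video_io`    | AVI/frame-directory clips, manifests, stats, splits |
| `sowfast.synthetic`   | seeded five-class behavior clip generator           |
| `sowfast.sampling`    | 64-frame windows, slow/fast subsampling, crops, views |
| `sowfast.model`       | architecture specs, network builder, accounting     |
| `sowfast.trainer`     | init, cosine schedule, SGD training loop            |
| `sowfast.evaluator`   | 30-view aggregation, confusion-matrix metrics       |
| `sowfast.nn`          | NumPy layers with explicit forward/backward         |

See `docs/methods.md` for the model assumptions, design decisions and
the limits of what the synthetic experiments demonstrate.
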