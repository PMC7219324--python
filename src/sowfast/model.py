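"""Dual-pathway spatiotemporal residual network for behavior recognition.

The network follows the SlowFast two-stream design with a two-layer
(basic-block) 3-D residual backbone:

* a **slow pathway** over 8 sparsely sampled frames with wide channels,
* a **fast pathway** over 32 densely sampled frames with 1/8 of the
  slow channel width at every stage,
* **lateral connections** after res2, res3 and res4 that carry fast
  features into the slow pathway through a time-strided (5,1,1)/stride-4
  convolution with twice the fast channel count, concatenated onto the
  slow tensor (an optional ``project_sum`` mode projects to the slow
  width and adds instead),
* global average pooling of both pathways, concatenation, dropout and a
  single fully connected softmax classifier.

Neither pathway ever downsamples time; spatial downsampling (stride
1x2x2) happens at conv1, pool1 and at the entry block of res3..res5.
In every residual block the second convolution is spatial-only
(temporal extent 1); the first convolution is spatial-only in the slow
res2/res3 stages and spatiotemporal (temporal extent 3) everywhere else.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from . import nn
from .video_io import CLASS_NAMES

__all__ = [
    "StageSpec",
    "ArchSpec",
    "VARIANTS",
    "make_arch_spec",
    "reduced_arch_spec",
    "build_network",
    "Network",
    "stage_output_shapes",
    "count_parameters",
    "count_parameters_millions",
    "save_checkpoint",
    "load_checkpoint",
]

RES_STAGES = ("res2", "res3", "res4", "res5")
VARIANTS = ("pmb-scn-34", "pmb-scn-34half", "pmb-scn-18")

_BLOCKS = {"pmb-scn-34": (3, 4, 6, 3), "pmb-scn-34half": (3, 4, 6, 3),
           "pmb-scn-18": (2, 2, 2, 2)}
_SLOW_CHANNELS = {
    "pmb-scn-34": (128, 256, 512, 1024),
    "pmb-scn-18": (128, 256, 512, 1024),
    "pmb-scn-34half": (64, 128, 256, 512),
}


@dataclass(frozen=True)
class StageSpec:
    """One residual stage of one pathway."""

    name: str
    n_blocks: int
    layer1_kernel: tuple[int, int, int]
    layer2_kernel: tuple[int, int, int]
    channels: int
    spatial_stride: int  # stride of the first block (1 or 2)

    def __post_init__(self):
        if self.layer2_kernel[0] != 1:
            raise ValueError("layer2 must be a spatial-only convolution")
        if self.spatial_stride not in (1, 2):
            raise ValueError("spatial stride must be 1 or 2")


@dataclass(frozen=True)
class ArchSpec:
    """Declarative description of both pathways and their fusion."""

    variant: str
    slow_conv1_channels: int
    slow_stages: tuple[StageSpec, ...]
    fast_stages: tuple[StageSpec, ...]
    beta: float = 1.0 / 8.0  # fast/slow channel ratio
    slow_len: int = 8
    fast_len: int = 32
    lateral_kernel: tuple[int, int, int] = (5, 1, 1)
    lateral_stride: int = 4
    lateral_channel_mult: int = 2
    fusion: str = "concat"  # 'concat' | 'project_sum'
    dropout: float = 0.5
    n_classes: int = len(CLASS_NAMES)

    @property
    def fast_conv1_channels(self) -> int:
        return max(int(round(self.slow_conv1_channels * self.beta)), 1)

    def validate(self) -> None:
        if self.fusion not in ("concat", "project_sum"):
            raise ValueError(f"unknown fusion mode {self.fusion!r}")
        if len(self.slow_stages) != 4 or len(self.fast_stages) != 4:
            raise ValueError("expected four residual stages per pathway")
        for s, f in zip(self.slow_stages, self.fast_stages):
            if f.channels != max(int(round(s.channels * self.beta)), 1):
                raise ValueError(
                    f"fast channels must be beta x slow at {s.name}"
                )
            if f.layer1_kernel[0] != 3:
                raise ValueError("fast layer1 kernels are spatiotemporal (t=3)")
        for s in self.slow_stages[:2]:
            if s.layer1_kernel[0] != 1:
                raise ValueError("slow res2/res3 layer1 must be spatial-only")
        for s in self.slow_stages[2:]:
            if s.layer1_kernel[0] != 3:
                raise ValueError("slow res4/res5 layer1 must have temporal extent 3")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchSpec":
        d = dict(d)
        for key in ("slow_stages", "fast_stages"):
            d[key] = tuple(
                StageSpec(**{**s, "layer1_kernel": tuple(s["layer1_kernel"]),
                             "layer2_kernel": tuple(s["layer2_kernel"])})
                for s in d[key]
            )
        d["lateral_kernel"] = tuple(d["lateral_kernel"])
        return cls(**d)


def _make_stages(channels, blocks, slow: bool) -> tuple[StageSpec, ...]:
    stages = []
    for i, (name, c, b) in enumerate(zip(RES_STAGES, channels, blocks)):
        t1 = 3 if (not slow or i >= 2) else 1
        stages.append(
            StageSpec(
                name=name,
                n_blocks=b,
                layer1_kernel=(t1, 3, 3),
                layer2_kernel=(1, 3, 3),
                channels=c,
                spatial_stride=1 if i == 0 else 2,
            )
        )
    return tuple(stages)


def make_arch_spec(
    variant: str,
    n_classes: int = len(CLASS_NAMES),
    fusion: str = "concat",
) -> ArchSpec:
    """The published configurations: depth 34 (blocks 3,4,6,3) at full or
    half width, or depth 18 (blocks 2,2,2,2) at full width."""
    key = variant.lower()
    if key not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    slow_ch = _SLOW_CHANNELS[key]
    blocks = _BLOCKS[key]
    fast_ch = tuple(max(c // 8, 1) for c in slow_ch)
    spec = ArchSpec(
        variant=key,
        slow_conv1_channels=64,
        slow_stages=_make_stages(slow_ch, blocks, slow=True),
        fast_stages=_make_stages(fast_ch, blocks, slow=False),
        fusion=fusion,
    )
    spec = replace(spec, n_classes=n_classes)
    spec.validate()
    return spec


def reduced_arch_spec(
    n_classes: int = len(CLASS_NAMES),
    width_divisor: int = 8,
    block_counts: tuple[int, int, int, int] = (1, 1, 1, 1),
    slow_len: int = 2,
    fast_len: int = 8,
    fusion: str = "concat",
) -> ArchSpec:
    """A desk-scale variant: channel widths divided by ``width_divisor``
    and shallow stages, keeping every structural element of the full
    network (dual pathways, laterals, fusion, classifier)."""
    slow_ch = tuple(max(c // width_divisor, 8) for c in (128, 256, 512, 1024))
    fast_ch = tuple(max(c // 8, 1) for c in slow_ch)
    spec = ArchSpec(
        variant=f"reduced-{width_divisor}x",
        slow_conv1_channels=max(64 // width_divisor, 8),
        slow_stages=_make_stages(slow_ch, block_counts, slow=True),
        fast_stages=_make_stages(fast_ch, block_counts, slow=False),
        slow_len=slow_len,
        fast_len=fast_len,
        fusion=fusion,
        n_classes=n_classes,
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# network construction


class ResBlock:
    """Two-layer residual block: conv-bn-relu, conv-bn, (+shortcut), relu.

    The shortcut is the identity when the block preserves shape, else a
    1x1x1 projection with normalization.
    """

    def __init__(self, c_in: int, spec: StageSpec, first: bool, dtype, name: str):
        c = spec.channels
        s = spec.spatial_stride if first else 1
        self.conv1 = nn.Conv3d(c_in, c, spec.layer1_kernel, (1, s, s), dtype,
                               f"{name}.conv1")
        self.bn1 = nn.BatchNorm3d(c, dtype=dtype, name=f"{name}.bn1")
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv3d(c, c, spec.layer2_kernel, (1, 1, 1), dtype,
                               f"{name}.conv2")
        self.bn2 = nn.BatchNorm3d(c, dtype=dtype, name=f"{name}.bn2")
        self.relu2 = nn.ReLU()
        if c_in != c or s != 1:
            self.proj = nn.Conv3d(c_in, c, (1, 1, 1), (1, s, s), dtype,
                                  f"{name}.proj")
            self.proj_bn = nn.BatchNorm3d(c, dtype=dtype, name=f"{name}.proj_bn")
        else:
            self.proj = self.proj_bn = None

    def layers(self):
        out = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2, self.relu2]
        if self.proj is not None:
            out += [self.proj, self.proj_bn]
        return out

    def forward(self, x, training=False):
        out = self.relu1.forward(
            self.bn1.forward(self.conv1.forward(x, training), training), training
        )
        out = self.bn2.forward(self.conv2.forward(out, training), training)
        if self.proj is not None:
            sc = self.proj_bn.forward(self.proj.forward(x, training), training)
        else:
            sc = x
        return self.relu2.forward(out + sc, training)

    def backward(self, dout):
        d = self.relu2.backward(dout)
        dsc = d  # gradient into the shortcut branch
        dmain = self.conv1.backward(
            self.bn1.backward(
                self.relu1.backward(self.conv2.backward(self.bn2.backward(d)))
            )
        )
        if self.proj is not None:
            dsc = self.proj.backward(self.proj_bn.backward(dsc))
        return dmain + dsc


class _Stem:
    """conv1 + bn + relu + pool1 of one pathway."""

    def __init__(self, c_out: int, temporal_kernel: int, dtype, name: str):
        self.conv = nn.Conv3d(3, c_out, (temporal_kernel, 7, 7), (1, 2, 2),
                              dtype, f"{name}.conv1", input_grad=False)
        self.bn = nn.BatchNorm3d(c_out, dtype=dtype, name=f"{name}.bn1")
        self.relu = nn.ReLU()
        self.pool = nn.MaxPool3d((1, 3, 3), (1, 2, 2))

    def layers(self):
        return [self.conv, self.bn, self.relu, self.pool]

    def forward(self, x, training=False):
        return self.pool.forward(
            self.relu.forward(self.bn.forward(self.conv.forward(x, training),
                                              training), training),
            training,
        )

    def backward(self, dout):
        return self.conv.backward(
            self.bn.backward(self.relu.backward(self.pool.backward(dout)))
        )


class _Lateral:
    """Time-strided transform of fast features for fusion into slow."""

    def __init__(self, c_fast: int, kernel, stride: int, mult: int,
                 slow_channels: int, fusion: str, dtype, name: str):
        c_out = mult * c_fast
        self.conv = nn.Conv3d(c_fast, c_out, kernel, (stride, 1, 1), dtype,
                              f"{name}.conv")
        self.bn = nn.BatchNorm3d(c_out, dtype=dtype, name=f"{name}.bn")
        self.relu = nn.ReLU()
        self.out_channels = c_out
        if fusion == "project_sum":
            self.proj = nn.Conv3d(c_out, slow_channels, (1, 1, 1), (1, 1, 1),
                                  dtype, f"{name}.proj")
            self.proj_bn = nn.BatchNorm3d(slow_channels, dtype=dtype,
                                          name=f"{name}.proj_bn")
            self.out_channels = slow_channels
        else:
            self.proj = self.proj_bn = None

    def layers(self):
        out = [self.conv, self.bn, self.relu]
        if self.proj is not None:
            out += [self.proj, self.proj_bn]
        return out

    def forward(self, f, training=False):
        out = self.relu.forward(
            self.bn.forward(self.conv.forward(f, training), training), training
        )
        if self.proj is not None:
            out = self.proj_bn.forward(self.proj.forward(out, training), training)
        return out

    def backward(self, dout):
        if self.proj is not None:
            dout = self.proj.backward(self.proj_bn.backward(dout))
        return self.conv.backward(self.bn.backward(self.relu.backward(dout)))


class Network:
    """Instantiated dual-pathway network with explicit forward/backward."""

    def __init__(self, spec: ArchSpec, dtype=np.float32):
        spec.validate()
        self.spec = spec
        self.dtype = dtype
        self.slow_stem = _Stem(spec.slow_conv1_channels, 1, dtype, "slow")
        self.fast_stem = _Stem(spec.fast_conv1_channels, 5, dtype, "fast")

        self.slow_stages: list[list[ResBlock]] = []
        self.fast_stages: list[list[ResBlock]] = []
        self.laterals: list[_Lateral] = []

        c_slow = spec.slow_conv1_channels
        c_fast = spec.fast_conv1_channels
        for i, (ss, fs) in enumerate(zip(spec.slow_stages, spec.fast_stages)):
            blocks = []
            c_in = c_slow
            for b in range(ss.n_blocks):
                blocks.append(ResBlock(c_in, ss, b == 0, dtype,
                                       f"slow.{ss.name}.b{b}"))
                c_in = ss.channels
            self.slow_stages.append(blocks)
            c_slow = ss.channels
            blocks = []
            c_in = c_fast
            for b in range(fs.n_blocks):
                blocks.append(ResBlock(c_in, fs, b == 0, dtype,
                                       f"fast.{fs.name}.b{b}"))
                c_in = fs.channels
            self.fast_stages.append(blocks)
            c_fast = fs.channels
            if i < 3:  # laterals attach after res2, res3, res4 only
                lat = _Lateral(c_fast, spec.lateral_kernel, spec.lateral_stride,
                               spec.lateral_channel_mult, c_slow, spec.fusion,
                               dtype, f"lateral.{ss.name}")
                self.laterals.append(lat)
                if spec.fusion == "concat":
                    c_slow = c_slow + lat.out_channels

        self.gap_slow = nn.GlobalAvgPool3d()
        self.gap_fast = nn.GlobalAvgPool3d()
        self.dropout = nn.Dropout(spec.dropout)
        feat = spec.slow_stages[-1].channels + spec.fast_stages[-1].channels
        self.fc = nn.Linear(feat, spec.n_classes, dtype=dtype)
        self.stage_activations: dict[str, dict[str, tuple]] = {}
        self._slow_c5 = spec.slow_stages[-1].channels

    # -- structure walkers -------------------------------------------------

    def modules(self):
        yield self.slow_stem
        yield self.fast_stem
        for stages in (self.slow_stages, self.fast_stages):
            for stage in stages:
                yield from stage
        yield from self.laterals

    def layers(self):
        for m in self.modules():
            yield from m.layers()
        yield self.gap_slow
        yield self.gap_fast
        yield self.dropout
        yield self.fc

    def params(self) -> list[nn.Param]:
        out = []
        for layer in self.layers():
            out.extend(layer.params())
        return out

    def zero_grad(self):
        for p in self.params():
            p.zero_grad()

    def set_dropout_rng(self, rng: np.random.Generator):
        self.dropout.rng = rng

    # -- forward / backward ------------------------------------------------

    def forward(self, x_slow: np.ndarray, x_fast: np.ndarray,
                training: bool = False) -> np.ndarray:
        spec = self.spec
        shapes = {
            "data_layer": {"slow": x_slow.shape[2:], "fast": x_fast.shape[2:]}
        }
        f = self.fast_stem.forward(x_fast, training)
        fast_outs = []
        for i, stage in enumerate(self.fast_stages):
            for block in stage:
                f = block.forward(f, training)
            fast_outs.append(f)
        self._fast_outs_shapes = [o.shape for o in fast_outs]

        s = self.slow_stem.forward(x_slow, training)
        shapes["pool1"] = {"slow": s.shape[2:], "fast": None}
        self._concat_splits = []
        for i, stage in enumerate(self.slow_stages):
            for block in stage:
                s = block.forward(s, training)
            name = spec.slow_stages[i].name
            shapes[name] = {"slow": s.shape[2:], "fast": fast_outs[i].shape[2:]}
            if i < 3:
                lat = self.laterals[i].forward(fast_outs[i], training)
                if spec.fusion == "concat":
                    self._concat_splits.append(s.shape[1])
                    s = np.concatenate([s, lat], axis=1)
                else:
                    s = s + lat
        fs = self.gap_slow.forward(s, training)
        ff = self.gap_fast.forward(f, training)
        feat = np.concatenate([fs, ff], axis=1)
        feat = self.dropout.forward(feat, training)
        logits = self.fc.forward(feat, training)
        self.stage_activations = shapes
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        spec = self.spec
        dfeat = self.dropout.backward(self.fc.backward(dlogits))
        c5 = self._slow_c5
        ds = self.gap_slow.backward(dfeat[:, :c5])
        df = self.gap_fast.backward(dfeat[:, c5:])

        dlat = [None, None, None]
        for i in range(3, -1, -1):
            if i < 3:
                if spec.fusion == "concat":
                    split = self._concat_splits[i]
                    dlat[i] = self.laterals[i].backward(ds[:, split:])
                    ds = np.ascontiguousarray(ds[:, :split])
                else:
                    dlat[i] = self.laterals[i].backward(ds)
            for block in reversed(self.slow_stages[i]):
                ds = block.backward(ds)
        self.slow_stem.backward(ds)

        for i in range(3, -1, -1):
            if i < 3:
                df = df + dlat[i]
            for block in reversed(self.fast_stages[i]):
                df = block.backward(df)
        self.fast_stem.backward(df)

    def predict_proba(self, x_slow: np.ndarray, x_fast: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward(x_slow, x_fast, training=False), axis=1)

    # -- state -------------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {}
        for i, p in enumerate(self.params()):
            state[f"param_{i:04d}_{p.name}"] = p.value
        for i, layer in enumerate(self.layers()):
            if isinstance(layer, nn.BatchNorm3d):
                state[f"bnstat_{i:04d}_mean"] = layer.running_mean
                state[f"bnstat_{i:04d}_var"] = layer.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value[...] = state[f"param_{i:04d}_{p.name}"]
        for i, layer in enumerate(self.layers()):
            if isinstance(layer, nn.BatchNorm3d):
                layer.running_mean[...] = state[f"bnstat_{i:04d}_mean"]
                layer.running_var[...] = state[f"bnstat_{i:04d}_var"]


def build_network(spec: ArchSpec, dtype=np.float32) -> Network:
    return Network(spec, dtype=dtype)


# ---------------------------------------------------------------------------
# accounting


def count_parameters(net: Network) -> int:
    """Total number of trainable scalar weights."""
    return int(sum(p.size for p in net.params()))


def count_parameters_millions(net: Network) -> float:
    return count_parameters(net) / 1e6


def _down(x: int, kernel: int, stride: int) -> int:
    return nn.conv_output_len(x, kernel, stride, (kernel - 1) // 2)


def stage_output_shapes(
    spec: ArchSpec,
    input_slow: tuple[int, int, int] | None = None,
    input_fast: tuple[int, int, int] | None = None,
) -> dict[str, dict[str, tuple[int, int, int]]]:
    """Per-stage (T, H, W) output sizes, by stride arithmetic.

    Temporal extents never change after the data layer; spatial sizes
    halve at conv1, pool1 and at the entry of res3..res5.
    """
    ts, hs, ws = input_slow or (spec.slow_len, 224, 224)
    tf, hf, wf = input_fast or (spec.fast_len, 224, 224)
    if min(hs, ws, hf, wf) < 32:  # five spatial halvings need 2^5 px
        raise ValueError("input too small for the stride pyramid (min 32 px)")
    table: dict[str, dict[str, tuple]] = {
        "data_layer": {"slow": (ts, hs, ws), "fast": (tf, hf, wf)}
    }
    h, w = _down(hs, 7, 2), _down(ws, 7, 2)
    table["conv1"] = {"slow": (ts, h, w), "fast": (tf, h, w)}
    h, w = _down(h, 3, 2), _down(w, 3, 2)
    table["pool1"] = {"slow": (ts, h, w), "fast": (tf, h, w)}
    for st in spec.slow_stages:
        if st.spatial_stride == 2:
            h, w = _down(h, 3, 2), _down(w, 3, 2)
        if h < 1 or w < 1:
            raise ValueError(
                f"input too small: spatial extent collapses at {st.name}"
            )
        table[st.name] = {"slow": (ts, h, w), "fast": (tf, h, w)}
    return table


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(net: Network, path, extra: dict | None = None) -> Path:
    """Self-describing checkpoint: weights + architecture spec (+ extras)."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    meta = {"arch": net.spec.to_dict(), "extra": extra or {}}
    np.savez_compressed(p, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8
    ), **net.state_arrays())
    return p


def load_checkpoint(path, dtype=np.float32) -> tuple[Network, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        spec = ArchSpec.from_dict(meta["arch"])
        net = build_network(spec, dtype=dtype)
        net.load_state_arrays({k: data[k] for k in data.files if k != "__meta__"})
    return net, meta.get("extra", {})
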