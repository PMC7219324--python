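"""Training recipe: He initialization, warm-up + half-period cosine
schedule, SGD with momentum and weight decay, cross-entropy loss.

Every convolution/classifier weight is drawn from a zero-mean Gaussian
whose variance is ``2 / n_l`` with ``n_l`` the layer fan-in (receptive
field volume times input channels); biases start at zero, normalization
scales at one.  The learning rate at iteration ``n`` is

    lr(n) = eta * 0.5 * (cos(pi * n / n_max) + 1)

with a linear warm-up from ``warmup_factor * eta`` over the first
``warmup_iters`` mini-batch steps.  One iteration is one mini-batch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import nn
from .model import Network
from .sampling import (
    SamplingConfig,
    extract_pathways,
    pathway_subsample,
    sample_window,
    train_crop,
)
from .video_io import CLASS_NAMES, check_class_coverage, read_clip

__all__ = ["TrainConfig", "TrainHistory", "init_weights", "lr_at", "train",
           "clips_to_batch"]


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the published recipe)."""

    base_lr: float = 0.0125
    epochs: int = 300
    batch_size: int = 8
    momentum: float = 0.9
    weight_decay: float = 1e-4
    dropout: float = 0.5
    warmup_epochs: float = 34.0  # linear warm-up span, in epochs
    warmup_factor: float = 0.1  # starting lr as a fraction of base_lr
    patience: int | None = None  # optional early stop on validation plateau
    input_mean: float = 0.45
    input_std: float = 0.225
    seed: int = 0
    # resolved at train time from the dataset size; may be set explicitly
    n_max: int | None = None
    warmup_iters: int | None = None

    def __post_init__(self):
        if self.base_lr <= 0:
            raise ValueError("base_lr must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.n_max is not None and self.warmup_iters is not None:
            if not 0 <= self.warmup_iters < self.n_max:
                raise ValueError("need 0 <= warmup_iters < n_max")


@dataclass
class TrainHistory:
    """Per-epoch loss, validation top-1 and learning rate, plus the full
    per-iteration learning-rate trace."""

    loss: list[float] = field(default_factory=list)
    val_top1: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    lr_by_iter: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_top1: float = float("nan")


def init_weights(net: Network, seed: int = 0) -> Network:
    """He fan-in Gaussian init for conv/linear weights; zero biases;
    unit normalization scales.  Deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    for layer in net.layers():
        if isinstance(layer, (nn.Conv3d, nn.Linear)):
            std = math.sqrt(2.0 / layer.fan_in)
            layer.weight.value[...] = rng.normal(
                0.0, std, size=layer.weight.value.shape
            ).astype(layer.weight.value.dtype)
            if isinstance(layer, nn.Linear):
                layer.bias.value[...] = 0.0
        elif isinstance(layer, nn.BatchNorm3d):
            layer.gamma.value[...] = 1.0
            layer.beta.value[...] = 0.0
            layer.running_mean[...] = 0.0
            layer.running_var[...] = 1.0
    return net


def lr_at(n: int, cfg: TrainConfig) -> float:
    """Learning rate at mini-batch iteration ``n``."""
    if cfg.n_max is None:
        raise ValueError("cfg.n_max must be resolved before querying lr_at")
    if not 0 <= n <= cfg.n_max:
        raise ValueError(f"iteration {n} outside [0, {cfg.n_max}]")
    warmup = cfg.warmup_iters or 0

    def cosine(k: int) -> float:
        return cfg.base_lr * 0.5 * (math.cos(math.pi * k / cfg.n_max) + 1.0)

    if n < warmup:
        start = cfg.warmup_factor * cfg.base_lr
        return start + (cosine(warmup) - start) * n / warmup
    return cosine(n)


def sgd_step(params, velocity: dict, lr: float, momentum: float,
             weight_decay: float) -> None:
    """Momentum SGD update with decoupled-in-gradient weight decay."""
    for p in params:
        v = velocity[id(p)]
        v *= momentum
        v += p.grad + weight_decay * p.value
        p.value -= lr * v


def clips_to_batch(
    clips: list[np.ndarray],
    cfg: TrainConfig,
    sampling: SamplingConfig,
    rng: np.random.Generator,
):
    """Sample a window + crop per clip and stack dual-pathway inputs.

    Returns ``(x_slow, x_fast)`` shaped ``(N, 3, T, S, S)`` float32,
    scaled to [0, 1] and standardized with the configured constants.
    """
    slows, fasts = [], []
    ratio = sampling.slow_stride // sampling.fast_stride
    for frames in clips:
        w = sample_window(frames.shape[0], "random", rng, sampling)
        pair = pathway_subsample(w, sampling)
        fast = extract_pathways(frames, pair).fast
        fast = train_crop(fast, sampling.train_crop, rng, sampling)
        slows.append(fast[::ratio])
        fasts.append(fast)
    return _standardize(np.stack(slows), cfg), _standardize(np.stack(fasts), cfg)


def _standardize(x: np.ndarray, cfg: TrainConfig) -> np.ndarray:
    x = x.astype(np.float32) / 255.0
    x = (x - cfg.input_mean) / cfg.input_std
    return np.ascontiguousarray(x.transpose(0, 4, 1, 2, 3))


def _center_view(frames: np.ndarray, cfg: TrainConfig, sampling: SamplingConfig):
    """Deterministic single view (center window, center crop) for the
    per-epoch validation pass."""
    k = sampling.n_temporal_views // 2
    w = sample_window(frames.shape[0], "uniform_k", k, sampling)
    pair = pathway_subsample(w, sampling)
    fast = extract_pathways(frames, pair).fast
    from .sampling import resize_shorter_side

    fast = resize_shorter_side(fast, max(sampling.train_scale, sampling.train_crop))
    h, w_ = fast.shape[1:3]
    size = sampling.train_crop
    dy, dx = (h - size) // 2, (w_ - size) // 2
    fast = fast[:, dy : dy + size, dx : dx + size]
    ratio = sampling.slow_stride // sampling.fast_stride
    return (
        _standardize(fast[::ratio][None], cfg),
        _standardize(fast[None], cfg),
    )


def _load_clips(manifest) -> tuple[list[np.ndarray], np.ndarray]:
    clips, labels = [], []
    for _, row in manifest.iterrows():
        clips.append(read_clip(row["clip_path"]).frames)
        labels.append(CLASS_NAMES.index(row["label"]))
    return clips, np.asarray(labels)


def train(
    net: Network,
    train_manifest,
    val_manifest,
    cfg: TrainConfig,
    sampling: SamplingConfig | None = None,
    checkpoint_path=None,
) -> tuple[Network, TrainHistory]:
    """Train with per-iteration cosine learning rate; fully reproducible
    given ``cfg.seed`` (init, data order, windows, crops, dropout).

    The best-validation weights are restored into ``net`` on return (and
    saved to ``checkpoint_path`` when given).  When ``val_manifest`` is
    None the final weights are kept.
    """
    sampling = sampling or SamplingConfig()
    check_class_coverage(train_manifest)
    clips, labels = _load_clips(train_manifest)
    val_data = _load_clips(val_manifest) if val_manifest is not None else None

    n = len(clips)
    steps = math.ceil(n / cfg.batch_size)
    cfg = replace(
        cfg,
        n_max=cfg.n_max or steps * cfg.epochs,
        warmup_iters=(
            cfg.warmup_iters
            if cfg.warmup_iters is not None
            else min(int(cfg.warmup_epochs * steps), max(steps * cfg.epochs - 1, 0))
        ),
    )

    root = np.random.SeedSequence(cfg.seed)
    s_init, s_order, s_aug, s_drop = root.spawn(4)
    init_weights(net, int(s_init.generate_state(1)[0] % (2**31)))
    net.dropout.rate = cfg.dropout
    net.set_dropout_rng(np.random.default_rng(s_drop))
    order_rng = np.random.default_rng(s_order)
    aug_rng = np.random.default_rng(s_aug)

    velocity = {id(p): np.zeros_like(p.value) for p in net.params()}
    history = TrainHistory()
    best_state = None
    it = 0
    for epoch in range(cfg.epochs):
        perm = order_rng.permutation(n)
        losses = []
        epoch_lr = lr_at(it, cfg)
        for b in range(steps):
            idx = perm[b * cfg.batch_size : (b + 1) * cfg.batch_size]
            xs, xf = clips_to_batch([clips[i] for i in idx], cfg, sampling, aug_rng)
            net.zero_grad()
            logits = net.forward(xs, xf, training=True)
            loss, dlogits = nn.cross_entropy(logits, labels[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch}, step {b}; "
                    "lower the learning rate or check the input scaling"
                )
            net.backward(dlogits)
            lr = lr_at(it, cfg)
            history.lr_by_iter.append(lr)
            sgd_step(net.params(), velocity, lr, cfg.momentum, cfg.weight_decay)
            losses.append(loss)
            it += 1

        history.loss.append(float(np.mean(losses)))
        history.lr.append(epoch_lr)
        if val_data is not None:
            acc = _validate(net, val_data, cfg, sampling)
            history.val_top1.append(acc)
            if best_state is None or acc > history.best_val_top1:
                history.best_val_top1 = acc
                history.best_epoch = epoch
                best_state = {k: v.copy() for k, v in net.state_arrays().items()}
            if (
                cfg.patience is not None
                and epoch - history.best_epoch >= cfg.patience
            ):
                break
        else:
            history.val_top1.append(float("nan"))

    if best_state is not None:
        net.load_state_arrays(best_state)
    if checkpoint_path is not None:
        from .model import save_checkpoint

        save_checkpoint(
            net,
            checkpoint_path,
            extra={
                "best_epoch": history.best_epoch,
                "best_val_top1": history.best_val_top1,
            },
        )
    return net, history


def _validate(net, val_data, cfg, sampling, chunk: int = 32) -> float:
    clips, labels = val_data
    views = [_center_view(frames, cfg, sampling) for frames in clips]
    preds = []
    for i in range(0, len(views), chunk):
        xs = np.concatenate([v[0] for v in views[i : i + chunk]])
        xf = np.concatenate([v[1] for v in views[i : i + chunk]])
        preds.append(np.argmax(net.predict_proba(xs, xf), axis=1))
    return float((np.concatenate(preds) == labels).mean())
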