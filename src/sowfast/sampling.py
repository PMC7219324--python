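"""Clip sampling: 64-frame windows, dual-pathway subsampling, crops, views.

Training draws one random 64-frame window per clip, resizes the shorter
spatial side to 240 and takes a random 224x224 crop.  Inference uses 30
views per clip: 10 temporal windows evenly spaced along the clip times 3
square crops of side 240 placed along the longer spatial axis.  Clips
shorter than one window are loop-padded (indices wrap modulo the clip
length), which preserves the motion statistics of periodic behaviors.

The slow pathway takes every 8th window frame (8 frames per 64-frame
window); the fast pathway takes every 2nd (32 frames), so the slow frame
set is always a subset of the fast one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .video_io import FrameSequence

__all__ = [
    "SamplingConfig",
    "WindowIndices",
    "PathwayPair",
    "ViewSet",
    "sample_window",
    "pathway_subsample",
    "extract_pathways",
    "resize_shorter_side",
    "train_crop",
    "test_views",
]


@dataclass(frozen=True)
class SamplingConfig:
    """Temporal/spatial sampling geometry.

    The defaults are the full-scale protocol; reduced settings (e.g.
    16-frame windows with 64-px crops) are used for desk-scale training.
    """

    window_len: int = 64
    slow_stride: int = 8
    fast_stride: int = 2
    train_crop: int = 224
    train_scale: int = 240
    test_scale: int = 240
    n_temporal_views: int = 10
    n_spatial_views: int = 3
    horizontal_flip: bool = False
    color_jitter: float = 0.0

    def __post_init__(self):
        if self.window_len % self.slow_stride or self.window_len % self.fast_stride:
            raise ValueError("window_len must be divisible by both strides")
        if self.slow_stride % self.fast_stride:
            raise ValueError("slow stride must be a multiple of the fast stride")


DEFAULT_CONFIG = SamplingConfig()


@dataclass(frozen=True)
class WindowIndices:
    """One contiguous (possibly wrapped) window of frame positions."""

    start: int
    indices: np.ndarray  # window_len consecutive positions mod clip length
    n_frames: int

    def __len__(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class PathwayPair:
    """Temporally subsampled slow/fast companions of one window.

    ``slow`` and ``fast`` are frame-index vectors into the raw clip when
    produced by :func:`pathway_subsample`, or pixel arrays once realized
    by :func:`extract_pathways`.
    """

    slow: np.ndarray
    fast: np.ndarray


@dataclass(frozen=True)
class ViewSet:
    """The inference views of one test clip: 10 temporal x 3 spatial."""

    views: list[PathwayPair]  # pixel-level pairs, (T, S, S, 3) uint8 each

    def __len__(self) -> int:
        return len(self.views)


def _start_range(n_frames: int, window_len: int) -> int:
    return max(n_frames - window_len, 0)


def sample_window(
    n_frames: int,
    mode: str = "random",
    seed_or_k=0,
    cfg: SamplingConfig = DEFAULT_CONFIG,
) -> WindowIndices:
    """Choose one window of ``cfg.window_len`` frames.

    ``mode='random'`` draws the start uniformly on ``[0, n - L]`` (a
    `numpy` Generator or an integer seed may be passed); ``mode='uniform_k'``
    returns the k-th of ``n_temporal_views`` starts evenly spaced over
    the same range.  Shorter clips wrap.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    hi = _start_range(n_frames, cfg.window_len)
    if mode == "random":
        rng = (
            seed_or_k
            if isinstance(seed_or_k, np.random.Generator)
            else np.random.default_rng(seed_or_k)
        )
        start = int(rng.integers(0, hi + 1))
    elif mode == "uniform_k":
        k = int(seed_or_k)
        if not 0 <= k < cfg.n_temporal_views:
            raise ValueError(f"k must be in [0, {cfg.n_temporal_views})")
        starts = np.linspace(0, hi, cfg.n_temporal_views)
        start = int(round(starts[k]))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    indices = (start + np.arange(cfg.window_len)) % n_frames
    return WindowIndices(start=start, indices=indices, n_frames=n_frames)


def pathway_subsample(
    w: WindowIndices, cfg: SamplingConfig = DEFAULT_CONFIG
) -> PathwayPair:
    """Slow takes every ``slow_stride``-th window position, fast every
    ``fast_stride``-th, both starting at position 0."""
    return PathwayPair(
        slow=w.indices[:: cfg.slow_stride].copy(),
        fast=w.indices[:: cfg.fast_stride].copy(),
    )


def extract_pathways(frames: np.ndarray, pair: PathwayPair) -> PathwayPair:
    """Realize index-level pathways as pixel arrays from the raw clip."""
    return PathwayPair(slow=frames[pair.slow], fast=frames[pair.fast])


def resize_shorter_side(frames: np.ndarray, target: int) -> np.ndarray:
    """Scale so the shorter spatial side equals ``target``, keeping aspect."""
    t, h, w = frames.shape[:3]
    if min(h, w) == target:
        return frames
    if h <= w:
        nh, nw = target, int(round(w * target / h))
    else:
        nh, nw = int(round(h * target / w)), target
    out = _sk_resize(
        frames,
        (t, nh, nw, frames.shape[3]),
        order=1,
        anti_aliasing=min(h, w) > target,
        anti_aliasing_sigma=None,
        preserve_range=True,
    )
    return np.clip(out, 0, 255).astype(np.uint8)


def train_crop(
    seq: FrameSequence | np.ndarray,
    size: int | None = None,
    seed=0,
    cfg: SamplingConfig = DEFAULT_CONFIG,
) -> np.ndarray:
    """Random square crop applied identically to all frames.

    The clip is first scaled so its shorter side equals
    ``cfg.train_scale`` (keeping train and test scales consistent), then
    a ``size`` x ``size`` crop is taken at a seeded uniform offset.
    """
    size = size or cfg.train_crop
    frames = seq.frames if isinstance(seq, FrameSequence) else seq
    if min(frames.shape[1:3]) != size:
        # a frame already matching the crop size is used as-is
        frames = resize_shorter_side(frames, cfg.train_scale)
    h, w = frames.shape[1:3]
    if h < size or w < size:
        raise ValueError(f"frames {h}x{w} smaller than crop {size} after resize")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    dy = int(rng.integers(0, h - size + 1))
    dx = int(rng.integers(0, w - size + 1))
    return frames[:, dy : dy + size, dx : dx + size]


def _spatial_offsets(length: int, size: int, n: int) -> list[int]:
    """Evenly placed crop offsets along the longer axis: first/center/last."""
    if n == 1 or length == size:
        return [max((length - size) // 2, 0)] * n if n == 1 else [0] * n
    span = length - size
    return [int(round(i * span / (n - 1))) for i in range(n)]


def test_views(
    seq: FrameSequence, cfg: SamplingConfig = DEFAULT_CONFIG
) -> ViewSet:
    """Build the full inference view set of one clip.

    The shorter spatial side is scaled to ``cfg.test_scale``; 3 square
    crops of that side are placed at offsets 0, (L - S)/2 and L - S
    along the longer axis; 10 windows are evenly spaced temporally.
    """
    frames = resize_shorter_side(seq.frames, cfg.test_scale)
    h, w = frames.shape[1:3]
    size = cfg.test_scale
    if h <= w:
        offsets = [(0, dx) for dx in _spatial_offsets(w, size, cfg.n_spatial_views)]
    else:
        offsets = [(dy, 0) for dy in _spatial_offsets(h, size, cfg.n_spatial_views)]

    views: list[PathwayPair] = []
    for k in range(cfg.n_temporal_views):
        window = sample_window(seq.n_frames, "uniform_k", k, cfg)
        pair = pathway_subsample(window, cfg)
        slow, fast = frames[pair.slow], frames[pair.fast]
        for dy, dx in offsets:
            views.append(
                PathwayPair(
                    slow=slow[:, dy : dy + size, dx : dx + size],
                    fast=fast[:, dy : dy + size, dx : dx + size],
                )
            )
    return ViewSet(views=views)
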