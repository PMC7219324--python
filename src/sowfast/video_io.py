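"""Clip and manifest I/O for the pig-behavior recognition pipeline.

A *clip* is either an AVI file or a directory of numbered image frames;
a *manifest* is a CSV table mapping clip paths to one of the five
behavior classes.  The class vocabulary order is fixed for every
confusion matrix and report in the package:

    feeding, lying, motoring, scratching, mounting
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import _avi

__all__ = [
    "CLASS_NAMES",
    "FrameSequence",
    "DatasetStats",
    "read_clip",
    "write_clip",
    "read_manifest",
    "write_manifest",
    "manifest_from_rows",
    "summarize_manifest",
    "stratified_split",
    "random_split",
]

#: Fixed, ordered behavior vocabulary used for all matrices and reports.
CLASS_NAMES: tuple[str, ...] = ("feeding", "lying", "motoring", "scratching", "mounting")

MANIFEST_COLUMNS = ("clip_path", "label", "n_frames", "fps", "duration_s")

_IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff")

DEFAULT_FPS = 25.0  # capture rate of the source footage (PAL)


@dataclass
class FrameSequence:
    """Ordered decoded frames of one clip.

    ``frames`` has shape ``(n_frames, height, width, 3)``, dtype uint8.
    """

    frames: np.ndarray
    fps: float = DEFAULT_FPS

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must have shape (T, H, W, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("a clip needs at least one frame")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.frames.dtype != np.uint8:
            raise ValueError("frames must be 8-bit per channel (uint8)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def size(self) -> tuple[int, int]:
        """(height, width) shared by all frames."""
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass
class DatasetStats:
    """Per-class clip counts and durations of one manifest."""

    class_counts: dict[str, int]
    class_durations_s: dict[str, float]
    duration_histogram: dict[str, np.ndarray]
    histogram_edges_s: np.ndarray
    total_duration_s: float
    n_clips: int = field(default=0)

    def __post_init__(self):
        if not self.n_clips:
            self.n_clips = sum(self.class_counts.values())


def read_clip(path, fps: float | None = None) -> FrameSequence:
    """Decode an AVI file or a directory of image frames.

    Frame directories carry no frame-rate metadata, so ``fps`` applies to
    them (default 25, the capture rate).  For AVI files the container's
    rate is used unless ``fps`` overrides it.
    """
    p = Path(path)
    if p.is_dir():
        files = sorted(
            f for f in p.iterdir() if f.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise ValueError(f"no image frames found in directory {p}")
        frames = np.stack([np.asarray(iio.imread(f))[..., :3] for f in files])
        if frames.dtype != np.uint8:
            frames = frames.astype(np.uint8)
        return FrameSequence(frames, fps=fps or DEFAULT_FPS)
    if not p.exists():
        raise FileNotFoundError(p)
    frames, container_fps = _avi.read_avi(p)
    return FrameSequence(frames, fps=fps or container_fps)


def write_clip(seq: FrameSequence, path, codec: str = "rawvideo") -> Path:
    """Write a clip as a lossless AVI file or a PNG frame directory.

    ``codec='rawvideo'`` writes an uncompressed RGB AVI; ``codec='png'``
    writes ``path`` as a directory of numbered PNG frames.
    """
    p = Path(path)
    if codec == "png":
        p.mkdir(parents=True, exist_ok=True)
        width = len(str(seq.n_frames - 1)) if seq.n_frames > 1 else 1
        for i, frame in enumerate(seq.frames):
            iio.imwrite(p / f"frame_{i:0{width}d}.png", frame)
        return p
    if codec != "rawvideo":
        raise ValueError(f"unsupported codec {codec!r}; use 'rawvideo' or 'png'")
    p.parent.mkdir(parents=True, exist_ok=True)
    _avi.write_avi(p, seq.frames, seq.fps)
    return p


def manifest_from_rows(rows: list[dict]) -> pd.DataFrame:
    """Build a validated manifest DataFrame from row dicts."""
    m = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    _validate_manifest(m)
    return m


def _validate_manifest(m: pd.DataFrame) -> None:
    missing = set(MANIFEST_COLUMNS) - set(m.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    bad = set(m["label"]) - set(CLASS_NAMES)
    if bad:
        raise ValueError(
            f"labels outside vocabulary {CLASS_NAMES}: {sorted(bad)}"
        )
    # duration must agree with frame count to within one frame
    slack = 1.0 / m["fps"].to_numpy()
    err = np.abs(m["duration_s"].to_numpy() - m["n_frames"].to_numpy() / m["fps"].to_numpy())
    if np.any(err > slack):
        raise ValueError("duration_s inconsistent with n_frames / fps")


def read_manifest(path) -> pd.DataFrame:
    """Read a manifest CSV; relative clip paths are resolved against it."""
    p = Path(path)
    m = pd.read_csv(p)
    _validate_manifest(m)
    m["clip_path"] = [
        str(q) if Path(q).is_absolute() else str(p.parent / q)
        for q in m["clip_path"]
    ]
    return m


def write_manifest(m: pd.DataFrame, path) -> Path:
    _validate_manifest(m)
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    m.to_csv(p, index=False)
    return p


def summarize_manifest(m: pd.DataFrame, bin_width_s: float = 1.0) -> DatasetStats:
    """Per-class counts, per-class binned duration histograms, total seconds."""
    if len(m) == 0:
        raise ValueError("empty manifest")
    _validate_manifest(m)
    durations = m["duration_s"].to_numpy(dtype=float)
    edges = np.arange(0.0, durations.max() + 2 * bin_width_s, bin_width_s)
    counts: dict[str, int] = {}
    per_class_dur: dict[str, float] = {}
    hists: dict[str, np.ndarray] = {}
    for cls in CLASS_NAMES:
        sel = m["label"] == cls
        counts[cls] = int(sel.sum())
        per_class_dur[cls] = float(durations[sel.to_numpy()].sum())
        hists[cls], _ = np.histogram(durations[sel.to_numpy()], bins=edges)
    return DatasetStats(
        class_counts=counts,
        class_durations_s=per_class_dur,
        duration_histogram=hists,
        histogram_edges_s=edges,
        total_duration_s=float(durations.sum()),
    )


def stratified_split(
    m: pd.DataFrame, fractions: list[float], seed: int
) -> list[pd.DataFrame]:
    """Partition a manifest class-by-class into ``len(fractions)`` subsets.

    Within each class the rows are shuffled with ``seed``; each subset
    receives ``floor(fraction * n)`` rows and the remainders are handed
    out one each to subsets in declaration order.  The partition is exact
    (disjoint, union equals the input) and deterministic given the seed.
    """
    fractions = list(fractions)
    if any(f <= 0 for f in fractions):
        raise ValueError("fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    _validate_manifest(m)
    rng = np.random.default_rng(seed)
    parts: list[list[pd.DataFrame]] = [[] for _ in fractions]
    for cls in CLASS_NAMES:
        cls_rows = m[m["label"] == cls]
        n = len(cls_rows)
        if n == 0:
            continue
        if n < len(fractions):
            raise ValueError(
                f"class {cls!r} has {n} rows, fewer than {len(fractions)} subsets"
            )
        order = rng.permutation(n)
        alloc = [int(np.floor(f * n)) for f in fractions]
        rem = n - sum(alloc)
        for i in range(rem):
            alloc[i % len(alloc)] += 1
        start = 0
        for i, k in enumerate(alloc):
            idx = order[start : start + k]
            parts[i].append(cls_rows.iloc[idx])
            start += k
    return [
        pd.concat(chunks, ignore_index=True)
        if chunks
        else m.iloc[0:0].copy()
        for chunks in parts
    ]


def random_split(m: pd.DataFrame, n_first: int, seed: int) -> list[pd.DataFrame]:
    """Split into a subset of ``n_first`` rows and the remainder, unstratified."""
    if not 0 < n_first < len(m):
        raise ValueError("n_first must be strictly inside (0, len(m))")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(m))
    first = m.iloc[order[:n_first]].reset_index(drop=True)
    rest = m.iloc[order[n_first:]].reset_index(drop=True)
    return [first, rest]


def check_class_coverage(m: pd.DataFrame) -> None:
    """Warn when any vocabulary class is absent from a training manifest."""
    missing = [c for c in CLASS_NAMES if (m["label"] == c).sum() == 0]
    if missing:
        warnings.warn(f"classes with no training clips: {missing}", stacklevel=2)
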