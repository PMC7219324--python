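"""Procedural generator of labeled synthetic pig-behavior clips.

Real footage of the five behaviors is not publicly deposited, so every
downstream stage (sampling, network, training, evaluation) is exercised
on procedurally generated clips whose classes are separable by the same
kind of spatiotemporal signatures that distinguish the behaviors:

========== ==================== =========================================
class      motion kind          signature
========== ==================== =========================================
feeding    local_oscillation    body static, head region bobbing at a
                                low temporal frequency
lying      static               nothing moves
motoring   translation          whole body translating across the pen
scratching local_oscillation    body region rubbing against a static
                                fixture at a strictly higher frequency
                                and amplitude than feeding
mounting   overlap_event        a second animal rises onto and overlaps
                                the first (the only two-object class)
========== ==================== =========================================

Objects are soft-edged ellipses over a fixed hatch-textured background;
per-clip intensities are drawn from a seeded RNG so no class is
separable by brightness alone.  Noise is additive Gaussian on intensity,
clipped to the 8-bit range.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .video_io import (
    CLASS_NAMES,
    FrameSequence,
    manifest_from_rows,
    write_clip,
    write_manifest,
)

__all__ = [
    "SyntheticClassSpec",
    "SceneSpec",
    "GeometryError",
    "default_class_specs",
    "generate_clip",
    "generate_dataset",
]

MOTION_KINDS = ("static", "local_oscillation", "translation", "overlap_event")


class GeometryError(ValueError):
    """An object's motion excursion would leave the frame."""


@dataclass(frozen=True)
class SyntheticClassSpec:
    """Motion parameters of one behavior class.

    ``frequency`` is in cycles/frame (bounded by the Nyquist rate 0.5 of
    frame sampling), ``amplitude`` in pixels at the 64-px reference
    scale, ``speed`` in px/frame, ``noise_sd`` in 8-bit intensity units.
    """

    class_name: str
    motion_kind: str
    frequency: float = 0.0
    amplitude: float = 0.0
    speed: float = 0.0
    n_objects: int = 1
    noise_sd: float = 1.5

    def __post_init__(self):
        if self.motion_kind not in MOTION_KINDS:
            raise ValueError(f"unknown motion kind {self.motion_kind!r}")
        if not 0.0 <= self.frequency <= 0.5:
            raise ValueError("frequency must lie in [0, 0.5] cycles/frame")
        if min(self.amplitude, self.speed, self.noise_sd) < 0:
            raise ValueError("amplitude, speed and noise_sd must be >= 0")
        if self.n_objects < 1:
            raise ValueError("n_objects must be >= 1")


@dataclass(frozen=True)
class SceneSpec:
    """Canvas geometry, duration and RNG seed of one clip."""

    width: int = 64
    height: int = 64
    n_frames: int = 64
    fps: float = 25.0
    background: str = "hatch"
    seed: int = 0

    def __post_init__(self):
        if self.width < 32 or self.height < 32:
            raise ValueError("scene must be at least 32x32 px")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def default_class_specs() -> dict[str, SyntheticClassSpec]:
    """The five default behavior signatures (one clip archetype per class).

    Feeding oscillates at 0.0625 cycles/frame (one bob per 16 frames at
    25 fps, ~1.6 Hz) and scratching at 0.25 cycles/frame with a larger
    amplitude — the rubbing motion is strictly faster than the feeding
    bob, which is the discriminative premise the fast pathway exploits.
    """
    specs = {
        "feeding": SyntheticClassSpec("feeding", "local_oscillation",
                                      frequency=0.0625, amplitude=1.5),
        "lying": SyntheticClassSpec("lying", "static"),
        "motoring": SyntheticClassSpec("motoring", "translation", speed=0.55),
        "scratching": SyntheticClassSpec("scratching", "local_oscillation",
                                         frequency=0.25, amplitude=4.0),
        "mounting": SyntheticClassSpec("mounting", "overlap_event",
                                       speed=0.45, n_objects=2),
    }
    assert specs["scratching"].frequency > specs["feeding"].frequency
    return specs


def _background(scene: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Fixed hatch texture with a per-clip base intensity."""
    y, x = np.mgrid[0 : scene.height, 0 : scene.width]
    base = rng.uniform(78.0, 92.0)
    hatch = 6.0 * np.sin(2 * np.pi * x / 9.0) + 6.0 * np.sin(2 * np.pi * y / 13.0)
    return base + hatch + 4.0 * np.sin(2 * np.pi * (x + y) / 21.0)


def _ellipse_alpha(
    h: int, w: int, cx: float, cy: float, ax: float, ay: float
) -> np.ndarray:
    """Soft-edged ellipse coverage in [0, 1]."""
    y, x = np.mgrid[0:h, 0:w]
    r = np.sqrt(((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2)
    z = np.clip((r - 1.0) / 0.025, -60.0, 60.0)  # avoid exp overflow far away
    return 1.0 / (1.0 + np.exp(z))


def _composite(img: np.ndarray, alpha: np.ndarray, intensity: float) -> np.ndarray:
    return img * (1.0 - alpha) + intensity * alpha


def _check_bounds(name, cx_lo, cx_hi, cy_lo, cy_hi, ax, ay, w, h, margin=2.0):
    if (cx_lo - ax - margin < 0 or cx_hi + ax + margin > w - 1
            or cy_lo - ay - margin < 0 or cy_hi + ay + margin > h - 1):
        raise GeometryError(
            f"{name}: motion excursion exceeds the {w}x{h} frame bounds"
        )


def generate_clip(cls: SyntheticClassSpec, scene: SceneSpec) -> FrameSequence:
    """Render one clip; deterministic given ``scene.seed``."""
    rng = np.random.default_rng(scene.seed)
    w, h, n = scene.width, scene.height, scene.n_frames
    s = min(w, h) / 64.0  # geometry scale relative to the 64-px reference
    bg = _background(scene, rng)

    body_i = rng.uniform(195.0, 215.0)
    head_i = np.clip(body_i + rng.uniform(-8.0, 8.0), 0, 255)
    ax, ay = (10.0 + rng.uniform(-1.0, 1.0)) * s, (6.0 + rng.uniform(-0.8, 0.8)) * s
    cx, cy = w / 2.0 + rng.uniform(-2, 2) * s, h / 2.0 + rng.uniform(-2, 2) * s
    amp = cls.amplitude * s
    speed = cls.speed * s
    t = np.arange(n)

    frames = np.empty((n, h, w), dtype=np.float64)
    kind = cls.motion_kind

    if kind == "static":
        img = _composite(bg, _ellipse_alpha(h, w, cx, cy, ax, ay), body_i)
        frames[:] = img

    elif kind == "local_oscillation":
        phase = rng.uniform(0, 2 * np.pi)
        dy = amp * np.sin(2 * np.pi * cls.frequency * t + phase)
        if cls.class_name == "scratching":
            # rub against a static vertical fixture beside the body
            bar_x = cx + ax + 3.0 * s
            if bar_x + 2.5 * s > w - 1:
                raise GeometryError("scratching fixture outside frame")
            bar = 1.0 / (1.0 + np.exp((np.abs(np.arange(w) - bar_x) - 1.5 * s) / 0.5))
            bg = _composite(bg, np.broadcast_to(bar, (h, w)), 60.0)
            hx, hy, hax, hay = cx + ax - 2.0 * s, cy, 4.0 * s, 4.0 * s
        else:  # feeding: head bobbing at the leading end of a static body
            hx, hy, hax, hay = cx - ax + 1.0 * s, cy, 4.0 * s, 3.0 * s
        _check_bounds(cls.class_name, hx, hx, hy - amp, hy + amp, hax, hay, w, h)
        base = _composite(bg, _ellipse_alpha(h, w, cx, cy, ax, ay), body_i)
        for i in range(n):
            frames[i] = _composite(
                base, _ellipse_alpha(h, w, hx, hy + dy[i], hax, hay), head_i
            )

    elif kind == "translation":
        travel = speed * (n - 1)
        x0 = (w - travel) / 2.0 - 0  # centre the trajectory
        _check_bounds(cls.class_name, x0, x0 + travel, cy, cy, ax, ay, w, h)
        for i in range(n):
            frames[i] = _composite(
                bg, _ellipse_alpha(h, w, x0 + speed * i, cy, ax, ay), body_i
            )

    elif kind == "overlap_event":
        # object 1 rests low; object 2 approaches and rises onto it
        c1x, c1y = cx, cy + 3.0 * s
        a2x, a2y = 7.0 * s, 4.5 * s
        start = np.array([c1x - 20.0 * s, c1y + 6.0 * s])
        end = np.array([c1x - 3.0 * s, c1y - 6.0 * s])
        n_move = max(int(np.linalg.norm(end - start) / max(speed, 1e-9)), 1)
        frac = np.clip(t / n_move, 0.0, 1.0)
        path = start[None, :] + frac[:, None] * (end - start)[None, :]
        _check_bounds(cls.class_name, path[:, 0].min(), path[:, 0].max(),
                      path[:, 1].min(), path[:, 1].max(), a2x, a2y, w, h)
        base = _composite(bg, _ellipse_alpha(h, w, c1x, c1y, ax, ay), body_i)
        for i in range(n):
            frames[i] = _composite(
                base, _ellipse_alpha(h, w, path[i, 0], path[i, 1], a2x, a2y), head_i
            )

    if cls.noise_sd > 0:
        frames = frames + rng.normal(0.0, cls.noise_sd, size=frames.shape)
    rgb = np.clip(frames, 0, 255).astype(np.uint8)[..., None].repeat(3, axis=-1)
    return FrameSequence(rgb, fps=scene.fps)


def generate_dataset(
    specs: dict[str, SyntheticClassSpec] | None,
    scene: SceneSpec,
    n_per_class: int,
    out_dir,
    seed: int,
    codec: str = "rawvideo",
    overwrite: bool = False,
):
    """Write ``n_per_class`` clips per class plus a manifest CSV.

    Per-clip seeds are spawned from the master ``seed`` so the dataset is
    bit-reproducible.  Refuses to write into a non-empty directory unless
    ``overwrite`` is set.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    specs = specs or default_class_specs()
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} is not empty; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)

    ext = ".avi" if codec == "rawvideo" else ""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(CLASS_NAMES) * n_per_class)
    rows = []
    k = 0
    for cls_name in CLASS_NAMES:
        cls = specs[cls_name]
        for i in range(n_per_class):
            clip_seed = int(children[k].generate_state(1)[0] % (2**31))
            k += 1
            seq = generate_clip(cls, replace(scene, seed=clip_seed))
            rel = f"{cls_name}/clip_{i:04d}{ext}"
            write_clip(seq, out / rel, codec="rawvideo" if ext else "png")
            rows.append(
                {
                    "clip_path": rel,
                    "label": cls_name,
                    "n_frames": seq.n_frames,
                    "fps": seq.fps,
                    "duration_s": seq.duration_s,
                }
            )
    manifest = manifest_from_rows(rows)
    write_manifest(manifest, out / "manifest.csv")
    # return the manifest with paths resolved for immediate use
    resolved = manifest.copy()
    resolved["clip_path"] = [str(out / p) for p in resolved["clip_path"]]
    return resolved
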