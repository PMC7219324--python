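"""30-view inference aggregation and evaluation metrics.

Each test clip contributes 30 views (10 temporal windows x 3 spatial
crops).  The per-sample label is the argmax of the *mean* of the 30
per-view softmax vectors; *views accuracy* instead scores every view's
own argmax.  The confusion matrix rows are ground truth, columns
predictions, in the fixed class vocabulary order; the per-class rate is
the row-normalized diagonal (ground-truth-conditioned, i.e. per-class
recall).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .sampling import SamplingConfig, test_views
from .video_io import CLASS_NAMES, read_clip

__all__ = [
    "ViewPrediction",
    "EvalReport",
    "predict_sample",
    "evaluate",
    "metrics_from_confusion",
]


@dataclass
class ViewPrediction:
    """Per-view softmax scores (n_views x n_classes) and argmax labels."""

    scores: np.ndarray
    labels: np.ndarray = field(init=False)

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 2:
            raise ValueError("scores must be (n_views, n_classes)")
        if np.any(s < 0) or np.any(np.abs(s.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("each view score must be a softmax vector")
        self.scores = s
        self.labels = s.argmax(axis=1)


@dataclass
class EvalReport:
    """Aggregate metrics of one evaluation run."""

    top1_accuracy: float
    views_accuracy: float
    confusion: np.ndarray  # rows = ground truth, counts
    per_class_rate: np.ndarray  # row-normalized diagonal; NaN for empty rows
    class_names: tuple[str, ...] = CLASS_NAMES
    n_samples: int = 0
    failures: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "top1_accuracy_pct": round(100 * self.top1_accuracy, 2),
            "views_accuracy_pct": round(100 * self.views_accuracy, 2),
            "per_class_rate_pct": {
                c: (None if np.isnan(r) else round(100 * r, 2))
                for c, r in zip(self.class_names, self.per_class_rate)
            },
            "confusion": self.confusion.astype(int).tolist(),
            "class_names": list(self.class_names),
            "n_samples": self.n_samples,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def __str__(self) -> str:
        lines = [
            f"top-1 accuracy : {100 * self.top1_accuracy:6.2f}%",
            f"views accuracy : {100 * self.views_accuracy:6.2f}%",
            "confusion (rows = ground truth):",
        ]
        width = max(len(c) for c in self.class_names)
        header = " " * (width + 2) + " ".join(
            f"{c[:6]:>6}" for c in self.class_names
        )
        lines.append(header)
        for c, row, rate in zip(self.class_names, self.confusion,
                                self.per_class_rate):
            cells = " ".join(f"{int(v):6d}" for v in row)
            pct = "   n/a" if np.isnan(rate) else f"{100 * rate:6.2f}"
            lines.append(f"{c:>{width}}  {cells}  {pct}%")
        return "\n".join(lines)


def predict_sample(net, views, expected_views: int = 30):
    """Average the per-view softmax scores of one clip.

    Returns ``(label, mean_scores, ViewPrediction)``; argmax ties break
    toward the lowest class index.  Raises when the view count differs
    from the 30-view protocol.
    """
    view_list = views.views if hasattr(views, "views") else list(views)
    if len(view_list) != expected_views:
        raise ValueError(
            f"protocol expects {expected_views} views, got {len(view_list)}"
        )
    xs = np.stack([v.slow for v in view_list])
    xf = np.stack([v.fast for v in view_list])
    from .trainer import TrainConfig, _standardize

    cfg = TrainConfig()
    scores = net.predict_proba(_standardize(xs, cfg), _standardize(xf, cfg))
    vp = ViewPrediction(scores)
    mean = scores.mean(axis=0)
    return int(np.argmax(mean)), mean, vp


def evaluate(
    net,
    manifest,
    sampling: SamplingConfig | None = None,
) -> EvalReport:
    """Run the full multi-view protocol over a manifest.

    Top-1 accuracy scores the per-sample (view-averaged) labels; views
    accuracy scores all individual view argmaxes.  Unreadable clips are
    recorded as failures and excluded with a warning.
    """
    sampling = sampling or SamplingConfig()
    n_views = sampling.n_temporal_views * sampling.n_spatial_views
    k = len(CLASS_NAMES)
    confusion = np.zeros((k, k), dtype=np.int64)
    view_correct = view_total = 0
    failures: list[str] = []
    for _, row in manifest.iterrows():
        truth = CLASS_NAMES.index(row["label"])
        try:
            seq = read_clip(row["clip_path"])
        except Exception as exc:  # noqa: BLE001 - report and continue
            failures.append(str(row["clip_path"]))
            warnings.warn(f"skipping unreadable clip {row['clip_path']}: {exc}",
                          stacklevel=2)
            continue
        label, _, vp = predict_sample(net, test_views(seq, sampling), n_views)
        confusion[truth, label] += 1
        view_correct += int((vp.labels == truth).sum())
        view_total += len(vp.labels)
    top1, rates = metrics_from_confusion(confusion)
    return EvalReport(
        top1_accuracy=top1,
        views_accuracy=view_correct / view_total if view_total else float("nan"),
        confusion=confusion,
        per_class_rate=rates,
        n_samples=int(confusion.sum()),
        failures=failures,
    )


def metrics_from_confusion(confusion) -> tuple[float, np.ndarray]:
    """Top-1 accuracy (trace/total) and row-wise per-class rates.

    Rows summing to zero yield NaN as the undefined-rate marker.
    """
    c = np.asarray(confusion)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(c < 0) or not np.issubdtype(c.dtype, np.number):
        raise ValueError("confusion entries must be non-negative counts")
    total = c.sum()
    if total == 0:
        raise ValueError("confusion matrix has no entries")
    top1 = float(np.trace(c) / total)
    row_sums = c.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(row_sums > 0, np.diag(c) / row_sums, np.nan)
    return top1, rates
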