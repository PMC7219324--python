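"""View aggregation and metric computation against hand-tallied oracles."""

from __future__ import annotations

import numpy as np
import pytest

import sowfast as sf
from sowfast.evaluator import ViewPrediction, metrics_from_confusion
from sowfast.sampling import PathwayPair
from sowfast.video_io import CLASS_NAMES


class ScriptedNet:
    """Stand-in network: maps the mean input intensity to a fixed class.

    Intensity buckets are 32 units wide, so a clip rendered at constant
    value 32*k is always 'classified' as class k.
    """

    def predict_proba(self, xs, xf):
        # undo the training standardization to recover mean intensity
        mean = (xf.mean(axis=(1, 2, 3, 4)) * 0.225 + 0.45) * 255.0
        cls = np.clip((mean // 32).astype(int), 0, 4)
        out = np.full((len(cls), 5), 0.025)
        out[np.arange(len(cls)), cls] = 0.9
        return out


def make_views(scores_rng=None, n=30, value=128):
    frames = np.full((2, 8, 8, 3), value, dtype=np.uint8)
    fast = np.full((8, 8, 8, 3), value, dtype=np.uint8)
    return sf.ViewSet(views=[PathwayPair(slow=frames, fast=fast)] * n)


class TestPredictSample:
    def test_identical_views_mean_equals_single(self):
        net = ScriptedNet()
        label, mean, vp = sf.predict_sample(net, make_views(value=128))
        assert label == 128 // 32
        assert np.allclose(mean, vp.scores[0])

    def test_view_order_invariance(self):
        class PermutedNet(ScriptedNet):
            def predict_proba(self, xs, xf):
                base = np.tile(np.eye(5), (6, 1))  # 30 x 5
                return base

        net = PermutedNet()
        views = make_views()
        label1, mean1, _ = sf.predict_sample(net, views)

        class ShuffledNet(ScriptedNet):
            def predict_proba(self, xs, xf):
                base = np.tile(np.eye(5), (6, 1))
                return base[np.random.default_rng(0).permutation(30)]

        label2, mean2, _ = sf.predict_sample(ShuffledNet(), views)
        assert label1 == label2
        assert np.allclose(mean1, mean2)

    def test_known_vectors_against_bruteforce_mean(self, rng):
        raw = rng.random((30, 5))
        scores = raw / raw.sum(axis=1, keepdims=True)

        class FixedNet:
            def predict_proba(self, xs, xf):
                return scores

        label, mean, vp = sf.predict_sample(FixedNet(), make_views())
        want_mean = sum(scores[i] for i in range(30)) / 30  # brute force
        assert np.allclose(mean, want_mean)
        assert label == int(np.argmax(want_mean))
        assert np.array_equal(vp.labels, scores.argmax(axis=1))

    def test_wrong_view_count_rejected(self):
        with pytest.raises(ValueError, match="protocol"):
            sf.predict_sample(ScriptedNet(), make_views(n=29))

    def test_tie_breaks_toward_lowest_index(self):
        class TieNet:
            def predict_proba(self, xs, xf):
                return np.full((30, 5), 0.2)

        label, _, _ = sf.predict_sample(TieNet(), make_views())
        assert label == 0

    def test_invalid_scores_rejected(self):
        with pytest.raises(ValueError, match="softmax"):
            ViewPrediction(np.full((30, 5), 0.5))


@pytest.fixture(scope="module")
def scripted_eval(tmp_path_factory):
    """Six constant-intensity clips whose scripted predictions are known:
    ground truth (0,1,2,3,4,0) vs predictions (0,1,2,3,3,1)."""
    out = tmp_path_factory.mktemp("eval")
    rows = []
    intensities = [0, 32, 64, 96, 96 + 0, 32]  # class 4 mislabeled as 3, etc.
    truths = [0, 1, 2, 3, 4, 0]
    for i, (val, truth) in enumerate(zip(intensities, truths)):
        frames = np.full((20, 32, 32, 3), val, dtype=np.uint8)
        path = out / f"clip{i}.avi"
        sf.write_clip(sf.FrameSequence(frames), path)
        rows.append(
            {
                "clip_path": str(path),
                "label": CLASS_NAMES[truth],
                "n_frames": 20,
                "fps": 25.0,
                "duration_s": 0.8,
            }
        )
    from sowfast.video_io import manifest_from_rows

    return manifest_from_rows(rows)


class TestEvaluate:
    def test_report_matches_hand_tally(self, scripted_eval, micro_sampling):
        report = sf.evaluate(ScriptedNet(), scripted_eval, micro_sampling)
        # hand tally: predictions (0,1,2,3,3,1) vs truth (0,1,2,3,4,0)
        assert report.n_samples == 6
        assert report.top1_accuracy == pytest.approx(4 / 6)
        assert report.views_accuracy == pytest.approx(4 / 6)
        want = np.zeros((5, 5), dtype=int)
        for t, p in [(0, 0), (1, 1), (2, 2), (3, 3), (4, 3), (0, 1)]:
            want[t, p] += 1
        assert np.array_equal(report.confusion, want)
        # internal consistency: metrics recomputed from the matrix agree
        top1, rates = metrics_from_confusion(report.confusion)
        assert top1 == report.top1_accuracy
        assert rates[0] == pytest.approx(0.5)

    def test_unreadable_clip_excluded_with_warning(self, scripted_eval,
                                                   micro_sampling, tmp_path):
        broken = scripted_eval.copy()
        bad = tmp_path / "missing.avi"
        broken.loc[0, "clip_path"] = str(bad)
        with pytest.warns(UserWarning, match="skipping"):
            report = sf.evaluate(ScriptedNet(), broken, micro_sampling)
        assert report.n_samples == 5
        assert report.failures == [str(bad)]


class TestMetricsFromConfusion:
    def test_identity_matrix_is_perfect(self):
        top1, rates = metrics_from_confusion(np.eye(5, dtype=int) * 7)
        assert top1 == 1.0
        assert np.allclose(rates, 1.0)

    def test_constant_predictor_on_balanced_classes(self):
        c = np.zeros((5, 5), dtype=int)
        c[:, 2] = 10  # everything predicted as class 2
        top1, rates = metrics_from_confusion(c)
        assert top1 == pytest.approx(0.2)
        assert rates[2] == 1.0 and rates[0] == 0.0

    def test_empty_row_marked_undefined(self):
        c = np.zeros((3, 3), dtype=int)
        c[0, 0] = 4
        top1, rates = metrics_from_confusion(c)
        assert top1 == 1.0
        assert np.isnan(rates[1]) and np.isnan(rates[2])

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            metrics_from_confusion(np.array([[1, -1], [0, 2]]))

    def test_report_serialization(self):
        report = sf.EvalReport(
            top1_accuracy=0.5,
            views_accuracy=0.25,
            confusion=np.eye(5, dtype=int),
            per_class_rate=np.ones(5),
            n_samples=5,
        )
        d = report.to_dict()
        assert d["top1_accuracy_pct"] == 50.0
        assert "feeding" in str(report) or "feeding" in d["per_class_rate_pct"]
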