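"""Clip round trips, manifest statistics and stratified splitting."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sowfast as sf
from sowfast.video_io import CLASS_NAMES, manifest_from_rows


def random_clip(rng, n=64, h=48, w=64, fps=25.0):
    frames = rng.integers(0, 256, (n, h, w, 3), dtype=np.uint8)
    return sf.FrameSequence(frames, fps=fps)


def make_manifest(counts, n_frames=64, fps=25.0):
    rows = []
    for cls, k in zip(CLASS_NAMES, counts):
        for i in range(k):
            rows.append(
                {
                    "clip_path": f"{cls}/c{i}.avi",
                    "label": cls,
                    "n_frames": n_frames,
                    "fps": fps,
                    "duration_s": n_frames / fps,
                }
            )
    return manifest_from_rows(rows)


class TestClipIO:
    def test_avi_round_trip_is_identity(self, rng, tmp_path):
        seq = random_clip(rng)
        path = sf.write_clip(seq, tmp_path / "clip.avi")
        back = sf.read_clip(path)
        assert back.n_frames == 64
        assert back.fps == 25.0
        assert np.array_equal(back.frames, seq.frames)

    def test_single_frame_clip(self, rng, tmp_path):
        seq = random_clip(rng, n=1)
        back = sf.read_clip(sf.write_clip(seq, tmp_path / "one.avi"))
        assert back.n_frames == 1

    def test_container_duration_one_frame_tolerance(self, rng, tmp_path):
        seq = random_clip(rng, n=64, fps=25.0)
        back = sf.read_clip(sf.write_clip(seq, tmp_path / "d.avi"))
        assert abs(back.duration_s - 2.56) <= 1 / 25.0

    def test_png_directory_round_trip(self, rng, tmp_path):
        seq = random_clip(rng, n=50)
        d = sf.write_clip(seq, tmp_path / "frames", codec="png")
        back = sf.read_clip(d)
        assert back.n_frames == 50
        assert back.fps == 25.0  # caller-supplied default for directories
        assert np.array_equal(back.frames, seq.frames)
        assert sf.read_clip(d, fps=30.0).fps == 30.0

    def test_empty_directory_raises(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(ValueError, match="no image frames"):
            sf.read_clip(tmp_path / "empty")

    def test_unreadable_file_raises(self, tmp_path):
        bad = tmp_path / "bad.avi"
        bad.write_bytes(b"this is not a RIFF container")
        with pytest.raises(ValueError, match="not a RIFF"):
            sf.read_clip(bad)


class TestManifest:
    def test_summarize_counts_and_total_duration(self):
        m = make_manifest([2, 2, 2, 2, 2])
        stats = sf.summarize_manifest(m)
        assert all(stats.class_counts[c] == 2 for c in CLASS_NAMES)
        assert stats.total_duration_s == pytest.approx(10 * 64 / 25, abs=1e-9)
        assert stats.n_clips == 10

    def test_single_class_leaves_others_at_zero(self):
        m = make_manifest([0, 3, 0, 0, 0])
        stats = sf.summarize_manifest(m)
        assert stats.class_counts["lying"] == 3
        assert sum(stats.class_counts.values()) == 3

    def test_balanced_five_by_200(self):
        m = make_manifest([200] * 5)
        stats = sf.summarize_manifest(m)
        assert tuple(stats.class_counts.values()) == (200,) * 5

    def test_total_duration_equals_row_sum(self, rng):
        lengths = rng.integers(20, 200, 25)
        rows = [
            {
                "clip_path": f"c{i}.avi",
                "label": CLASS_NAMES[i % 5],
                "n_frames": int(n),
                "fps": 25.0,
                "duration_s": n / 25.0,
            }
            for i, n in enumerate(lengths)
        ]
        stats = sf.summarize_manifest(manifest_from_rows(rows))
        assert stats.total_duration_s == pytest.approx(
            float(lengths.sum() / 25.0), abs=1e-9
        )

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="vocabulary"):
            manifest_from_rows(
                [
                    {
                        "clip_path": "x.avi",
                        "label": "sleeping",
                        "n_frames": 10,
                        "fps": 25.0,
                        "duration_s": 0.4,
                    }
                ]
            )

    def test_csv_round_trip_resolves_relative_paths(self, tmp_path):
        m = make_manifest([1, 1, 1, 1, 1])
        path = sf.write_manifest(m, tmp_path / "m.csv")
        back = sf.read_manifest(path)
        assert len(back) == 5
        assert all(str(tmp_path) in p for p in back["clip_path"])


class TestStratifiedSplit:
    def test_published_partition_sizes(self):
        # 789 rows in a 158/157/158/158/158 pattern, split 4:1:1
        m = make_manifest([158, 157, 158, 158, 158])
        subsets = sf.stratified_split(m, [4 / 6, 1 / 6, 1 / 6], seed=0)
        assert [len(s) for s in subsets] == [529, 130, 130]

    def test_identity_fraction(self):
        m = make_manifest([3, 3, 3, 3, 3])
        (only,) = sf.stratified_split(m, [1.0], seed=5)
        assert sorted(only["clip_path"]) == sorted(m["clip_path"])

    def test_deterministic_and_seed_sensitive(self):
        m = make_manifest([20, 20, 20, 20, 20])
        a1 = sf.stratified_split(m, [0.5, 0.5], seed=3)
        a2 = sf.stratified_split(m, [0.5, 0.5], seed=3)
        b = sf.stratified_split(m, [0.5, 0.5], seed=4)
        for s1, s2 in zip(a1, a2):
            pd.testing.assert_frame_equal(s1, s2)
        assert sorted(b[0]["clip_path"]) != sorted(a1[0]["clip_path"])
        assert [len(s) for s in b] == [len(s) for s in a1]

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        counts=st.lists(st.integers(3, 40), min_size=5, max_size=5),
        n_parts=st.integers(2, 3),
        seed=st.integers(0, 1000),
    )
    def test_partition_is_exact(self, counts, n_parts, seed):
        """Subsets are disjoint and their union equals the input."""
        m = make_manifest(counts)
        fracs = [1.0 / n_parts] * n_parts
        subsets = sf.stratified_split(m, fracs, seed)
        paths = [p for s in subsets for p in s["clip_path"]]
        assert len(paths) == len(m)
        assert sorted(paths) == sorted(m["clip_path"])

    def test_too_few_rows_raises(self):
        m = make_manifest([1, 3, 3, 3, 3])
        with pytest.raises(ValueError, match="fewer than"):
            sf.stratified_split(m, [0.5, 0.5], seed=0)

    def test_arbitrary_size_split(self):
        m = make_manifest([200] * 5)
        test1, train = sf.video_io.random_split(m, 211, seed=0)
        assert len(test1) == 211 and len(train) == 789
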