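"""Shared fixtures: micro networks and small synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

import sowfast as sf


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def micro_spec():
    """Smallest structurally complete architecture (for 32-px inputs)."""
    return sf.reduced_arch_spec()


@pytest.fixture()
def micro_net(micro_spec):
    net = sf.build_network(micro_spec)
    sf.init_weights(net, seed=7)
    return net


@pytest.fixture(scope="session")
def micro_sampling():
    """16-frame windows, 32-px crops: the smallest geometry the stride
    pyramid admits."""
    return sf.SamplingConfig(
        window_len=16, train_crop=32, train_scale=32, test_scale=32
    )


def make_inputs(rng, batch=2, t_slow=2, t_fast=8, size=32):
    xs = rng.normal(0, 1, (batch, 3, t_slow, size, size)).astype(np.float32)
    xf = rng.normal(0, 1, (batch, 3, t_fast, size, size)).astype(np.float32)
    return xs, xf


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """3 clips per class at 64x64, written once per test session."""
    out = tmp_path_factory.mktemp("synth")
    scene = sf.SceneSpec(width=64, height=64, n_frames=64, fps=25)
    manifest = sf.generate_dataset(None, scene, 3, out, seed=99)
    return manifest
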