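"""Architecture construction, shape accounting and network properties."""

from __future__ import annotations

import numpy as np
import pytest

import sowfast as sf
from sowfast import nn
from sowfast.model import make_arch_spec, reduced_arch_spec, stage_output_shapes

from conftest import make_inputs


class TestArchSpec:
    def test_depth34_configuration(self):
        spec = make_arch_spec("pmb-scn-34")
        assert [s.n_blocks for s in spec.slow_stages] == [3, 4, 6, 3]
        assert spec.slow_stages[-1].channels == 1024
        assert spec.fast_stages[-1].channels == 128
        assert spec.slow_conv1_channels == 64
        assert spec.fast_conv1_channels == 8

    def test_depth18_block_counts(self):
        spec = make_arch_spec("pmb-scn-18")
        assert [s.n_blocks for s in spec.slow_stages] == [2, 2, 2, 2]
        assert [s.channels for s in spec.slow_stages] == [128, 256, 512, 1024]

    def test_halfwidth_fast_channels(self):
        spec = make_arch_spec("pmb-scn-34half")
        assert [s.channels for s in spec.slow_stages] == [64, 128, 256, 512]
        assert spec.fast_stages[0].channels == 8  # 64 / 8

    def test_temporal_kernel_placement(self):
        spec = make_arch_spec("pmb-scn-34")
        # slow: spatial-only in res2/res3, spatiotemporal in res4/res5
        assert [s.layer1_kernel[0] for s in spec.slow_stages] == [1, 1, 3, 3]
        # fast: spatiotemporal everywhere; layer2 always spatial-only
        assert all(s.layer1_kernel[0] == 3 for s in spec.fast_stages)
        assert all(s.layer2_kernel[0] == 1 for s in spec.slow_stages)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown variant"):
            make_arch_spec("pmb-scn-50")

    def test_yaml_round_trip(self):
        import yaml

        spec = make_arch_spec("pmb-scn-18")
        back = sf.ArchSpec.from_dict(yaml.safe_load(yaml.safe_dump(spec.to_dict())))
        assert back == spec


class TestShapeAccounting:
    def test_single_conv_parameter_count(self):
        conv = nn.Conv3d(4, 8, (3, 3, 3))
        assert sum(p.size for p in conv.params()) == 864  # 27 * 4 * 8

    def test_half_resolution_input(self):
        table = stage_output_shapes(make_arch_spec("pmb-scn-34"),
                                    (8, 112, 112), (32, 112, 112))
        assert table["res5"]["slow"] == (8, 4, 4)

    def test_temporal_extent_never_changes(self):
        table = stage_output_shapes(make_arch_spec("pmb-scn-18"))
        assert all(v["slow"][0] == 8 for v in table.values())
        assert all(v["fast"][0] == 32 for v in table.values())

    def test_too_small_input_raises(self):
        with pytest.raises(ValueError, match="too small"):
            stage_output_shapes(make_arch_spec("pmb-scn-34"), (8, 8, 8),
                                (32, 8, 8))

    def test_arithmetic_matches_actual_activations(self, micro_net, rng):
        """Dual route: the stride-arithmetic table must agree with the
        shapes the instantiated network actually produces."""
        xs, xf = make_inputs(rng, batch=1, size=64)
        micro_net.forward(xs, xf)
        table = stage_output_shapes(micro_net.spec, (2, 64, 64), (8, 64, 64))
        for stage in ("res2", "res3", "res4", "res5"):
            assert micro_net.stage_activations[stage]["slow"] == table[stage]["slow"]
            assert micro_net.stage_activations[stage]["fast"] == table[stage]["fast"]


class TestNetworkProperties:
    def test_classifier_width_is_concatenated_pathways(self, micro_net):
        spec = micro_net.spec
        assert micro_net.fc.weight.value.shape == (
            spec.n_classes,
            spec.slow_stages[-1].channels + spec.fast_stages[-1].channels,
        )

    def test_logits_width_and_batch_independence(self, micro_net, rng):
        xs, xf = make_inputs(rng, batch=8, size=32)
        full = micro_net.forward(xs, xf)
        assert full.shape == (8, micro_net.spec.n_classes)
        single = micro_net.forward(xs[:1], xf[:1])
        assert np.allclose(full[0], single[0], atol=1e-5)

    def test_zeroed_classifier_gives_uniform_softmax(self, micro_net, rng):
        micro_net.fc.weight.value[...] = 0
        micro_net.fc.bias.value[...] = 0
        xs, xf = make_inputs(rng, batch=2, size=32)
        proba = micro_net.predict_proba(xs, xf)
        assert np.allclose(proba, 0.2)

    def test_eval_forward_deterministic(self, micro_net, rng):
        xs, xf = make_inputs(rng, batch=2, size=32)
        a = micro_net.forward(xs, xf)
        b = micro_net.forward(xs, xf)
        assert np.array_equal(a, b)

    def test_project_sum_keeps_slow_shape(self, rng):
        """In project_sum mode lateral fusion must not change the slow
        tensor shape, so both fusion modes share the shape table."""
        spec = reduced_arch_spec(fusion="project_sum")
        net = sf.build_network(spec)
        sf.init_weights(net, 3)
        xs, xf = make_inputs(rng, batch=1, size=32)
        logits = net.forward(xs, xf)
        assert logits.shape == (1, 5)
        table = stage_output_shapes(spec, (2, 32, 32), (8, 32, 32))
        for stage in ("res2", "res3", "res4", "res5"):
            assert net.stage_activations[stage]["slow"] == table[stage]["slow"]

    def test_concat_has_more_parameters_than_project_sum_saves(self):
        # concat widens the next slow stage; project_sum pays for the
        # projection instead — the two counts must differ
        c = sf.count_parameters(sf.build_network(reduced_arch_spec()))
        p = sf.count_parameters(
            sf.build_network(reduced_arch_spec(fusion="project_sum"))
        )
        assert c != p

    def test_every_parameter_receives_gradient(self, micro_net, rng):
        """No dead branches: each trainable tensor gets a nonzero
        gradient on at least one of a few random batches."""
        micro_net.dropout.rate = 0.0  # isolate architecture connectivity
        touched = {id(p): False for p in micro_net.params()}
        for trial in range(3):
            xs, xf = make_inputs(rng, batch=4, size=32)
            micro_net.zero_grad()
            logits = micro_net.forward(xs, xf, training=True)
            _, dl = nn.cross_entropy(logits, np.array([0, 1, 2, 3]))
            micro_net.backward(dl)
            for p in micro_net.params():
                if np.any(p.grad != 0):
                    touched[id(p)] = True
        assert all(touched.values())

    def test_checkpoint_round_trip(self, micro_net, rng, tmp_path):
        xs, xf = make_inputs(rng, batch=2, size=32)
        want = micro_net.forward(xs, xf)
        path = sf.save_checkpoint(micro_net, tmp_path / "ck.npz",
                                  extra={"epoch": 3})
        net2, extra = sf.load_checkpoint(path)
        assert extra["epoch"] == 3
        assert np.array_equal(net2.forward(xs, xf), want)
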