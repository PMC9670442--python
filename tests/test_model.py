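"""Network topology, shapes, and forward-pass contracts."""

import numpy as np
import pytest

from cardiov.experiments import TINY_DEEP_CONFIG
from cardiov.model import (
    CardioVNet,
    ModelConfig,
    count_layers,
    load_checkpoint,
    save_checkpoint,
)
from cardiov.nn import Tensor


class TestConfig:
    def test_default_is_the_seven_stage_topology(self):
        cfg = ModelConfig()
        assert cfg.stage_channels == (64, 160, 160, 400, 400, 1024, 1024)
        assert cfg.stage_blocks == (2, 2, 2, 3, 3, 4, 4)
        assert cfg.output_dim == 3

    @pytest.mark.parametrize("head,dim", [("ordinal", 3),
                                          ("classification", 4),
                                          ("regression", 1)])
    def test_head_output_dims(self, head, dim):
        assert ModelConfig(head=head).output_dim == dim

    def test_channels_must_divide_groups(self):
        with pytest.raises(ValueError):
            ModelConfig(stage_channels=(30,), stage_blocks=(1,), groups=16)

    def test_round_trips_through_dict(self):
        cfg = ModelConfig(stage_channels=(16,), stage_blocks=(2,), groups=4)
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg


class TestLayerCount:
    @pytest.mark.parametrize("blocks,expected", [
        ((1,), 4),
        ((1, 1), 7),
        ((2, 2, 2, 3, 3, 4, 4), 61),
    ])
    def test_three_convs_per_block_plus_dense(self, blocks, expected):
        cfg = ModelConfig(stage_channels=(8,) * len(blocks),
                          stage_blocks=blocks, groups=4, se_reduction=4,
                          kernel_size=8)
        net = CardioVNet(cfg, seed=0)
        assert count_layers(net) == expected == 3 * sum(blocks) + 1

    def test_counted_layers_enumerate_main_path_modules(self, tiny_deep_net):
        n_convs = sum(3 for stage in tiny_deep_net.stages for _ in stage)
        assert count_layers(tiny_deep_net) == n_convs + 1


class TestForward:
    def test_stage_lengths_follow_floor_halving(self, tiny_deep_net):
        capture = {}
        tiny_deep_net.eval()
        out = tiny_deep_net.forward(np.zeros((2, 12, 1000), dtype=np.float32),
                                    capture=capture)
        length = 1000
        for s in range(1, 8):
            length //= 2
            assert capture[f"stage{s}"].shape[2] == length
        assert out.shape == (2, 3)

    def test_finite_logits_on_zero_input(self, tiny_deep_net):
        tiny_deep_net.eval()
        z = tiny_deep_net.forward(np.zeros((1, 12, 256), dtype=np.float32))
        assert np.isfinite(z.data).all()

    def test_eval_forward_is_deterministic(self, tiny_deep_net):
        x = np.random.default_rng(0).normal(size=(2, 12, 256)).astype("f4")
        tiny_deep_net.eval()
        z1 = tiny_deep_net.forward(x).data
        z2 = tiny_deep_net.forward(x).data
        assert np.array_equal(z1, z2)

    def test_wrong_lead_count_rejected(self, tiny_deep_net):
        with pytest.raises(ValueError):
            tiny_deep_net.forward(np.zeros((1, 3, 256)))

    def test_too_short_input_rejected(self, tiny_deep_net):
        with pytest.raises(ValueError):
            tiny_deep_net.forward(np.zeros((1, 12, 64)))

    def test_gradient_reaches_the_input(self, tiny_deep_net):
        x = Tensor(np.random.default_rng(1).normal(size=(1, 12, 256)),
                   requires_grad=True)
        tiny_deep_net.eval()
        tiny_deep_net.forward(x)[0, 0].backward()
        assert x.grad is not None and np.abs(x.grad).max() > 0


class TestSqueezeExcite:
    def test_gate_is_per_channel_and_bounded(self, rng):
        from cardiov.nn import SqueezeExcite, relu, sigmoid

        se = SqueezeExcite(8, reduction=4, rng=rng)
        x = rng.normal(size=(2, 8, 16))
        gate = sigmoid(se.fc2(relu(se.fc1(Tensor(x).mean(axis=2))))).data
        assert gate.shape == (2, 8)
        assert ((gate > 0) & (gate < 1)).all()
        out = se(Tensor(x)).data
        assert np.allclose(out, x * gate[:, :, None])

    def test_saturated_gate_is_identity(self, rng):
        from cardiov.nn import SqueezeExcite

        se = SqueezeExcite(4, reduction=2, rng=rng)
        se.fc2.bias.data[:] = 60.0  # sigmoid -> 1
        se.fc2.weight.data[:] = 0.0
        x = rng.normal(size=(1, 4, 10))
        assert np.allclose(se(Tensor(x)).data, x, atol=1e-7)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path):
        cfg = ModelConfig(stage_channels=(8,), stage_blocks=(1,), groups=4,
                          se_reduction=4, kernel_size=8)
        net = CardioVNet(cfg, seed=3)
        x = np.random.default_rng(5).normal(size=(2, 12, 64)).astype("f4")
        net.eval()
        before = net.forward(x).data
        path = save_checkpoint(net, tmp_path / "ckpt.npz")
        restored = load_checkpoint(path)
        restored.eval()
        assert np.allclose(restored.forward(x).data, before, atol=1e-6)

    def test_head_swap_changes_output_width(self):
        cfg = ModelConfig(stage_channels=(8,), stage_blocks=(1,), groups=4,
                          se_reduction=4, kernel_size=8)
        net = CardioVNet(cfg, seed=0)
        net.set_head("classification", seed=1)
        net.eval()
        assert net.forward(np.zeros((1, 12, 64), dtype="f4")).shape == (1, 4)
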