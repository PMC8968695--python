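"""Architecture contracts: shape algebra, attention-gate behavior, and the
equivalence of a degenerate R2P block with a plain double-conv block."""

import numpy as np
import pytest

from renalseg.errors import ConfigurationError
from renalseg.nn import (AttentionGate, NetworkConfig, R2PBlock,
                         R2PBlockConfig, Tensor, build_network, conv2d,
                         leaky_relu, load_checkpoint, save_checkpoint,
                         softmax)


def block_cfg(**kw):
    defaults = dict(kernel_sizes=(3,), recurrence_steps=0, dropout_rate=0.0)
    defaults.update(kw)
    return R2PBlockConfig(**defaults)


class TestR2PBlock:
    def test_output_shape_contract(self, rng):
        blk = R2PBlock(32, 64, block_cfg(recurrence_steps=2), rng)
        blk.eval()
        y = blk(Tensor(rng.normal(size=(1, 32, 16, 16))))
        assert y.shape == (1, 64, 16, 16)

    def test_parallel_branches_concatenate_before_projection(self, rng):
        blk = R2PBlock(4, 8, block_cfg(kernel_sizes=(3, 5)), rng)
        assert blk.project is not None
        assert blk.project.weight.shape == (8, 16, 1, 1)  # 2 branches x 8

    def test_degenerate_block_equals_plain_double_conv(self, rng):
        # t=0, one kernel, residual projection zeroed, no batchnorm:
        # the block must reproduce conv -> act -> conv -> act exactly
        cfg = block_cfg(use_batchnorm=False)
        blk = R2PBlock(3, 5, cfg, rng)
        blk.residual.weight.data[:] = 0.0
        blk.residual.bias.data[:] = 0.0
        x = Tensor(rng.normal(size=(2, 3, 8, 8)))
        got = blk(x).data

        u1, u2 = blk.branches[0].unit1, blk.branches[0].unit2
        h = leaky_relu(conv2d(x, u1.conv_in.weight, u1.conv_in.bias),
                       cfg.leaky_slope)
        h = leaky_relu(conv2d(h, u2.conv_in.weight, u2.conv_in.bias),
                       cfg.leaky_slope)
        assert np.array_equal(got, h.data)

    def test_recurrence_changes_output(self, rng):
        x = np.random.default_rng(0).normal(size=(1, 2, 8, 8))
        outs = []
        for t in (0, 2):
            blk = R2PBlock(2, 4, block_cfg(recurrence_steps=t),
                           np.random.default_rng(7))
            blk.eval()
            outs.append(blk(Tensor(x)).data)
        assert not np.allclose(outs[0], outs[1])


class TestAttentionGate:
    def test_output_shape_and_map_range(self, rng):
        gate = AttentionGate(8, 16, 0.01, rng)
        x = Tensor(rng.normal(size=(2, 8, 16, 16)))
        g = Tensor(rng.normal(size=(2, 16, 8, 8)))
        out = gate(x, g)
        assert out.shape == x.shape
        amap = gate.attention_map(x, g).data
        assert amap.shape == (2, 1, 16, 16)
        assert np.all((amap > 0) & (amap < 1))

    def test_zeroed_final_projection_halves_x_exactly(self, rng):
        gate = AttentionGate(6, 12, 0.01, rng)
        gate.psi.weight.data[:] = 0.0
        gate.psi.bias.data[:] = 0.0
        x = Tensor(rng.normal(size=(1, 6, 8, 8)))
        g = Tensor(rng.normal(size=(1, 12, 4, 4)))
        out = gate(x, g).data
        assert np.array_equal(out, 0.5 * x.data)  # logistic(0) = 0.5

    def test_incompatible_sizes_rejected(self, rng):
        gate = AttentionGate(6, 12, 0.01, rng)
        with pytest.raises(ValueError):
            gate(Tensor(np.zeros((1, 6, 16, 16))),
                 Tensor(np.zeros((1, 12, 16 // 3, 16 // 3))))


class TestLeakyRelu:
    @pytest.mark.parametrize("v, slope, expected", [
        (3.0, 0.01, 3.0),
        (-2.0, 0.01, -0.02),
        (-5.0, 1e-9, pytest.approx(0.0, abs=1e-6)),
    ])
    def test_values(self, v, slope, expected):
        out = leaky_relu(Tensor(np.array([v])), slope).data[0]
        assert out == expected


class TestNetwork:
    @pytest.mark.parametrize("depth, side", [(4, 8), (5, 4), (6, 2)])
    def test_bottleneck_side_for_input_128(self, depth, side):
        cfg = NetworkConfig(input_size=128, depth=depth, base_filters=1,
                            n_classes=2, block=block_cfg())
        assert cfg.bottleneck_side == side
        net = build_network(cfg, seed=0)
        # verify the actual deepest feature map side by tracing the encoder
        x = Tensor(np.zeros((1, 1, 128, 128), dtype=np.float32))
        h = x
        from renalseg.nn.autodiff import maxpool2x2
        for enc in net.encoders:
            h = maxpool2x2(enc(h))
        assert net.bottleneck(h).shape[2:] == (side, side)

    def test_indivisible_input_rejected(self):
        with pytest.raises(ConfigurationError):
            NetworkConfig(input_size=100, depth=4, base_filters=2,
                          n_classes=2, block=block_cfg())

    def test_forward_softmax_and_shape(self, rng):
        cfg = NetworkConfig(input_size=32, depth=2, base_filters=2,
                            n_classes=3, block=block_cfg())
        net = build_network(cfg, seed=1)
        probs = net.predict(rng.normal(size=(2, 1, 32, 32)).astype(np.float32))
        assert probs.shape == (2, 3, 32, 32)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_per_sample_purity(self, rng):
        cfg = NetworkConfig(input_size=32, depth=2, base_filters=2,
                            n_classes=2, block=block_cfg())
        net = build_network(cfg, seed=1)
        x = rng.normal(size=(1, 1, 32, 32)).astype(np.float32)
        batch = np.concatenate([x, x, rng.normal(
            size=(1, 1, 32, 32)).astype(np.float32)])
        p = net.predict(batch)
        assert np.allclose(p[0], p[1], atol=1e-6)

    def test_parameter_count_deterministic(self):
        cfg = NetworkConfig(input_size=32, depth=2, base_filters=4,
                            n_classes=2, block=block_cfg(kernel_sizes=(3, 5)))
        a = build_network(cfg, seed=3)
        b = build_network(cfg, seed=4)
        assert a.n_parameters() == b.n_parameters()
        c = build_network(cfg, seed=3)
        assert all(np.array_equal(p.data, q.data)
                   for p, q in zip(a.parameters(), c.parameters()))

    def test_wrong_spatial_size_rejected(self, rng):
        cfg = NetworkConfig(input_size=32, depth=2, base_filters=2,
                            n_classes=2, block=block_cfg())
        net = build_network(cfg, seed=0)
        with pytest.raises(ValueError):
            net(Tensor(np.zeros((1, 1, 16, 16), dtype=np.float32)))

    def test_checkpoint_round_trip(self, tmp_path, rng):
        cfg = NetworkConfig(input_size=16, depth=2, base_filters=2,
                            n_classes=3, block=block_cfg())
        net = build_network(cfg, seed=5)
        x = rng.normal(size=(1, 1, 16, 16)).astype(np.float32)
        before = net.predict(x)
        save_checkpoint(tmp_path / "m.npz", net)
        loaded = load_checkpoint(tmp_path / "m.npz")
        assert loaded.cfg == cfg
        assert np.allclose(loaded.predict(x), before, atol=1e-7)
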