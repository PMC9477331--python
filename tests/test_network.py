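"""Gating arithmetic, gradient correctness, and the asymmetric forward
contract of the channel-gated encoder-decoder."""

import numpy as np
import pytest

from nucseg.network import (
    FGDCNet,
    NetworkConfig,
    channel_average_pool,
    fgdc_state,
    gate_from_previous,
    layer_input_info,
    resblock_apply,
)
from nucseg.training import combined_loss, combined_loss_grad


def tiny_config(**kw):
    defaults = dict(depth=2, base_channels=3, label_size=8, seed=1, dtype="float64")
    defaults.update(kw)
    return NetworkConfig(**defaults)


class TestGatingOps:
    def test_average_pool_constant_and_arithmetic(self):
        const = np.full((4, 4, 3), 2.5)
        assert np.allclose(channel_average_pool(const), 2.5)
        small = np.array([[1.0, 2.0], [3.0, 4.0]])[..., None]
        assert channel_average_pool(small)[0] == pytest.approx(2.5)

    def test_average_pool_linearity(self):
        rng = np.random.default_rng(0)
        f, g = rng.random((5, 5, 4)), rng.random((5, 5, 4))
        assert np.allclose(
            channel_average_pool(f + g),
            channel_average_pool(f) + channel_average_pool(g),
        )

    def test_info_zero_weights_give_half(self):
        ap = np.array([1.0, -2.0, 3.0])
        i = layer_input_info(ap, np.zeros((3, 3)), np.zeros(3))
        assert np.allclose(i, 0.5)

    def test_info_saturates_with_large_bias(self):
        ap = np.zeros(2)
        w = np.zeros((2, 2))
        prev = layer_input_info(ap, w, np.zeros(2))
        for bias in (2.0, 5.0, 20.0):
            cur = layer_input_info(ap, w, np.full(2, bias))
            assert np.all(cur > prev)
            prev = cur
        assert np.all(prev > 1 - 1e-6)

    def test_info_scalar_hand_value(self):
        i = layer_input_info(np.array([2.0]), np.array([[0.5]]), np.array([-0.25]))
        assert i[0] == pytest.approx(1 / (1 + np.exp(-0.75)))

    def test_gate_dimension_rules(self):
        s32 = np.full(32, 0.5)
        g = gate_from_previous(s32, np.zeros((32, 64)), np.zeros(64), "encoding")
        assert g.shape == (64,)
        s64 = np.full(64, 0.5)
        g = gate_from_previous(s64, np.zeros((64, 32)), np.zeros(32), "decoding")
        assert g.shape == (32,)
        assert np.allclose(g, 0.5)

    def test_gate_rejects_wrong_kernel_shape(self):
        with pytest.raises(ValueError, match="gate kernel"):
            gate_from_previous(np.full(32, 0.5), np.zeros((32, 32)), np.zeros(32), "encoding")

    def test_state_product_and_bounds(self):
        g = np.full(4, 0.5)
        i = np.full(4, 0.5)
        assert np.allclose(fgdc_state(g, i), 0.25)
        rng = np.random.default_rng(1)
        g, i = rng.uniform(0.01, 0.99, 8), rng.uniform(0.01, 0.99, 8)
        s = fgdc_state(g, i)
        assert np.all(s <= np.minimum(g, i))
        assert np.all((s > 0) & (s < 1))

    def test_state_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            fgdc_state(np.zeros(3), np.zeros(4))

    def test_resblock_dead_weights_reduce_to_relu(self):
        rng = np.random.default_rng(2)
        f = rng.normal(size=(6, 6, 4))
        z33 = np.zeros((3, 3, 4, 4))
        out = resblock_apply(f, np.full(4, 0.7), z33, np.zeros(4), z33, np.zeros(4))
        assert np.allclose(out, np.maximum(f, 0))

    def test_resblock_zero_state_reduces_to_relu(self):
        rng = np.random.default_rng(3)
        f = rng.normal(size=(5, 5, 2))
        k1 = rng.normal(size=(3, 3, 2, 2))
        k2 = rng.normal(size=(3, 3, 2, 2))
        out = resblock_apply(f, np.zeros(2), k1, rng.normal(size=2), k2, rng.normal(size=2))
        assert np.allclose(out, np.maximum(f, 0))

    def test_resblock_scalar_hand_composition(self):
        # 1x1 feature, 1 channel, 3x3 kernels with only the center tap set
        f = np.array([[[2.0]]])
        k1 = np.zeros((3, 3, 1, 1)); k1[1, 1, 0, 0] = 0.5
        k2 = np.zeros((3, 3, 1, 1)); k2[1, 1, 0, 0] = -1.0
        b1, b2 = np.array([0.25]), np.array([0.1])
        s = np.array([0.8])
        # a = 0.5*2 + 0.25 = 1.25 ; fhat = -1*1.25 + 0.1 = -1.15
        # out = relu(-1.15*0.8 + 2) = 1.08
        out = resblock_apply(f, s, k1, b1, k2, b2)
        assert out[0, 0, 0] == pytest.approx(1.08)


class TestForwardContract:
    def test_output_shape_and_range(self):
        cfg = NetworkConfig(depth=3, base_channels=4, label_size=48, seed=0)
        net = FGDCNet(cfg)
        x = np.random.default_rng(0).random((2, 96, 96, 3))
        y = net.forward(x)
        assert y.shape == (2, 48, 48)
        assert np.all((y > 0) & (y < 1))

    def test_wrong_input_side_rejected(self):
        net = FGDCNet(tiny_config())
        with pytest.raises(ValueError, match="shape"):
            net.forward(np.zeros((1, 12, 12, 3)))

    def test_seeded_instantiations_bit_stable(self):
        cfg = tiny_config()
        x = np.random.default_rng(5).random((1, 16, 16, 3))
        y1 = FGDCNet(cfg).forward(x)
        y2 = FGDCNet(cfg).forward(x)
        assert np.array_equal(y1, y2)

    def test_channel_states_in_unit_interval(self):
        net = FGDCNet(tiny_config(depth=2))
        x = np.random.default_rng(6).normal(size=(3, 16, 16, 3)) * 10
        net.forward(x)
        for s in net.last_states:
            assert np.all((s > 0) & (s < 1))

    def test_state_ablation_reduces_to_plain_encoder_decoder(self):
        """With every channel state forced to 0, each gated block passes
        ReLU(F): the network degenerates to stem/pool/up/head convs plus
        plain rectifications — computed here independently from the same
        weights."""
        cfg = tiny_config(depth=2)
        net = FGDCNet(cfg)
        x = np.random.default_rng(7).normal(size=(2, 16, 16, 3))
        got = net.forward(x, state_override=0.0)

        f = net.stem.forward(x.astype(np.float64))
        for l in range(cfg.depth):
            for _ in net.enc_blocks[l]:
                f = np.maximum(f, 0)
            if l < cfg.depth - 1:
                f = net.pools[l].forward(f)
                f = net.downs[l].forward(f)
        for idx in range(len(net.ups)):
            f = net.ups[idx].forward(f)
            for _ in net.dec_blocks[idx]:
                f = np.maximum(f, 0)
        logits = net.head.forward(f)[..., 0]
        probs = 1 / (1 + np.exp(-logits))
        half = cfg.label_size // 2
        expected = probs[:, half : half + cfg.label_size, half : half + cfg.label_size]
        assert np.allclose(got, expected)


class TestGradients:
    def test_finite_difference_check(self):
        net = FGDCNet(tiny_config())
        rng = np.random.default_rng(0)
        x = rng.random((2, 16, 16, 3))
        y = (rng.random((2, 8, 8)) > 0.5).astype(float)

        preds = net.forward(x)
        _, dpred = combined_loss_grad(preds, y)
        for p in net.params():
            p.zero_grad()
        net.backward(dpred)

        def loss_value():
            out = net.forward(x)
            net._cache = None
            return combined_loss(out, y)

        eps = 1e-6
        check_rng = np.random.default_rng(1)
        for param in net.params():
            flat = param.value.ravel()
            grad = param.grad.ravel()
            for idx in check_rng.choice(flat.size, size=min(3, flat.size), replace=False):
                old = flat[idx]
                flat[idx] = old + eps
                up = loss_value()
                flat[idx] = old - eps
                down = loss_value()
                flat[idx] = old
                numeric = (up - down) / (2 * eps)
                analytic = grad[idx]
                assert numeric == pytest.approx(analytic, abs=1e-7, rel=1e-4)

    def test_every_weight_tensor_receives_gradient(self):
        net = FGDCNet(tiny_config(depth=3, label_size=8, base_channels=2))
        rng = np.random.default_rng(2)
        x = rng.random((4, 16, 16, 3))
        y = (rng.random((4, 8, 8)) > 0.5).astype(float)
        preds = net.forward(x)
        _, dpred = combined_loss_grad(preds, y)
        for p in net.params():
            p.zero_grad()
        net.backward(dpred)
        dead = [p.name for p in net.params() if np.abs(p.grad).max() == 0.0]
        assert dead == [], f"dead branches: {dead}"


class TestParameterCount:
    @staticmethod
    def expected_count(cfg: NetworkConfig) -> int:
        def conv(k, cin, cout):
            return k * k * cin * cout + cout

        def dense(cin, cout):
            return cin * cout + cout

        chans = [cfg.base_channels * 2 ** l for l in range(cfg.depth)]
        total = conv(3, 3, chans[0])  # stem
        for l, c in enumerate(chans):
            total += dense(c, c)  # info kernel
            if l > 0:
                total += dense(chans[l - 1], c)  # encoding gate: 2*C_{l-1}
            total += cfg.blocks_per_level * 2 * conv(3, c, c)
            if l < cfg.depth - 1:
                total += conv(1, c, chans[l + 1])  # channel-doubling 1x1
        for l in range(cfg.depth - 2, -1, -1):
            c = chans[l]
            total += conv(2, chans[l + 1], c)  # transposed conv
            total += dense(c, c)  # info
            total += dense(chans[l + 1], c)  # decoding gate: C_{l-1}/2
            total += cfg.blocks_per_level * 2 * conv(3, c, c)
        total += conv(1, chans[0], 1)  # head
        return total

    @pytest.mark.parametrize(
        "cfg,frozen",
        [
            (NetworkConfig(depth=2, base_channels=4, label_size=8), 3997),
            (NetworkConfig(depth=3, base_channels=8, label_size=48), 66825),
        ],
    )
    def test_count_matches_closed_form_and_frozen_value(self, cfg, frozen):
        net = FGDCNet(cfg)
        assert net.num_params() == self.expected_count(cfg) == frozen
        assert str(frozen) in net.summary()


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path):
        cfg = tiny_config()
        net = FGDCNet(cfg)
        x = np.random.default_rng(3).random((1, 16, 16, 3))
        before = net.forward(x)
        path = tmp_path / "ckpt.npz"
        net.save(path)
        loaded = FGDCNet.load(path)
        assert loaded.config == cfg
        assert np.allclose(loaded.forward(x), before)


class TestConfigValidation:
    def test_indivisible_input_side(self):
        with pytest.raises(ValueError, match="divisible"):
            NetworkConfig(depth=4, base_channels=4, label_size=6)

    def test_odd_label_size(self):
        with pytest.raises(ValueError, match="even"):
            NetworkConfig(label_size=47)
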