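import numpy as np
import pytest

from omsas.acrnet import (ACRNet, ACRNetConfig, AttentionCondenser,
                          CondenserConfig, ReservationBlock, ResidualUnit,
                          RetractingBlock, apply_attention, build_acrnet,
                          channel_excite, channel_squeeze, count_parameters,
                          default_config, tiny_config)

RNG = np.random.default_rng(0)


class TestAttentionPrimitive:
    def test_squeeze_constant_channel(self):
        m = np.full((3, 4, 4), 0.0)
        m[1] = 7.0
        np.testing.assert_allclose(channel_squeeze(m), [0.0, 7.0, 0.0])

    def test_squeeze_1x1_spatial(self):
        m = RNG.random((5, 1, 1))
        np.testing.assert_allclose(channel_squeeze(m), m[:, 0, 0])

    def test_squeeze_hand_example(self):
        m = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        np.testing.assert_allclose(channel_squeeze(m), [2.5])

    def test_excite_zero_weights_give_half(self):
        e = channel_excite(np.array([1.0, -2.0]),
                           np.zeros((1, 2)), np.zeros((2, 1)))
        np.testing.assert_allclose(e, 0.5)

    def test_excite_hand_example(self):
        # 1 channel: sigmoid(relu(2*3)) = sigmoid(6)
        e = channel_excite([3.0], [[2.0]], [[1.0]])
        np.testing.assert_allclose(e, 1 / (1 + np.exp(-6.0)))

    def test_excite_range_open_unit_interval(self):
        rng = np.random.default_rng(3)
        e = channel_excite(rng.normal(size=4), rng.normal(size=(2, 4)),
                           rng.normal(size=(4, 2)))
        assert np.all(e > 0) and np.all(e < 1)

    def test_excite_shape_mismatch(self):
        with pytest.raises(ValueError):
            channel_excite([1.0, 2.0], np.zeros((1, 3)), np.zeros((2, 1)))

    @pytest.mark.parametrize("gate,factor", [(1.0, 1.0), (0.0, 0.0), (0.5, 0.5)])
    def test_apply_attention_scales_channels(self, gate, factor):
        m = RNG.random((2, 3, 3))
        out = apply_attention(m, np.array([gate, 1.0]))
        np.testing.assert_allclose(out[0], factor * m[0])
        np.testing.assert_allclose(out[1], m[1])


class TestBlocks:
    def test_reservation_shape_and_sign(self):
        block = ReservationBlock(8, 16, np.random.default_rng(1))
        y = block.forward(RNG.random((2, 8, 32, 32)))
        assert y.shape == (2, 16, 32, 32)
        assert y.min() >= 0.0

    def test_reservation_parameter_audit(self):
        block = ReservationBlock(8, 16, np.random.default_rng(1))
        # conv weights + conv bias + norm scale + norm offset
        assert count_parameters(block) == 8 * 16 + 16 + 2 * 16

    def test_retracting_shape(self):
        block = RetractingBlock(16, 32, np.random.default_rng(1))
        y = block.forward(RNG.random((1, 16, 32, 32)))
        assert y.shape == (1, 32, 32, 32)

    def test_retracting_parameter_audit_vs_full_conv(self):
        block = RetractingBlock(16, 32, np.random.default_rng(1))
        weights = 9 * 16 + 16 * 32          # depthwise + pointwise kernels
        biases = 16 + 32
        assert count_parameters(block) == weights + biases
        assert weights == 656               # far below 9*16*32 = 4608
        for c_in, c_out in [(4, 2), (8, 8), (3, 64)]:
            separable = 9 * c_in + c_in * c_out
            full = 9 * c_in * c_out
            if c_out >= 2:
                assert separable < full

    def test_residual_unit_identity_at_init(self):
        """With the branch's final norm scale zero-initialised the unit
        reduces to ReLU(x) at construction time."""
        unit = ResidualUnit(4, 4, np.random.default_rng(2))
        x = RNG.normal(size=(1, 4, 8, 8))
        np.testing.assert_allclose(unit.forward(x), np.maximum(x, 0.0))

    def test_residual_unit_shape_preserved(self):
        unit = ResidualUnit(4, 4, np.random.default_rng(2))
        x = RNG.random((2, 4, 8, 8))
        assert unit.forward(x).shape == x.shape

    def test_residual_gradient_reaches_input(self):
        unit = ResidualUnit(4, 4, np.random.default_rng(2))
        x = RNG.random((1, 4, 8, 8)) + 0.1
        y = unit.forward(x)
        gx = unit.backward(np.ones_like(y))
        assert np.isfinite(gx).all() and np.abs(gx).sum() > 0


class TestAttentionCondenser:
    def test_output_shape_equals_input(self):
        for c, h, w in [(4, 8, 8), (6, 16, 12)]:
            cond = AttentionCondenser(c, CondenserConfig(ratio=2),
                                      np.random.default_rng(1))
            x = RNG.random((2, c, h, w))
            assert cond.forward(x).shape == x.shape

    def test_never_amplifies(self):
        cond = AttentionCondenser(8, CondenserConfig(ratio=4),
                                  np.random.default_rng(1))
        x = RNG.normal(size=(2, 8, 8, 8))
        y = cond.forward(x)
        assert (np.abs(y) <= np.abs(x) + 1e-12).all()

    def test_zero_weights_halve_the_input(self):
        cond = AttentionCondenser(4, CondenserConfig(ratio=2),
                                  np.random.default_rng(1))
        for p in cond.params():
            p.value[...] = 0.0
        x = RNG.random((1, 4, 8, 8))
        np.testing.assert_allclose(cond.forward(x), 0.5 * x)

    def test_parameter_count_decreases_as_ratio_doubles(self):
        counts = [count_parameters(
            AttentionCondenser(64, CondenserConfig(ratio=r),
                               np.random.default_rng(0)))
            for r in (1, 2, 4, 8, 16)]
        assert counts == sorted(counts, reverse=True)
        assert len(set(counts)) == len(counts)


def closed_form_count(cfg: ACRNetConfig) -> int:
    """Independent parameter audit summed block by block."""
    def conv1x1(ci, co):
        return ci * co + co

    def ln(c):
        return 2 * c

    def reservation(ci, co):
        return conv1x1(ci, co) + ln(co)

    def retracting(ci, co):
        return 9 * ci + ci + conv1x1(ci, co)

    def residual(ci, co):
        total = retracting(ci, co) + ln(co) + retracting(co, co) + ln(co)
        if ci != co:
            total += conv1x1(ci, co)
        return total

    def condenser(c, ratio):
        b = max(1, c // ratio)
        return conv1x1(c, b) + (9 * b + b) + conv1x1(b, b) + conv1x1(b, c)

    widths = cfg.stage_widths
    total = reservation(1, widths[0])
    for i, w in enumerate(widths):
        total += cfg.units_per_stage * residual(w, w)
        total += condenser(w, cfg.condenser_ratio)
        if i < len(widths) - 1:
            total += reservation(w, widths[i + 1])
    for i in range(len(widths) - 2, -1, -1):
        total += reservation(widths[i + 1] + widths[i], widths[i])
        total += residual(widths[i], widths[i])
    total += conv1x1(widths[0], 1)
    return total


class TestNetwork:
    def test_forward_contract_tiny(self):
        model = build_acrnet(tiny_config(seed=0))
        y = model.forward(RNG.random((2, 1, 64, 64)))
        assert y.shape == (2, 1, 64, 64)
        assert y.min() >= 0.0 and y.max() <= 1.0

    def test_parameter_count_matches_closed_form_audit(self):
        for cfg in [tiny_config(),
                    ACRNetConfig(input_size=(64, 64), stage_widths=(8, 16, 32),
                                 units_per_stage=1, condenser_ratio=4),
                    default_config()]:
            model = build_acrnet(cfg)
            assert count_parameters(model) == closed_form_count(cfg)

    def test_default_budget_under_6_91_million(self):
        assert count_parameters(build_acrnet(default_config())) <= 6.91e6

    def test_forward_deterministic(self):
        model = build_acrnet(tiny_config(seed=5))
        x = RNG.random((1, 1, 64, 64))
        np.testing.assert_array_equal(model.forward(x), model.forward(x))

    def test_same_seed_same_weights(self):
        a = build_acrnet(tiny_config(seed=9))
        b = build_acrnet(tiny_config(seed=9))
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ACRNetConfig(stage_widths=(8,))
        with pytest.raises(ValueError):
            ACRNetConfig(input_size=(60, 60))  # not divisible by pooling
        with pytest.raises(ValueError):
            ACRNetConfig(units_per_stage=0)

    def test_checkpoint_round_trip(self, tmp_path):
        model = build_acrnet(tiny_config(seed=2))
        x = RNG.random((1, 1, 64, 64))
        before = model.forward(x)
        path = tmp_path / "ckpt.npz"
        model.save(path)
        restored = ACRNet.load(path)
        np.testing.assert_array_equal(restored.forward(x), before)
        assert restored.config == model.config
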