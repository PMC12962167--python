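"""Network structure, counting, determinism, serialization and gradients."""

import numpy as np
import pytest

from hbpnet import (NetConfig, apply_attention, build_model, count_macs,
                    count_parameters, layer_table, summary)
from hbpnet.nn.layers import BatchNorm3d, Conv3d, ConvTranspose3d
from hbpnet.training import bce_loss, bce_loss_grad


def enumeration_oracle_params(widths, head, stem_k=75, enc_k=27,
                              dec_ks=(27, 75, 125, 25), up_ks=(4, 27, 8, 4),
                              head_ks=(25, 25, 27, 27, 1)):
    """Independent layer-by-layer parameter enumeration (kept deliberately
    separate from the production counting code)."""
    w1, w2, w3, w4 = widths
    h1, h2, h3, h4, h5 = head
    total = 0

    def conv(cin, cout, kvol, bn=True, bias=False):
        return cin * cout * kvol + (cout if bias else 0) + (2 * cout if bn else 0)

    total += conv(3, w1, stem_k)
    total += conv(w1, w2, enc_k) + conv(w2, w3, enc_k) + conv(w3, w4, enc_k)
    total += w4 * w3 * up_ks[0] + w3          # transposed convs carry biases
    total += conv(2 * w3, w3, dec_ks[0])
    total += w3 * w2 * up_ks[1] + w2
    total += conv(2 * w2, w2, dec_ks[1])
    total += w2 * w1 * up_ks[2] + w1
    total += conv(2 * w1, w1, dec_ks[2])
    total += w1 * 3 * up_ks[3] + 3
    total += conv(6, 3, dec_ks[3])
    total += conv(3, h1, head_ks[0]) + conv(h1, h2, head_ks[1]) \
        + conv(h2, h3, head_ks[2])
    total += conv(h3, h4, head_ks[3], bn=False, bias=True)
    total += conv(h4, h5, head_ks[4], bn=False, bias=True)
    return total


class TestCounting:
    def test_reduced_width_count_matches_enumeration_oracle(self):
        cfg = NetConfig(stage_widths=(2, 4, 8, 16), head_widths=(2, 4, 8, 4, 1),
                        input_dims=(16, 16, 16))
        assert count_parameters(cfg) == enumeration_oracle_params(
            (2, 4, 8, 16), (2, 4, 8, 4, 1))

    def test_instantiated_model_matches_analytic_count(self, tiny_config,
                                                       tiny_model):
        assert tiny_model.n_parameters() == count_parameters(tiny_config)

    def test_parameter_count_independent_of_input_dims(self):
        a = NetConfig(input_dims=(128, 128, 128))
        b = NetConfig(input_dims=(160, 128, 128))
        assert count_parameters(a) == count_parameters(b)

    def test_macs_linear_in_temporal_length(self):
        cfg = NetConfig(input_dims=(128, 128, 128))
        m128 = count_macs(cfg, (128, 128, 128))
        m160 = count_macs(cfg, (160, 128, 128))
        m64 = count_macs(cfg, (64, 128, 128))
        assert m160 * 128 == m128 * 160
        assert m64 * 2 == m128

    def test_summary_lists_every_stage(self):
        text = summary(NetConfig(input_dims=(128, 128, 128)))
        for name in ("enc1", "enc4", "up3", "dec1", "head1", "tail2", "total"):
            assert name in text


class TestConfigValidation:
    def test_temporal_length_must_divide_pool_product(self):
        with pytest.raises(ValueError, match="divisible"):
            NetConfig(input_dims=(130, 128, 128))

    def test_spatial_dims_must_divide_pool_product(self):
        with pytest.raises(ValueError, match="divisible"):
            NetConfig(input_dims=(128, 100, 100))

    def test_head_must_end_in_one_channel(self):
        with pytest.raises(ValueError):
            NetConfig(head_widths=(12, 24, 48, 24, 2))


class TestForward:
    def test_output_in_unit_interval_with_length_T(self, tiny_model, rng):
        x = rng.uniform(0, 1, (2, 3, 8, 16, 16)).astype(np.float32)
        hbp, a_st = tiny_model.forward(x)
        assert hbp.shape == (2, 8)
        assert hbp.min() >= 0 and hbp.max() <= 1
        assert a_st.shape == x.shape
        assert a_st.min() >= 0 and a_st.max() <= 1

    def test_evaluation_mode_is_bit_deterministic(self, tiny_model, rng):
        x = rng.uniform(0, 1, (1, 3, 8, 16, 16)).astype(np.float32)
        a, _ = tiny_model.forward(x)
        b, _ = tiny_model.forward(x)
        np.testing.assert_array_equal(a, b)

    def test_same_seed_same_initialization(self, tiny_config, rng):
        m1 = build_model(tiny_config, seed=5)
        m2 = build_model(tiny_config, seed=5)
        for p, q in zip(m1.params(), m2.params()):
            np.testing.assert_array_equal(p.value, q.value)

    def test_shape_mismatch_rejected(self, tiny_model, rng):
        x = rng.uniform(0, 1, (1, 3, 8, 8, 8)).astype(np.float32)
        with pytest.raises(ValueError, match="input"):
            tiny_model.forward(x)

    def test_zero_clip_zeroes_enhanced_features(self):
        # X* = X * A_st vanishes with the input regardless of attention
        a = np.random.default_rng(0).uniform(0, 1, (2, 3, 4, 4, 4))
        assert np.all(apply_attention(np.zeros_like(a), a) == 0)

    def test_attention_identity_and_scaling(self):
        x = np.full((1, 3, 2, 2, 2), 0.5)
        assert np.all(apply_attention(x, np.ones_like(x)) == x)
        np.testing.assert_allclose(apply_attention(x, np.full_like(x, 0.4)),
                                   0.2)
        with pytest.raises(ValueError):
            apply_attention(x, np.ones((1, 3, 2, 2, 1)))


class TestSerialization:
    def test_checkpoint_round_trips_bit_exactly(self, tiny_config, rng,
                                                tmp_path):
        m = build_model(tiny_config, seed=3)
        x = rng.uniform(0, 1, (1, 3, 8, 16, 16)).astype(np.float32)
        ref, _ = m.forward(x)
        path = tmp_path / "ckpt.npz"
        m.save(path)
        loaded = m.load(path)
        out, _ = loaded.forward(x)
        np.testing.assert_array_equal(ref, out)
        for p, q in zip(m.params(), loaded.params()):
            np.testing.assert_array_equal(p.value, q.value)


class TestGradients:
    def test_conv_backward_is_exact_adjoint(self, rng):
        """<conv(x), dy> == <x, conv^T(dy)> and the weight gradient matches
        the directional derivative, for both GEMM and FFT execution paths."""
        for kernel, stride in [((3, 3, 3), (1, 1, 1)), ((1, 5, 5), (1, 2, 2)),
                               ((5, 5, 5), (1, 1, 1))]:
            c = Conv3d(3, 4, kernel, stride)
            c.init(np.random.default_rng(0))
            x = rng.standard_normal((2, 3, 8, 12, 12)).astype(np.float32)
            y = c.forward(x, training=True)
            dy = rng.standard_normal(y.shape).astype(np.float32)
            c.weight.grad[...] = 0
            dx = c.backward(dy)
            lhs = float((y.astype(np.float64) * dy).sum())
            rhs = float((x.astype(np.float64) * dx).sum())
            assert lhs == pytest.approx(rhs, rel=1e-4)
            v = rng.standard_normal(c.weight.value.shape).astype(np.float32)
            c2 = Conv3d(3, 4, kernel, stride)
            c2.weight.value[...] = v
            lhs_w = float((c.weight.grad.astype(np.float64) * v).sum())
            rhs_w = float((c2.forward(x).astype(np.float64) * dy).sum())
            assert lhs_w == pytest.approx(rhs_w, rel=1e-4)

    def test_transposed_conv_backward_is_exact_adjoint(self, rng):
        for kernel, stride, pad, opad in [((1, 2, 2), (1, 2, 2), 0, 0),
                                          ((3, 3, 3), (2, 2, 2), 1, 1)]:
            c = ConvTranspose3d(4, 3, kernel, stride, pad, opad, bias=False)
            c.init(np.random.default_rng(0))
            x = rng.standard_normal((2, 4, 4, 6, 6)).astype(np.float32)
            y = c.forward(x, training=True)
            dy = rng.standard_normal(y.shape).astype(np.float32)
            c.weight.grad[...] = 0
            dx = c.backward(dy)
            lhs = float((y.astype(np.float64) * dy).sum())
            rhs = float((x.astype(np.float64) * dx).sum())
            assert lhs == pytest.approx(rhs, rel=1e-4)

    def test_batchnorm_gradients_match_finite_differences(self, rng):
        bn = BatchNorm3d(3)
        bn.init(np.random.default_rng(0))
        bn.gamma.value[...] = rng.uniform(0.5, 1.5, 3).astype(np.float32)
        x = rng.standard_normal((2, 3, 4, 5, 5)).astype(np.float32)
        c = rng.standard_normal(x.shape).astype(np.float32)

        def loss():
            return float((bn.forward(x, True).astype(np.float64) * c).sum())

        loss()
        bn.gamma.grad[...] = 0
        bn.beta.grad[...] = 0
        bn.forward(x, True)
        bn.backward(c)
        eps = 1e-3
        for arr, grad in [(bn.gamma.value, bn.gamma.grad),
                          (bn.beta.value, bn.beta.grad)]:
            for i in range(arr.size):
                old = arr[i]
                arr[i] = old + eps
                up = loss()
                arr[i] = old - eps
                down = loss()
                arr[i] = old
                fd = (up - down) / (2 * eps)
                assert fd == pytest.approx(float(grad[i]), rel=0.05, abs=1e-3)

    def test_every_parameter_group_receives_gradient(self, tiny_config, rng):
        """No dead branch: with random weights and one batch, every
        parameter group's gradient is nonzero at initialization."""
        m = build_model(tiny_config, seed=2)
        x = rng.uniform(0, 1, (2, 3, 8, 16, 16)).astype(np.float32)
        y = rng.uniform(0.05, 0.95, (2, 8))
        m.zero_grad()
        pred, _ = m.forward(x, training=True)
        m.backward(bce_loss_grad(y, pred.astype(np.float64)).astype(np.float32))
        for p in m.params():
            assert np.abs(p.grad).sum() > 0, f"dead gradient in {p.name}"

    def test_end_to_end_gradient_matches_finite_differences(self, tiny_config,
                                                            rng):
        """Spot-check full-network backprop against central differences on
        well-conditioned coordinates (float32 forward noise and ReLU kinks
        rule out tight agreement on near-zero gradients)."""
        m = build_model(tiny_config, seed=3)
        x = rng.uniform(0, 1, (2, 3, 8, 16, 16)).astype(np.float32)
        y = rng.uniform(0.05, 0.95, (2, 8))

        def loss():
            pred, _ = m.forward(x, training=True)
            return bce_loss(y, np.clip(pred, 0, 1))

        m.zero_grad()
        loss()
        pred, _ = m.forward(x, training=True)
        m.backward(bce_loss_grad(y, pred.astype(np.float64)).astype(np.float32))
        eps = 3e-3
        checked = 0
        r = np.random.default_rng(0)
        nums, anas = [], []
        for p in m.params():
            flat = p.value.reshape(-1)
            gflat = p.grad.reshape(-1)
            for i in r.integers(0, flat.size, size=min(3, flat.size)):
                old = flat[i]
                flat[i] = old + eps
                up = loss()
                flat[i] = old - eps
                down = loss()
                flat[i] = old
                nums.append((up - down) / (2 * eps))
                anas.append(float(gflat[i]))
                checked += 1
        nums, anas = np.asarray(nums), np.asarray(anas)
        assert checked > 50
        assert np.corrcoef(nums, anas)[0, 1] > 0.995
        big = np.abs(nums) > 2e-3
        assert big.sum() >= 10
        np.testing.assert_allclose(anas[big], nums[big], rtol=0.2)
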