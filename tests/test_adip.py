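"""Log-power transform, purification attention, gating, and fusion."""

import numpy as np
import pytest

from eedcl.adip import (ADIPBlock, ADIPConfig, ADIPStage, LayerFusion,
                        gated_residual, log_power)
from eedcl.nn import Tensor


class TestLogPower:
    def test_constant_input_closed_form(self):
        x = Tensor(np.full((1, 6, 3), 2.0))
        out = log_power(x, w=3, eps=1e-8).data
        np.testing.assert_allclose(out, np.log(4.0 + 1e-8), rtol=1e-9)

    def test_zero_input_is_log_eps(self):
        out = log_power(Tensor(np.zeros((1, 4, 2))), w=2, eps=1e-8).data
        np.testing.assert_allclose(out, np.log(1e-8))
        assert np.isfinite(out).all()

    def test_full_window_alternating_signal(self):
        a = 1.7
        sig = a * np.resize([1.0, -1.0], 8)
        x = Tensor(sig[None, :, None])
        out = log_power(x, w=8, eps=1e-8).data
        np.testing.assert_allclose(out, np.log(a * a + 1e-8), rtol=1e-7)

    def test_shape_preserved_and_window_clamped(self):
        x = Tensor(np.random.default_rng(0).normal(size=(2, 5, 4)))
        with pytest.warns(UserWarning):
            out = log_power(x, w=50)
        assert out.shape == x.shape


class TestAttend:
    def make_block(self, dim=4, seed=0):
        return ADIPBlock(dim, ADIPConfig(), np.random.default_rng(seed))

    def test_rows_sum_to_one_nonnegative(self, rng):
        block = self.make_block()
        block.attend(Tensor(rng.normal(size=(2, 6, 4))))
        attn = block.last_attention
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-6)
        assert (attn >= 0).all()

    def test_identical_tokens_uniform_attention(self):
        block = self.make_block()
        x = Tensor(np.tile(np.array([1.0, 2.0, -1.0, 0.5]), (1, 5, 1)))
        block.attend(x)
        np.testing.assert_allclose(block.last_attention, 1.0 / 5, atol=1e-6)

    def test_two_token_hand_computed_softmax(self):
        block = self.make_block(dim=2)
        block.wq.weight.data = np.eye(2, dtype=np.float32)
        block.wk.weight.data = np.eye(2, dtype=np.float32)
        block.wv.weight.data = np.eye(2, dtype=np.float32)
        x = np.array([[[1.0, 0.0], [0.0, 1.0]]])
        out = block.attend(Tensor(x)).data
        s = np.exp(1 / np.sqrt(2)) + np.exp(0)
        a_same = np.exp(1 / np.sqrt(2)) / s
        expected_attn = np.array([[a_same, 1 - a_same],
                                  [1 - a_same, a_same]])
        np.testing.assert_allclose(block.last_attention[0], expected_attn,
                                   atol=1e-6)
        np.testing.assert_allclose(out[0], expected_attn @ x[0], atol=1e-6)

    def test_nan_input_rejected(self):
        block = self.make_block()
        bad = np.zeros((1, 3, 4))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            block.attend(Tensor(bad))

    def test_token_permutation_equivariance(self, rng):
        block = self.make_block()
        x = rng.normal(size=(1, 6, 4))
        base = block.attend(Tensor(x)).data
        perm = np.array([3, 1, 5, 0, 2, 4])
        out = block.attend(Tensor(x[:, perm])).data
        np.testing.assert_allclose(out, base[:, perm], atol=1e-6)


class TestGatedResidual:
    def setup_method(self):
        rng = np.random.default_rng(2)
        self.f_attn = Tensor(rng.normal(size=(2, 4, 3)))
        self.f_power = Tensor(rng.normal(size=(2, 4, 3)))

    def test_gate_saturation_high(self):
        out = gated_residual(self.f_attn, self.f_power,
                             Tensor(np.full(3, 1e3)))
        np.testing.assert_allclose(out.data, self.f_attn.data, atol=1e-6)

    def test_gate_saturation_low(self):
        out = gated_residual(self.f_attn, self.f_power,
                             Tensor(np.full(3, -1e3)))
        np.testing.assert_allclose(out.data, self.f_power.data, atol=1e-6)

    def test_zero_gate_midpoint(self):
        out = gated_residual(self.f_attn, self.f_power, Tensor(np.zeros(3)))
        np.testing.assert_allclose(
            out.data, (self.f_attn.data + self.f_power.data) / 2, atol=1e-9)

    @pytest.mark.parametrize("gate", [-5.0, -1.0, 0.0, 1.3, 8.0])
    def test_convex_combination_bounds(self, gate):
        out = gated_residual(self.f_attn, self.f_power,
                             Tensor(np.full(3, gate))).data
        lo = np.minimum(self.f_attn.data, self.f_power.data)
        hi = np.maximum(self.f_attn.data, self.f_power.data)
        assert (out >= lo - 1e-9).all() and (out <= hi + 1e-9).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gated_residual(self.f_attn, Tensor(np.zeros((2, 5, 3))),
                           Tensor(np.zeros(3)))


try:
    from hypothesis import given, settings, strategies as st

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(gate=st.floats(min_value=-20, max_value=20,
                          allow_nan=False),
           seed=st.integers(min_value=0, max_value=2 ** 16))
    def test_gated_residual_always_convex(gate, seed):
        """For any gate logit, the refined map lies elementwise between
        the attended and power maps."""
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(1, 3, 4))
        p = rng.normal(size=(1, 3, 4))
        out = gated_residual(Tensor(a), Tensor(p),
                             Tensor(np.full(4, gate))).data
        assert (out >= np.minimum(a, p) - 1e-9).all()
        assert (out <= np.maximum(a, p) + 1e-9).all()
except ImportError:        # hypothesis is an optional test dependency
    pass


class TestFusion:
    def test_unit_weights_plain_sum(self, rng):
        fusion = LayerFusion()
        a = Tensor(rng.normal(size=(1, 4, 3)))
        b = Tensor(rng.normal(size=(1, 4, 3)))
        np.testing.assert_allclose(fusion(a, b).data, a.data + b.data,
                                   atol=1e-7)

    def test_beta_zero_medium_only(self, rng):
        fusion = LayerFusion()
        fusion.beta.data = np.array(0.0, dtype=np.float32)
        a = Tensor(rng.normal(size=(1, 4, 3)))
        b = Tensor(rng.normal(size=(1, 4, 3)))
        np.testing.assert_allclose(fusion(a, b).data, a.data, atol=1e-7)

    def test_cancellation(self, rng):
        fusion = LayerFusion()
        a = Tensor(rng.normal(size=(1, 4, 3)))
        np.testing.assert_allclose(fusion(a, Tensor(-a.data)).data, 0.0,
                                   atol=1e-6)


class TestDenseApplication:
    def test_refined_maps_exist_per_layer(self, rng):
        """Every hierarchical layer yields one refined medium and one
        refined fine map (2L in total)."""
        from eedcl.model import EEDModel, desk_config

        cfg = desk_config(n_channels=4, window_samples=256)
        model = EEDModel(cfg, 0).eval()
        x = rng.normal(size=(2, 4, 256)).astype(np.float32)
        model(x)
        assert len(model.attention_records()) == 2 * cfg.n_layers

    def test_dip_mode_skips_attention(self, rng):
        block = ADIPBlock(4, ADIPConfig(mode="dip"), rng)
        x = Tensor(np.full((1, 6, 4), 2.0))
        out = block(x)
        np.testing.assert_allclose(out.data, np.log(4.0 + 1e-8), rtol=1e-6)
        assert block.last_attention is None
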