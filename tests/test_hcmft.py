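"""Hierarchical layer branches and the multiscale gated linear attention."""

import numpy as np
import pytest

from eedcl.hcmft import (CoarseBranch, FineBranch, HCTLayer, MGLAConfig,
                         MediumBranch, _pool_tokens, mg_la)
from eedcl.nn import Tensor


def saturated_gates(dim, n_scales=1, sign=1.0):
    return Tensor(np.full((n_scales, dim), sign * 1e4))


def brute_force_qkv(q, k, v):
    """Triple-loop oracle for Q (K^T V) on a single (n, d) instance."""
    n, d = q.shape
    kv = np.zeros((d, d))
    for i in range(n):
        for a in range(d):
            for b in range(d):
                kv[a, b] += k[i, a] * v[i, b]
    out = np.zeros((n, d))
    for i in range(n):
        for b in range(d):
            for a in range(d):
                out[i, b] += q[i, a] * kv[a, b]
    return out


class TestMGLA:
    def test_single_scale_identity_phi_matches_brute_force(self):
        """MG-LA at S=1 with saturated gates and identity linearization
        must equal the explicit triple-loop Q(KᵀV) on random instances."""
        cfg = MGLAConfig(n_scales=1, scale_windows=(1,), phi="identity")
        worst = 0.0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            q, k, v = (rng.normal(size=(3, 2)) for _ in range(3))
            out = mg_la(Tensor(q[None]), Tensor(k[None]), Tensor(v[None]),
                        saturated_gates(2), cfg).data[0]
            ref = brute_force_qkv(q, k, v)
            worst = max(worst, np.abs(out - ref).max() /
                        max(np.abs(ref).max(), 1e-12))
        assert worst < 1e-5

    def test_both_association_orders_agree(self):
        cfg = MGLAConfig(n_scales=1, scale_windows=(1,), phi="identity")
        rng = np.random.default_rng(0)
        q, k, v = (rng.normal(size=(1, 8, 4)) for _ in range(3))
        right = mg_la(Tensor(q), Tensor(k), Tensor(v),
                      saturated_gates(4), cfg).data
        left = (q[0] @ k[0].T) @ v[0]      # (QKᵀ)V association
        np.testing.assert_allclose(right[0], left, rtol=1e-5)

    def test_zero_values_give_zero_output(self, rng):
        cfg = MGLAConfig()
        q = Tensor(rng.normal(size=(2, 8, 4)))
        k = Tensor(rng.normal(size=(2, 8, 4)))
        out = mg_la(q, k, Tensor(np.zeros((2, 8, 4))),
                    Tensor(np.zeros((3, 4))), cfg)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_gate_sigmoid_weighting(self, rng):
        cfg = MGLAConfig(n_scales=1, scale_windows=(1,), phi="identity")
        q = Tensor(rng.normal(size=(1, 4, 3)))
        k = Tensor(rng.normal(size=(1, 4, 3)))
        v = Tensor(rng.normal(size=(1, 4, 3)))
        full = mg_la(q, k, v, saturated_gates(3), cfg).data
        half = mg_la(q, k, v, Tensor(np.zeros((1, 3))), cfg).data
        np.testing.assert_allclose(half, 0.5 * full, rtol=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        cfg = MGLAConfig()
        with pytest.raises(ValueError):
            mg_la(Tensor(np.zeros((1, 4, 3))), Tensor(np.zeros((1, 4, 3))),
                  Tensor(np.zeros((1, 5, 3))), Tensor(np.zeros((3, 3))), cfg)


class TestCoarseBranch:
    def test_token_halving(self, rng):
        cgb = CoarseBranch(8, MGLAConfig(), rng)
        out = cgb(Tensor(rng.normal(size=(2, 8, 8)).astype(np.float32)))
        assert out.shape == (2, 4, 8)

    def test_degenerate_path_is_layernormed_maxpool(self, rng):
        cgb = CoarseBranch(8, MGLAConfig(), rng)
        for p in (cgb.wq.weight, cgb.wk.weight, cgb.wv.weight,
                  cgb.proj.weight, cgb.proj.bias):
            p.data = np.zeros_like(p.data)
        cgb.ffn = None                      # identity FFN (test mode)
        x = Tensor(rng.normal(size=(1, 8, 8)).astype(np.float32))
        out = cgb(x).data
        ref = cgb.ln(_pool_tokens(x, 2, 2, kind="max")).data
        np.testing.assert_allclose(out, ref, atol=1e-6)

    def test_odd_token_count_rejected(self, rng):
        cgb = CoarseBranch(8, MGLAConfig(), rng)
        with pytest.raises(ValueError):
            cgb(Tensor(np.zeros((1, 7, 8), np.float32)))

    def test_msa_dropin_matches_shape(self, rng):
        cgb = CoarseBranch(8, MGLAConfig(), rng, attention="msa")
        out = cgb(Tensor(rng.normal(size=(2, 8, 8)).astype(np.float32)))
        assert out.shape == (2, 4, 8)


class TestConvBranches:
    def test_fine_branch_kernel_and_shape(self, rng):
        fgb = FineBranch(8, rng)
        assert fgb.conv.weight.shape[-1] == 3
        out = fgb(Tensor(rng.normal(size=(2, 8, 8)).astype(np.float32)))
        assert out.shape == (2, 4, 8)

    def test_medium_branch_kernel_and_shape(self, rng):
        mgb = MediumBranch(8, rng)
        assert mgb.conv.weight.shape[-1] == 7
        out = mgb(Tensor(rng.normal(size=(2, 8, 8)).astype(np.float32)))
        assert out.shape == (2, 4, 8)

    def test_average_pool_of_ramp(self):
        from eedcl.nn import avg_pool1d
        ramp = Tensor(np.arange(8.0)[None, None, :])
        out = avg_pool1d(ramp, 2, 2).data[0, 0]
        np.testing.assert_allclose(out, [0.5, 2.5, 4.5, 6.5])
        assert out.mean() == pytest.approx(ramp.data.mean())

    def test_stride1_maxpool_identity_on_constants(self, rng):
        fgb = FineBranch(4, rng)
        fgb.eval()                          # deterministic (dropout off)
        x = Tensor(np.ones((1, 8, 4), np.float32))
        out1 = fgb(x).data
        out2 = fgb(x).data
        np.testing.assert_array_equal(out1, out2)


class TestHCTLayer:
    def test_additive_integration_identity(self, rng):
        layer = HCTLayer(8, MGLAConfig(), rng)
        layer.eval()
        x = Tensor(rng.normal(size=(2, 8, 8)).astype(np.float32))
        out, f_mg, f_fg = layer(x)
        f_cg = layer.cgb(x)
        np.testing.assert_allclose(out.data,
                                   (f_cg + f_mg + f_fg).data, atol=1e-5)

    def test_two_branch_variant(self, rng):
        layer = HCTLayer(8, MGLAConfig(), rng, use_medium=False)
        out, f_mg, f_fg = layer(Tensor(np.random.default_rng(0)
                                       .normal(size=(1, 8, 8))
                                       .astype(np.float32)))
        assert f_mg is None
        assert out.shape == (1, 4, 8)

    def test_halving_chain(self, rng):
        layers = [HCTLayer(8, MGLAConfig(), rng) for _ in range(3)]
        x = Tensor(rng.normal(size=(1, 16, 8)).astype(np.float32))
        for layer in layers:
            layer.eval()
            x, _, _ = layer(x)
        assert x.shape == (1, 2, 8)

    def test_feature_permutation_equivariance(self, rng):
        """Permuting feature dims consistently in all branch parameters
        permutes the layer output identically (checked on the conv
        branches, whose parameters act per feature)."""
        mgb = MediumBranch(6, rng)
        mgb.eval()
        x = np.random.default_rng(1).normal(size=(1, 8, 6)).astype(np.float32)
        base = mgb(Tensor(x)).data
        perm = np.array([2, 0, 1, 5, 3, 4])
        mgb.conv.weight.data = mgb.conv.weight.data[perm][:, perm]
        mgb.conv.bias.data = mgb.conv.bias.data[perm]
        mgb.bn.gamma.data = mgb.bn.gamma.data[perm]
        mgb.bn.beta.data = mgb.bn.beta.data[perm]
        mgb.bn.running_mean = mgb.bn.running_mean[perm]
        mgb.bn.running_var = mgb.bn.running_var[perm]
        out = mgb(Tensor(x[:, :, perm])).data
        np.testing.assert_allclose(out, base[:, :, perm], atol=1e-5)
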