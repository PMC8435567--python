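"""SKA / SGE / CBAM attention math against hand values and numpy oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from skaresnet.attention import (BranchTransform, CBAM, SGE, SKAConfig,
                                 SKAModule, SKASelect, aggregate,
                                 channel_standardize, cbam_layer,
                                 fuse_descriptor, select_branch_weights,
                                 sge_enhance, ska_module)
from skaresnet.autodiff import Tensor

from _oracles import cbam as oracle_cbam, ska as oracle_ska
from conftest import randomize_bn_stats


# ---------------------------------------------------------------------------
# Divide branches
# ---------------------------------------------------------------------------

class TestBranchTransform:
    def test_preserves_shape(self, rng):
        br = BranchTransform(8, 5, rng=rng)
        out = br(rng.normal(size=(1, 8, 6, 6)))
        assert out.shape == (1, 8, 6, 6)

    def test_identity_kernel_frozen_bn_is_relu(self, rng):
        br = BranchTransform(3, 3, rng=rng).eval()
        w = np.zeros((3, 1, 3, 3))
        w[:, 0, 1, 1] = 1.0                    # center-tap identity
        br.conv.weight.data = w
        x = rng.uniform(0.1, 2.0, (2, 3, 4, 4))
        assert np.allclose(br(x), x)           # BN starts as identity
        assert np.allclose(br(np.full((2, 3, 4, 4), -1.0)), 0.0)

    def test_channel_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="channels"):
            BranchTransform(4, 3, rng=rng)(rng.normal(size=(1, 5, 4, 4)))


# ---------------------------------------------------------------------------
# Fuse
# ---------------------------------------------------------------------------

class TestFuse:
    def test_constant_channels_standardize_to_zero(self, rng):
        from skaresnet.attention import SKAFuse

        fuse = SKAFuse(4, SKAConfig(groups=2, d_min=4), rng=rng)
        y = np.full((2, 4, 3, 3), 1.7)
        g, _ = fuse_descriptor(y, y, fuse)
        assert np.allclose(g, 0.0, atol=1e-9)

    def test_symmetry_in_branches(self, rng):
        from skaresnet.attention import SKAFuse

        fuse = SKAFuse(4, SKAConfig(groups=2, d_min=4), rng=rng).eval()
        y1, y2 = rng.normal(size=(2, 2, 4, 3, 3))
        a = fuse_descriptor(y1, y2, fuse)
        b = fuse_descriptor(y2, y1, fuse)
        assert np.array_equal(a.g, b.g) and np.array_equal(a.g1, b.g1)

    def test_two_channel_toy_standardization(self):
        # pooled descriptor (1, 3) -> standardized (-1, 1) (population std)
        g = channel_standardize(np.array([[1.0, 3.0]]))
        assert np.allclose(g.numpy(), [[-1.0, 1.0]], atol=1e-4)

    def test_shape_mismatch_raises(self, rng):
        from skaresnet.attention import SKAFuse

        fuse = SKAFuse(4, SKAConfig(groups=2, d_min=4), rng=rng)
        with pytest.raises(ValueError, match="differ"):
            fuse_descriptor(np.zeros((1, 4, 3, 3)), np.zeros((1, 4, 2, 2)), fuse)

    def test_zero_variance_is_finite(self):
        g = channel_standardize(np.full((3, 5), 2.0))
        assert np.isfinite(g.numpy()).all()


# ---------------------------------------------------------------------------
# SGE
# ---------------------------------------------------------------------------

class TestSGE:
    def test_uniform_map_gives_half_gate(self, rng):
        y = np.broadcast_to(rng.normal(size=(2, 4, 1, 1)), (2, 4, 3, 3)).copy()
        out = sge_enhance(y, np.ones(2), np.zeros(2), groups=2)
        assert np.allclose(out, 0.5 * y)

    def test_gamma_beta_zero_is_exactly_half(self, rng):
        y = rng.normal(size=(2, 4, 5, 5))
        out = sge_enhance(y, np.zeros(2), np.zeros(2), groups=2)
        assert np.array_equal(out, 0.5 * y)

    def test_hand_derived_single_group_case(self):
        # spatial values (1, 3): descriptor 2, similarities (2, 6),
        # standardized (-1, 1), gate sigmoid -> (1*s(-1), 3*s(1))
        y = np.array([1.0, 3.0]).reshape(1, 1, 1, 2)
        out = sge_enhance(y, np.ones(1), np.zeros(1), groups=1)
        assert np.allclose(out.ravel(), [0.26894, 2.19318], atol=1e-4)

    def test_indivisible_groups_raise(self):
        with pytest.raises(ValueError, match="divide"):
            sge_enhance(np.zeros((1, 3, 2, 2)), np.ones(2), np.zeros(2), groups=2)

    def test_matches_numpy_oracle(self, rng):
        from _oracles import sge as oracle_sge

        y = rng.normal(size=(2, 6, 4, 4))
        gamma, beta = rng.normal(size=3), rng.normal(size=3)
        assert np.allclose(sge_enhance(y, gamma, beta, 3),
                           oracle_sge(y, gamma, beta, 3), atol=1e-10)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

class TestAggregation:
    def test_softmax_head_closed_form(self, rng):
        sel = SKASelect(3, rng=rng)
        sel.head.weight.data = np.zeros((3, 2))
        sel.head.bias.data = np.array([1.0, 0.0])
        w = select_branch_weights(np.zeros((2, 3)), sel)
        assert np.allclose(w.v1, 0.7310586, atol=1e-6)
        assert np.allclose(w.v2, 0.2689414, atol=1e-6)
        sel.head.bias.data = np.zeros(2)
        w = select_branch_weights(rng.normal(size=(2, 3)) @ np.zeros((3, 3)), sel)
        assert np.allclose(w.v1, 0.5)

    def test_branch_weight_normalization_many(self, rng):
        sel = SKASelect(8, rng=rng)
        w = select_branch_weights(rng.normal(size=(1000, 8)), sel)
        assert np.all((w.v1 > 0) & (w.v1 < 1))
        assert np.abs(w.v1 + w.v2 - 1.0).max() < 1e-6

    def test_degenerate_and_convex_cases(self, rng):
        y1, y2 = rng.normal(size=(2, 3, 4, 2, 2))
        v = np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 0.0]])
        assert np.allclose(aggregate(y1, y2, v), y1)
        v = rng.dirichlet([1, 1], size=3)
        assert np.allclose(aggregate(y1, y1, v), y1)

    def test_hand_arithmetic(self):
        y1 = np.full((1, 1, 1, 1), 2.0)
        y2 = np.full((1, 1, 1, 1), 4.0)
        out = aggregate(y1, y2, np.array([[0.25, 0.75]]))
        assert np.allclose(out, 3.5)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="differ"):
            aggregate(np.zeros((1, 2, 2, 2)), np.zeros((1, 2, 3, 3)),
                      np.array([[0.5, 0.5]]))


# ---------------------------------------------------------------------------
# full SKA module
# ---------------------------------------------------------------------------

class TestSKAModule:
    def test_output_shape_preserved(self, rng):
        mod = SKAModule(32, SKAConfig(groups=32), rng=rng)
        assert mod(rng.normal(size=(2, 32, 8, 8))).shape == (2, 32, 8, 8)

    @pytest.mark.parametrize("use_sge", [True, False])
    def test_matches_sequential_numpy_oracle(self, rng, use_sge):
        mod = SKAModule(4, SKAConfig(groups=2, d_min=3), use_sge=use_sge,
                        rng=rng).eval()
        randomize_bn_stats(mod, rng)
        for shape in [(1, 4, 2, 2), (2, 4, 4, 4)]:
            x = rng.normal(size=shape)
            got = ska_module(x, mod)
            want = oracle_ska(x, mod)
            assert np.allclose(got, want, rtol=1e-5, atol=1e-10)

    def test_identical_branches_make_selection_irrelevant(self, rng):
        mod = SKAModule(4, SKAConfig(groups=2, d_min=3), rng=rng).eval()
        # force the 5x5 branch to equal the 3x3 branch
        w3 = mod.branch_a.conv.weight.data
        w5 = np.zeros_like(mod.branch_b.conv.weight.data)
        w5[:, :, 1:4, 1:4] = w3
        mod.branch_b.conv.weight.data = w5
        for p_a, p_b in [(mod.branch_a.bn, mod.branch_b.bn),
                         (mod.sge_a, mod.sge_b)]:
            for (n, pa), (_, pb) in zip(p_a.named_parameters(),
                                        p_b.named_parameters()):
                pb.data = pa.data.copy()
        randomize_bn_stats(mod.branch_a.bn, np.random.default_rng(5))
        mod.branch_b.bn.running_mean = mod.branch_a.bn.running_mean.copy()
        mod.branch_b.bn.running_var = mod.branch_a.bn.running_var.copy()
        x = rng.normal(size=(2, 4, 5, 5))
        got = ska_module(x, mod)
        enhanced = mod.sge_a.forward(mod.branch_a.forward(Tensor(x))).numpy()
        assert np.allclose(got, enhanced, atol=1e-10)

    def test_determinism(self, rng):
        mod = SKAModule(4, SKAConfig(groups=2, d_min=3),
                        rng=np.random.default_rng(3)).eval()
        x = rng.normal(size=(2, 4, 3, 3))
        assert np.array_equal(ska_module(x, mod), ska_module(x, mod))

    @settings(deadline=None, max_examples=12, derandomize=True)
    @given(n=st.integers(1, 2), cg=st.integers(1, 3), g=st.integers(1, 2),
           h=st.integers(2, 5), w=st.integers(2, 5))
    def test_shape_preservation_randomized(self, n, cg, g, h, w):
        c = cg * g
        mod = SKAModule(c, SKAConfig(groups=g, d_min=3),
                        rng=np.random.default_rng(0)).eval()
        x = np.random.default_rng(1).normal(size=(n, c, h, w))
        assert ska_module(x, mod).shape == (n, c, h, w)


# ---------------------------------------------------------------------------
# CBAM
# ---------------------------------------------------------------------------

class TestCBAM:
    def test_zero_weights_quarter_passthrough(self, rng):
        mod = CBAM(4, rho=2, rng=rng)
        for p in mod.parameters():
            p.data = np.zeros_like(p.data)
        f = rng.normal(size=(2, 4, 3, 3))
        assert np.allclose(cbam_layer(f, mod), 0.25 * f)

    def test_attenuation_bound(self, rng):
        mod = CBAM(8, rng=rng)
        f = rng.normal(size=(2, 8, 5, 5))
        out = cbam_layer(f, mod)
        assert np.all(np.abs(out) <= np.abs(f) + 1e-12)
        assert out.shape == f.shape

    def test_spatially_constant_input_hand_evaluation(self, rng):
        from _oracles import sigmoid

        mod = CBAM(3, rho=1, rng=rng)
        c = rng.normal(size=(1, 3))
        f = np.broadcast_to(c[:, :, None, None], (1, 3, 9, 9)).copy()

        def mlp(v):
            h = np.maximum(v @ mod.mlp1.weight.data + mod.mlp1.bias.data, 0)
            return h @ mod.mlp2.weight.data + mod.mlp2.bias.data

        mc = sigmoid(2.0 * mlp(c))             # avg pool == max pool here
        got = cbam_layer(f, mod)
        gated = f * mc[:, :, None, None]
        ratio = got / gated
        # spatial gate is constant away from the conv padding border
        inner = ratio[:, :, 3:6, 3:6]
        assert np.allclose(inner, inner[0, 0, 0, 0], atol=1e-12)
        assert np.all((inner > 0) & (inner < 1))

    def test_matches_numpy_oracle(self, rng):
        mod = CBAM(6, rho=2, rng=rng)
        f = rng.normal(size=(2, 6, 5, 5))
        assert np.allclose(cbam_layer(f, mod), oracle_cbam(f, mod),
                           rtol=1e-5, atol=1e-10)
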