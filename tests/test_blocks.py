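"""Layer-level oracles: conv blocks, dense residual module, GRU attention."""

import numpy as np
import pytest

from raunet._nn import GRUCell, Module
from raunet._tensor import Tensor
from raunet.blocks import (
    ConvBlock,
    DenseResidualModule,
    RecurrentAttentionModule,
    dilated_kernel_extent,
    global_max_pool,
    gru_step,
)


def rng():
    return np.random.default_rng(0)


class TestDilatedKernelExtent:
    @pytest.mark.parametrize("k,d,expected", [(3, 1, 3), (3, 2, 5), (3, 3, 7), (5, 2, 9)])
    def test_extent_formula(self, k, d, expected):
        assert dilated_kernel_extent(k, d) == expected

    def test_invalid_dilation(self):
        with pytest.raises(ValueError, match="dilation"):
            dilated_kernel_extent(3, 0)


class TestConvBlock:
    def test_shape_contract(self):
        block = ConvBlock(8, 8, kernel_size=3, rng=rng())
        out = block(Tensor(np.random.default_rng(1).normal(size=(1, 8, 16, 16)).astype(np.float32)))
        assert out.data.shape == (1, 8, 16, 16)

    def test_zero_weights_give_zero_output(self):
        block = ConvBlock(4, 4, rng=rng())
        block.conv.weight.data[:] = 0
        block.conv.bias.data[:] = 0
        x = Tensor(np.random.default_rng(2).normal(size=(2, 4, 8, 8)).astype(np.float32))
        out = block(x)
        np.testing.assert_array_equal(out.data, 0)

    def test_direct_convolution_sum_oracle(self):
        """3x3 ones kernel on a ones image: interior 9, corner 4 (zero pad)."""
        block = ConvBlock(1, 1, kernel_size=3, norm=False, activation=False, rng=rng())
        block.conv.weight.data[:] = 1.0
        block.conv.bias.data[:] = 0.0
        out = block(Tensor(np.ones((1, 1, 5, 5), dtype=np.float32))).data[0, 0]
        assert out[2, 2] == 9.0
        assert out[0, 0] == 4.0
        assert out[0, 2] == 6.0

    def test_dilated_conv_matches_explicit_loop(self):
        """Dilated conv equals a scalar loop over taps spaced by the rate."""
        r = np.random.default_rng(5)
        x = r.normal(size=(1, 1, 9, 9))
        w = r.normal(size=(1, 1, 3, 3))
        block = ConvBlock(1, 1, kernel_size=3, dilation=2, norm=False, activation=False, rng=rng())
        block.conv.weight.data = w.astype(np.float32)
        block.conv.bias.data[:] = 0
        got = block(Tensor(x.astype(np.float32))).data[0, 0]
        d = 2
        xp = np.pad(x[0, 0], d)
        want = np.zeros((9, 9))
        for r_ in range(9):
            for c in range(9):
                for i in range(3):
                    for j in range(3):
                        want[r_, c] += w[0, 0, i, j] * xp[r_ + i * d, c + j * d]
        np.testing.assert_allclose(got, want, atol=1e-5)


class TestGlobalMaxPool:
    def test_single_spike(self):
        x = np.zeros((1, 1, 4, 4), dtype=np.float32)
        x[0, 0, 2, 3] = 5.0
        assert global_max_pool(Tensor(x)).data[0, 0] == 5.0

    def test_constant_map(self):
        x = np.full((1, 3, 4, 4), 2.5, dtype=np.float32)
        np.testing.assert_array_equal(global_max_pool(Tensor(x)).data, 2.5)

    def test_exhaustive_scan_oracle(self):
        x = np.random.default_rng(8).normal(size=(2, 3, 4, 4)).astype(np.float32)
        got = global_max_pool(Tensor(x)).data
        for n in range(2):
            for c in range(3):
                best = -np.inf
                for i in range(4):
                    for j in range(4):
                        best = max(best, x[n, c, i, j])
                assert got[n, c] == best


def scalar_gru_oracle(cell: GRUCell, x, h):
    """Textbook GRU equations evaluated scalar by scalar."""

    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))

    H = cell.hidden_size
    w_ih, w_hh = cell.w_ih.data, cell.w_hh.data
    b_ih, b_hh = cell.b_ih.data, cell.b_hh.data
    out = np.zeros((x.shape[0], H))
    for n in range(x.shape[0]):
        gi = np.zeros(3 * H)
        gh = np.zeros(3 * H)
        for k in range(3 * H):
            for i in range(x.shape[1]):
                gi[k] += x[n, i] * w_ih[i, k]
            for j in range(H):
                gh[k] += h[n, j] * w_hh[j, k]
            gi[k] += b_ih[k]
            gh[k] += b_hh[k]
        for j in range(H):
            r = sig(gi[j] + gh[j])
            z = sig(gi[H + j] + gh[H + j])
            nn = np.tanh(gi[2 * H + j] + r * gh[2 * H + j])
            out[n, j] = (1 - z) * nn + z * h[n, j]
    return out


class TestGRU:
    def test_zero_everything_gives_zero_hidden(self):
        cell = GRUCell(4, 2, rng=rng())
        for p in cell.parameters():
            p.data[:] = 0
        h = gru_step(cell, Tensor(np.zeros((1, 4))), Tensor(np.zeros((1, 2))))
        np.testing.assert_array_equal(h.data, 0)

    def test_hidden_state_bounded(self):
        cell = GRUCell(4, 2, rng=np.random.default_rng(3))
        h = Tensor(np.zeros((5, 2)))
        x = Tensor(np.random.default_rng(4).normal(scale=3.0, size=(5, 4)))
        for _ in range(10):
            h = gru_step(cell, x, h)
        assert np.all(np.abs(h.data) < 1.0)

    def test_matches_scalar_oracle(self):
        cell = GRUCell(4, 2, rng=np.random.default_rng(7)).astype(np.float64)
        x = np.random.default_rng(9).normal(size=(3, 4))
        h = np.random.default_rng(10).uniform(-0.9, 0.9, size=(3, 2))
        got = gru_step(cell, Tensor(x), Tensor(h)).data
        want = scalar_gru_oracle(cell, x, h)
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_length_mismatch_rejected(self):
        cell = GRUCell(4, 2, rng=rng())
        with pytest.raises(ValueError, match="hidden"):
            gru_step(cell, Tensor(np.zeros((1, 4))), Tensor(np.zeros((1, 3))))


def brute_force_dense_residual(module: DenseResidualModule, x):
    """Straight-line re-implementation with explicit loops (float64).

    Convolutions, group norm, PReLU and the dense accumulation are written
    as plain index arithmetic, independent of the autograd engine.
    """

    def conv(x_, w, b, d):
        O, C, k, _ = w.shape
        H, W = x_.shape[1:]
        pad = d * (k - 1) // 2
        xp = np.pad(x_, ((0, 0), (pad, pad), (pad, pad)))
        out = np.zeros((O, H, W))
        for o in range(O):
            for c in range(C):
                for i in range(k):
                    for j in range(k):
                        out[o] += w[o, c, i, j] * xp[c, i * d : i * d + H, j * d : j * d + W]
            out[o] += b[o]
        return out

    def gn(x_, gamma, beta, groups, eps=1e-5):
        C = x_.shape[0]
        per = C // groups
        out = np.empty_like(x_)
        for g in range(groups):
            sl = x_[g * per : (g + 1) * per]
            mu, var = sl.mean(), sl.var()
            out[g * per : (g + 1) * per] = (sl - mu) / np.sqrt(var + eps)
        return out * gamma[:, None, None] + beta[:, None, None]

    def pr(x_, slope):
        return np.where(x_ > 0, x_, slope[:, None, None] * x_)

    def conv_block(x_, blk, act=True):
        y = conv(x_, blk.conv.weight.data, blk.conv.bias.data, blk.conv.dilation)
        y = gn(y, blk.norm.gamma.data, blk.norm.beta.data, blk.norm.groups)
        if act:
            y = pr(y, blk.act.slope.data)
        return y

    inputs = [x]
    for unit, act in zip(module.units, module.acts):
        y = conv_block(inputs[-1], unit.squeeze)
        y = conv_block(y, unit.dilated)
        y = conv_block(y, unit.expand, act=False)
        total = np.zeros_like(x)
        for prev in inputs:
            total = total + prev
        inputs.append(pr(total + y, act.slope.data))
    return inputs[-1]


class TestDenseResidual:
    def test_zero_weight_cumulative_sums(self):
        """With x_t^3 = 0 the module reduces to PReLU'd cumulative sums."""
        module = DenseResidualModule(4, rng=rng())
        for name, p in module.named_parameters():
            if "conv" in name:
                p.data[:] = 0
        x = np.abs(np.random.default_rng(3).normal(size=(1, 4, 8, 8))).astype(np.float32)
        out = module(Tensor(x)).data
        # nonnegative input: x2 = x1, x3 = 2 x1, x4 = 4 x1
        np.testing.assert_allclose(out, 4 * x, atol=1e-5)

    def test_shape_and_internal_channels(self):
        module = DenseResidualModule(16, rng=rng())
        out = module(Tensor(np.random.default_rng(1).normal(size=(1, 16, 32, 32)).astype(np.float32)))
        assert out.data.shape == (1, 16, 32, 32)
        assert module.units[0].dilated.conv.weight.data.shape == (8, 8, 3, 3)
        assert [u.dilated.conv.dilation for u in module.units] == [1, 2, 3]

    def test_matches_brute_force_oracle(self):
        module = DenseResidualModule(4, rng=np.random.default_rng(11)).astype(np.float64)
        x = np.random.default_rng(12).normal(scale=0.5, size=(1, 4, 8, 8))
        got = module(Tensor(x)).data
        want = brute_force_dense_residual(module, x[0])
        np.testing.assert_allclose(got[0], want, atol=1e-5)

    def test_odd_channels_rejected(self):
        with pytest.raises(ValueError, match="even"):
            DenseResidualModule(5, rng=rng())

    def test_receptive_field_is_holefree_square(self):
        """The (1,2,3)-dilation cascade leaves no gridding holes."""
        module = DenseResidualModule(2, rng=rng())
        for name, p in dict(module.named_parameters()).items():
            if name.endswith("conv.weight"):
                p.data[:] = 0.01
            elif name.endswith("conv.bias"):
                p.data[:] = 0
            elif "norm" in name:
                pass  # disabled below
        for unit in module.units:
            unit.squeeze.norm = None
            unit.dilated.norm = None
            unit.expand.norm = None
        x = Tensor(np.abs(np.random.default_rng(5).normal(size=(1, 2, 31, 31))) + 0.1, requires_grad=True)
        out = module(x)
        g = np.zeros_like(out.data)
        g[0, 0, 15, 15] = 1.0
        out.backward(g)
        footprint = np.abs(x.grad[0]).sum(axis=0) > 0
        rs, cs = np.nonzero(footprint)
        sub = footprint[rs.min() : rs.max() + 1, cs.min() : cs.max() + 1]
        assert sub.all(), "gradient footprint has holes"
        assert sub.shape[0] == sub.shape[1] == 13  # 1 + 2*(1+2+3)


class TestRecurrentAttention:
    def test_channel_halving_shape(self):
        mod = RecurrentAttentionModule(32, rng=rng())
        out = mod(Tensor(np.random.default_rng(1).normal(size=(1, 32, 16, 16)).astype(np.float32)))
        assert out.data.shape == (1, 16, 16, 16)

    def test_alpha_zero_degenerates_to_conv_blocks(self):
        """Forcing alpha ~ 0 and unit outer slopes gives plain conv blocks."""
        mod = RecurrentAttentionModule(8, iterations=2, rng=np.random.default_rng(2))
        mod.proj.weight.data[:] = 0
        mod.proj.bias.data[:] = -50.0  # sigmoid -> ~2e-22
        for act in mod.acts:
            act.slope.data[:] = 1.0  # outer PReLU = identity
        x = Tensor(np.random.default_rng(3).normal(size=(1, 8, 8, 8)).astype(np.float32))
        got = mod(x).data
        want = mod.blocks[1](mod.blocks[0](x)).data
        np.testing.assert_allclose(got, want, atol=1e-5)

    def test_hidden_state_carries_between_iterations(self):
        """Perturbing iteration-1 input changes iteration-2 attention via h."""
        mod = RecurrentAttentionModule(8, iterations=2, rng=np.random.default_rng(4))
        x1 = np.random.default_rng(5).normal(size=(1, 8, 8, 8)).astype(np.float32)
        x2 = x1 + np.float32(0.5)

        def alphas(xin):
            seen = []
            batch = xin.shape[0]
            h = Tensor(np.zeros((batch, mod.out_channels // 2), dtype=np.float32))
            y = Tensor(xin)
            from raunet._tensor import prelu, sigmoid, spatial_max

            for l in range(mod.iterations):
                xl = mod.blocks[l](y)
                if l == 1:
                    xl = Tensor(fixed_x2)  # hold iteration-2 input fixed
                h = mod.gru(spatial_max(xl), h)
                a = sigmoid(mod.proj(h))
                seen.append(a.data.copy())
                y = prelu(xl + xl * a.reshape(batch, mod.out_channels, 1, 1), mod.acts[l].slope)
            return seen

        fixed_x2 = np.random.default_rng(6).normal(size=(1, 4, 8, 8)).astype(np.float32)
        a_ref = alphas(x1)
        a_pert = alphas(x2)
        assert not np.allclose(a_ref[1], a_pert[1]), "hidden state not carried over"

    def test_invalid_iterations(self):
        with pytest.raises(ValueError, match="iterations"):
            RecurrentAttentionModule(8, iterations=0, rng=rng())


def test_block_forward_deterministic():
    mod = DenseResidualModule(4, rng=np.random.default_rng(0))
    x = np.random.default_rng(1).normal(size=(1, 4, 8, 8)).astype(np.float32)
    np.testing.assert_array_equal(mod(Tensor(x)).data, mod(Tensor(x)).data)


def test_blocks_finite_for_finite_inputs():
    for mod in (DenseResidualModule(8, rng=rng()), RecurrentAttentionModule(16, rng=rng())):
        x = np.random.default_rng(2).normal(scale=10, size=(1, mod.channels if hasattr(mod, "channels") else 16, 8, 8))
        out = mod(Tensor(x.astype(np.float32)))
        assert np.all(np.isfinite(out.data))
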