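import numpy as np
import pytest

from histossm.autograd import Tensor
from histossm.gmamba import (GMambaBlock, GMambaConfig, SsmOnlyBlock,
                             SsmParams, bidirectional_global_extract,
                             channel_attention, dense_conv_mac_count,
                             depthwise_separable_conv, dsc_mac_count,
                             flatten_rows, fuse, gmamba_block, ssm_scan,
                             unflatten)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def dense_conv_oracle(f, kernel):
    """Brute-force dense 'same' convolution; kernel (k, k, C_in, C_out)."""
    h, w, c_in = f.shape
    k = kernel.shape[0]
    c_out = kernel.shape[3]
    p = k // 2
    fp = np.pad(f, ((p, p), (p, p), (0, 0)))
    out = np.zeros((h, w, c_out))
    for i in range(h):
        for j in range(w):
            patch = fp[i:i + k, j:j + k, :]
            for co in range(c_out):
                out[i, j, co] = np.sum(patch * kernel[:, :, :, co])
    return out


def scan_oracle(x, params, direction="forward"):
    """Naive per-step recurrence, counting update steps."""
    xs = x[::-1] if direction == "backward" else x
    L, C = xs.shape
    N = params.state_dim
    y = np.zeros_like(xs, dtype=float)
    steps = 0
    for ci in range(C):
        s = np.zeros(N)
        for t in range(L):
            s = params.a[ci] * s + params.b[ci] * xs[t, ci]
            y[t, ci] = params.c[ci] @ s + params.d[ci] * xs[t, ci]
            steps += 1
    y = y[::-1] if direction == "backward" else y
    return y, steps


def random_ssm_params(rng, c, n):
    return SsmParams(a=rng.uniform(0.05, 0.95, (c, n)),
                     b=rng.normal(size=(c, n)),
                     c=rng.normal(size=(c, n)),
                     d=rng.normal(size=c))


# ---------------------------------------------------------------------------
# depthwise separable convolution
# ---------------------------------------------------------------------------

class TestDsc:
    def test_delta_kernel_identity(self, rng):
        f = rng.normal(size=(6, 6, 3))
        dw = np.zeros((3, 3, 3))
        dw[1, 1, :] = 1.0
        out = depthwise_separable_conv(f, dw, np.eye(3))
        np.testing.assert_allclose(out, f, atol=1e-12)

    def test_constant_map_interior_sum(self):
        v = 0.7
        f = np.full((7, 7, 2), v)
        dw = np.ones((3, 3, 2))
        out = depthwise_separable_conv(f, dw, np.eye(2))
        np.testing.assert_allclose(out[1:-1, 1:-1], 9 * v, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_composed_dense_conv(self, seed):
        rng = np.random.default_rng(seed)
        c_in, c_out, k = int(rng.integers(1, 5)), int(rng.integers(1, 5)), 3
        f = rng.normal(size=(5, 5, c_in))
        dw = rng.normal(size=(k, k, c_in))
        pw = rng.normal(size=(c_in, c_out))
        got = depthwise_separable_conv(f, dw, pw)
        composed = np.einsum("klc,co->klco", dw, pw)
        np.testing.assert_allclose(got, dense_conv_oracle(f, composed), atol=1e-5)

    def test_biases(self, rng):
        f = rng.normal(size=(4, 4, 2))
        dw = np.zeros((3, 3, 2))
        dw[1, 1] = 1.0
        out = depthwise_separable_conv(f, dw, np.eye(2),
                                       b_dw=np.array([1.0, 2.0]),
                                       b_pw=np.array([10.0, 20.0]))
        np.testing.assert_allclose(out, f + [1.0, 2.0] + [10.0, 20.0], atol=1e-12)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            depthwise_separable_conv(rng.normal(size=(4, 4, 2)),
                                     np.zeros((3, 3, 3)), np.eye(3))
        with pytest.raises(ValueError):
            depthwise_separable_conv(rng.normal(size=(4, 4, 2)),
                                     np.zeros((2, 2, 2)), np.eye(2))

    def test_mac_count_formulas(self):
        # explicit multiply counting at tiny size
        h = w = 4
        c_in, c_out, k = 2, 3, 3
        dsc_muls = h * w * c_in * k * k + h * w * c_in * c_out
        dense_muls = h * w * c_out * k * k * c_in
        assert dsc_mac_count(h, w, c_in, c_out, k) == dsc_muls
        assert dense_conv_mac_count(h, w, c_in, c_out, k) == dense_muls
        ratio = dense_muls / dsc_muls
        assert ratio == pytest.approx(k**2 * c_out / (k**2 + c_out))


# ---------------------------------------------------------------------------
# flatten / unflatten
# ---------------------------------------------------------------------------

class TestFlatten:
    def test_row_major_order(self):
        f = np.array([[1.0, 2.0], [3.0, 4.0]])[:, :, None]
        np.testing.assert_array_equal(flatten_rows(f).ravel(), [1, 2, 3, 4])

    def test_round_trip(self, rng):
        f = rng.normal(size=(3, 5, 4))
        np.testing.assert_array_equal(unflatten(flatten_rows(f), (3, 5)), f)

    def test_token_index_position(self):
        # token 5 of a W=4 map sits at (row 1, col 1)
        h, w = 3, 4
        f = np.arange(h * w, dtype=float).reshape(h, w, 1)
        seq = flatten_rows(f)
        assert seq[5, 0] == f[1, 1, 0]

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            unflatten(rng.normal(size=(7, 2)), (2, 4))


# ---------------------------------------------------------------------------
# state-space scan
# ---------------------------------------------------------------------------

class TestSsmScan:
    def test_memoryless_limit(self, rng):
        c, n = 2, 3
        params = SsmParams(a=np.zeros((c, n)), b=rng.normal(size=(c, n)),
                           c=rng.normal(size=(c, n)), d=np.zeros(c))
        x = rng.normal(size=(6, c))
        y = ssm_scan(x, params)
        expected = x * np.sum(params.b * params.c, axis=1)
        np.testing.assert_allclose(y, expected, atol=1e-12)

    def test_scalar_hand_recurrence(self):
        params = SsmParams(a=[[0.5]], b=[[1.0]], c=[[1.0]], d=[0.0])
        y = ssm_scan(np.ones((2, 1)), params)
        np.testing.assert_allclose(y.ravel(), [1.0, 1.5], atol=1e-12)

    @pytest.mark.parametrize("direction", ["forward", "backward"])
    def test_matches_naive_loop_oracle(self, direction, rng):
        params = random_ssm_params(rng, 3, 4)
        x = rng.normal(size=(11, 3))
        expected, steps = scan_oracle(x, params, direction)
        np.testing.assert_allclose(ssm_scan(x, params, direction), expected,
                                   atol=1e-6)
        assert steps == 11 * 3  # L steps per channel: linear complexity

    def test_backward_is_reversed_forward_of_reversed(self, rng):
        params = random_ssm_params(rng, 2, 3)
        x = rng.normal(size=(9, 2))
        back = ssm_scan(x, params, "backward")
        ref = ssm_scan(x[::-1], params, "forward")[::-1]
        np.testing.assert_allclose(back, ref, atol=1e-12)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            SsmParams(a=[[1.5]], b=[[1.0]], c=[[1.0]], d=[0.0])
        with pytest.raises(ValueError):
            SsmParams(a=[[np.nan]], b=[[1.0]], c=[[1.0]], d=[0.0])
        with pytest.raises(ValueError):
            ssm_scan(np.zeros((4, 1)),
                     SsmParams(a=[[0.5]], b=[[1.0]], c=[[1.0]], d=[0.0]),
                     direction="sideways")


class TestBidirectional:
    def test_zero_input_zero_output(self, rng):
        params = random_ssm_params(rng, 3, 2)
        out = bidirectional_global_extract(np.zeros((4, 5, 3)), params, params,
                                           rng.normal(size=(6, 3)))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_shape_contract(self, rng):
        f = rng.normal(size=(4, 6, 3))
        params = random_ssm_params(rng, 3, 2)
        out = bidirectional_global_extract(f, params, params,
                                           rng.normal(size=(6, 3)))
        assert out.shape == f.shape

    def test_memoryless_is_pointwise(self, rng):
        c = 2
        zero_a = lambda: SsmParams(a=np.zeros((c, 2)),
                                   b=rng.normal(size=(c, 2)),
                                   c=rng.normal(size=(c, 2)), d=np.ones(c))
        pf, pb = zero_a(), zero_a()
        proj = rng.normal(size=(2 * c, c))
        f = rng.normal(size=(3, 4, c))
        out = bidirectional_global_extract(f, pf, pb, proj)
        gain_f = np.sum(pf.b * pf.c, axis=1) + pf.d
        gain_b = np.sum(pb.b * pb.c, axis=1) + pb.d
        flat = flatten_rows(f)
        expected = unflatten(
            np.concatenate([flat * gain_f, flat * gain_b], axis=1) @ proj, (3, 4))
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_projection_shape_error(self, rng):
        params = random_ssm_params(rng, 3, 2)
        with pytest.raises(ValueError):
            bidirectional_global_extract(rng.normal(size=(4, 4, 3)), params,
                                         params, rng.normal(size=(3, 3)))


# ---------------------------------------------------------------------------
# attention and fusion
# ---------------------------------------------------------------------------

class TestAttentionFusion:
    def test_zero_weights_give_half(self, rng):
        fl = rng.normal(size=(4, 4, 3))
        fg = rng.normal(size=(4, 4, 3))
        alpha = channel_attention(fl, fg, np.zeros((6, 3)), np.zeros(3))
        np.testing.assert_allclose(alpha, 0.5)

    def test_large_bias_saturates(self, rng):
        fl = rng.normal(size=(4, 4, 2))
        alpha = channel_attention(fl, fl, np.zeros((4, 2)), np.full(2, 50.0))
        np.testing.assert_allclose(alpha, 1.0, atol=1e-12)

    def test_spatial_permutation_invariance(self, rng):
        fl = rng.normal(size=(5, 5, 3))
        fg = rng.normal(size=(5, 5, 3))
        w, b = rng.normal(size=(6, 3)), rng.normal(size=3)
        perm = rng.permutation(25)
        fl_p = fl.reshape(25, 3)[perm].reshape(5, 5, 3)
        fg_p = fg.reshape(25, 3)[perm].reshape(5, 5, 3)
        np.testing.assert_allclose(channel_attention(fl, fg, w, b),
                                   channel_attention(fl_p, fg_p, w, b),
                                   atol=1e-12)

    def test_fuse_endpoints_and_midpoint(self):
        fl = np.full((3, 3, 2), 2.0)
        fg = np.full((3, 3, 2), 4.0)
        np.testing.assert_array_equal(fuse(fl, fg, 1.0), fl)
        np.testing.assert_array_equal(fuse(fl, fg, 0.0), fg)
        np.testing.assert_allclose(fuse(fl, fg, 0.5), 3.0)

    def test_fuse_convexity_bound(self, rng):
        fl = rng.normal(size=(6, 6, 4))
        fg = rng.normal(size=(6, 6, 4))
        alpha = rng.random(4)
        out = fuse(fl, fg, alpha)
        lo = np.minimum(fl, fg) - 1e-12
        hi = np.maximum(fl, fg) + 1e-12
        assert np.all(out >= lo) and np.all(out <= hi)

    def test_fuse_spatial_alpha(self, rng):
        fl = rng.normal(size=(4, 4, 2))
        fg = rng.normal(size=(4, 4, 2))
        amap = rng.random((4, 4))
        out = fuse(fl, fg, amap)
        np.testing.assert_allclose(
            out, amap[:, :, None] * fl + (1 - amap[:, :, None]) * fg)

    def test_fuse_rejects_out_of_range(self, rng):
        fl = rng.normal(size=(2, 2, 2))
        with pytest.raises(ValueError):
            fuse(fl, fl, 1.5)


# ---------------------------------------------------------------------------
# whole block
# ---------------------------------------------------------------------------

class TestBlock:
    def test_shape_contract(self, rng):
        cfg = GMambaConfig(channels=3, out_channels=5, state_dim=4, seed=0)
        out = gmamba_block(rng.normal(size=(6, 6, 3)), cfg)
        assert out.shape == (6, 6, 5)

    def test_alpha_one_ignores_global_branch(self, rng):
        blk = GMambaBlock(3, 3, 3, 4, np.random.default_rng(0), mode="fixed",
                          fixed_alpha=1.0, dtype=np.float64)
        blk.eval()
        x = Tensor(rng.normal(size=(1, 5, 5, 3)))
        before = blk(x).data.copy()
        for p in (blk.glob.fwd.b, blk.glob.fwd.c, blk.glob.bwd.b):
            p.data = p.data + 10.0  # perturb the global branch
        np.testing.assert_allclose(blk(x).data, before, atol=1e-12)

    def test_decoder_alpha_locality(self, rng):
        blk = GMambaBlock(2, 2, 3, 4, np.random.default_rng(1), mode="spatial",
                          dtype=np.float64)
        blk.eval()
        x = Tensor(rng.normal(size=(1, 4, 4, 2)))
        amap = np.full((1, 4, 4), 0.5)
        base = blk(x, alpha_map=Tensor(amap)).data
        amap2 = amap.copy()
        amap2[0, 2, 1] = 0.9
        out = blk(x, alpha_map=Tensor(amap2)).data
        diff = np.abs(out - base).sum(axis=-1)[0]
        changed = np.argwhere(diff > 1e-12)
        assert changed.tolist() == [[2, 1]]

    def test_spatial_mode_requires_map(self, rng):
        blk = GMambaBlock(2, 2, 3, 2, np.random.default_rng(0), mode="spatial")
        with pytest.raises(ValueError):
            blk(Tensor(rng.normal(size=(1, 4, 4, 2)).astype(np.float32)))

    def test_ssm_only_block_shape(self, rng):
        blk = SsmOnlyBlock(3, 3, 4, np.random.default_rng(0), dtype=np.float64)
        out = blk(Tensor(rng.normal(size=(2, 4, 4, 3))))
        assert out.shape == (2, 4, 4, 3)

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            GMambaConfig(channels=4, mode="nonsense")
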