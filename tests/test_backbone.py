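"""Backbone unit tests: deformable sampling, Ghost modules, DFC attention,
bottlenecks, re-parameterization and embedding extraction, each checked
against independent straight-loop oracles."""

import numpy as np
import pytest

from ghostcbir import autodiff as ad
from ghostcbir.autodiff import Tensor
from ghostcbir.backbone import (Backbone, BatchNormStats, Bottleneck,
                                BottleneckConfig, ConvBranch, DFCAttention,
                                DFCAttentionConfig, GhostModule,
                                GhostModuleConfig, full_backbone_spec,
                                reparameterize, toy_backbone_spec)
from ghostcbir.layers import Conv2d, DeformConv2d


# ---------------------------------------------------------------------------
# loop oracles
# ---------------------------------------------------------------------------

def conv_loop(x, w, b, stride=1, pad=0):
    """Direct nested-loop 2-D convolution (cross-correlation), zero padding."""
    N, C, H, W = x.shape
    Cout, Cin, K, _ = w.shape
    Ho = (H + 2 * pad - K) // stride + 1
    Wo = (W + 2 * pad - K) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    y = np.zeros((N, Cout, Ho, Wo))
    for n in range(N):
        for co in range(Cout):
            for i in range(Ho):
                for j in range(Wo):
                    acc = b[co] if b is not None else 0.0
                    for ci in range(Cin):
                        for ky in range(K):
                            for kx in range(K):
                                acc += (w[co, ci, ky, kx]
                                        * xp[n, ci, i * stride + ky, j * stride + kx])
                    y[n, co, i, j] = acc
    return y


def bilinear_at(plane, py, px):
    """Bilinear read of a 2-D plane at a fractional position; zero outside."""
    H, W = plane.shape
    y0, x0 = int(np.floor(py)), int(np.floor(px))
    total = 0.0
    for dy, dx in ((0, 0), (0, 1), (1, 0), (1, 1)):
        yy, xx = y0 + dy, x0 + dx
        if 0 <= yy < H and 0 <= xx < W:
            wy = (py - y0) if dy else (1 - (py - y0))
            wx = (px - x0) if dx else (1 - (px - x0))
            total += wy * wx * plane[yy, xx]
    return total


def deform_loop(x, w, b, off, stride=1, pad=1, offset_groups=1):
    """Per-position deformable convolution with explicit bilinear weights."""
    N, C, H, W = x.shape
    Cout, Cin, K, _ = w.shape
    Ho, Wo = off.shape[2], off.shape[3]
    Cpg = C // offset_groups
    y = np.zeros((N, Cout, Ho, Wo))
    o6 = off.reshape(N, offset_groups, K * K, 2, Ho, Wo)
    for n in range(N):
        for co in range(Cout):
            for i in range(Ho):
                for j in range(Wo):
                    acc = b[co] if b is not None else 0.0
                    for ci in range(Cin):
                        og = ci // Cpg
                        for t, (ky, kx) in enumerate(
                                (divmod(t, K) for t in range(K * K))):
                            py = i * stride - pad + ky + o6[n, og, t, 0, i, j]
                            px = j * stride - pad + kx + o6[n, og, t, 1, i, j]
                            acc += w[co, ci, ky, kx] * bilinear_at(x[n, ci], py, px)
                    y[n, co, i, j] = acc
    return y


# ---------------------------------------------------------------------------
# offset generation
# ---------------------------------------------------------------------------

class TestOffsetGeneration:
    def test_zero_generator_gives_zero_offsets(self, rng):
        layer = DeformConv2d(2, 3, k=3, rng=rng)  # generator zero-initialized
        x = Tensor(rng.normal(size=(1, 2, 5, 5)))
        assert np.all(layer.offsets(x).data == 0.0)

    def test_offset_field_has_2k2_channels(self, rng):
        layer = DeformConv2d(1, 1, k=3, offset_groups=1, rng=rng)
        off = layer.offsets(Tensor(rng.normal(size=(1, 1, 5, 5))))
        assert off.shape[1] == 18  # 2 * K^2 with K = 3
        four = DeformConv2d(4, 4, k=3, offset_groups=4, rng=rng)
        off4 = four.offsets(Tensor(rng.normal(size=(1, 4, 5, 5))))
        assert off4.shape[1] == 18 * 4

    def test_generator_matches_plain_convolution_loop(self, rng):
        layer = DeformConv2d(1, 1, k=3, rng=rng)
        layer.offset_gen.weight.data = rng.normal(size=layer.offset_gen.weight.shape)
        layer.offset_gen.bias.data = rng.normal(size=18)
        x = rng.normal(size=(1, 1, 5, 5))
        got = layer.offsets(Tensor(x)).data
        want = conv_loop(x, layer.offset_gen.weight.data,
                         layer.offset_gen.bias.data, stride=1, pad=1)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_channel_mismatch_raises(self, rng):
        layer = DeformConv2d(2, 3, k=3, rng=rng)
        with pytest.raises(ValueError):
            layer(Tensor(rng.normal(size=(1, 3, 5, 5))))


# ---------------------------------------------------------------------------
# deformable convolution
# ---------------------------------------------------------------------------

class TestDeformableConv:
    def test_zero_offsets_reduce_to_standard_convolution(self, rng):
        x = rng.normal(size=(2, 3, 6, 6))
        w = rng.normal(size=(4, 3, 3, 3))
        b = rng.normal(size=4)
        off = np.zeros((2, 18, 6, 6))
        got = ad.deform_conv2d(Tensor(x), Tensor(w), Tensor(b), Tensor(off),
                               stride=1, padding=1).data
        want = ad.conv2d(Tensor(x), Tensor(w), Tensor(b), stride=1, padding=1).data
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_interior_all_ones_sums_to_nine(self):
        x = np.ones((1, 1, 5, 5))
        w = np.ones((1, 1, 3, 3))
        off = np.zeros((1, 18, 3, 3))  # valid padding: 3x3 output
        y = ad.deform_conv2d(Tensor(x), Tensor(w), None, Tensor(off),
                             stride=1, padding=0).data
        assert y[0, 0, 1, 1] == pytest.approx(9.0)

    @pytest.mark.parametrize("offset_groups", [1, 2])
    def test_matches_bruteforce_bilinear_oracle(self, rng, offset_groups):
        x = rng.normal(size=(1, 2, 6, 6))
        w = rng.normal(size=(3, 2, 3, 3))
        b = rng.normal(size=3)
        off = rng.uniform(-1, 1, size=(1, 18 * offset_groups, 6, 6))
        got = ad.deform_conv2d(Tensor(x), Tensor(w), Tensor(b), Tensor(off),
                               stride=1, padding=1,
                               offset_groups=offset_groups).data
        want = deform_loop(x, w, b, off, stride=1, pad=1,
                           offset_groups=offset_groups)
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_nonfinite_offsets_rejected(self, rng):
        x = rng.normal(size=(1, 1, 4, 4))
        w = rng.normal(size=(1, 1, 3, 3))
        off = np.zeros((1, 18, 4, 4))
        off[0, 0, 0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            ad.deform_conv2d(Tensor(x), Tensor(w), None, Tensor(off), padding=1)

    def test_input_gradient_matches_finite_differences(self, rng):
        """Offsets make sampling input-dependent, so check analytic input
        gradients against central differences."""
        x = rng.normal(size=(1, 2, 5, 5))
        w = rng.normal(size=(2, 2, 3, 3))
        off = rng.uniform(-1, 1, size=(1, 18, 5, 5))
        probe = rng.normal(size=(1, 2, 5, 5))

        def forward(xa):
            return ad.deform_conv2d(Tensor(xa), Tensor(w), None, Tensor(off),
                                    padding=1).data

        xt = Tensor(x, requires_grad=True)
        out = ad.deform_conv2d(xt, Tensor(w), None, Tensor(off), padding=1)
        out.backward(probe)
        eps = 1e-5
        num = np.zeros_like(x)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            hi, lo = x.copy(), x.copy()
            hi[i] += eps
            lo[i] -= eps
            num[i] = ((forward(hi) - forward(lo)) * probe).sum() / (2 * eps)
        np.testing.assert_allclose(xt.grad, num, atol=1e-3)


# ---------------------------------------------------------------------------
# ghost module / DFC attention / bottleneck
# ---------------------------------------------------------------------------

class TestGhostModule:
    def test_output_channels_are_concatenated(self, rng):
        mod = GhostModule(GhostModuleConfig(3, 4, 4), rng=rng)
        y = mod(Tensor(rng.normal(size=(1, 3, 6, 6))))
        assert y.shape[1] == 8

    def test_zero_secondary_weights_zero_second_block(self, rng):
        mod = GhostModule(GhostModuleConfig(3, 4, 4), rng=rng)
        mod.cheap.weight.data[...] = 0.0
        mod.bn2.beta.data[...] = 0.0
        y = mod(Tensor(rng.normal(size=(1, 3, 6, 6))))
        np.testing.assert_allclose(y.data[:, 4:], 0.0, atol=1e-12)

    def test_matches_composition_oracle(self, rng):
        mod = GhostModule(GhostModuleConfig(3, 4, 4), rng=rng).eval()
        x = Tensor(rng.normal(size=(2, 3, 6, 6)))
        got = mod(x).data
        y1 = ad.relu(mod.bn1(mod.primary(x)))
        y2 = ad.relu(mod.bn2(mod.cheap(y1)))
        want = np.concatenate([y1.data, y2.data], axis=1)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_inconsistent_channel_arithmetic_rejected(self):
        with pytest.raises(ValueError):
            GhostModuleConfig(3, 4, 6)  # 6 not a multiple of 4


class TestDFCAttention:
    def test_zero_weights_give_half_everywhere(self, rng):
        att = DFCAttention(3, 5, DFCAttentionConfig(), rng=rng)
        for layer in (att.squeeze, att.mix, att.horizontal, att.vertical):
            layer.weight.data[...] = 0.0
            layer.bias.data[...] = 0.0
        y = att(Tensor(rng.normal(size=(1, 3, 8, 8))))
        np.testing.assert_allclose(y.data, 0.5, atol=1e-12)

    def test_output_in_unit_interval_and_gating_shrinks(self, rng):
        att = DFCAttention(3, 6, DFCAttentionConfig(), rng=rng)
        x = Tensor(rng.normal(size=(2, 3, 8, 8)))
        a = att(x).data
        assert np.all(a >= 0.0) and np.all(a <= 1.0)
        ghost_map = rng.normal(size=(2, 6, 8, 8))
        assert np.all(np.abs(ghost_map * a) <= np.abs(ghost_map) + 1e-15)

    def test_matches_stage_composition_oracle(self, rng):
        att = DFCAttention(4, 6, DFCAttentionConfig(), rng=rng).eval()
        x = Tensor(rng.normal(size=(1, 4, 10, 10)))
        got = att(x).data
        a = ad.avg_pool2d(x, 2)
        a = att.mix(att.squeeze(a))
        a = att.vertical(att.horizontal(a))
        a = ad.sigmoid(a)
        want = ad.bilinear_resize(a, 10, 10).data
        np.testing.assert_allclose(got, want, atol=1e-6)


class TestBottleneck:
    def test_stride_two_halves_spatial_dims(self, rng):
        block = Bottleneck(BottleneckConfig(4, 8, 6, stride=2), rng=rng).eval()
        y = block(Tensor(rng.normal(size=(1, 4, 8, 8))))
        assert y.shape == (1, 6, 4, 4)

    def test_zero_residual_branch_is_identity(self, rng):
        block = Bottleneck(BottleneckConfig(4, 8, 4, stride=1), rng=rng).eval()
        for mod in (block.ghost2.primary, block.ghost2.cheap):
            mod.weight.data[...] = 0.0
        for bn in (block.ghost2.bn1, block.ghost2.bn2):
            bn.gamma.data[...] = 0.0
            bn.beta.data[...] = 0.0
        x = Tensor(rng.normal(size=(1, 4, 6, 6)))
        np.testing.assert_allclose(block(x).data, x.data, atol=1e-12)

    @pytest.mark.parametrize("stride", [1, 2])
    def test_matches_composition_oracle(self, rng, stride):
        cfg = BottleneckConfig(4, 8, 6, stride=stride)
        block = Bottleneck(cfg, rng=rng).eval()
        x = Tensor(rng.normal(size=(2, 4, 8, 8)))
        got = block(x).data
        f = block.ghost1(x) * block.attention(x)
        if stride == 2:
            f = block.down_bn(block.down(f))
        want = (block.ghost2(f) + block.shortcut(x)).data
        np.testing.assert_allclose(got, want, atol=1e-5)


# ---------------------------------------------------------------------------
# re-parameterization
# ---------------------------------------------------------------------------

class TestReparameterize:
    def test_single_branch_is_identity(self, rng):
        w = rng.normal(size=(2, 2, 3, 3))
        b = rng.normal(size=2)
        mw, mb = reparameterize([ConvBranch(w, b)])
        np.testing.assert_allclose(mw, w)
        np.testing.assert_allclose(mb, b)

    def test_two_scalar_1x1_kernels_sum(self):
        b1 = ConvBranch(np.full((1, 1, 1, 1), 0.5), np.zeros(1))
        b2 = ConvBranch(np.full((1, 1, 1, 1), 0.25), np.zeros(1))
        mw, mb = reparameterize([b1, b2], target_k=1)
        assert mw[0, 0, 0, 0] == pytest.approx(0.75)
        assert mb[0] == pytest.approx(0.0)

    def test_merged_equals_sum_of_branch_outputs_with_bn(self, rng):
        def bn_stats(c):
            return BatchNormStats(mean=rng.normal(size=c),
                                  var=rng.uniform(0.5, 2.0, size=c),
                                  scale=rng.normal(size=c),
                                  shift=rng.normal(size=c))

        b3 = ConvBranch(rng.normal(size=(3, 2, 3, 3)), rng.normal(size=3), bn_stats(3))
        b1 = ConvBranch(rng.normal(size=(3, 2, 1, 1)), rng.normal(size=3), bn_stats(3))
        mw, mb = reparameterize([b3, b1], target_k=3)
        for _ in range(20):
            x = Tensor(rng.normal(size=(1, 2, 6, 6)))
            merged = ad.conv2d(x, Tensor(mw), Tensor(mb), padding=1).data

            def branch_out(br):
                y = ad.conv2d(x, Tensor(br.weight), Tensor(br.bias),
                              padding=(br.weight.shape[2] // 2)).data
                s = br.bn.scale / np.sqrt(br.bn.var + br.bn.epsilon)
                return (y - br.bn.mean[None, :, None, None]) * s[None, :, None, None] \
                    + br.bn.shift[None, :, None, None]

            np.testing.assert_allclose(merged, branch_out(b3) + branch_out(b1),
                                       atol=1e-5)

    def test_idempotent(self, rng):
        branches = [ConvBranch(rng.normal(size=(2, 2, 3, 3)), rng.normal(size=2)),
                    ConvBranch(rng.normal(size=(2, 2, 1, 1)), rng.normal(size=2))]
        mw, mb = reparameterize(branches)
        mw2, mb2 = reparameterize([ConvBranch(mw, mb)])
        np.testing.assert_allclose(mw2, mw)
        np.testing.assert_allclose(mb2, mb)

    def test_incompatible_geometry_rejected(self, rng):
        with pytest.raises(ValueError):
            reparameterize([ConvBranch(rng.normal(size=(2, 2, 3, 3))),
                            ConvBranch(rng.normal(size=(4, 2, 3, 3)))])
        with pytest.raises(ValueError):
            reparameterize([])


# ---------------------------------------------------------------------------
# embedding extraction
# ---------------------------------------------------------------------------

class TestExtractFeatures:
    def test_full_spec_yields_960_dimensional_embedding(self):
        from ghostcbir import build_backbone, extract_features
        bb = build_backbone(full_backbone_spec(), seed=0)
        emb = extract_features(np.zeros((1, 64, 64)), bb)
        assert emb.shape == (1, 960)

    def test_global_pool_of_constant_map_is_the_constant(self):
        fmap = Tensor(np.stack([np.full((4, 4), c) for c in (1.5, -2.0, 0.25)])[None])
        pooled = fmap.mean(axis=(2, 3)).data
        np.testing.assert_allclose(pooled[0], [1.5, -2.0, 0.25])

    def test_toy_backbone_matches_block_composition_oracle(self, rng):
        from ghostcbir import build_backbone
        bb = build_backbone(toy_backbone_spec(), seed=11).eval()
        x = Tensor(rng.normal(size=(2, 1, 16, 16)))
        got = bb(x).data
        y = ad.relu(bb.stem_bn(bb.stem(x)))
        for block in bb.blocks:
            y = block(y)
        y = ad.relu(bb.head_bn(bb.head_conv(y)))
        np.testing.assert_allclose(got, y.mean(axis=(2, 3)).data, atol=1e-10)

    def test_forward_is_deterministic(self, rng):
        from ghostcbir import build_backbone, extract_features
        bb = build_backbone(toy_backbone_spec(), seed=5)
        x = rng.random((3, 16, 16))
        np.testing.assert_array_equal(extract_features(x, bb),
                                      extract_features(x, bb))

    def test_wrong_input_geometry_rejected(self, rng):
        from ghostcbir import build_backbone
        bb = build_backbone(toy_backbone_spec(), seed=5)
        with pytest.raises(ValueError):
            bb(Tensor(rng.normal(size=(1, 3, 16, 16))))
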