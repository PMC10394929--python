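"""Network construction, parameter accounting, inference and Grad-CAM."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikecount.hrnet import (
    ConfigError,
    HRNetConfig,
    build_network,
    count_parameters,
    forward,
    grad_cam,
    predict_mask,
)
from spikecount.nn import Tensor

from conftest import tiny_config


# -- independent closed-form parameter enumeration --------------------------

def _bn(c):
    return 2 * c


def _conv(cin, cout, k, bias=False):
    return cin * cout * k * k + (cout if bias else 0)


def _fuse(chs):
    n = 0
    for i, ci in enumerate(chs):
        for j, cj in enumerate(chs):
            if j == i:
                continue
            if j > i:
                n += _conv(cj, ci, 1) + _bn(ci)
            else:
                for s in range(i - j):
                    cout = ci if s == i - j - 1 else cj
                    n += _conv(cj, cout, 3) + _bn(cout)
    return n


def expected_param_count(width, num_classes=2, stem=64, stage1_blocks=4,
                         stage_modules=(1, 4, 3), blocks=4):
    """Layer-by-layer enumeration of the segmentation network's scalars."""
    chs = [width * 2**i for i in range(4)]
    c1 = stem * 4

    def bottleneck(cin, planes, down):
        n = (_conv(cin, planes, 1) + _bn(planes) + _conv(planes, planes, 3)
             + _bn(planes) + _conv(planes, 4 * planes, 1) + _bn(4 * planes))
        return n + (_conv(cin, 4 * planes, 1) + _bn(4 * planes) if down else 0)

    def stage(sub, modules):
        per_branch = sum(blocks * (2 * (_conv(c, c, 3) + _bn(c))) for c in sub)
        return modules * (per_branch + _fuse(sub))

    n = _conv(3, stem, 3) + _bn(stem) + _conv(stem, stem, 3) + _bn(stem)
    n += bottleneck(stem, stem, True)
    n += (stage1_blocks - 1) * bottleneck(c1, stem, False)
    n += _conv(c1, chs[0], 3) + _bn(chs[0]) + _conv(c1, chs[1], 3, ) + _bn(chs[1])
    n += stage(chs[:2], stage_modules[0])
    n += _conv(chs[1], chs[2], 3) + _bn(chs[2])
    n += stage(chs[:3], stage_modules[1])
    n += _conv(chs[2], chs[3], 3) + _bn(chs[3])
    n += stage(chs, stage_modules[2])
    cat = sum(chs)
    n += _conv(cat, cat, 1, bias=True) + _bn(cat) + _conv(cat, num_classes, 1, bias=True)
    return n


class TestConstruction:
    def test_unknown_variant_is_a_config_error(self):
        with pytest.raises(ConfigError, match="variant"):
            HRNetConfig(variant="w48")

    def test_branch_widths_double_per_branch(self):
        assert HRNetConfig(variant="w32").branch_widths == [32, 64, 128, 256]
        assert HRNetConfig(variant="w18").branch_widths == [18, 36, 72, 144]

    @pytest.mark.parametrize("variant,classes", [("w32", 2), ("w32", 3), ("w18", 2)])
    def test_parameter_count_matches_closed_form_enumeration(self, variant, classes):
        net = build_network(HRNetConfig(variant=variant, num_classes=classes))
        width = {"w32": 32, "w18": 18}[variant]
        assert count_parameters(net) == expected_param_count(width, classes)

    def test_w32_outweighs_w18(self):
        w32 = count_parameters(build_network(HRNetConfig(variant="w32")))
        w18 = count_parameters(build_network(HRNetConfig(variant="w18")))
        assert w32 > w18

    def test_repeated_builds_have_identical_counts(self):
        cfg = tiny_config()
        assert count_parameters(build_network(cfg, seed=0)) == count_parameters(
            build_network(cfg, seed=99)
        )

    def test_classifier_delta_between_class_counts(self):
        """Changing 2 -> 3 classes adds exactly one 1x1-classifier row: the
        concatenated channel count plus one bias."""
        two = count_parameters(build_network(HRNetConfig(variant="w32", num_classes=2)))
        three = count_parameters(build_network(HRNetConfig(variant="w32", num_classes=3)))
        assert three - two == sum(HRNetConfig(variant="w32").branch_widths) + 1

    def test_attention_gates_add_parameters_and_preserve_names(self):
        plain = build_network(HRNetConfig(variant="w32"))
        gated = build_network(HRNetConfig(variant="w32", cbam_enabled=True))
        n_plain = {n for n, _ in plain.named_parameters()}
        n_gated = {n for n, _ in gated.named_parameters()}
        assert count_parameters(gated) > count_parameters(plain)
        assert n_plain < n_gated
        extra = count_parameters(gated) - count_parameters(plain)
        # standard gates: shared MLP (2 * C * C//16) per gated tensor + 2*7*7 conv
        widths = HRNetConfig(variant="w32").branch_widths
        gated_channels = widths[1:] + [sum(widths)]
        assert extra == sum(2 * c * (c // 16) + 2 * 49 for c in gated_channels)


class TestInference:
    def test_forward_shape_contract_at_working_resolution(self):
        net = build_network(tiny_config(), seed=1)
        x = np.random.default_rng(0).random((1, 3, 480, 480), dtype=np.float32)
        assert forward(net, x).shape == (1, 2, 480, 480)

    def test_forward_is_deterministic_in_evaluation_mode(self):
        net = build_network(tiny_config(), seed=2)
        x = np.random.default_rng(1).random((2, 3, 64, 64), dtype=np.float32)
        a, b = forward(net, x), forward(net, x)
        assert np.array_equal(a, b)

    def test_softmax_of_logits_normalizes_per_pixel(self):
        net = build_network(tiny_config(), seed=3)
        x = np.random.default_rng(2).random((1, 3, 64, 64), dtype=np.float32)
        z = forward(net, x)
        z = z - z.max(axis=1, keepdims=True)
        sm = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        assert np.allclose(sm.sum(axis=1), 1.0, atol=1e-6)

    def test_indivisible_input_size_is_rejected_with_explanation(self):
        net = build_network(tiny_config(), seed=4)
        x = np.zeros((1, 3, 66, 66), dtype=np.float32)
        with pytest.raises(ValueError, match="divisible by 4"):
            forward(net, x)

    def test_flip_equivariance_smoke_on_stride_one_paths(self):
        """Sanity smoke test of the convolution/upsampling plumbing: with
        left-right-symmetric kernels, the stride-1 residual blocks and the
        bilinear upsampling path are exactly flip-equivariant.  (The full
        network is not: stride-2 downsampling on even-sized grids samples a
        mirror-asymmetric pixel lattice.)"""
        from spikecount.hrnet import BasicBlock, _FuseUp
        from spikecount.nn import seed_init

        seed_init(11)
        block = BasicBlock(4)
        up = _FuseUp(4, 3)
        for mod in (block, up):
            for _, p in mod.named_parameters():
                if p.data.ndim == 4:
                    p.data = 0.5 * (p.data + p.data[..., ::-1])
        block.train(), up.train()
        x = np.random.default_rng(3).random((1, 4, 9, 9), dtype=np.float32)
        direct = up(block(Tensor(x)), 18, 18).data
        flipped = up(
            block(Tensor(np.ascontiguousarray(x[:, :, :, ::-1]))), 18, 18
        ).data[:, :, :, ::-1]
        assert np.allclose(direct, flipped, atol=1e-5)


class TestPredictMask:
    def test_uniform_class_preference(self):
        logits = np.stack([np.zeros((4, 4)), np.ones((4, 4))])
        assert predict_mask(logits).sum() == 16

    def test_exact_ties_break_toward_background(self):
        logits = np.zeros((2, 5, 5))
        assert predict_mask(logits).sum() == 0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_per_pixel_argmax_oracle(self, seed):
        rng = np.random.default_rng(seed)
        logits = rng.standard_normal((3, 6, 6))
        got = predict_mask(logits)
        for r in range(6):
            for c in range(6):
                best = max(range(3), key=lambda k: (logits[k, r, c], -k))
                assert got[r, c] == best


class TestGradCAM:
    def test_map_is_normalized_and_input_sized(self):
        net = build_network(tiny_config(), seed=6)
        x = np.random.default_rng(4).random((3, 64, 64), dtype=np.float32)
        cam = grad_cam(net, x, target_class=1)
        assert cam.shape == (64, 64)
        assert cam.min() >= 0.0 and cam.max() <= 1.0

    def test_out_of_range_class_is_rejected(self):
        net = build_network(tiny_config(), seed=7)
        with pytest.raises(ValueError, match="target_class"):
            grad_cam(net, np.zeros((3, 64, 64), dtype=np.float32), target_class=5)

    def test_linear_head_highlights_its_source_channel(self):
        """If the class score reads a single feature channel, the map must be
        that channel's (rectified) activation, upsampled and normalized."""
        net = build_network(tiny_config(), seed=8)
        k = 2
        w = np.zeros_like(net.head.classifier.weight.data)
        w[1, k, 0, 0] = 1.0
        net.head.classifier.weight.data = w
        net.head.classifier.bias.data = np.zeros_like(net.head.classifier.bias.data)
        x = np.random.default_rng(5).random((3, 64, 64), dtype=np.float32)
        cam = grad_cam(net, x, target_class=1)
        net.eval()
        net(Tensor(x[None]), retain_feature=True)
        feat = net.head._last_feature.data[0, k]
        from spikecount.nn import upsample_bilinear

        expected = upsample_bilinear(Tensor(feat[None, None]), 64, 64).data[0, 0]
        expected = np.maximum(expected, 0.0)
        if expected.max() > 0:
            expected = (expected - expected.min()) / (expected.max() - expected.min())
        assert np.allclose(cam, expected, atol=1e-5)
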