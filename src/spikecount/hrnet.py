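"""High-resolution semantic-segmentation network (HRNetV2-style), with optional CBAM.

The network keeps a high-resolution stream throughout: a two-convolution
stride-2 stem brings the input to 1/4 resolution, a bottleneck stage widens it
to 256 channels, and three further stages run 2/3/4 parallel branches whose
widths double as resolution halves (w32: 32/64/128/256; w18: 18/36/72/144).
Every stage module ends with full cross-resolution fusion (1x1 conv +
upsampling toward higher resolution, strided 3x3 chains toward lower).  The
representation head upsamples all branches to the top resolution, concatenates
them (480 channels for w32, 270 for w18), fuses with a 1x1 convolution + batch
norm + rectifier, and classifies per pixel with a final 1x1 convolution; the
logits are bilinearly upsampled back to the input size.

With ``cbam_enabled`` a CBAM gate is applied to each lower-resolution branch
immediately before its upsampling in the head, plus one gate on the
concatenated representation before the fusion convolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .cbam import CBAM
from .nn import Tensor

__all__ = [
    "ConfigError",
    "HRNetConfig",
    "HRNetSeg",
    "build_network",
    "count_parameters",
    "forward",
    "predict_mask",
    "grad_cam",
]

_VARIANT_WIDTHS = {"w18": 18, "w32": 32}


class ConfigError(ValueError):
    pass


@dataclass
class HRNetConfig:
    """Network specification.

    ``base_width``/``stem_width``/``stage_modules``/``stage1_blocks``/
    ``blocks_per_branch`` default to the standard architecture and exist so
    that width- and depth-reduced networks can be built for small-scale
    experiments; the published variants are selected by ``variant`` alone.
    """

    variant: str = "w32"
    num_classes: int = 2
    cbam_enabled: bool = False
    input_edge: int = 480
    base_width: int | None = None
    stem_width: int = 64
    stage1_blocks: int = 4
    stage_modules: tuple = (1, 4, 3)
    blocks_per_branch: int = 4
    cbam_reduction: int = 16
    cbam_kernel: int = 7

    def __post_init__(self):
        if self.variant not in _VARIANT_WIDTHS:
            raise ConfigError(f"unknown variant {self.variant!r}; expected w18 or w32")
        if self.num_classes < 2:
            raise ConfigError("num_classes must be >= 2")
        if self.input_edge < 4:
            raise ConfigError("input_edge must be >= 4")
        if len(self.stage_modules) != 3:
            raise ConfigError("stage_modules must give module counts for stages 2-4")

    @property
    def branch_widths(self) -> list[int]:
        w = self.base_width if self.base_width is not None else _VARIANT_WIDTHS[self.variant]
        return [w * 2**i for i in range(4)]


def _conv_bn(cin, cout, k, stride=1, bias=False):
    return nn.Sequential(
        nn.Conv2d(cin, cout, k, stride=stride, padding=k // 2, bias=bias),
        nn.BatchNorm2d(cout),
    )


class BasicBlock(nn.Module):
    def __init__(self, channels):
        super().__init__()
        self.conv1 = _conv_bn(channels, channels, 3)
        self.conv2 = _conv_bn(channels, channels, 3)

    def forward(self, x):
        y = self.conv2(nn.relu(self.conv1(x)))
        return nn.relu(nn.add(y, x))


class Bottleneck(nn.Module):
    expansion = 4

    def __init__(self, cin, planes, downsample: bool):
        super().__init__()
        cout = planes * self.expansion
        self.conv1 = _conv_bn(cin, planes, 1)
        self.conv2 = _conv_bn(planes, planes, 3)
        self.conv3 = _conv_bn(planes, cout, 1)
        self.downsample = _conv_bn(cin, cout, 1) if downsample else None

    def forward(self, x):
        y = nn.relu(self.conv1(x))
        y = nn.relu(self.conv2(y))
        y = self.conv3(y)
        shortcut = self.downsample(x) if self.downsample is not None else x
        return nn.relu(nn.add(y, shortcut))


class _FuseDown(nn.Module):
    """Chain of stride-2 3x3 convolutions taking branch j down to branch i (> j)."""

    def __init__(self, cj, ci, steps):
        super().__init__()
        layers = []
        for s in range(steps):
            last = s == steps - 1
            layers.append(_conv_bn(cj, ci if last else cj, 3, stride=2))
            if not last:
                layers.append(nn.ReLU())
        self.chain = nn.Sequential(*layers)

    def forward(self, x):
        return self.chain(x)


class _FuseUp(nn.Module):
    """1x1 channel projection of branch j followed by upsampling to branch i (< j)."""

    def __init__(self, cj, ci):
        super().__init__()
        self.proj = _conv_bn(cj, ci, 1)

    def forward(self, x, out_h, out_w):
        return nn.upsample_bilinear(self.proj(x), out_h, out_w, align_corners=False)


class HRModule(nn.Module):
    """Parallel per-branch residual blocks followed by full cross-branch fusion."""

    def __init__(self, widths, blocks_per_branch):
        super().__init__()
        self.widths = list(widths)
        self.branches = nn.ModuleList(
            nn.Sequential(*[BasicBlock(c) for _ in range(blocks_per_branch)])
            for c in widths
        )
        fuse = nn.ModuleList()
        for i, ci in enumerate(widths):
            row = nn.ModuleList()
            for j, cj in enumerate(widths):
                if j == i:
                    row.append(nn.Module())  # identity placeholder
                elif j > i:
                    row.append(_FuseUp(cj, ci))
                else:
                    row.append(_FuseDown(cj, ci, i - j))
            fuse.append(row)
        self.fuse = fuse

    def forward(self, xs):
        xs = [b(x) for b, x in zip(self.branches, xs)]
        outs = []
        for i in range(len(xs)):
            h, w = xs[i].shape[2], xs[i].shape[3]
            acc = xs[i]
            for j in range(len(xs)):
                if j == i:
                    continue
                layer = self.fuse[i][j]
                y = layer(xs[j], h, w) if isinstance(layer, _FuseUp) else layer(xs[j])
                acc = nn.add(acc, y)
            outs.append(nn.relu(acc))
        return outs


class _Head(nn.Module):
    """Representation head: upsample, concatenate, fuse, classify."""

    def __init__(self, widths, num_classes, cbam_enabled, reduction, kernel):
        super().__init__()
        cat = sum(widths)
        self.widths = list(widths)
        self.cbam_enabled = cbam_enabled
        if cbam_enabled:
            # one gate per lower-resolution branch + one on the concatenation
            self.branch_gates = nn.ModuleList(
                CBAM(c, reduction, kernel) for c in widths[1:]
            )
            self.concat_gate = CBAM(cat, reduction, kernel)
        self.fuse = nn.Sequential(
            nn.Conv2d(cat, cat, 1, bias=True), nn.BatchNorm2d(cat), nn.ReLU()
        )
        self.classifier = nn.Conv2d(cat, num_classes, 1, bias=True)

    def forward(self, xs, retain_feature=False):
        h, w = xs[0].shape[2], xs[0].shape[3]
        ups = [xs[0]]
        for k, x in enumerate(xs[1:]):
            if self.cbam_enabled:
                x = self.branch_gates[k](x)
            ups.append(nn.upsample_bilinear(x, h, w, align_corners=False))
        rep = nn.concat(ups, axis=1)
        if self.cbam_enabled:
            rep = self.concat_gate(rep)
        feature = self.fuse(rep)
        if retain_feature:
            self._last_feature = feature
        return self.classifier(feature)


class HRNetSeg(nn.Module):
    """Full segmentation network; see the module docstring for the layout."""

    def __init__(self, config: HRNetConfig):
        super().__init__()
        self.config = config
        widths = config.branch_widths
        sw = config.stem_width
        self.stem1 = _conv_bn(3, sw, 3, stride=2)
        self.stem2 = _conv_bn(sw, sw, 3, stride=2)
        blocks = [Bottleneck(sw, sw, downsample=True)]
        blocks += [
            Bottleneck(sw * Bottleneck.expansion, sw, downsample=False)
            for _ in range(config.stage1_blocks - 1)
        ]
        self.layer1 = nn.Sequential(*blocks)
        c1 = sw * Bottleneck.expansion
        self.transition1 = nn.ModuleList(
            [
                nn.Sequential(_conv_bn(c1, widths[0], 3), nn.ReLU()),
                nn.Sequential(_conv_bn(c1, widths[1], 3, stride=2), nn.ReLU()),
            ]
        )
        m2, m3, m4 = config.stage_modules
        bpb = config.blocks_per_branch
        self.stage2 = nn.Sequential(*[HRModule(widths[:2], bpb) for _ in range(m2)])
        self.transition2 = nn.Sequential(_conv_bn(widths[1], widths[2], 3, stride=2), nn.ReLU())
        self.stage3 = nn.Sequential(*[HRModule(widths[:3], bpb) for _ in range(m3)])
        self.transition3 = nn.Sequential(_conv_bn(widths[2], widths[3], 3, stride=2), nn.ReLU())
        self.stage4 = nn.Sequential(*[HRModule(widths, bpb) for _ in range(m4)])
        self.head = _Head(
            widths,
            config.num_classes,
            config.cbam_enabled,
            config.cbam_reduction,
            config.cbam_kernel,
        )

    def forward(self, x: Tensor, retain_feature: bool = False) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        if h % 4 or w % 4:
            raise ValueError(
                f"input spatial size {h}x{w} must be divisible by 4 "
                "(two stride-2 stem convolutions)"
            )
        y = nn.relu(self.stem1(x))
        y = nn.relu(self.stem2(y))
        y = self.layer1(y)
        xs = [t(y) for t in self.transition1]
        for mod in self.stage2:
            xs = mod(xs)
        xs = xs + [self.transition2(xs[-1])]
        for mod in self.stage3:
            xs = mod(xs)
        xs = xs + [self.transition3(xs[-1])]
        for mod in self.stage4:
            xs = mod(xs)
        logits = self.head(xs, retain_feature=retain_feature)
        return nn.upsample_bilinear(logits, h, w, align_corners=False)

    # -- parameter partitions (transfer learning) ----------------------
    def backbone_parameters(self):
        return [(n, p) for n, p in self.named_parameters() if not n.startswith("head.")]

    def head_parameters(self):
        return [(n, p) for n, p in self.named_parameters() if n.startswith("head.")]


def build_network(config: HRNetConfig, seed: int = 0) -> HRNetSeg:
    """Construct the network with deterministic (seeded) weight initialization."""
    nn.seed_init(seed)
    return HRNetSeg(config)


def count_parameters(network: nn.Module) -> int:
    """Number of learnable scalars in the network."""
    return int(sum(p.data.size for p in network.parameters()))


def forward(network: HRNetSeg, batch: np.ndarray) -> np.ndarray:
    """Deterministic evaluation-mode forward pass.

    ``batch`` is (N, 3, H, W) float in [0, 1]; returns (N, num_classes, H, W)
    logits at the input resolution.
    """
    batch = np.asarray(batch, dtype=np.float32)
    if batch.ndim != 4 or batch.shape[1] != 3:
        raise ValueError("expected an Nx3xHxW batch")
    was_training = network.training
    network.eval()
    try:
        out = network(Tensor(batch)).data
    finally:
        network.train(was_training)
    return out


def predict_mask(logits: np.ndarray) -> np.ndarray:
    """Per-pixel argmax of (num_classes, H, W) scores; ties go to the lower class."""
    logits = np.asarray(logits)
    if logits.ndim != 3:
        raise ValueError("expected num_classes x H x W logits")
    if not np.all(np.isfinite(logits)):
        raise ValueError("logits must be finite")
    return logits.argmax(axis=0)


def grad_cam(network: HRNetSeg, image: np.ndarray, target_class: int) -> np.ndarray:
    """Gradient-weighted class-activation map on the final convolutional output.

    The class score is the spatial sum of the target class's logits; each
    channel of the head's fused feature map is weighted by the spatial mean of
    the score's gradient with respect to it, the weighted sum is rectified,
    bilinearly upsampled to the input size, and min-max normalized to [0, 1]
    (an identically-zero map is returned unchanged).
    """
    if target_class < 0 or target_class >= network.config.num_classes:
        raise ValueError(
            f"target_class {target_class} out of range "
            f"(num_classes={network.config.num_classes})"
        )
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 3 or image.shape[0] != 3:
        raise ValueError("expected a 3xHxW image")
    was_training = network.training
    network.eval()
    try:
        x = Tensor(image[None])
        logits = network(x, retain_feature=True)
        score = nn.reduce_sum(logits, axes=(0, 2, 3))
        score_c = nn.reduce_sum(
            nn.mul(score, Tensor(np.eye(network.config.num_classes)[target_class]))
        )
        score_c.backward()
    finally:
        network.train(was_training)
    feature = network.head._last_feature
    weights = feature.grad.mean(axis=(2, 3))  # (1, C)
    cam = np.maximum((weights[0][:, None, None] * feature.data[0]).sum(axis=0), 0.0)
    cam_t = Tensor(cam[None, None])
    cam_up = nn.upsample_bilinear(
        cam_t, image.shape[1], image.shape[2], align_corners=False
    ).data[0, 0]
    peak = cam_up.max()
    if peak > 0:
        cam_up = (cam_up - cam_up.min()) / (peak - cam_up.min())
    return cam_up
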