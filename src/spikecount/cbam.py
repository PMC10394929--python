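"""Convolutional Block Attention Module (CBAM).

CBAM refines a feature tensor with two sequential multiplicative gates:

1. *Channel attention* — the feature map is reduced by global average pooling
   and global max pooling, both vectors pass through one shared two-layer
   perceptron (C -> C/r -> C, rectifier in between, no biases), the two outputs
   are summed and squashed with a sigmoid to one weight per channel in (0, 1).
2. *Spatial attention* — the channel-wise maximum and mean of the (already
   channel-gated) tensor are stacked into a 2-channel map and convolved with a
   single odd-sized kernel to one channel, again squashed with a sigmoid.

Both gates are strictly inside (0, 1), so the refined tensor is an elementwise
attenuation of the input.  Channel attention is always applied first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["CBAM", "CBAMParams", "channel_attention", "spatial_attention", "apply_cbam"]


@dataclass
class CBAMParams:
    """Configuration of a CBAM gate.

    reduction_ratio
        Bottleneck ratio *r* of the shared MLP; the hidden width is
        ``max(1, C // r)``.
    spatial_kernel
        Odd edge length of the spatial-attention convolution (2 in / 1 out
        channels).
    """

    channels: int
    reduction_ratio: int = 16
    spatial_kernel: int = 7

    def __post_init__(self):
        if self.channels < 1:
            raise ValueError("channels must be >= 1")
        if self.reduction_ratio < 1:
            raise ValueError("reduction_ratio must be >= 1")
        if self.spatial_kernel < 1 or self.spatial_kernel % 2 == 0:
            raise ValueError("spatial_kernel must be a positive odd integer")


class CBAM(nn.Module):
    """Sequential channel-then-spatial attention gate for NCHW tensors."""

    def __init__(self, channels: int, reduction_ratio: int = 16, spatial_kernel: int = 7):
        super().__init__()
        self.params = CBAMParams(channels, reduction_ratio, spatial_kernel)
        hidden = max(1, channels // reduction_ratio)
        # shared MLP, bias-free in both layers
        self.fc1 = nn.Linear(channels, hidden, bias=False)
        self.fc2 = nn.Linear(hidden, channels, bias=False)
        self.spatial_conv = nn.Conv2d(
            2, 1, spatial_kernel, padding=spatial_kernel // 2, bias=False
        )

    # -- gates ---------------------------------------------------------
    def _mlp(self, v: Tensor) -> Tensor:
        return self.fc2(nn.relu(self.fc1(v)))

    def channel_gate(self, x: Tensor) -> Tensor:
        """Per-channel weights, shape (N, C)."""
        if x.ndim != 4:
            raise ValueError("expected an NCHW tensor")
        if x.shape[1] != self.params.channels:
            raise ValueError(
                f"feature tensor has {x.shape[1]} channels, gate expects "
                f"{self.params.channels}"
            )
        avg = nn.reduce_mean(x, (2, 3))
        mx = nn.reduce_max(x, (2, 3))
        return nn.sigmoid(nn.add(self._mlp(avg), self._mlp(mx)))

    def spatial_gate(self, x: Tensor) -> Tensor:
        """Per-position weights, shape (N, 1, H, W); stacking order (max, mean)."""
        mx = nn.reduce_max(x, 1, keepdims=True)
        avg = nn.reduce_mean(x, 1, keepdims=True)
        return nn.sigmoid(self.spatial_conv(nn.concat([mx, avg], axis=1)))

    def forward(self, x: Tensor) -> Tensor:
        w = self.channel_gate(x)
        xg = nn.mul(x, nn.reshape(w, (x.shape[0], x.shape[1], 1, 1)))
        m = self.spatial_gate(xg)
        return nn.mul(xg, m)


# -- functional single-tensor API (C, H, W) ---------------------------------

def _as_batch(x: np.ndarray) -> Tensor:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError("expected a CxHxW feature tensor")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature tensor must be finite")
    return Tensor(x[None])


def channel_attention(x: np.ndarray, gate: CBAM) -> np.ndarray:
    """Channel weights w = sigmoid(MLP(avgpool(x)) + MLP(maxpool(x))), shape (C,)."""
    return gate.channel_gate(_as_batch(x)).data[0]


def spatial_attention(x: np.ndarray, gate: CBAM) -> np.ndarray:
    """Spatial map sigmoid(conv([max; mean])), shape (1, H, W)."""
    return gate.spatial_gate(_as_batch(x)).data[0]


def apply_cbam(x: np.ndarray, gate: CBAM) -> np.ndarray:
    """Channel-gate then spatial-gate *x*; returns a tensor of the same shape."""
    return gate(_as_batch(x)).data[0]
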