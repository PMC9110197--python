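"""Building blocks of the attention-gated parallel U-Net.

Four bespoke components sit on top of the generic layers:

* :class:`ConvBlock` — the double (3x3 conv, batch-norm, ReLU) unit every
  encoder/decoder stage is made of.
* :class:`TwoModalBlock` — fuses same-scale PET and fused PET/CT encoder
  features: the concatenation is passed through a small conv stack whose
  sigmoid output gates the concatenation elementwise.
* :class:`SpatialAttention` / :class:`ChannelAttention` and their
  composition :class:`HybridAttention` — CBAM-style gates with residual
  ("x + x * gate") form, applied to the concatenated skip features of the
  two subnetworks.
* :class:`MFABlock` — multiscale feature aggregation: the four decoder
  scales of both subnetworks are resampled to full resolution, compressed
  to 16 channels each, concatenated into a 64-channel map F, and combined
  as ``F*alpha*beta + F*alpha + F`` with learned channel (alpha) and
  pixelwise (beta) gates.

Every gate exposes a ``gate_override`` attribute (None, or a constant in
[0, 1]) so the closed-form limits of the residual algebra — override 0
returning the input unchanged, override 1 doubling it — can be exercised
directly.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor


def _maybe_override(gate: Tensor, override) -> Tensor:
    if override is None:
        return gate
    return Tensor(np.full_like(gate.data, override))


class ConvBlock(nn.Module):
    """Two rounds of 3x3 convolution + batch normalization + ReLU."""

    def __init__(self, in_ch: int, out_ch: int, rng):
        super().__init__()
        self.body = nn.Sequential(
            nn.Conv2d(in_ch, out_ch, 3, rng),
            nn.BatchNorm2d(out_ch),
            nn.ReLU(),
            nn.Conv2d(out_ch, out_ch, 3, rng),
            nn.BatchNorm2d(out_ch),
            nn.ReLU(),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.body(x)


class TwoModalBlock(nn.Module):
    """Gated fusion of same-scale PET and fused PET/CT encoder features.

    Inputs of C channels each are concatenated (2C); a learned gate in
    [0, 1] with 2C channels multiplies the concatenation elementwise.

    Parameters
    ----------
    channels : int
        Channel count C of each input.
    gate_variant : {"conv3x3", "conv1x1"}
        Shape of the second gate convolution. ``conv3x3`` is the default
        (1x1 conv + ReLU, then 3x3 conv, then sigmoid); ``conv1x1``
        replaces the 3x3 convolution with a second 1x1.
    """

    def __init__(self, channels: int, rng, gate_variant: str = "conv3x3"):
        super().__init__()
        if gate_variant not in ("conv3x3", "conv1x1"):
            raise ValueError(f"unknown gate_variant {gate_variant!r}")
        c2 = 2 * channels
        k2 = 3 if gate_variant == "conv3x3" else 1
        self.conv1 = nn.Conv2d(c2, c2, 1, rng)
        self.conv2 = nn.Conv2d(c2, c2, k2, rng)
        self.gate_override = None

    def forward(self, x1: Tensor, x2: Tensor) -> Tensor:
        if x1.shape != x2.shape:
            raise ValueError(f"shape mismatch: {x1.shape} vs {x2.shape}")
        cat = nn.concat([x1, x2], axis=1)
        gate = nn.sigmoid(self.conv2(nn.relu(self.conv1(cat))))
        gate = _maybe_override(gate, self.gate_override)
        return cat * gate


class SpatialAttention(nn.Module):
    """Residual spatial gate from channel-pooled descriptors.

    The channelwise mean map and channelwise max map (1 x H x W each) are
    concatenated, convolved 3x3, and squashed by a sigmoid into a spatial
    gate s; the output is ``x + x * s``.
    """

    def __init__(self, rng):
        super().__init__()
        self.conv = nn.Conv2d(2, 1, 3, rng)
        self.gate_override = None

    def forward(self, x: Tensor) -> Tensor:
        pooled = nn.concat([nn.channel_mean(x), nn.channel_max(x)], axis=1)
        gate = nn.sigmoid(self.conv(pooled))
        gate = _maybe_override(gate, self.gate_override)
        return x + x * gate


class ChannelAttention(nn.Module):
    """Residual channel gate from global pooling and a shared two-layer MLP.

    Global average- and max-pooled descriptors (C each) pass through one
    shared MLP with hidden width floor(C/3) and ReLU; the two outputs are
    summed and squashed into per-channel weights alpha, and the output is
    ``x + x * alpha``.
    """

    def __init__(self, channels: int, rng, hidden: int | None = None,
                 bias: bool = False):
        super().__init__()
        if hidden is None:
            hidden = channels // 3
        if hidden < 1:
            raise ValueError(
                f"channel attention needs >= 3 channels (got {channels})")
        self.channels = channels
        self.hidden = hidden
        self.fc1 = nn.Linear(channels, hidden, rng, bias=bias)
        self.fc2 = nn.Linear(hidden, channels, rng, bias=bias)
        self.gate_override = None

    def _mlp(self, v: Tensor) -> Tensor:
        return self.fc2(nn.relu(self.fc1(v)))

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        avg = nn.global_avg_pool2d(x)
        mx = nn.global_max_pool2d(x)
        flat_avg = _reshape(avg, (n, c))
        flat_max = _reshape(mx, (n, c))
        alpha = nn.sigmoid(self._mlp(flat_avg) + self._mlp(flat_max))
        alpha = _reshape(alpha, (n, c, 1, 1))
        alpha = _maybe_override(alpha, self.gate_override)
        return x + x * alpha


class HybridAttention(nn.Module):
    """Channel-then-spatial attention over the concatenated skip features.

    Applied on concat(F_hybrid, F_CT) at each scale; the composition order
    is configurable (channel-first by default, the CBAM convention).
    """

    def __init__(self, channels: int, rng, order: str = "channel_first"):
        super().__init__()
        if order not in ("channel_first", "spatial_first"):
            raise ValueError(f"unknown attention order {order!r}")
        self.order = order
        self.channel = ChannelAttention(channels, rng)
        self.spatial = SpatialAttention(rng)

    def forward(self, f_hybrid: Tensor, f_ct: Tensor) -> Tensor:
        if f_hybrid.shape[2:] != f_ct.shape[2:]:
            raise ValueError(
                f"spatial mismatch: {f_hybrid.shape} vs {f_ct.shape}")
        x = nn.concat([f_hybrid, f_ct], axis=1)
        if self.order == "channel_first":
            return self.spatial(self.channel(x))
        return self.channel(self.spatial(x))


class MFABlock(nn.Module):
    """Multiscale feature aggregation over four decoder scales.

    Per scale the decoder_A and decoder_B maps are concatenated, resampled
    bilinearly to ``out_size``, and compressed to ``per_scale_channels``
    (default 16) by a 1x1 convolution; the four results are concatenated
    into F (64 channels). A channel gate alpha (sigmoid MLP on the
    average-pooled F, hidden width floor(64/3)=21) and a pixelwise gate
    beta (sigmoid of 1x1 conv of ReLU of 3x3 conv of F*alpha) combine as
    ``F*alpha*beta + F*alpha + F``.
    """

    def __init__(self, pair_channels: list[tuple[int, int]], rng,
                 out_size: int = 50, per_scale_channels: int = 16):
        super().__init__()
        self.n_scales = len(pair_channels)
        self.out_size = out_size
        self.compress = [
            nn.Conv2d(ca + cb, per_scale_channels, 1, rng)
            for ca, cb in pair_channels
        ]
        total = self.n_scales * per_scale_channels
        self.total_channels = total
        hidden = total // 3
        self.fc1 = nn.Linear(total, hidden, rng, bias=False)
        self.fc2 = nn.Linear(hidden, total, rng, bias=False)
        self.conv3 = nn.Conv2d(total, total, 3, rng)
        self.conv1 = nn.Conv2d(total, total, 1, rng)
        self.alpha_override = None
        self.beta_override = None

    def aggregate(self, decoder_pairs) -> Tensor:
        """Resample + compress + concatenate the four scales into F."""
        if len(decoder_pairs) != self.n_scales:
            raise ValueError(
                f"expected {self.n_scales} decoder scales, got {len(decoder_pairs)}")
        maps = []
        for (a, b), comp in zip(decoder_pairs, self.compress):
            if a.shape[2:] != b.shape[2:]:
                raise ValueError("decoder pair not spatially aligned")
            cat = nn.concat([a, b], axis=1)
            maps.append(comp(nn.bilinear_resize(cat, self.out_size)))
        return nn.concat(maps, axis=1)

    def forward(self, decoder_pairs) -> Tensor:
        f = self.aggregate(decoder_pairs)
        n, c = f.shape[0], f.shape[1]
        pooled = _reshape(nn.global_avg_pool2d(f), (n, c))
        alpha = nn.sigmoid(self.fc2(nn.relu(self.fc1(pooled))))
        alpha = _reshape(alpha, (n, c, 1, 1))
        alpha = _maybe_override(alpha, self.alpha_override)
        fa = f * alpha
        beta = nn.sigmoid(self.conv1(nn.relu(self.conv3(fa))))
        beta = _maybe_override(beta, self.beta_override)
        return fa * beta + fa + f


def _reshape(x: Tensor, shape) -> Tensor:
    """Differentiable reshape."""
    orig = x.data.shape
    out = Tensor(x.data.reshape(shape))
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)

        def backward(g):
            x._accumulate(g.reshape(orig))

        out._backward = backward
    return out
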