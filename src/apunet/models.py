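"""Model assembly: the parallel U-Net, its ablations, and a plain U-Net.

Seven variants share one construction path so that adding or removing a
block never changes the output contract (all emit ``num_classes`` logits
at the input resolution):

``unet``
    Single-modality (CT) U-Net, encoder channels 64..1024.
``meu_net``
    Multi-encoder U-Net: three encoders (CT, PET, fused) with the U-Net
    schedule; same-scale skip features and the bottlenecks are summed.
``pu_net``
    Parallel U-Net: UNet_A (two encoders, fused + PET, channels 16..256)
    and UNet_B (CT, channels 32..512); skip features of the three encoder
    paths are concatenated and passed plain; the two subnetwork logit maps
    are summed.
``sapu_net`` / ``capu_net``
    PU-Net plus a spatial / channel attention gate on the concatenated
    skip features.
``mfpu_net``
    PU-Net plus the multiscale feature-aggregation head over both
    decoders' four scales.
``apu_net``
    The full model: two-modal fusion gates on the UNet_A encoder pairs,
    hybrid (channel + spatial) attention on skips, and the MFA head.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import nn
from .blocks import ConvBlock, ChannelAttention, HybridAttention, MFABlock, \
    SpatialAttention, TwoModalBlock
from .nn import Tensor
from .phantom import ImageTriplet

VARIANTS = ("unet", "meu_net", "pu_net", "sapu_net", "capu_net", "mfpu_net",
            "apu_net")


class BlockOptions(BaseModel):
    """Switches for the points the architecture description leaves open."""

    model_config = ConfigDict(extra="forbid")

    gate_variant: Literal["conv3x3", "conv1x1"] = "conv3x3"
    attention_order: Literal["channel_first", "spatial_first"] = "channel_first"
    dropout_p: float = Field(0.5, ge=0.0, lt=1.0)
    mfa_per_scale_channels: int = Field(16, ge=1)


class ModelSpec(BaseModel):
    """Architecture variant plus the per-layer channel/size schedule."""

    model_config = ConfigDict(extra="forbid")

    variant: Literal[VARIANTS] = "apu_net"
    base_channels_a: int = Field(16, ge=1)
    base_channels_b: int = Field(32, ge=1)
    base_channels_unet: int = Field(64, ge=1)
    depth: int = Field(5, ge=2)
    input_size: int = Field(50, ge=8)
    num_classes: int = Field(2, ge=2)
    block_options: BlockOptions = BlockOptions()

    def channels_a(self) -> list[int]:
        return [self.base_channels_a * 2 ** i for i in range(self.depth)]

    def channels_b(self) -> list[int]:
        return [self.base_channels_b * 2 ** i for i in range(self.depth)]

    def channels_unet(self) -> list[int]:
        return [self.base_channels_unet * 2 ** i for i in range(self.depth)]

    def spatial_sizes(self) -> list[int]:
        """Encoder sizes by repeated floor-halving, e.g. 50,25,12,6,3."""
        sizes = [self.input_size]
        for _ in range(self.depth - 1):
            sizes.append(sizes[-1] // 2)
        return sizes


@dataclass
class ForwardTrace:
    """Per-block output shapes and the final logits of one forward pass."""

    blocks: list[tuple[str, int, int, int]] = field(default_factory=list)
    outputs: dict[str, np.ndarray] = field(default_factory=dict)

    def record(self, name: str, t: Tensor) -> None:
        _, c, h, w = t.shape
        self.blocks.append((name, c, h, w))

    def shape_of(self, name: str) -> tuple[int, int, int]:
        for bname, c, h, w in self.blocks:
            if bname == name:
                return (c, h, w)
        raise KeyError(name)


class _Encoder(nn.Module):
    """Contracting path: ConvBlock per level, 2x2 max-pool between levels."""

    def __init__(self, in_ch: int, channels: list[int], rng):
        super().__init__()
        self.blocks = []
        prev = in_ch
        for c in channels:
            self.blocks.append(ConvBlock(prev, c, rng))
            prev = c
        self.pool = nn.MaxPool2d(2)

    def forward(self, x: Tensor) -> list[Tensor]:
        feats = []
        for i, block in enumerate(self.blocks):
            if i > 0:
                x = self.pool(x)
            x = block(x)
            feats.append(x)
        return feats


class _Decoder(nn.Module):
    """Expanding path: transpose-conv upsampling, skip concat, ConvBlock.

    ``sizes`` is the full encoder size ladder (fine to coarse); transpose
    convolutions get output-padding where doubling misses the mirrored
    size (12 -> 25).
    """

    def __init__(self, channels: list[int], sizes: list[int], rng):
        super().__init__()
        self.ups = []
        self.blocks = []
        depth = len(channels)
        for level in range(depth - 2, -1, -1):  # coarse to fine
            c_in = channels[level + 1]
            c_out = channels[level]
            target = sizes[level]
            cur = sizes[level + 1]
            opad = target - 2 * cur
            self.ups.append(nn.ConvTranspose2d(c_in, c_out, 2, rng, stride=2,
                                               output_padding=opad))
            self.blocks.append(ConvBlock(2 * c_out, c_out, rng))

    def forward(self, bottom: Tensor, skips: list[Tensor],
                trace: ForwardTrace | None = None, name: str = "decoder"):
        """``skips`` ordered fine-to-coarse (level 0 first). Returns the
        list of stage outputs, coarse to fine."""
        x = bottom
        outs = []
        n_stages = len(self.ups)
        for i, (up, block) in enumerate(zip(self.ups, self.blocks)):
            level = n_stages - 1 - i
            x = up(x)
            x = block(nn.concat([skips[level], x], axis=1))
            outs.append(x)
            if trace is not None:
                trace.record(f"{name}_U{level + 1}", x)
        return outs


class SingleUNet(nn.Module):
    """Plain U-Net over one modality (or summed multi-encoder features)."""

    def __init__(self, spec: ModelSpec, rng, n_encoders: int = 1):
        super().__init__()
        self.spec = spec
        ch = spec.channels_unet()
        self.encoders = [_Encoder(1, ch, rng) for _ in range(n_encoders)]
        self.dropout = nn.Dropout(spec.block_options.dropout_p)
        self.decoder = _Decoder(ch, spec.spatial_sizes(), rng)
        self.head = nn.Conv2d(ch[0], spec.num_classes, 1, rng)

    def forward(self, images: list[Tensor], trace: ForwardTrace | None = None):
        feats = [enc(img) for enc, img in zip(self.encoders, images)]
        depth = self.spec.depth
        if len(feats) == 1:
            merged = feats[0]
        else:
            # sum same-scale features across encoders
            merged = []
            for i in range(depth):
                s = feats[0][i]
                for f in feats[1:]:
                    s = s + f[i]
                merged.append(s)
        if trace is not None:
            for i, f in enumerate(merged):
                trace.record(f"encoder_block{i + 1}", f)
        bottom = self.dropout(merged[-1])
        outs = self.decoder(bottom, merged[:-1], trace, "decoder")
        logits = self.head(outs[-1])
        if trace is not None:
            trace.record("head", logits)
        return {"main": logits}


class ParallelUNet(nn.Module):
    """UNet_A (fused + PET encoders) and UNet_B (CT) with optional gates."""

    def __init__(self, spec: ModelSpec, rng):
        super().__init__()
        self.spec = spec
        v = spec.variant
        opts = spec.block_options
        self.use_two_modal = v == "apu_net"
        self.use_channel_att = v in ("capu_net", "apu_net")
        self.use_spatial_att = v in ("sapu_net", "apu_net")
        self.use_mfa = v in ("mfpu_net", "apu_net")

        cha = spec.channels_a()
        chb = spec.channels_b()
        sizes = spec.spatial_sizes()
        self.enc1_a = _Encoder(1, cha, rng)  # fused PET/CT
        self.enc2_a = _Encoder(1, cha, rng)  # PET
        self.enc_b = _Encoder(1, chb, rng)   # CT
        self.dropout_a = nn.Dropout(opts.dropout_p)
        self.dropout_b = nn.Dropout(opts.dropout_p, seed=1)

        n_skips = spec.depth - 1
        self.two_modal = [TwoModalBlock(cha[i], rng, opts.gate_variant)
                          for i in range(n_skips)] if self.use_two_modal else None
        skip_ch = [2 * cha[i] + chb[i] for i in range(n_skips)]
        self.attention = []
        for i in range(n_skips):
            if self.use_channel_att and self.use_spatial_att:
                self.attention.append(
                    HybridAttention(skip_ch[i], rng, opts.attention_order))
            elif self.use_channel_att:
                self.attention.append(ChannelAttention(skip_ch[i], rng))
            elif self.use_spatial_att:
                self.attention.append(SpatialAttention(rng))
            else:
                self.attention.append(None)
        self.reduce_a = [nn.Conv2d(skip_ch[i], cha[i], 1, rng)
                         for i in range(n_skips)]
        self.reduce_b = [nn.Conv2d(skip_ch[i], chb[i], 1, rng)
                         for i in range(n_skips)]
        self.decoder_a = _Decoder(cha, sizes, rng)
        self.decoder_b = _Decoder(chb, sizes, rng)
        self.head_a = nn.Conv2d(cha[0], spec.num_classes, 1, rng)
        self.head_b = nn.Conv2d(chb[0], spec.num_classes, 1, rng)
        if self.use_mfa:
            # decoder stage channels, coarse to fine (e.g. 128..16 / 256..32)
            pairs = [(cha[i], chb[i]) for i in range(n_skips - 1, -1, -1)]
            self.mfa = MFABlock(pairs, rng, out_size=spec.input_size,
                                per_scale_channels=opts.mfa_per_scale_channels)
            self.head_main = nn.Conv2d(self.mfa.total_channels,
                                       spec.num_classes, 1, rng)

    def forward(self, ct: Tensor, pet: Tensor, fused: Tensor,
                trace: ForwardTrace | None = None):
        f1 = self.enc1_a(fused)
        f2 = self.enc2_a(pet)
        fb = self.enc_b(ct)
        if trace is not None:
            for i in range(self.spec.depth):
                trace.record(f"encoder1_A_block{i + 1}", f1[i])
                trace.record(f"encoder2_A_block{i + 1}", f2[i])
                trace.record(f"encoder_B_block{i + 1}", fb[i])

        n_skips = self.spec.depth - 1
        skips_a, skips_b = [], []
        for i in range(n_skips):
            if self.use_two_modal:
                h = self.two_modal[i](f1[i], f2[i])
            else:
                h = nn.concat([f1[i], f2[i]], axis=1)
            att = self.attention[i]
            if isinstance(att, HybridAttention):
                x = att(h, fb[i])
            elif att is not None:
                x = att(nn.concat([h, fb[i]], axis=1))
            else:
                x = nn.concat([h, fb[i]], axis=1)
            if trace is not None:
                trace.record(f"skip{i + 1}_attended", x)
            skips_a.append(self.reduce_a[i](x))
            skips_b.append(self.reduce_b[i](x))

        bottom_a = self.dropout_a(f1[-1] + f2[-1])  # bottleneck fusion by sum
        bottom_b = self.dropout_b(fb[-1])
        outs_a = self.decoder_a(bottom_a, skips_a, trace, "decoder_A")
        outs_b = self.decoder_b(bottom_b, skips_b, trace, "decoder_B")
        logits_a = self.head_a(outs_a[-1])
        logits_b = self.head_b(outs_b[-1])
        outputs = {"decoder_a": logits_a, "decoder_b": logits_b}
        if self.use_mfa:
            pairs = list(zip(outs_a, outs_b))  # coarse to fine
            f_mfa = self.mfa(pairs)
            if trace is not None:
                trace.record("F_MFA", f_mfa)
            outputs["main"] = self.head_main(f_mfa)
        else:
            outputs["main"] = logits_a + logits_b
        if trace is not None:
            for name in ("decoder_a", "decoder_b", "main"):
                trace.record(f"head_{name}", outputs[name])
        return outputs


def build_model(spec: ModelSpec, seed: int = 0) -> nn.Module:
    """Construct a network from its spec; (spec, seed) fixes every weight."""
    if spec.variant not in VARIANTS:
        raise ValueError(f"unknown variant {spec.variant!r}")
    rng = np.random.default_rng(seed)
    if spec.variant == "unet":
        return SingleUNet(spec, rng, n_encoders=1)
    if spec.variant == "meu_net":
        return SingleUNet(spec, rng, n_encoders=3)
    return ParallelUNet(spec, rng)


def _to_tensor(img: np.ndarray) -> Tensor:
    return Tensor(np.asarray(img, dtype=np.float32)[None, None])


def model_inputs(model: nn.Module, triplet: ImageTriplet):
    """Map a triplet onto the argument list the variant consumes."""
    if isinstance(model, SingleUNet):
        if len(model.encoders) == 1:
            return ([_to_tensor(triplet.ct)],)
        return ([_to_tensor(triplet.ct), _to_tensor(triplet.pet),
                 _to_tensor(triplet.fused)],)
    return (_to_tensor(triplet.ct), _to_tensor(triplet.pet),
            _to_tensor(triplet.fused))


def forward_trace(model: nn.Module, triplet: ImageTriplet) -> ForwardTrace:
    """Run one eval-mode forward pass recording every block's output shape."""
    model.eval()
    trace = ForwardTrace()
    outputs = model(*model_inputs(model, triplet), trace=trace)
    trace.outputs = {k: v.data for k, v in outputs.items()}
    return trace


def predict_mask(model: nn.Module, triplet: ImageTriplet) -> np.ndarray:
    """Argmax-over-classes binary mask at input resolution (eval mode)."""
    if triplet.ct.shape[0] != model.spec.input_size:
        raise ValueError(
            f"triplet size {triplet.ct.shape} does not match model input size "
            f"{model.spec.input_size}")
    model.eval()
    outputs = model(*model_inputs(model, triplet))
    return outputs["main"].data[0].argmax(axis=0).astype(np.uint8)


def count_parameters(model: nn.Module) -> int:
    """Total number of trainable scalars."""
    return int(sum(p.data.size for p in model.parameters()))
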