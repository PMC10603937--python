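"""The segmentation model: pyramid encoders with per-stage spatial
attention, the attention U-Net decoder built around concatenation fusion
(``x' = Conv1x1([x, skip])`` back to the channel count of ``x``) with
attention applied *before* upsampling, and the stacking of two (or more)
encoder–decoder units where stack k+1 re-encodes the original image
together with stack k's softmax output to refine and denoise it.

Backbone names from the published deep-learning zoos (EfficientNet,
ResNet-D, SEResNeXt) are accepted as registry keys; without an external
pretrained-backbone plug-in they resolve to built-in TinyEncoder presets
with the same stride-2..32 pyramid contract, so every architecture path is
exercisable on a CPU without pretrained weights.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._layers import Conv2d, ConvNormAct, Module, Parameter
from ._tensor import (Tensor, concat, pad_replicate, resize_bilinear, softmax,
                      zero_insert2x)

# name -> stage channels at strides (2, 4, 8, 16, 32)
ENCODER_REGISTRY: dict[str, tuple[int, ...]] = {
    "tiny": (8, 16, 24, 32, 40),
    "tiny-slim": (6, 12, 16, 24, 32),
    "tiny-wide": (12, 24, 40, 56, 72),
    # published-backbone names; TinyEncoder fallbacks with graded widths
    "efficientnet-b0": (8, 16, 24, 40, 56),
    "efficientnet-b1": (8, 16, 28, 44, 60),
    "efficientnet-b2": (8, 16, 28, 48, 64),
    "efficientnet-b3": (10, 20, 32, 48, 68),
    "efficientnet-b4": (10, 20, 36, 56, 72),
    "efficientnet-b5": (12, 24, 40, 64, 80),
    "resnet34d": (12, 24, 48, 64, 80),
    "resnet50d": (16, 32, 56, 72, 96),
    "seresnext50-32x4d": (16, 32, 56, 80, 96),
}

COUPLING_MODES = ("image+probs", "probs_only", "logits")


@dataclass(frozen=True)
class EncoderSpec:
    name: str = "tiny"
    in_channels: int = 1
    stage_channels: tuple[int, ...] = ()
    pretrained: bool = False
    spatial_attention: bool = True

    def resolved_channels(self) -> tuple[int, ...]:
        if self.stage_channels:
            ch = tuple(self.stage_channels)
        else:
            if self.name not in ENCODER_REGISTRY:
                raise KeyError(
                    f"unknown encoder {self.name!r}; registered: "
                    f"{sorted(ENCODER_REGISTRY)}")
            ch = ENCODER_REGISTRY[self.name]
        if len(ch) != 5 or any(c <= 0 for c in ch):
            raise ValueError("stage_channels must be 5 positive ints")
        return ch


@dataclass(frozen=True)
class DecoderSpec:
    channels: tuple[int, ...] = (32, 24, 16, 12, 8)
    upsample_mode: str = "bilinear"       # or "transposed"
    attention_before_upsample: bool = True
    out_classes: int = 5

    def __post_init__(self):
        if len(self.channels) != 5:
            raise ValueError("decoder needs 5 per-level channel counts")
        if self.upsample_mode not in ("bilinear", "transposed"):
            raise ValueError("upsample_mode must be 'bilinear' or 'transposed'")


@dataclass(frozen=True)
class StackedModelSpec:
    """Ordered (encoder, decoder) specs plus the inter-stack coupling rule."""

    stacks: tuple[tuple[EncoderSpec, DecoderSpec], ...]
    coupling: str = "image+probs"
    # stop-gradient on the inter-stack coupling: stack k trains on its own
    # (auxiliary) loss and stack k+1 treats the incoming probabilities as
    # data, as in stacked-hourglass intermediate supervision
    detach_coupling: bool = True
    # residual refinement: stack k+1 predicts a logit-space correction on
    # top of stack k's output, so at initialisation it reproduces the
    # previous stack's segmentation and learns only the refinement
    residual_refine: bool = True

    def __post_init__(self):
        if not self.stacks:
            raise ValueError("need at least one stack")
        if self.coupling not in COUPLING_MODES:
            raise ValueError(f"coupling must be one of {COUPLING_MODES}")
        C = self.stacks[0][1].out_classes
        if any(d.out_classes != C for _, d in self.stacks):
            raise ValueError("all stacks must share out_classes")

    @property
    def n_classes(self) -> int:
        return self.stacks[0][1].out_classes


def default_spec(n_classes: int, n_stacks: int = 2, encoder: str = "tiny",
                 encoder2: str | None = None,
                 coupling: str = "image+probs",
                 in_channels: int = 1,
                 upsample_mode: str = "bilinear",
                 detach_coupling: bool = True) -> StackedModelSpec:
    """Convenience builder for the common one- and two-stack configurations."""
    dec = DecoderSpec(out_classes=n_classes, upsample_mode=upsample_mode)
    stacks = []
    for k in range(n_stacks):
        name = encoder if k == 0 or encoder2 is None else encoder2
        cin = in_channels if k == 0 else _coupled_channels(in_channels,
                                                           n_classes, coupling)
        stacks.append((EncoderSpec(name=name, in_channels=cin), dec))
    return StackedModelSpec(stacks=tuple(stacks), coupling=coupling,
                            detach_coupling=detach_coupling)


def _coupled_channels(image_channels: int, C: int, coupling: str) -> int:
    if coupling == "image+probs":
        return image_channels + C
    return C


class SpatialAttention(Module):
    """Pixel-wise gate from channel-pooled statistics.

    ``gate = sigmoid(conv7x7([channel-mean; channel-max]))``, multiplied
    onto the feature map.  ``force_gate`` clamps the gate to a constant
    (used to verify that the attention decoder strictly generalizes the
    plain decoder: gate ≡ 1 is the identity).
    """

    def __init__(self, rng: np.random.Generator, kernel_size: int = 7):
        super().__init__()
        # replicate padding keeps the gate constant on constant inputs
        self.pad = kernel_size // 2
        self.conv = Conv2d(2, 1, kernel_size, rng, padding=0)
        self.force_gate: float | None = None

    def forward(self, f: Tensor) -> Tensor:
        if self.force_gate is not None:
            return f * float(self.force_gate)
        mean = f.mean(axis=1, keepdims=True)
        mx = f.max(axis=1, keepdims=True)
        pooled = pad_replicate(concat([mean, mx], axis=1), self.pad)
        gate = self.conv(pooled).sigmoid()
        return f * gate


def spatial_attention(f, module: SpatialAttention) -> Tensor:
    """Apply a spatial-attention gate to an (N, C, H, W) feature map."""
    return module(f if isinstance(f, Tensor) else Tensor(f))


class AttentionFusion(Module):
    """Concatenation fusion ``x' = Conv1x1(Cx + Cskip -> Cx)([x, skip])``.

    The skip map is resized (bilinear) to x's spatial dims when they
    differ; the output always has x's channel count and spatial size.
    """

    def __init__(self, c_x: int, c_skip: int, rng: np.random.Generator):
        super().__init__()
        self.c_x = c_x
        self.c_skip = c_skip
        self.projection = Conv2d(c_x + c_skip, c_x, 1, rng)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        if x.data.shape[1] != self.c_x or skip.data.shape[1] != self.c_skip:
            raise ValueError(
                f"fusion expects channels ({self.c_x}, {self.c_skip}), got "
                f"({x.data.shape[1]}, {skip.data.shape[1]})")
        skip = resize_bilinear(skip, x.data.shape[2], x.data.shape[3])
        return self.projection(concat([x, skip], axis=1))

    def set_passthrough(self) -> None:
        """Make the projection select the first Cx input channels (bias 0),
        so the fused output equals x exactly."""
        w = np.zeros_like(self.projection.weight.data)
        for c in range(self.c_x):
            w[c, c, 0, 0] = 1.0
        self.projection.weight.data = w
        self.projection.bias.data = np.zeros_like(self.projection.bias.data)


def attention_fuse(x, skip, fusion: AttentionFusion) -> Tensor:
    """Fuse a primary map with a skip map through 1x1-projected concatenation."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    skip = skip if isinstance(skip, Tensor) else Tensor(skip)
    return fusion(x, skip)


class EncoderStage(Module):
    """Stride-2 down-block: ConvNormAct(s2) + ConvNormAct(s1) [+ attention]."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 attention: bool):
        super().__init__()
        self.down = ConvNormAct(cin, cout, rng, stride=2)
        self.refine = ConvNormAct(cout, cout, rng)
        self.attn = SpatialAttention(rng) if attention else None

    def forward(self, x: Tensor) -> Tensor:
        x = self.refine(self.down(x))
        if self.attn is not None:
            x = self.attn(x)
        return x


class TinyEncoder(Module):
    """Compact 5-stage pyramid encoder (strides 2, 4, 8, 16, 32)."""

    def __init__(self, spec: EncoderSpec, rng: np.random.Generator):
        super().__init__()
        if spec.pretrained:
            raise ValueError(
                "pretrained backbones require an external plug-in; "
                "built-in encoders train from scratch")
        ch = spec.resolved_channels()
        self.stage_channels = ch
        self.stem = ConvNormAct(spec.in_channels, ch[0], rng, stride=2)
        self.stem_attn = SpatialAttention(rng) if spec.spatial_attention else None
        self.stages = [EncoderStage(ch[i], ch[i + 1], rng, spec.spatial_attention)
                       for i in range(4)]

    def forward(self, x: Tensor) -> list[Tensor]:
        f = self.stem(x)
        if self.stem_attn is not None:
            f = self.stem_attn(f)
        pyramid = [f]
        for stage in self.stages:
            f = stage(f)
            pyramid.append(f)
        return pyramid


class Upsample2x(Module):
    """x2 spatial upsampling: pure bilinear, or zero-insertion + 3x3 conv
    (the transposed-convolution variant)."""

    def __init__(self, channels: int, mode: str, rng: np.random.Generator):
        super().__init__()
        self.mode = mode
        self.conv = Conv2d(channels, channels, 3, rng, padding=1) \
            if mode == "transposed" else None

    def forward(self, x: Tensor) -> Tensor:
        if self.mode == "transposed":
            return self.conv(zero_insert2x(x))
        n, c, h, w = x.data.shape
        return resize_bilinear(x, 2 * h, 2 * w)


class DecoderLevel(Module):
    """One decoder level: fuse skip -> spatial attention -> x2 upsample ->
    two-convolution refinement."""

    def __init__(self, c_x: int, c_skip: int | None, c_out: int,
                 spec: DecoderSpec, rng: np.random.Generator):
        super().__init__()
        self.fusion = AttentionFusion(c_x, c_skip, rng) if c_skip else None
        self.attn = SpatialAttention(rng) if spec.attention_before_upsample else None
        self.up = Upsample2x(c_x, spec.upsample_mode, rng)
        self.refine1 = ConvNormAct(c_x, c_out, rng)
        self.refine2 = ConvNormAct(c_out, c_out, rng)

    def forward(self, x: Tensor, skip: Tensor | None) -> Tensor:
        if self.fusion is not None and skip is not None:
            x = self.fusion(x, skip)
        if self.attn is not None:
            x = self.attn(x)
        x = self.up(x)
        return self.refine2(self.refine1(x))


class AttentionUNetDecoder(Module):
    """Five-level decoder over a stride-2..32 pyramid, attention before each
    upsampling step, 1x1 head to class logits at input resolution."""

    def __init__(self, encoder_channels: tuple[int, ...], spec: DecoderSpec,
                 rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        e = encoder_channels
        skips = [e[3], e[2], e[1], e[0], None]
        self.levels = []
        c_x = e[4]
        for c_skip, c_out in zip(skips, spec.channels):
            self.levels.append(DecoderLevel(c_x, c_skip, c_out, spec, rng))
            c_x = c_out
        self.head = Conv2d(c_x, spec.out_classes, 1, rng)

    def forward(self, pyramid: list[Tensor]) -> Tensor:
        if len(pyramid) != 5:
            raise ValueError(f"expected a 5-level pyramid, got {len(pyramid)}")
        x = pyramid[4]
        skips = [pyramid[3], pyramid[2], pyramid[1], pyramid[0], None]
        for level, skip in zip(self.levels, skips):
            x = level(x, skip)
        return self.head(x)

    def freeze_attention(self, gate: float | None = 1.0) -> None:
        """Clamp every spatial-attention gate to a constant (None unclamps)."""
        for m in self.modules():
            if isinstance(m, SpatialAttention):
                m.force_gate = gate


def decoder_forward(pyramid, decoder: AttentionUNetDecoder) -> Tensor:
    """Run a decoder over a 5-level feature pyramid, returning class logits."""
    pyramid = [p if isinstance(p, Tensor) else Tensor(p) for p in pyramid]
    return decoder(pyramid)


def couple_stacks(image: Tensor, prev_probabilities: Tensor,
                  coupling: str = "image+probs") -> Tensor:
    """Build the next stack's input from the original image and the previous
    stack's output (default: channel-concatenation image ⊕ softmax)."""
    if coupling not in COUPLING_MODES:
        raise ValueError(f"coupling must be one of {COUPLING_MODES}")
    image = image if isinstance(image, Tensor) else Tensor(image)
    prev = prev_probabilities if isinstance(prev_probabilities, Tensor) \
        else Tensor(prev_probabilities)
    if image.data.shape[-2:] != prev.data.shape[-2:]:
        raise ValueError("image and probability map spatial dims differ")
    if coupling == "image+probs":
        return concat([image, prev], axis=1)
    return prev


class StackedModel(Module):
    """Composition of encoder–decoder stacks; forward returns the ordered
    list of per-stack class-probability maps (softmax over channels)."""

    def __init__(self, spec: StackedModelSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.encoders = []
        self.decoders = []
        for k, (enc_spec, dec_spec) in enumerate(spec.stacks):
            if k > 0:
                want = _coupled_channels(spec.stacks[0][0].in_channels,
                                         spec.n_classes, spec.coupling)
                if enc_spec.in_channels != want:
                    enc_spec = replace(enc_spec, in_channels=want)
            enc = TinyEncoder(enc_spec, rng)
            self.encoders.append(enc)
            dec = AttentionUNetDecoder(enc.stage_channels, dec_spec, rng)
            if k > 0 and spec.residual_refine:
                # zero head: the refiner starts as the exact identity on the
                # previous stack's segmentation
                dec.head.weight.data[...] = 0.0
                dec.head.bias.data[...] = 0.0
            self.decoders.append(dec)

    @property
    def n_stacks(self) -> int:
        return len(self.encoders)

    def forward(self, x: Tensor) -> list[Tensor]:
        x = x if isinstance(x, Tensor) else Tensor(x)
        h, w = x.data.shape[-2:]
        if h % 32 or w % 32:
            raise ValueError(f"input dims must be divisible by 32, got {h}x{w}")
        outputs: list[Tensor] = []
        inp = x
        prev_logits = None
        for k, (enc, dec) in enumerate(zip(self.encoders, self.decoders)):
            logits = dec(enc(inp))
            if k > 0 and self.spec.residual_refine:
                logits = logits + prev_logits
            probs = softmax(logits, axis=1)
            outputs.append(probs)
            fed = Tensor(probs.data) if self.spec.detach_coupling else probs
            inp = couple_stacks(x, fed, self.spec.coupling)
            prev_logits = Tensor(logits.data) if self.spec.detach_coupling \
                else logits
        return outputs

    def stack_parameters(self, k: int) -> list[Parameter]:
        stack = Module()
        stack.enc = self.encoders[k]
        stack.dec = self.decoders[k]
        return stack.parameters()


def build_stacked(spec: StackedModelSpec, seed: int = 0) -> StackedModel:
    """Instantiate a stacked model from its spec with seeded initialisation."""
    for enc_spec, _ in spec.stacks:
        if not enc_spec.stage_channels and enc_spec.name not in ENCODER_REGISTRY:
            raise KeyError(
                f"unknown encoder {enc_spec.name!r}; registered encoders: "
                f"{sorted(ENCODER_REGISTRY)}")
    rng = np.random.default_rng(seed)
    return StackedModel(spec, rng)


def pad_to_stride(images: np.ndarray, stride: int = 32) -> tuple[np.ndarray, tuple[int, int]]:
    """Reflect-pad (N, H, W) images so H and W are multiples of ``stride``;
    returns the padded stack and the original (H, W) so the padding can be
    undone at output."""
    n, h, w = images.shape
    ph = (-h) % stride
    pw = (-w) % stride
    if ph or pw:
        images = np.pad(images, ((0, 0), (0, ph), (0, pw)), mode="reflect")
    return images, (h, w)


def predict_masks(model: StackedModel, images: np.ndarray,
                  batch_size: int = 8) -> np.ndarray:
    """Segment (N, H, W) images into (N, H, W) argmax label masks.

    Inputs whose dims are not multiples of 32 are reflect-padded for the
    forward pass and cropped back afterwards.
    """
    from ._tensor import no_grad
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 2:
        images = images[None]
    padded, (h, w) = pad_to_stride(images)
    model.eval()
    out = []
    with no_grad():
        for i in range(0, len(padded), batch_size):
            batch = Tensor(padded[i:i + batch_size, None])
            probs = model(batch)[-1]
            out.append(np.argmax(probs.data, axis=1))
    return np.concatenate(out)[:, :h, :w].astype(np.int64)
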