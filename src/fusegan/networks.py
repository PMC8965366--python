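"""Declarative builders for the three architectures.

* a 3-D U-Net generator (stride-2 encoder convolutions, stride-2 transposed
  decoder convolutions, channel-concatenation skips, [0, 1] output);
* a patch discriminator (stride-2 convolutions, leaky rectifier, flattened
  single-logit head squashed to (0, 1));
* a dual-branch residual fusion classifier whose body minus the final
  affine head is the fusion feature extractor F used by the feature-fusion
  loss.

Every spec carries a ``width_scale`` so faithful tiny CPU instances of the
full-width architectures exist; at full scale the channel lists are
64-128-256-512-1024-1024 (generator encoder), 1024-512-256-128-64-1
(generator decoder) and 32-64-128-256-512-1024 (discriminator).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .nn import (
    BatchNorm3d,
    Conv3d,
    ConvTranspose3d,
    Dropout,
    LeakyReLU,
    Linear,
    Module,
    Tensor,
    concat,
    conv3d,
)

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "FusionSpec",
    "UNetGenerator",
    "PatchDiscriminator",
    "FusionClassifier",
    "ResBlock3d",
    "build_generator",
    "build_discriminator",
    "build_fusion_classifier",
]


def _scaled(channels: list[int], scale: float, keep_last_unit: bool = False) -> list[int]:
    out = [max(1, int(round(c * scale))) for c in channels]
    if keep_last_unit:
        out[-1] = 1
    return out


@dataclass
class GeneratorSpec:
    encoder_channels: list[int] = field(default_factory=lambda: [64, 128, 256, 512, 1024, 1024])
    decoder_channels: list[int] = field(default_factory=lambda: [1024, 512, 256, 128, 64, 1])
    kernel: int = 3
    stride: int = 2
    output_activation: str = "sigmoid"
    width_scale: float = 1.0
    leaky_slope: float = 0.2

    @property
    def depth(self) -> int:
        return len(self.encoder_channels)

    def validate(self) -> None:
        if len(self.encoder_channels) != len(self.decoder_channels):
            raise ValueError("encoder and decoder must have equal depth")
        if self.decoder_channels[-1] != 1:
            raise ValueError("last decoder channel count must be 1")
        if self.output_activation not in ("sigmoid", "none"):
            raise ValueError(f"unknown output activation {self.output_activation!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DiscriminatorSpec:
    channels: list[int] = field(default_factory=lambda: [32, 64, 128, 256, 512, 1024])
    input_edge: int = 64
    kernel: int = 3
    stride: int = 2
    leaky_slope: float = 0.2
    width_scale: float = 1.0

    def validate(self) -> None:
        edge = self.input_edge
        for _ in self.channels:
            edge = (edge + 2 - self.kernel) // self.stride + 1
        if edge < 1:
            raise ValueError(
                f"input edge {self.input_edge} collapses below 1 voxel over "
                f"{len(self.channels)} stride-{self.stride} layers"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FusionSpec:
    branch_blocks: int = 3
    trunk_blocks: int = 2
    base_channels: int = 8
    input_edge: int = 128
    dropout_rate: float = 0.5
    n_classes: int = 2

    def validate(self) -> None:
        total = self.branch_blocks + self.trunk_blocks
        if self.input_edge % (2**total) != 0:
            raise ValueError(
                f"input edge {self.input_edge} not divisible by 2^{total}"
            )
        if self.branch_blocks < 1 or self.trunk_blocks < 1:
            raise ValueError("need at least one branch and one trunk block")

    def to_dict(self) -> dict:
        return asdict(self)


class UNetGenerator(Module):
    """1-channel cubic patch -> same-shape 1-channel patch in [0, 1]."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        super().__init__()
        spec.validate()
        self.spec = spec
        enc = _scaled(spec.encoder_channels, spec.width_scale)
        dec = _scaled(spec.decoder_channels, spec.width_scale, keep_last_unit=True)
        depth = spec.depth
        self.encoders = []
        in_ch = 1
        for ch in enc:
            self.encoders.append(
                Conv3d(in_ch, ch, kernel=spec.kernel, stride=spec.stride, pad=1, rng=rng)
            )
            in_ch = ch
        self.decoders = []
        for i, ch in enumerate(dec):
            if i == 0:
                dec_in = enc[-1]
            else:
                dec_in = dec[i - 1] + enc[depth - 1 - i]
            self.decoders.append(
                ConvTranspose3d(
                    dec_in, ch, kernel=spec.kernel, stride=spec.stride,
                    pad=1, output_padding=1, rng=rng,
                )
            )

    def forward(self, x: Tensor) -> Tensor:
        depth = self.spec.depth
        edge = x.shape[-1]
        if edge % (2**depth) != 0:
            raise ValueError(
                f"input edge {edge} not divisible by 2^{depth} (generator depth)"
            )
        skips = []
        h = x
        for enc in self.encoders:
            h = enc(h).leaky_relu(self.spec.leaky_slope)
            skips.append(h)
        for i, dec in enumerate(self.decoders):
            h = dec(h)
            if i < depth - 1:
                h = h.relu()
                h = concat([h, skips[depth - 2 - i]], axis=1)
        if self.spec.output_activation == "sigmoid":
            h = h.sigmoid()
        return h


class PatchDiscriminator(Module):
    """Cubic patch -> scalar probability in (0, 1)."""

    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator):
        super().__init__()
        spec.validate()
        self.spec = spec
        channels = _scaled(spec.channels, spec.width_scale)
        self.convs = []
        in_ch, edge = 1, spec.input_edge
        for ch in channels:
            self.convs.append(
                Conv3d(in_ch, ch, kernel=spec.kernel, stride=spec.stride, pad=1, rng=rng)
            )
            in_ch = ch
            edge = (edge + 2 - spec.kernel) // spec.stride + 1
        self.head = Linear(in_ch * edge**3, 1, rng=rng)

    def logit(self, x: Tensor) -> Tensor:
        h = x
        for conv in self.convs:
            h = conv(h).leaky_relu(self.spec.leaky_slope)
        h = h.reshape(h.shape[0], -1)
        return self.head(h)

    def forward(self, x: Tensor) -> Tensor:
        return self.logit(x).sigmoid()


class ResBlock3d(Module):
    """4 convolutions (first stride 2) with 2 shortcut connections.

    conv -> batch-norm -> rectifier ordering; the first shortcut is a
    strided 1x1x1 projection across the downsampling pair, the second an
    identity across the stride-1 pair.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv3d(in_ch, out_ch, stride=2, rng=rng)
        self.bn1 = BatchNorm3d(out_ch)
        self.conv2 = Conv3d(out_ch, out_ch, stride=1, rng=rng)
        self.bn2 = BatchNorm3d(out_ch)
        self.proj = Conv3d(in_ch, out_ch, kernel=1, stride=2, pad=0, rng=rng)
        self.conv3 = Conv3d(out_ch, out_ch, stride=1, rng=rng)
        self.bn3 = BatchNorm3d(out_ch)
        self.conv4 = Conv3d(out_ch, out_ch, stride=1, rng=rng)
        self.bn4 = BatchNorm3d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h))
        h = (h + self.proj(x)).relu()
        g = self.bn3(self.conv3(h)).relu()
        g = self.bn4(self.conv4(g))
        return (g + h).relu()


class FusionClassifier(Module):
    """Dual-branch residual classifier; ``features`` is the fusion model F."""

    def __init__(self, spec: FusionSpec, rng: np.random.Generator):
        super().__init__()
        spec.validate()
        self.spec = spec

        def branch() -> list[Module]:
            blocks: list[Module] = []
            in_ch = 1
            for i in range(spec.branch_blocks):
                out_ch = spec.base_channels * 2**i
                blocks.append(ResBlock3d(in_ch, out_ch, rng))
                blocks.append(Dropout(spec.dropout_rate, rng=np.random.default_rng(rng.integers(2**31))))
                in_ch = out_ch
            return blocks

        self.mri_branch = branch()
        self.pet_branch = branch()
        branch_out = spec.base_channels * 2 ** (spec.branch_blocks - 1)
        self.trunk = []
        in_ch = 2 * branch_out
        for i in range(spec.trunk_blocks):
            out_ch = spec.base_channels * 2 ** (spec.branch_blocks + i)
            self.trunk.append(ResBlock3d(in_ch, out_ch, rng))
            self.trunk.append(Dropout(spec.dropout_rate, rng=np.random.default_rng(rng.integers(2**31))))
            in_ch = out_ch
        self._trunk_out_channels = in_ch
        feat_edge = spec.input_edge // 2 ** (spec.branch_blocks + spec.trunk_blocks)
        self.head = Linear(in_ch * feat_edge**3, spec.n_classes, rng=rng)

    def feature_length(self, edge: int) -> int:
        total = self.spec.branch_blocks + self.spec.trunk_blocks
        if edge % 2**total != 0:
            raise ValueError(f"input edge {edge} not divisible by 2^{total}")
        return self._trunk_out_channels * (edge // 2**total) ** 3

    def features(
        self, mri: Tensor, pet: Tensor, capture: dict | None = None
    ) -> Tensor:
        """Fusion feature extractor F(mri, pet): flattened fused vector.

        ``capture``, if given, receives the last branch activations under
        keys 'mri' and 'pet' (used for class-activation mapping).
        """
        if mri.shape != pet.shape:
            raise ValueError(f"MRI/PET shape mismatch: {mri.shape} vs {pet.shape}")
        hm, hp = mri, pet
        for layer in self.mri_branch:
            hm = layer(hm)
        for layer in self.pet_branch:
            hp = layer(hp)
        if capture is not None:
            capture["mri"], capture["pet"] = hm, hp
        h = concat([hm, hp], axis=1)
        for layer in self.trunk:
            h = layer(h)
        return h.reshape(h.shape[0], -1)

    def forward(self, mri: Tensor, pet: Tensor, capture: dict | None = None) -> Tensor:
        return self.head(self.features(mri, pet, capture=capture))


def build_generator(spec: GeneratorSpec, seed: int) -> UNetGenerator:
    return UNetGenerator(spec, np.random.default_rng(seed))


def build_discriminator(spec: DiscriminatorSpec, seed: int) -> PatchDiscriminator:
    return PatchDiscriminator(spec, np.random.default_rng(seed))


def build_fusion_classifier(spec: FusionSpec, seed: int) -> FusionClassifier:
    return FusionClassifier(spec, np.random.default_rng(seed))
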