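"""Single-encoder, multi-decoder U-Net.

One convolutional encoder is shared by up to four segmentation decoders (one
per lesion family: microaneurysms MA, hemorrhages HE, hard exudates EX, soft
exudates SE) and one image-reconstruction decoder.  Every decoder mirrors the
encoder, upsampling with kernel-2 stride-2 transposed convolutions and
fusing the matching encoder level's feature maps through skip connections.
Each convolution is followed by batch normalisation and then ReLU.

Segmentation heads emit logits; the sigmoid lives in the losses and metrics
so that raw scores stay available.  The reconstruction head is
sigmoid-activated so its output lies in [0, 1] like the input image.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import nn
from .nn import Tensor

LESIONS = ("MA", "HE", "EX", "SE")


@dataclass
class NetworkConfig:
    """Topology of the encoder/decoder graph.

    depth
        Number of resolution levels; the bottleneck sits at level depth-1,
        so inputs must be divisible by ``2**(depth-1)``.
    base_channels
        Feature channels at the first level; level ``l`` has
        ``base_channels * 2**l``.
    lesions
        Names of the segmentation decoders, in order.  A single-entry tuple
        with ``reconstruction=False`` reduces the graph to a standard U-Net.
    """

    depth: int = 5
    base_channels: int = 32
    in_channels: int = 3
    lesions: tuple[str, ...] = LESIONS
    reconstruction: bool = True
    double_conv: bool = True
    skip_mode: str = "concat"  # or "add"
    recon_skips: bool = True

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be at least 2")
        if self.skip_mode not in ("concat", "add"):
            raise ValueError(f"unknown skip_mode {self.skip_mode!r}")
        if len(set(self.lesions)) != len(self.lesions):
            raise ValueError("duplicate lesion names")

    @property
    def channels(self) -> list[int]:
        return [self.base_channels * 2**l for l in range(self.depth)]

    @property
    def n_seg_decoders(self) -> int:
        return len(self.lesions)

    @property
    def divisor(self) -> int:
        return 2 ** (self.depth - 1)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lesions"] = list(self.lesions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["lesions"] = tuple(d["lesions"])
        return cls(**d)


class ConvBlock(nn.Module):
    """conv3x3 -> BN -> ReLU, optionally doubled (classic U-Net block)."""

    def __init__(self, in_ch: int, out_ch: int, double: bool, rng) -> None:
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.double = double
        if double:
            self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng)
            self.bn2 = nn.BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn1(self.conv1(x)).relu()
        if self.double:
            x = self.bn2(self.conv2(x)).relu()
        return x


class Decoder(nn.Module):
    """Expanding path mirroring the encoder; one output head."""

    def __init__(self, cfg: NetworkConfig, out_channels: int, skips: bool, rng):
        super().__init__()
        ch = cfg.channels
        self.use_skips = skips
        self.ups = nn.ModuleList(
            nn.ConvTranspose2x2(ch[l + 1], ch[l], rng)
            for l in reversed(range(cfg.depth - 1))
        )
        fuse_in = [
            (2 * ch[l] if (skips and cfg.skip_mode == "concat") else ch[l])
            for l in reversed(range(cfg.depth - 1))
        ]
        self.blocks = nn.ModuleList(
            ConvBlock(fi, ch[l], cfg.double_conv, rng)
            for fi, l in zip(fuse_in, reversed(range(cfg.depth - 1)))
        )
        self.skip_mode = cfg.skip_mode
        self.head = nn.Conv2d(ch[0], out_channels, 1, rng)

    def forward(self, bottleneck: Tensor, skips: Sequence[Tensor]) -> Tensor:
        x = bottleneck
        # skips[l] is the encoder output at level l; walk top-down
        for up, block, skip in zip(self.ups, self.blocks, reversed(skips[:-1])):
            x = up(x)
            if self.use_skips:
                x = nn.concat([skip, x], axis=1) if self.skip_mode == "concat" else skip + x
            x = block(x)
        return self.head(x)


@dataclass
class NetworkOutputs:
    """Forward-pass results: sigmoid reconstruction plus per-lesion logits."""

    reconstruction: Tensor | None
    seg_logits: dict[str, Tensor] = field(default_factory=dict)


class MultiDecoderUNet(nn.Module):
    """The shared-encoder, five-decoder segmentation/reconstruction network."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        ch = config.channels
        ins = [config.in_channels] + ch[:-1]
        self.encoder = nn.ModuleList(
            ConvBlock(i, o, config.double_conv, rng) for i, o in zip(ins, ch)
        )
        self.seg_decoders = nn.ModuleList(
            Decoder(config, 1, skips=True, rng=rng) for _ in config.lesions
        )
        if config.reconstruction:
            self.recon_decoder = Decoder(
                config, config.in_channels, skips=config.recon_skips, rng=rng
            )
        else:
            self.recon_decoder = None

    # -- parameter groups (update-set isolation between training phases) --
    def encoder_parameters(self) -> list[Tensor]:
        return self.encoder.parameters()

    def seg_parameters(self, lesion: str | None = None) -> list[Tensor]:
        if lesion is None:
            return self.seg_decoders.parameters()
        return self.seg_decoders[self.config.lesions.index(lesion)].parameters()

    def recon_parameters(self) -> list[Tensor]:
        return [] if self.recon_decoder is None else self.recon_decoder.parameters()

    # -- forward ----------------------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected (N, {self.config.in_channels}, H, W) batch, got {x.shape}"
            )
        d = self.config.divisor
        if x.shape[2] % d or x.shape[3] % d:
            raise ValueError(
                f"spatial size {x.shape[2]}x{x.shape[3]} not divisible by {d}"
            )

    def encode(self, x) -> tuple[list[Tensor], Tensor]:
        """Run the shared encoder; returns per-level skip features and the
        bottleneck (the last element of the skip list)."""
        t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
        self._check_input(t.data)
        skips: list[Tensor] = []
        for l, block in enumerate(self.encoder):
            if l > 0:
                t = nn.functional.max_pool2x2(t)
            t = block(t)
            skips.append(t)
        return skips, skips[-1]

    def forward(self, x) -> NetworkOutputs:
        skips, z = self.encode(x)
        seg = {
            name: dec(z, skips)
            for name, dec in zip(self.config.lesions, self.seg_decoders)
        }
        recon = None
        if self.recon_decoder is not None:
            recon = self.recon_decoder(z, skips).sigmoid()
        return NetworkOutputs(reconstruction=recon, seg_logits=seg)

    def predict_proba(self, x) -> dict[str, np.ndarray]:
        """Evaluation-mode sigmoid probability maps, one per lesion."""
        was_training = self.training
        self.eval()
        out = self.forward(x)
        if was_training:
            self.train()
        return {name: t.sigmoid().data for name, t in out.seg_logits.items()}

    def describe(self) -> str:
        """Human-readable table of parameter counts per component."""
        rows = [("encoder", sum(p.data.size for p in self.encoder_parameters()))]
        for name, dec in zip(self.config.lesions, self.seg_decoders):
            rows.append((f"decoder[{name}]", sum(p.data.size for p in dec.parameters())))
        if self.recon_decoder is not None:
            rows.append(
                ("decoder[recon]", sum(p.data.size for p in self.recon_parameters()))
            )
        rows.append(("total", self.n_parameters()))
        width = max(len(r[0]) for r in rows)
        return "\n".join(f"{n:<{width}}  {c:>10,d}" for n, c in rows)


def build_network(config: NetworkConfig, seed: int = 0) -> MultiDecoderUNet:
    """Construct a seeded network; identical seeds give identical parameters."""
    return MultiDecoderUNet(config, seed=seed)
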