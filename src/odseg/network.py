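"""U-shaped segmentation network: ResNet34 encoder, attention-reconstructed
skips, multiscale top fusion, deconvolution decoder.

Variants (ablation axes):

* ``baseline`` — encoder + decoder with plain additive skips.
* ``baseline_dsse`` — DsSE modules reconstruct the stage-2/3/4 skips,
  each attending against the next-deeper stage.
* ``baseline_msff`` — MsFF fuses stages 3-5 into the map handed to the
  decoder.
* ``afenet`` — both modules (the full attention-fusion-enhanced network).

Encoder taps (input H x W):
  stage1 = stem conv output (64 ch, /2) — not used as a skip;
  stage2..5 = the four residual layers (64/4, 128/8, 256/16, 512/32).
Each decoder block is 1x1 conv (width / ``decoder_reduction``) ->
3x3 stride-2 transposed conv -> 1x1 conv to the skip width, every conv
followed by batch norm + ReLU; skips fuse by element-wise addition. After
the last block the map sits at half input resolution; the head
(3x3 stride-2 deconv to 32 ch, 1x1 conv 32->32, 1x1 conv 32->1) restores
full resolution and emits a single-channel logit map.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .attention import DsSE, MsFF, DEFAULT_COMPRESSION_RATIO
from .nn.tensor import Tensor, as_tensor

__all__ = [
    "VARIANTS",
    "NetworkConfig",
    "SegmentationOutput",
    "AFENet",
    "build_model",
    "count_parameters",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

VARIANTS = ("baseline", "baseline_dsse", "baseline_msff", "afenet")

RESNET34_STAGE_CHANNELS = (64, 64, 128, 256, 512)
RESNET34_BLOCKS = (3, 4, 6, 3)

# binarization rule, used everywhere: foreground iff probability >= 0.5
BINARY_THRESHOLD = 0.5


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``width_multiplier`` < 1 shrinks every channel width uniformly (minimum
    1) for small-scale CPU runs; parameter-count comparisons against the
    full model only make sense at 1.0.
    """

    variant: str = "afenet"
    input_size: tuple = (256, 256)
    stage_channels: tuple = RESNET34_STAGE_CHANNELS
    r: int = DEFAULT_COMPRESSION_RATIO
    decoder_reduction: int = 4
    pretrained_encoder: bool = False
    width_multiplier: float = 1.0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if tuple(self.stage_channels) != RESNET34_STAGE_CHANNELS:
            raise ValueError(
                f"stage_channels must match the ResNet34 trunk {RESNET34_STAGE_CHANNELS}"
            )
        if not 0.0 < self.width_multiplier <= 1.0:
            raise ValueError("width_multiplier must be in (0, 1]")
        self.input_size = tuple(int(v) for v in self.input_size)
        self.stage_channels = tuple(int(v) for v in self.stage_channels)

    @property
    def use_dsse(self) -> bool:
        return self.variant in ("baseline_dsse", "afenet")

    @property
    def use_msff(self) -> bool:
        return self.variant in ("baseline_msff", "afenet")

    def scaled_channels(self) -> tuple:
        """Stage widths under the multiplier, preserving the 1:1:2:4:8 ratio
        (DsSE requires adjacent stages to differ by exactly 2x in width)."""
        base = max(int(round(self.stage_channels[1] * self.width_multiplier)), 1)
        return (base, base, 2 * base, 4 * base, 8 * base)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


@dataclass
class SegmentationOutput:
    """Probability map in [0,1] and its thresholded binary mask, (1, H, W)."""

    probability: np.ndarray
    binary: np.ndarray


# ---------------------------------------------------------------------------
# encoder


def _conv_bn_block(cin, cout, k, stride=1, padding=0):
    return nn.Sequential(
        nn.Conv2d(cin, cout, k, stride=stride, padding=padding, bias=False),
        nn.BatchNorm2d(cout),
        nn.ReLU(),
    )


class BasicBlock(nn.Module):
    """Two 3x3 convs with identity (or projected) shortcut."""

    def __init__(self, cin: int, cout: int, stride: int = 1):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, stride=stride, padding=1, bias=False)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.shortcut = nn.Sequential(
                nn.Conv2d(cin, cout, 1, stride=stride, bias=False),
                nn.BatchNorm2d(cout),
            )
        else:
            self.shortcut = nn.Identity()

    def forward(self, x):
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h))
        return (h + self.shortcut(x)).relu()


class ResNet34Encoder(nn.Module):
    """ResNet34 trunk with classifier head removed; exposes five stage taps."""

    def __init__(self, channels: tuple = RESNET34_STAGE_CHANNELS):
        super().__init__()
        c1, c2, c3, c4, c5 = channels
        self.stem_conv = nn.Conv2d(3, c1, 7, stride=2, padding=3, bias=False)
        self.stem_bn = nn.BatchNorm2d(c1)
        self.stem_pool = nn.MaxPool2d(3, stride=2, padding=1)
        widths = (c2, c3, c4, c5)
        layers = []
        cin = c1
        for li, (cout, nblocks) in enumerate(zip(widths, RESNET34_BLOCKS)):
            stride = 1 if li == 0 else 2  # layer1 keeps the stem-pool resolution
            blocks = [BasicBlock(cin, cout, stride)]
            blocks += [BasicBlock(cout, cout) for _ in range(nblocks - 1)]
            layers.append(nn.Sequential(*blocks))
            cin = cout
        self.layer1, self.layer2, self.layer3, self.layer4 = layers

    def forward(self, x):
        s1 = self.stem_bn(self.stem_conv(x)).relu()  # /2
        s2 = self.layer1(self.stem_pool(s1))  # /4
        s3 = self.layer2(s2)  # /8
        s4 = self.layer3(s3)  # /16
        s5 = self.layer4(s4)  # /32
        return s1, s2, s3, s4, s5


# ---------------------------------------------------------------------------
# decoder


class DecoderBlock(nn.Module):
    """1x1 reduce -> 3x3 stride-2 deconv -> 1x1 expand, BN+ReLU throughout."""

    def __init__(self, cin: int, cout: int, reduction: int = 4):
        super().__init__()
        mid = max(cin // reduction, 1)
        self.reduce = _conv_bn_block(cin, mid, 1)
        self.up = nn.Sequential(
            nn.ConvTranspose2d(mid, mid, 3, stride=2, padding=1, output_padding=1, bias=False),
            nn.BatchNorm2d(mid),
            nn.ReLU(),
        )
        self.expand = _conv_bn_block(mid, cout, 1)

    def forward(self, x):
        return self.expand(self.up(self.reduce(x)))


class SegmentationHead(nn.Module):
    """Restore full resolution and map to a single-channel logit."""

    def __init__(self, cin: int, mid: int = 32):
        super().__init__()
        self.up = nn.Sequential(
            nn.ConvTranspose2d(cin, mid, 3, stride=2, padding=1, output_padding=1, bias=False),
            nn.BatchNorm2d(mid),
            nn.ReLU(),
        )
        self.mix = _conv_bn_block(mid, mid, 1)
        self.out = nn.Conv2d(mid, 1, 1)

    def forward(self, x):
        return self.out(self.mix(self.up(x)))


# ---------------------------------------------------------------------------
# full network


class AFENet(nn.Module):
    """The assembled U-shaped network for any of the four variants."""

    def __init__(self, cfg: NetworkConfig):
        super().__init__()
        self.cfg = cfg
        ch = cfg.scaled_channels()
        c1, c2, c3, c4, c5 = ch
        self.encoder = ResNet34Encoder(ch)
        if cfg.use_dsse:
            # skips at stage 2/3/4; each attends against the next-deeper stage
            self.dsse = [DsSE(c, cfg.r) for c in (c2, c3, c4)]
        else:
            self.dsse = []
        self.msff = MsFF(c3, c4, c5, cfg.r) if cfg.use_msff else None
        self.dec4 = DecoderBlock(c5, c4, cfg.decoder_reduction)  # /32 -> /16
        self.dec3 = DecoderBlock(c4, c3, cfg.decoder_reduction)  # /16 -> /8
        self.dec2 = DecoderBlock(c3, c2, cfg.decoder_reduction)  # /8 -> /4
        self.dec1 = DecoderBlock(c2, c2, cfg.decoder_reduction)  # /4 -> /2
        self.head = SegmentationHead(c2)

    def forward(self, x):
        """(N, 3, H, W) image -> (N, 1, H, W) logits."""
        x = as_tensor(x)
        _, s2, s3, s4, s5 = self.encoder(x)
        if self.dsse:
            skip2 = self.dsse[0](s2, s3)
            skip3 = self.dsse[1](s3, s4)
            skip4 = self.dsse[2](s4, s5)
        else:
            skip2, skip3, skip4 = s2, s3, s4
        top = self.msff(s3, s4, s5) if self.msff is not None else s5
        d = self.dec4(top) + skip4
        d = self.dec3(d) + skip3
        d = self.dec2(d) + skip2
        d = self.dec1(d)  # half resolution, no skip (stem tap unused)
        return self.head(d)


def build_model(cfg: NetworkConfig, seed: int = 0) -> AFENet:
    """Construct a variant with seeded He initialization.

    ``pretrained_encoder=True`` is accepted only with an explicit local
    weights file loaded afterwards via ``load_checkpoint``; no weights ship
    with the package, so requesting it at build time raises.
    """
    if cfg.pretrained_encoder:
        raise ValueError(
            "no bundled encoder weights are available; build with "
            "pretrained_encoder=False and load a checkpoint instead"
        )
    nn.manual_seed(seed)
    return AFENet(cfg)


def count_parameters(model: nn.Module) -> int:
    """Number of trainable scalars (conv weights, biases, BN affine terms)."""
    return model.num_parameters()


def predict(model: AFENet, image) -> SegmentationOutput:
    """Segment one (3, H, W) image in [0,1]; H and W must be divisible by 32.

    Ties at probability exactly 0.5 map to foreground (>= rule).
    """
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 3 or img.shape[0] != 3:
        raise ValueError(f"expected a (3, H, W) image, got {img.shape}")
    h, w = img.shape[1:]
    if h % 32 or w % 32:
        raise ValueError(
            f"spatial size {h}x{w} not divisible by 32; resize the image first"
        )
    model.eval()
    with nn.no_grad():
        logits = model(Tensor(img[None]))
    prob = 1.0 / (1.0 + np.exp(-logits.data[0].astype(np.float64)))
    binary = (prob >= BINARY_THRESHOLD).astype(np.uint8)
    return SegmentationOutput(probability=prob, binary=binary)


# ---------------------------------------------------------------------------
# checkpoints: single .npz with the weights and the config that built them


def save_checkpoint(model: AFENet, path) -> None:
    import json

    state = {f"param/{k}": v for k, v in model.state_dict().items()}
    state["config_json"] = np.frombuffer(
        json.dumps(model.cfg.to_dict()).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_checkpoint(path) -> AFENet:
    import json

    with np.load(path) as z:
        cfg = NetworkConfig.from_dict(json.loads(bytes(z["config_json"]).decode()))
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    model = AFENet(cfg)
    model.load_state_dict(state)
    return model
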