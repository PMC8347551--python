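"""FAC-Net segmentation model: a CE-Net-style encoder/decoder backbone into
which the Feedback Fusion Block (FFB) and Attention Mechanism Block (AMB)
plug.

Layout for an H x W input (H, W divisible by 32) and base width C:

* stem (7x7 stride-2 convolution + 2x2 max pool) -> C x H/4
* four residual encoder stages E1..E4 with channel doubling and spatial
  halving: C x H/4, 2C x H/8, 4C x H/16, 8C x H/32
* context block on E4: dense-atrous cascade (rates 1/3/5) followed by
  residual multi-kernel max pooling (kernels 2/3/5/6)
* three-stage decoder with transposed-convolution upsampling; each decoder
  output is concatenated with the matching skip feature and fused by a 3x3
  convolution; an AMB follows each fusion when enabled
* with FFB enabled, the skip features for E1/E2/E3 are replaced by FFB
  outputs computed from the encoder pairs (E1,E2), (E2,E3), (E3,E4); E4
  itself feeds only the context block
* a two-step upsampling tail restores full resolution; a final 1x1
  convolution and logistic squashing give the lesion probability map.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .amb import VALID_STATS, AttentionBlock
from .errors import ConfigurationError, DimensionError, ShapeError
from .ffb import FeedbackFusionBlock
from .nn import functional as F
from .nn.tensor import Tensor


@dataclass
class ModelConfig:
    """Hyper-parameters of a FAC-Net variant.

    ``use_ffb``/``use_amb`` encode the ablation grid (backbone only, +FFB,
    +AMB, full model).  ``sam_stats`` selects the spatial-attention
    statistics; the default is the full max+avg+mode combination.
    """

    use_ffb: bool = True
    use_amb: bool = True
    base_width: int = 64
    mode_bins: int = 32
    spatial_norm: str = "softmax"
    pretrained_encoder: bool = False
    sam_stats: tuple[str, ...] = VALID_STATS
    reduction: int = 16
    ffb_pool: str = "max"
    ffb_gate: str = "sigmoid"

    def __post_init__(self):
        self.sam_stats = tuple(self.sam_stats)
        if self.base_width < 8:
            raise ConfigurationError(f"base_width must be >= 8, got {self.base_width}")
        if self.mode_bins < 2:
            raise ConfigurationError(f"mode_bins must be >= 2, got {self.mode_bins}")
        if self.spatial_norm not in ("softmax", "sigmoid"):
            raise ConfigurationError(
                f"spatial_norm must be softmax or sigmoid, got {self.spatial_norm!r}")
        if self.pretrained_encoder:
            raise ConfigurationError(
                "no pretrained encoder weights are distributed; "
                "set pretrained_encoder=False")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sam_stats"] = list(self.sam_stats)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "sam_stats" in d:
            d["sam_stats"] = tuple(d["sam_stats"])
        return cls(**d)


@dataclass
class EncoderPyramid:
    """The four encoder stage outputs, shallow to deep."""

    stages: list[Tensor] = field(default_factory=list)

    def __iter__(self):
        return iter(self.stages)

    def __getitem__(self, i):
        return self.stages[i]

    def __len__(self):
        return len(self.stages)


class ResidualBlock(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, stride: int = 1):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, padding=1, bias=False)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(out_ch)
        self.proj = None
        if stride != 1 or in_ch != out_ch:
            self.proj = nn.Sequential(
                nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False),
                nn.BatchNorm2d(out_ch),
            )

    def forward(self, x):
        identity = x if self.proj is None else self.proj(x)
        out = F.relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        return F.relu(F.add(out, identity))


class DenseAtrousBlock(nn.Module):
    """Cascaded atrous branches (rates 1, 3, 5) added residually, after the
    dense-atrous-convolution design of the context encoder backbone."""

    def __init__(self, ch: int):
        super().__init__()
        self.b1 = nn.Conv2d(ch, ch, 3, padding=1)
        self.b2_a = nn.Conv2d(ch, ch, 3, padding=3, dilation=3)
        self.b2_b = nn.Conv2d(ch, ch, 1)
        self.b3_a = nn.Conv2d(ch, ch, 3, padding=1)
        self.b3_b = nn.Conv2d(ch, ch, 3, padding=3, dilation=3)
        self.b3_c = nn.Conv2d(ch, ch, 1)
        self.b4_a = nn.Conv2d(ch, ch, 3, padding=1)
        self.b4_b = nn.Conv2d(ch, ch, 3, padding=3, dilation=3)
        self.b4_c = nn.Conv2d(ch, ch, 3, padding=5, dilation=5)
        self.b4_d = nn.Conv2d(ch, ch, 1)

    def forward(self, x):
        y1 = F.relu(self.b1(x))
        y2 = F.relu(self.b2_b(self.b2_a(x)))
        y3 = F.relu(self.b3_c(self.b3_b(self.b3_a(x))))
        y4 = F.relu(self.b4_d(self.b4_c(self.b4_b(self.b4_a(x)))))
        return F.add(F.add(F.add(F.add(x, y1), y2), y3), y4)


class MultiKernelPoolBlock(nn.Module):
    """Residual multi-kernel max pooling: pool at kernels 2/3/5/6, project
    each pooled grid to one channel, upsample back, concatenate with the
    input, and restore the channel count with a 1x1 convolution."""

    KERNELS = (2, 3, 5, 6)

    def __init__(self, ch: int):
        super().__init__()
        for k in self.KERNELS:
            setattr(self, f"proj{k}", nn.Conv2d(ch, 1, 1))
        self.restore = nn.Conv2d(ch + len(self.KERNELS), ch, 1)

    def forward(self, x):
        h, w = x.shape[2:]
        branches = [x]
        for k in self.KERNELS:
            p = F.max_pool2d(x, min(k, h, w))
            p = getattr(self, f"proj{k}")(p)
            branches.append(F.bilinear_resize(p, (h, w)))
        return self.restore(F.concat(branches, axis=1))


class DecoderBlock(nn.Module):
    """1x1 channel squeeze, learned x2 transposed-conv upsampling, 1x1
    expansion to the target width."""

    def __init__(self, in_ch: int, out_ch: int):
        super().__init__()
        mid = max(in_ch // 4, 4)
        self.squeeze = nn.ConvBNReLU(in_ch, mid, 1)
        self.up = nn.Deconv2x2(mid, mid, bias=False)
        self.up_bn = nn.BatchNorm2d(mid)
        self.expand = nn.ConvBNReLU(mid, out_ch, 1)

    def forward(self, x):
        x = self.squeeze(x)
        x = F.relu(self.up_bn(self.up(x)))
        return self.expand(x)


class SegmentationModel(nn.Module):
    """FAC-Net: maps a (N,3,H,W) image batch to a (N,1,H,W) probability map."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        c = config.base_width
        self.stem = nn.ConvBNReLU(3, c, 7, stride=2, padding=3)
        self.stage1 = nn.Sequential(ResidualBlock(c, c), ResidualBlock(c, c))
        self.stage2 = nn.Sequential(ResidualBlock(c, 2 * c, stride=2),
                                    ResidualBlock(2 * c, 2 * c))
        self.stage3 = nn.Sequential(ResidualBlock(2 * c, 4 * c, stride=2),
                                    ResidualBlock(4 * c, 4 * c))
        self.stage4 = nn.Sequential(ResidualBlock(4 * c, 8 * c, stride=2),
                                    ResidualBlock(8 * c, 8 * c))
        self.context = nn.Sequential(DenseAtrousBlock(8 * c),
                                     MultiKernelPoolBlock(8 * c))
        if config.use_ffb:
            self.ffb1 = FeedbackFusionBlock(c, pool=config.ffb_pool,
                                            gate=config.ffb_gate)
            self.ffb2 = FeedbackFusionBlock(2 * c, pool=config.ffb_pool,
                                            gate=config.ffb_gate)
            self.ffb3 = FeedbackFusionBlock(4 * c, pool=config.ffb_pool,
                                            gate=config.ffb_gate)
        self.decoder3 = DecoderBlock(8 * c, 4 * c)
        self.fuse3 = nn.ConvBNReLU(8 * c, 4 * c, 3, padding=1)
        self.decoder2 = DecoderBlock(4 * c, 2 * c)
        self.fuse2 = nn.ConvBNReLU(4 * c, 2 * c, 3, padding=1)
        self.decoder1 = DecoderBlock(2 * c, c)
        self.fuse1 = nn.ConvBNReLU(2 * c, c, 3, padding=1)
        if config.use_amb:
            amb_kw = dict(reduction=config.reduction, stats=config.sam_stats,
                          bins=config.mode_bins, norm=config.spatial_norm)
            self.amb3 = AttentionBlock(4 * c, **amb_kw)
            self.amb2 = AttentionBlock(2 * c, **amb_kw)
            self.amb1 = AttentionBlock(c, **amb_kw)
        t1, t2 = max(c // 2, 8), max(c // 4, 8)
        self.up1 = nn.Deconv2x2(c, t1, bias=False)
        self.up1_bn = nn.BatchNorm2d(t1)
        self.tail1 = nn.ConvBNReLU(t1, t1, 3, padding=1)
        self.up2 = nn.Deconv2x2(t1, t2, bias=False)
        self.up2_bn = nn.BatchNorm2d(t2)
        self.tail2 = nn.ConvBNReLU(t2, t2, 3, padding=1)
        self.head = nn.Conv2d(t2, 1, 1)

    # -- pieces ------------------------------------------------------------
    def _check_input(self, x: Tensor) -> None:
        if x.ndim != 4 or x.shape[1] != 3:
            raise ShapeError(
                f"expected a (N,3,H,W) image batch, got shape {tuple(x.shape)}")
        n, _, h, w = x.shape
        if h % 32:
            raise DimensionError(f"input height {h} is not divisible by 32")
        if w % 32:
            raise DimensionError(f"input width {w} is not divisible by 32")

    def encode(self, x) -> EncoderPyramid:
        x = nn.as_tensor(x)
        self._check_input(x)
        s = F.max_pool2d(self.stem(x), 2)
        e1 = self.stage1(s)
        e2 = self.stage2(e1)
        e3 = self.stage3(e2)
        e4 = self.stage4(e3)
        return EncoderPyramid([e1, e2, e3, e4])

    def forward(self, x) -> Tensor:
        pyramid = self.encode(x)
        e1, e2, e3, e4 = pyramid.stages
        if self.config.use_ffb:
            skip1 = self.ffb1(e1, e2)
            skip2 = self.ffb2(e2, e3)
            skip3 = self.ffb3(e3, e4)
        else:
            skip1, skip2, skip3 = e1, e2, e3
        d = self.context(e4)
        d = self.fuse3(F.concat([self.decoder3(d), skip3], axis=1))
        if self.config.use_amb:
            d = self.amb3(d)
        d = self.fuse2(F.concat([self.decoder2(d), skip2], axis=1))
        if self.config.use_amb:
            d = self.amb2(d)
        d = self.fuse1(F.concat([self.decoder1(d), skip1], axis=1))
        if self.config.use_amb:
            d = self.amb1(d)
        d = self.tail1(F.relu(self.up1_bn(self.up1(d))))
        d = self.tail2(F.relu(self.up2_bn(self.up2(d))))
        return F.sigmoid(self.head(d))


def build_model(config: ModelConfig, seed: int | None = None) -> SegmentationModel:
    """Construct a FAC-Net variant; ``seed`` fixes the Kaiming-normal
    parameter initialisation."""
    if seed is not None:
        nn.manual_seed(seed)
    return SegmentationModel(config)


def forward_encoder(model: SegmentationModel, image_batch) -> EncoderPyramid:
    """Run only the encoder, returning the four-stage feature pyramid."""
    with nn.no_grad():
        return model.encode(image_batch)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: SegmentationModel, extra: dict | None = None) -> None:
    """Write weights plus the producing ModelConfig to an .npz file."""
    meta = {"config": model.config.to_dict(), "extra": extra or {}}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **model.state_dict())


def load_checkpoint(path, config: ModelConfig | None = None
                    ) -> tuple[SegmentationModel, dict]:
    """Rebuild the model stored at ``path``.  If ``config`` is given it must
    match the stored one exactly; a mismatch is refused."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    stored = ModelConfig.from_dict(meta["config"])
    if config is not None and config.to_dict() != stored.to_dict():
        raise ConfigurationError(
            f"checkpoint was produced by config {stored.to_dict()}, "
            f"which does not match the requested {config.to_dict()}")
    model = SegmentationModel(stored)
    model.load_state_dict(state)
    model.eval()
    return model, meta["extra"]
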