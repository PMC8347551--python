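"""Attention Mechanism Block (AMB): channel attention (CAM) followed by a
spatial attention (SAM) whose per-position statistics include, besides the
usual across-channel maximum and mean, the across-channel *mode*.

The mode of continuous activations is defined by per-position equal-width
histogram quantisation: at each pixel the C channel values are binned over
that pixel's own [min, max] range and the midpoint of the most populated bin
is returned (ties resolved toward the bin with the smaller midpoint; a
degenerate range returns the common value).  The statistic is piecewise
constant in its inputs, so it is treated as a constant during
backpropagation — gradients reach the SAM input through the max and mean
branches and through the gated residual path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError
from .nn import functional as F
from .nn.tensor import Tensor

VALID_STATS = ("max", "avg", "mode")


def channel_mode(x, bins: int = 32):
    """Across-channel mode map: (N,C,H,W) -> (N,1,H,W) (or (C,H,W) -> (1,H,W)).

    Accepts an ndarray or a Tensor; a Tensor input yields a *constant*
    Tensor (no gradient path).
    """
    if bins < 2:
        raise ConfigurationError(f"channel_mode needs bins >= 2, got {bins}")
    raw = x.data if isinstance(x, Tensor) else np.asarray(x)
    squeeze = raw.ndim == 3
    if squeeze:
        raw = raw[None]
    arr = raw.astype(np.float64)  # binning is computed in double precision
    n, c, h, w = arr.shape
    lo = arr.min(axis=1, keepdims=True)
    hi = arr.max(axis=1, keepdims=True)
    span = hi - lo
    degenerate = span <= 0
    safe_span = np.where(degenerate, 1.0, span)
    idx = np.floor((arr - lo) / safe_span * bins).astype(np.int64)
    np.clip(idx, 0, bins - 1, out=idx)
    # counts per bin; argmax returns the first (= smallest-midpoint) maximum
    counts = np.empty((n, bins, h, w), dtype=np.int32)
    for b in range(bins):
        counts[:, b] = (idx == b).sum(axis=1)
    modal = counts.argmax(axis=1)[:, None]  # (N,1,H,W)
    width = safe_span / bins
    out = lo + (modal + 0.5) * width
    out = np.where(degenerate, lo, out).astype(raw.dtype)
    if squeeze:
        out = out[0]
    return Tensor(out) if isinstance(x, Tensor) else out


class ChannelAttention(nn.Module):
    """Squeeze-excite channel gating: global average pool, a C -> C/r -> C
    bottleneck with a rectifier between, logistic normalisation, and
    per-channel rescaling of the input."""

    def __init__(self, channels: int, reduction: int = 16):
        super().__init__()
        if channels < reduction:
            raise ConfigurationError(
                f"channel attention needs C >= reduction ratio "
                f"({channels} < {reduction})")
        self.channels = channels
        self.fc1 = nn.Linear(channels, channels // reduction)
        self.fc2 = nn.Linear(channels // reduction, channels)

    def forward_detail(self, a):
        a = nn.as_tensor(a)
        n, c = a.shape[:2]
        pooled = F.reshape(F.global_avg_pool(a), (n, c))
        wc = F.sigmoid(self.fc2(F.relu(self.fc1(pooled))))
        wc = F.reshape(wc, (n, c, 1, 1))
        return wc, F.mul(a, wc)

    def forward(self, a):
        return self.forward_detail(a)[1]


class SpatialAttention(nn.Module):
    """Per-position gating from across-channel statistics.

    ``stats`` selects any nonempty subset of ("max", "avg", "mode"); the
    selected maps are summed element-wise and normalised — softmax over all
    H*W positions by default, or an independent logistic per position — to
    the weight map WP (1 x H x W).  The output adds the gated map back onto
    the input: A'' = A' + WP * A'.
    """

    def __init__(self, stats=VALID_STATS, bins: int = 32,
                 norm: str = "softmax"):
        super().__init__()
        stats = tuple(stats)
        if not stats or any(s not in VALID_STATS for s in stats):
            raise ConfigurationError(
                f"stats must be a nonempty subset of {VALID_STATS}, got {stats}")
        if norm not in ("softmax", "sigmoid"):
            raise ConfigurationError(f"norm must be softmax or sigmoid, got {norm!r}")
        if bins < 2:
            raise ConfigurationError(f"bins must be >= 2, got {bins}")
        self.stats, self.bins, self.norm = stats, bins, norm

    def forward_detail(self, a_p):
        a_p = nn.as_tensor(a_p)
        maps = []
        if "max" in self.stats:
            maps.append(F.channel_max(a_p))
        if "avg" in self.stats:
            maps.append(F.channel_mean(a_p))
        if "mode" in self.stats:
            maps.append(channel_mode(a_p, self.bins))
        summed = maps[0]
        for m in maps[1:]:
            summed = F.add(summed, m)
        if self.norm == "softmax":
            wp = F.spatial_softmax(summed)
        else:
            wp = F.sigmoid(summed)
        a_pp = F.add(a_p, F.mul(a_p, wp))
        return wp, a_pp

    def forward(self, a_p):
        return self.forward_detail(a_p)[1]


@dataclass
class AmbTensors:
    A: Tensor      # C x H x W input (decoder feature after skip fusion)
    WC: Tensor     # C x 1 x 1 channel weights, in [0,1]
    A_p: Tensor    # C x H x W A' = A * WC
    WP: Tensor     # 1 x H x W spatial weights
    A_pp: Tensor   # C x H x W output


class AttentionBlock(nn.Module):
    """CAM and SAM in series, applied to the decoder feature after each
    skip-connection fusion."""

    def __init__(self, channels: int, reduction: int = 16, stats=VALID_STATS,
                 bins: int = 32, norm: str = "softmax"):
        super().__init__()
        self.cam = ChannelAttention(channels, reduction=reduction)
        self.sam = SpatialAttention(stats=stats, bins=bins, norm=norm)

    def forward_detail(self, a) -> AmbTensors:
        a = nn.as_tensor(a)
        wc, a_p = self.cam.forward_detail(a)
        wp, a_pp = self.sam.forward_detail(a_p)
        return AmbTensors(A=a, WC=wc, A_p=a_p, WP=wp, A_pp=a_pp)

    def forward(self, a) -> Tensor:
        return self.forward_detail(a).A_pp
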